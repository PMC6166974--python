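# te-regnet

Did a family of retroviral LTR insertions get co-opted into a tissue-specific
regulatory network?  `te-regnet` implements, as a reusable and fully tested
pipeline, the computational analyses used to ask this question for an LTR
family (THE1B-like elements, 366 bp) and the placenta:

1. **TE-to-gene proximity** — assign TE elements to genes either by a
   10-kb window around the transcription start site (TSS) or by overlap
   with the 20-kb region upstream of the longest transcript
   (windowBed-style half-open interval arithmetic).
2. **Relative coexpression** — for each tissue pair, compare the Pearson
   correlation (on √TPM tissue profiles) of TE-associated genes with that
   of TE-absent genes, `ratio = corr_TE+ / corr_TE−`.  Significance comes
   from resampling size-matched gene sets from the TE-absent pool (5,000
   draws by default); each pair is summarised by the empirical p and the
   odds ratio `(1 − p)/p`.  Ratios below 1 in every pair involving one
   tissue mean TE-associated genes are specifically *divergent* there.
3. **Cross-species enriched-gene calling** — restrict two species to
   1-to-1 orthologs (TPM re-normalised over the retained set), bring
   samples onto a common scale with TMM (trimmed mean of M-values)
   factors, test the focal tissue against every other comparison group
   with the rank product `RP_g = (∏_k rank_k(g))^{1/k}` over all sample
   combinations, estimate a permutation pfp (false-positive proportion)
   per gene, and call genes significant at pfp ≤ 0.15 in **all**
   comparisons.
4. **Binomial TE enrichment** — with background rate p0 = fraction of all
   genes with ≥ 1 TE near the promoter, test whether the enriched set
   carries TE-adjacent genes more often than `Binomial(n, p0)` predicts
   (exact one-sided upper tail).
5. **PWM scanning** — keep TFs expressed at ≥ 10 TPM in all focal-tissue
   samples and scan the TE 5′ insertion-junction sequence with each PWM's
   log2-odds matrix (background-smoothed), reporting windows scoring ≥ 8
   bits on either strand.

A synthetic-data generator (`simulate_bundle`) produces every input the
pipeline consumes — multi-tissue log-normal expression with controllable
cross-tissue correlation, a planted TE-associated gene set that is
up-shifted and divergent in one focal tissue, a second species sharing
orthologs, and TE intervals planted near truth-gene TSSs — so the whole
chain is testable and calibratable without external downloads.

## Worked example

```python
import te_regnet as tr

bundle = tr.simulate_bundle(tr.SimulationConfig(
    seed=1, n_genes=2000, te_fraction=0.1, effect_size=2.0))
results = tr.relative_coexpr_test(bundle.expression, bundle.truth_genes,
                                  n_resamples=5000, seed=17)
for r in results[:4]:
    print(f"{r.tissue_a}/{r.tissue_b}  ratio={r.ratio:.3f} "
          f"p={r.p_empirical:.4f} odds={r.odds_ratio:.0f}")
```

prints

```
placenta/tissue2  ratio=0.235 p=0.0002 odds=5000
placenta/tissue3  ratio=0.070 p=0.0002 odds=5000
placenta/tissue4  ratio=0.153 p=0.0002 odds=5000
placenta/tissue5  ratio=0.196 p=0.0002 odds=5000
```

Every pair involving the focal tissue has its observed ratio far below 1
and below all 5,000 resampled null ratios (p at the floor 1/5001, odds
ratio 5000); pairs not involving placenta hover near ratio 1 with small
odds ratios.  The `examples/` directory walks through each capability the
same way (`python examples/03_relative_coexpression.py` reproduces the
full table above, and `examples/04_enriched_genes.py` prints
`precision 1.00, recall 0.90` for recovering 50 planted placenta-up genes
at FDR 0.15).

## Command line

Each stage is also exposed as a thin CLI over the library:

```bash
te-regnet simulate --seed 1 --n-genes 1000 --out-dir sim/
te-regnet associate --te sim/te.bed --genes sim/genes.gtf --mode tss --out pairs.tsv
te-regnet coexpr --expr sim/expression.tsv --samples sim/samples.tsv \
    --te-genes pairs.tsv --resamples 5000 --seed 17 --out coexpr.tsv
te-regnet run --config pipeline.toml     # all stages, JSON report
```

All stages are deterministic for a fixed seed: identical configuration
gives byte-identical outputs.

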