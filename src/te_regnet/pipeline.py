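"""End-to-end orchestration: associate -> coexpr -> enrich-genes ->
te-enrich (-> pwm-scan when motifs are supplied), over files on disk, with
a machine-readable JSON report.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .association import (pair_by_tss_window, pair_by_upstream_promoter,
                          te_gene_indicator)
from .coexpression import odds_ratio_matrix, relative_coexpr_test
from .enriched import (OrthologMap, call_enriched, rank_product,
                       restrict_to_orthologs, tmm_factors)
from .enrichment import binomial_enrichment
from .expression import ExpressionMatrix
from .pwm import filter_expressed_tfs, junction_sequence, logodds_from_pwm, scan_sequence

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "tissue_enriched_genes",
            "comparison_seeds"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full pipeline run.

    Serialisable to/from a flat TOML table; unknown keys are rejected."""

    expression: str
    samples: str
    te_bed: str
    genes_gtf: str
    out_dir: str
    focal_tissue: str
    expression_b: str | None = None
    samples_b: str | None = None
    orthologs: str | None = None
    motifs: str | None = None
    genome_fasta: str | None = None
    window_kb: float = 10.0
    promoter_kb: float = 20.0
    n_resamples: int = 5000
    fdr_cutoff: float = 0.15
    min_tpm: float = 1.0
    tf_min_tpm: float = 10.0
    pwm_threshold: float = 8.0
    junction_flank_bp: int = 50
    n_perm: int = 100
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def comparison_seeds(seed: int, n: int) -> list[int]:
    """Stable per-comparison child seeds below 2^31."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def tissue_enriched_genes(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    ortholog_map: OrthologMap,
    focal_tissue: str,
    fdr_cutoff: float = 0.15,
    n_perm: int = 100,
    seed: int = 0,
):
    """Call focal-tissue-enriched species-A genes against every other
    species-A tissue and against the species-B focal tissue.

    Restricts both species to 1-to-1 orthologs (TPM re-normalised over the
    retained set), pools all samples on species-A gene ids, TMM-normalises
    across the pooled samples, then runs one rank-product comparison per
    contrast and intersects the significant-up calls.

    Returns (enriched gene set, per-comparison RankProductResult dict,
    TMM factors).
    """
    ra, rb, kept = restrict_to_orthologs(expr_a, expr_b, ortholog_map)
    b_to_a = {b: a for a, b in kept.pairs}
    rb_values = rb.values.rename(index=b_to_a).loc[ra.values.index]
    pooled = pd.concat([ra.values, rb_values], axis=1)
    factors = tmm_factors(pooled)
    norm = pooled.div(factors, axis=1)

    focal_a = ra.samples_of_tissue(focal_tissue)
    focal_b = [s for s in rb.sample_ids
               if rb.tissue_of_sample[s] == focal_tissue]
    if not focal_b:
        raise ValueError(f"species B has no {focal_tissue!r} samples")
    other_tissues = [t for t in ra.tissues if t != focal_tissue]
    contrasts = [(f"{focal_tissue}_vs_{t}", ra.samples_of_tissue(t))
                 for t in other_tissues]
    contrasts.append((f"{focal_tissue}_vs_speciesB_{focal_tissue}", focal_b))
    seeds = comparison_seeds(seed, len(contrasts))
    results = {}
    for (cid, group_b), s in zip(contrasts, seeds):
        results[cid] = rank_product(norm, focal_a, group_b, direction="up",
                                    n_perm=n_perm, seed=s, comparison_id=cid)
    enriched = call_enriched(results, fdr_cutoff,
                             required=[c for c, _ in contrasts])
    return enriched, results, factors


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage the configuration enables; returns the report
    dict (also written to <out_dir>/report.json)."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "parameters": cfg.to_dict(), "stages": {}}

    import contextlib

    @contextlib.contextmanager
    def _stage(name):
        logger.info("stage: %s", name)
        try:
            yield
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    with _stage("load"):
        expr = _io.read_expression_tsv(cfg.expression, cfg.samples)
        te = _io.read_bed6(cfg.te_bed)
        genes = _io.read_gtf(cfg.genes_gtf)

    with _stage("associate"):
        tss_pairs = pair_by_tss_window(te, genes, cfg.window_kb)
        prom_pairs = pair_by_upstream_promoter(te, genes, cfg.promoter_kb)
        _io.write_pairings_tsv(tss_pairs, out / "pairings_tss.tsv")
        _io.write_pairings_tsv(prom_pairs, out / "pairings_promoter.tsv")
        te_genes = sorted({p.gene_id for p in tss_pairs})
        report["stages"]["associate"] = {
            "n_tss_pairings": len(tss_pairs),
            "n_promoter_pairings": len(prom_pairs),
            "n_te_genes_tss": len(te_genes),
            "n_te_genes_promoter": len({p.gene_id for p in prom_pairs}),
        }

    with _stage("coexpr"):
        usable_te = [g for g in te_genes if g in set(expr.gene_ids)]
        results = relative_coexpr_test(
            expr, usable_te, n_resamples=cfg.n_resamples, seed=cfg.seed,
            expressed_min_tpm=cfg.min_tpm)
        coexpr_df = pd.DataFrame([
            {"tissue_a": r.tissue_a, "tissue_b": r.tissue_b,
             "corr_plus": r.corr_te_plus, "corr_minus": r.corr_te_minus,
             "ratio": r.ratio, "p_empirical": r.p_empirical,
             "odds_ratio": r.odds_ratio, "direction": r.direction}
            for r in results])
        coexpr_df.to_csv(out / "coexpression.tsv", sep="\t", index=False,
                         float_format="%.10g")
        orm = odds_ratio_matrix(results)
        orm.to_csv(out / "odds_ratio_matrix.tsv", sep="\t", float_format="%.10g")
        focal_rows = coexpr_df[(coexpr_df.tissue_a == cfg.focal_tissue)
                               | (coexpr_df.tissue_b == cfg.focal_tissue)]
        report["stages"]["coexpr"] = {
            "seed": cfg.seed,
            "n_resamples": cfg.n_resamples,
            "n_te_genes_used": len(usable_te),
            "focal_pairs": focal_rows.drop(columns=["direction"]).to_dict("records"),
        }

    enriched: set[str] | None = None
    if cfg.expression_b and cfg.samples_b and cfg.orthologs:
        with _stage("enrich-genes"):
            expr_b = _io.read_expression_tsv(cfg.expression_b, cfg.samples_b)
            omap = OrthologMap(_io.read_orthologs_tsv(cfg.orthologs))
            enriched, rp_results, factors = tissue_enriched_genes(
                expr, expr_b, omap, cfg.focal_tissue,
                fdr_cutoff=cfg.fdr_cutoff, n_perm=cfg.n_perm, seed=cfg.seed)
            _io.write_gene_list(enriched, out / "enriched_genes.txt")
            report["stages"]["enrich_genes"] = {
                "seed": cfg.seed, "n_perm": cfg.n_perm,
                "n_orthologs_used": len(omap),
                "n_enriched": len(enriched),
                "comparisons": sorted(rp_results),
                "tmm_factors": {s: round(float(f), 6) for s, f in factors.items()},
            }

        with _stage("te-enrich"):
            has_te, counts = te_gene_indicator(prom_pairs, genes)
            testable = sorted(set(enriched) & set(has_te.index))
            if testable:
                enr = binomial_enrichment(has_te, testable)
                _io.write_json_report(enr.to_dict(), out / "te_enrichment.json")
                report["stages"]["te_enrich"] = enr.to_dict()
            else:
                report["stages"]["te_enrich"] = {"note": "no enriched genes to test"}

    if cfg.motifs and cfg.genome_fasta:
        with _stage("pwm-scan"):
            pwms = _io.read_meme_motifs(cfg.motifs)
            genome = _io.read_fasta(cfg.genome_fasta)
            focal_samples = expr.samples_of_tissue(cfg.focal_tissue)
            focal_expr = ExpressionMatrix(
                expr.values[focal_samples],
                expr.tissue_of_sample.loc[focal_samples])
            known_tfs = [p.tf_name for p in pwms if p.tf_name in set(expr.gene_ids)]
            if known_tfs:
                kept_tfs = filter_expressed_tfs(focal_expr, known_tfs, cfg.tf_min_tpm)
                pwms = [p for p in pwms if p.tf_name in kept_tfs]
            hits = []
            for el in te.elements:
                if el.chrom not in genome:
                    continue
                try:
                    seq = junction_sequence(el, genome, cfg.junction_flank_bp)
                except ValueError:
                    continue
                for p in pwms:
                    hits.extend(scan_sequence(
                        seq, logodds_from_pwm(p), cfg.pwm_threshold,
                        sequence_id=f"{el.te_id}_junction", tf_name=p.tf_name))
            pd.DataFrame(
                [(h.tf_name, h.sequence_id, h.offset, h.strand, h.score) for h in hits],
                columns=["tf_name", "sequence_id", "offset", "strand", "score"],
            ).to_csv(out / "pwm_hits.tsv", sep="\t", index=False,
                     float_format="%.6f")
            report["stages"]["pwm_scan"] = {
                "n_motifs_scanned": len(pwms),
                "threshold": cfg.pwm_threshold,
                "n_hits": len(hits),
            }

    _io.write_json_report(report, out / "report.json")
    return report
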