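"""Synthetic multi-tissue expression and TE-annotation generator.

Produces every input the pipeline consumes — two species' TPM matrices with
tissue labels, gene models, a TE annotation, a 1-to-1 ortholog map and a
truth record — with controllable planted effects, so every downstream stage
can be exercised and calibrated without external data.

Expression model (log scale, per gene g and sample s of tissue t):

    log x_gs = m0 + tau_t + f_g + delta_g * [t == focal, g planted] + eps_gs

where f_g ~ N(0, sigma_f^2) is a gene latent shared by all samples and both
species (it induces the cross-tissue and cross-species correlation),
eps_gs ~ N(0, noise_sd^2) is sample noise, and sigma_f is chosen so that the
cross-tissue correlation of per-sample log expression equals ``base_corr``:
sigma_f^2 / (sigma_f^2 + noise_sd^2) = base_corr.  The planted divergence
delta_g = effect_size * noise_sd * (1 + z_g), z_g ~ N(0,1), acts only on
TE-associated truth genes in the focal tissue: its mean shifts the group
mean by effect_size noise-units while its gene-specific spread makes the
truth set genuinely more divergent (a constant shift alone would leave
Pearson correlations unchanged and the coexpression test blind).  Values
are exponentiated and rescaled per sample to TPM (column sum 1e6).

TEs of a fixed element length are planted within the TSS window of every
truth gene; an equal number of background TEs is placed uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import GeneModel, TEAnnotation, TEElement
from .expression import ExpressionMatrix, TPM_SUM

__all__ = ["SimulationConfig", "SyntheticBundle", "simulate_bundle", "write_bundle"]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 1000
    n_tissues: int = 5
    n_samples_per_tissue: int = 1
    te_fraction: float = 0.1
    focal_tissue: str = "placenta"
    effect_size: float = 2.0
    base_corr: float = 0.7
    noise_sd: float = 0.5
    genome_length: int = 50_000_000
    window_kb: float = 10.0
    te_length: int = 366  # THE1B-like element length
    tissue_labels: list[str] | None = None
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if not 0 <= self.te_fraction <= 1:
            raise ValueError("te_fraction must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")
        for name in ("n_genes", "n_samples_per_tissue", "genome_length", "te_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.base_corr < 1:
            raise ValueError("base_corr must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.tissue_labels is None:
            self.tissue_labels = [self.focal_tissue] + [
                f"tissue{i}" for i in range(2, self.n_tissues + 1)]
        if len(self.tissue_labels) != self.n_tissues:
            raise ValueError("tissue_labels length must equal n_tissues")
        if self.focal_tissue not in self.tissue_labels:
            raise ValueError(
                f"focal_tissue {self.focal_tissue!r} not in tissue labels")
        n_truth = int(round(self.te_fraction * self.n_genes))
        if self.n_genes < 2 * n_truth:
            raise ValueError(
                f"n_genes={self.n_genes} < 2 x truth-set size {n_truth}")

    @property
    def n_truth(self) -> int:
        return int(round(self.te_fraction * self.n_genes))


@dataclass
class SyntheticBundle:
    expression: ExpressionMatrix
    expression_b: ExpressionMatrix
    te_annotation: TEAnnotation
    gene_models: list[GeneModel]
    ortholog_map: list[tuple[str, str]]
    truth: pd.DataFrame  # gene_id, te_associated, planted_effect
    config: SimulationConfig = field(repr=False)

    @property
    def truth_genes(self) -> list[str]:
        return list(self.truth.loc[self.truth["te_associated"], "gene_id"])


def _simulate_log_expression(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    gene_latent: np.ndarray,
    planted_delta: np.ndarray | None,
    prefix: str,
) -> ExpressionMatrix:
    tissues = cfg.tissue_labels
    samples, tissue_of_sample = [], {}
    for t in tissues:
        for j in range(cfg.n_samples_per_tissue):
            s = f"{prefix}{t}_s{j + 1}"
            samples.append(s)
            tissue_of_sample[s] = t
    tau = rng.normal(0.0, 0.2, size=len(tissues))
    tau_of_sample = np.array([tau[tissues.index(tissue_of_sample[s])] for s in samples])
    eps = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, len(samples)))
    log_x = 4.0 + tau_of_sample[None, :] + gene_latent[:, None] + eps
    if planted_delta is not None:
        focal_cols = [i for i, s in enumerate(samples)
                      if tissue_of_sample[s] == cfg.focal_tissue]
        log_x[:, focal_cols] += planted_delta[:, None]
    x = np.exp(log_x)
    x *= TPM_SUM / x.sum(axis=0, keepdims=True)
    gene_ids = [f"{'gB' if prefix else 'gA'}{i:05d}" for i in range(cfg.n_genes)]
    values = pd.DataFrame(x, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    return ExpressionMatrix(values, pd.Series(tissue_of_sample))


def simulate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate a full synthetic input bundle from the configuration.

    Identical configuration and seed give bit-identical outputs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, n_truth = cfg.n_genes, cfg.n_truth

    # --- gene models on a single chromosome ------------------------------
    spacing = cfg.genome_length // (n + 1)
    min_span = 2 * (int(cfg.window_kb * 1000) + cfg.te_length) + 1000
    if spacing < min_span:
        raise ValueError(
            f"genome_length too small: gene spacing {spacing} bp < {min_span} bp "
            "needed to keep TSS windows disjoint")
    strands = rng.choice(["+", "-"], size=n)
    tx_lengths = rng.integers(5_000, 20_001, size=n)
    genes: list[GeneModel] = []
    for i in range(n):
        tss = (i + 1) * spacing
        L = int(tx_lengths[i])
        if strands[i] == "+":
            transcripts = [(tss, tss + L)]
        else:
            transcripts = [(tss + 1 - L, tss + 1)]
        # a fraction of genes carry a second, shorter transcript so the
        # longest-transcript rule is exercised
        if rng.random() < 0.3:
            L2 = max(500, L // 2)
            if strands[i] == "+":
                transcripts.append((tss, tss + L2))
            else:
                transcripts.append((tss + 1 - L2, tss + 1))
        genes.append(GeneModel(f"gA{i:05d}", cfg.chrom, strands[i], tuple(transcripts)))

    # --- TE placement ----------------------------------------------------
    truth_idx = np.sort(rng.choice(n, size=n_truth, replace=False))
    truth_ids = {genes[i].gene_id for i in truth_idx}
    span = int(cfg.window_kb * 1000)
    elements: list[TEElement] = []
    for k, gi in enumerate(truth_idx):
        g = genes[gi]
        d = int(rng.integers(0, span + 1))
        upstream = bool(rng.random() < 0.5)
        if upstream and g.tss - d - cfg.te_length >= 0:
            start = g.tss - d - cfg.te_length
        else:
            start = g.tss + d
        elements.append(TEElement(f"te_planted_{k:04d}", cfg.chrom,
                                  start, start + cfg.te_length,
                                  "+" if rng.random() < 0.5 else "-"))
    for k in range(n_truth):
        start = int(rng.integers(0, cfg.genome_length - cfg.te_length))
        elements.append(TEElement(f"te_bg_{k:04d}", cfg.chrom,
                                  start, start + cfg.te_length,
                                  "+" if rng.random() < 0.5 else "-"))

    # --- expression ------------------------------------------------------
    sigma_f = cfg.noise_sd * np.sqrt(cfg.base_corr / (1.0 - cfg.base_corr))
    gene_latent = rng.normal(0.0, sigma_f, size=n)
    delta = np.zeros(n)
    if cfg.effect_size > 0:
        # Strictly-positive per-gene up-shifts for the truth genes in the
        # focal tissue: a firm floor (every planted gene is genuinely up,
        # so rank-based differential expression can recover the whole set)
        # plus a heavy-tailed log-normal spread whose SD equals
        # effect_size * noise_sd — the spread, not the mean, is what makes
        # the set *divergent* in correlation terms (a constant shift would
        # leave Pearson correlations unchanged).
        scale = cfg.effect_size * cfg.noise_sd
        ln_mean, ln_sd = 0.35, 1.0
        sig2 = np.log1p((ln_sd / ln_mean) ** 2)
        mu = np.log(ln_mean) - sig2 / 2
        delta[truth_idx] = scale * (1.1 + rng.lognormal(mu, np.sqrt(sig2), n_truth))
    expr_a = _simulate_log_expression(cfg, rng, gene_latent, delta, prefix="")
    # species B shares the gene latents (orthologs) but not the planted
    # effect: the divergence is species-A-specific
    expr_b = _simulate_log_expression(cfg, rng, gene_latent, None, prefix="B_")

    ortholog_map = [(f"gA{i:05d}", f"gB{i:05d}") for i in range(n)]
    truth = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "te_associated": [g.gene_id in truth_ids for g in genes],
        "planted_effect": [(g.gene_id in truth_ids) and cfg.effect_size > 0
                           for g in genes],
    })
    return SyntheticBundle(expr_a, expr_b, TEAnnotation(elements), genes,
                           ortholog_map, truth, cfg)


def write_bundle(bundle: SyntheticBundle, directory) -> dict[str, Path]:
    """Write every bundle component as plain-text files; round-trips
    losslessly through the io module readers."""
    from . import io as _io

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": d / "expression.tsv",
        "samples": d / "samples.tsv",
        "expression_b": d / "expression_b.tsv",
        "samples_b": d / "samples_b.tsv",
        "te_bed": d / "te.bed",
        "genes_gtf": d / "genes.gtf",
        "orthologs": d / "orthologs.tsv",
        "truth": d / "truth.tsv",
    }
    _io.write_expression_tsv(bundle.expression, paths["expression"], paths["samples"])
    _io.write_expression_tsv(bundle.expression_b, paths["expression_b"], paths["samples_b"])
    _io.write_bed6(bundle.te_annotation, paths["te_bed"])
    _io.write_gtf(bundle.gene_models, paths["genes_gtf"])
    _io.write_orthologs_tsv(bundle.ortholog_map, paths["orthologs"])
    # one row per TE-associated truth gene; absent genes are implicitly
    # non-associated
    truth_rows = bundle.truth[bundle.truth["te_associated"]]
    truth_rows.to_csv(paths["truth"], sep="\t", index=False)
    return paths
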