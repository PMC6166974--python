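"""Relative coexpression of TE-associated genes between tissue pairs.

For a pair of tissues the statistic is the ratio

    ratio = corr_TE+ / corr_TE-

where corr_TE+ is the Pearson correlation, across TE-associated genes, of
the two tissues' expression profiles (sqrt-TPM, per-tissue mean over
samples), and corr_TE- is the same correlation across TE-absent genes.
Under no TE effect the ratio is close to 1; a ratio below 1 means the
TE-associated set is more divergent in expression between the two tissues.

Significance comes from a size-matched resampling null: random gene sets of
size |TE+| are drawn (without replacement) from the TE-absent pool, the
ratio is recomputed with the draw as numerator set and the remaining
TE-absent genes as denominator set, and the observed ratio is ranked within
the null.  The per-pair result is summarised as an odds ratio (1-p)/p.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, sqrt_transform

logger = logging.getLogger(__name__)

__all__ = [
    "CoexprPairResult",
    "tissue_correlation",
    "relative_coexpr_test",
    "odds_ratio_matrix",
    "plot_odds_ratio_heatmap",
]


@dataclass
class CoexprPairResult:
    """Observed ratio, resampling null, and summary for one tissue pair."""

    tissue_a: str
    tissue_b: str
    corr_te_plus: float
    corr_te_minus: float
    ratio: float
    null_ratios: np.ndarray = field(repr=False)
    p_empirical: float
    odds_ratio: float
    direction: str  # side of the null median the observed ratio falls on
    valid: bool = True
    note: str = ""
    p_adjusted: float | None = None  # BH-adjusted across pairs, if requested


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise ValueError("zero-variance profile: correlation undefined")
    return float((xc @ yc) / denom)


def tissue_correlation(
    expr: ExpressionMatrix,
    gene_set,
    tissue_a: str,
    tissue_b: str,
) -> float:
    """Pearson correlation, across ``gene_set``, between the two tissues'
    per-gene mean expression profiles.  ``expr`` is used on its current
    scale — transform first if sqrt-TPM is wanted."""
    gene_set = list(gene_set)
    if len(gene_set) < 3:
        raise ValueError("gene_set must contain at least 3 genes")
    pa = expr.tissue_profile(tissue_a).loc[gene_set].to_numpy()
    pb = expr.tissue_profile(tissue_b).loc[gene_set].to_numpy()
    return _pearson(pa, pb)


def _rowwise_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with the matching row of Y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = (Xc * Yc).sum(axis=1)
    den = np.sqrt((Xc**2).sum(axis=1) * (Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def relative_coexpr_test(
    expr: ExpressionMatrix,
    te_genes,
    n_resamples: int = 5000,
    seed: int = 0,
    expressed_min_tpm: float = 1.0,
    alternative: str = "lower",
    exhaustive: bool = False,
    transform: bool = True,
    bh_adjust: bool = False,
) -> list[CoexprPairResult]:
    """Run the relative-coexpression test for every unordered tissue pair.

    Parameters
    ----------
    expr : ExpressionMatrix
        TPM-scale matrix; the square-root transform is applied internally
        unless ``transform`` is False.
    te_genes : iterable of gene ids
        The TE-associated gene set (numerator pool after the expressed
        filter); must be a subset of ``expr``'s genes.
    n_resamples : int
        Size of the Monte-Carlo null (ignored when ``exhaustive``).
    seed : int
        Seed for the resampling RNG.  The resampled index sets are drawn
        once, before iterating tissue pairs, so the stream does not depend
        on pair order.
    expressed_min_tpm : float
        Expressed-gene filter: keep genes with mean TPM over all samples at
        or above this value.
    alternative : {"lower", "higher", "two-sided"}
        Tail of the null used for the empirical p (default: TE-associated
        genes are *less* coexpressed).
    exhaustive : bool
        Enumerate every size-matched subset of the TE-absent pool instead
        of Monte-Carlo sampling (small instances only).
    """
    if alternative not in ("lower", "higher", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    te_genes = set(te_genes)
    unknown = te_genes - set(expr.gene_ids)
    if unknown:
        raise ValueError(f"te_genes not in expression matrix: {sorted(unknown)[:5]}")

    mean_tpm = expr.values.mean(axis=1)
    expressed = expr.values.index[mean_tpm >= expressed_min_tpm]
    work = expr.subset_genes(expressed)
    if transform:
        work = sqrt_transform(work)

    plus_ids = [g for g in expressed if g in te_genes]
    minus_ids = [g for g in expressed if g not in te_genes]
    k, m = len(plus_ids), len(minus_ids)
    if k < 3 or m - k < 3:
        raise ValueError(
            f"after expressed filter: |TE+|={k}, |TE-|={m}; both the TE+ set "
            "and the null complement need >=3 genes"
        )

    tissues = work.tissues
    if len(tissues) < 2:
        raise ValueError("at least 2 tissues required")
    profiles = pd.DataFrame({t: work.tissue_profile(t) for t in tissues})
    plus = profiles.loc[plus_ids].to_numpy()  # k x T
    minus = profiles.loc[minus_ids].to_numpy()  # m x T

    # Resampled index sets into the TE- pool, drawn once for all pairs.
    if exhaustive:
        combos = list(itertools.combinations(range(m), k))
        idx = np.array(combos, dtype=np.intp)  # B x k
        B = len(combos)
        mask = np.zeros((B, m), dtype=bool)
        mask[np.arange(B)[:, None], idx] = True
        comp = np.nonzero(~mask)[1].reshape(B, m - k)
    else:
        B = int(n_resamples)
        if B < 1:
            raise ValueError("n_resamples must be >= 1")
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((B, m)), axis=1)
        idx = order[:, :k]
        comp = order[:, k:]

    results: list[CoexprPairResult] = []
    for ta, tb in itertools.combinations(tissues, 2):
        pa_plus, pb_plus = plus[:, tissues.index(ta)], plus[:, tissues.index(tb)]
        pa_minus, pb_minus = minus[:, tissues.index(ta)], minus[:, tissues.index(tb)]
        try:
            r_plus = _pearson(pa_plus, pb_plus)
            r_minus = _pearson(pa_minus, pb_minus)
            if r_minus == 0.0:
                raise ValueError("corr_TE- is zero; ratio undefined")
        except ValueError as exc:
            logger.warning("tissue pair (%s, %s) not computed: %s", ta, tb, exc)
            results.append(CoexprPairResult(
                ta, tb, np.nan, np.nan, np.nan, np.array([]),
                np.nan, np.nan, "", valid=False, note=str(exc)))
            continue
        observed = r_plus / r_minus

        num = _rowwise_pearson(pa_minus[idx], pb_minus[idx])
        den = _rowwise_pearson(pa_minus[comp], pb_minus[comp])
        with np.errstate(invalid="ignore", divide="ignore"):
            null = num / den
        null = null[np.isfinite(null)]
        Beff = null.size
        if Beff == 0:
            results.append(CoexprPairResult(
                ta, tb, r_plus, r_minus, observed, null,
                np.nan, np.nan, "", valid=False, note="degenerate null"))
            continue

        p_lower = (1 + int(np.sum(null <= observed))) / (Beff + 1)
        p_higher = (1 + int(np.sum(null >= observed))) / (Beff + 1)
        if alternative == "lower":
            p = p_lower
        elif alternative == "higher":
            p = p_higher
        else:
            p = min(1.0, 2 * min(p_lower, p_higher))
        direction = "lower" if observed < float(np.median(null)) else "higher"
        results.append(CoexprPairResult(
            ta, tb, r_plus, r_minus, observed, null, p, (1 - p) / p, direction))

    if bh_adjust:
        # Benjamini-Hochberg across tissue pairs; off by default since each
        # pair is conventionally reported on its own
        from scipy.stats import false_discovery_control
        valid_idx = [i for i, r in enumerate(results) if r.valid]
        if valid_idx:
            adj = false_discovery_control(
                [results[i].p_empirical for i in valid_idx], method="bh")
            for i, a in zip(valid_idx, adj):
                results[i].p_adjusted = float(a)
    return results


def odds_ratio_matrix(results: list[CoexprPairResult]) -> pd.DataFrame:
    """Symmetric tissue x tissue matrix of per-pair odds ratios.

    Diagonal and any missing/invalid pair are NaN (an explicit gap)."""
    tissues = list(dict.fromkeys(
        t for r in results for t in (r.tissue_a, r.tissue_b)))
    mat = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    for r in results:
        if r.valid:
            mat.loc[r.tissue_a, r.tissue_b] = r.odds_ratio
            mat.loc[r.tissue_b, r.tissue_a] = r.odds_ratio
    return mat


def plot_odds_ratio_heatmap(matrix: pd.DataFrame, path) -> None:
    """Render the odds-ratio matrix as a heat map image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(matrix), 1 + 0.6 * len(matrix)))
    im = ax.imshow(matrix.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(matrix)), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix)), matrix.index)
    for i in range(len(matrix)):
        for j in range(len(matrix)):
            v = matrix.iat[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.3g}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="odds ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
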