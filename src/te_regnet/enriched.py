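"""Cross-species calling of tissue-enriched genes.

The procedure mirrors a standard comparative RNA-seq design: restrict both
species to 1-to-1 orthologs and re-normalise TPM over the retained set,
bring samples onto a common scale with TMM (trimmed mean of M-values)
factors, run a rank-product differential-expression test of the focal
tissue against every other comparison group, estimate a permutation-based
false-positive proportion (pfp) per gene, and call a gene "enriched" when
it is significantly up in *every* comparison at the chosen pfp cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import ExpressionMatrix, TPM_SUM

__all__ = [
    "OrthologMap",
    "RankProductResult",
    "tpm_from_counts",
    "restrict_to_orthologs",
    "tmm_factors",
    "rank_product",
    "call_enriched",
]


@dataclass
class OrthologMap:
    """Strict 1-to-1 ortholog pairs between two species."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        a = [p[0] for p in self.pairs]
        b = [p[1] for p in self.pairs]
        if len(set(a)) != len(a) or len(set(b)) != len(b):
            raise ValueError("ortholog map is not 1-to-1: duplicated gene id")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class RankProductResult:
    """Per-gene rank products and permutation pfp for one comparison.

    ``table`` is indexed by gene id with columns ``rank_product`` and
    ``pfp``; ``direction`` is the tested alternative ("up" = higher in
    group A).
    """

    comparison_id: str
    direction: str
    table: pd.DataFrame
    n_perm: int

    def significant(self, pfp_cutoff: float) -> set[str]:
        return set(self.table.index[self.table["pfp"] <= pfp_cutoff])


def tpm_from_counts(
    counts: pd.DataFrame,
    effective_lengths: pd.Series,
    tissue_of_sample: pd.Series | None = None,
) -> ExpressionMatrix:
    """Convert a count matrix to TPM given per-gene effective lengths.

    TPM_g = (count_g / length_g) / sum_g'(count_g' / length_g') * 1e6,
    per sample.
    """
    lengths = pd.Series(effective_lengths).loc[counts.index]
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    dead = totals[totals == 0]
    if len(dead):
        raise ValueError(f"all-zero sample(s): {list(dead.index)}")
    tpm = rates.div(totals, axis=1) * TPM_SUM
    if tissue_of_sample is None:
        tissue_of_sample = pd.Series(list(counts.columns), index=counts.columns)
    return ExpressionMatrix(tpm, tissue_of_sample)


def restrict_to_orthologs(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    ortholog_map: OrthologMap,
) -> tuple[ExpressionMatrix, ExpressionMatrix, OrthologMap]:
    """Restrict both matrices to resolvable 1-to-1 ortholog pairs, row-align
    them in pair order, and re-normalise each sample's TPM to sum 1e6 over
    the retained set."""
    genes_a = set(expr_a.gene_ids)
    genes_b = set(expr_b.gene_ids)
    kept = [(a, b) for a, b in ortholog_map.pairs if a in genes_a and b in genes_b]
    dropped = len(ortholog_map) - len(kept)
    if dropped:
        import logging
        logging.getLogger(__name__).warning(
            "%d ortholog pairs unresolvable in the matrices; dropped", dropped)
    if not kept:
        raise ValueError("no ortholog pair resolvable in both matrices")

    def _renorm(expr: ExpressionMatrix, ids: list[str]) -> ExpressionMatrix:
        sub = expr.values.loc[ids]
        totals = sub.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total after ortholog restriction")
        return ExpressionMatrix(sub.div(totals, axis=1) * TPM_SUM, expr.tissue_of_sample)

    out_a = _renorm(expr_a, [a for a, _ in kept])
    out_b = _renorm(expr_b, [b for _, b in kept])
    return out_a, out_b, OrthologMap(kept)


def tmm_factors(
    values: pd.DataFrame,
    reference: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors.

    For each sample j against the reference r, over genes positive in both,
    M = log2(x_j) - log2(x_r) and A = (log2-abundance mean); the most
    extreme ``trim_m`` of M and ``trim_a`` of A are trimmed from each tail
    and the factor is 2^(precision-weighted mean of the surviving M),
    with weights from the delta-method variance 1/((N-x)/(N x)) summed over
    the two samples (N = sample total).  Factors are rescaled so their
    geometric mean is 1.  M is computed on the values as given — the input
    is expected to be TPM, already on a common library scale, so the
    factors capture composition and residual scale differences.

    ``reference=None`` picks the sample whose upper-quartile expression is
    closest to the mean upper quartile.
    """
    if values.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    X = values.to_numpy(dtype=float)
    samples = list(values.columns)
    if reference is None:
        uq = np.nanquantile(np.where(X > 0, X, np.nan), 0.75, axis=0)
        reference = samples[int(np.argmin(np.abs(uq - uq.mean())))]
    if reference not in samples:
        raise KeyError(f"reference sample {reference!r} not in matrix")
    ref = values[reference].to_numpy(dtype=float)
    n_ref = ref.sum()
    factors = {}
    for j, s in enumerate(samples):
        x = X[:, j]
        if s == reference:
            factors[s] = 1.0
            continue
        ok = (x > 0) & (ref > 0)
        xs, rs = x[ok], ref[ok]
        n_x = x.sum()
        M = np.log2(xs) - np.log2(rs)
        A = 0.5 * (np.log2(xs) + np.log2(rs))
        n = M.size
        lo_m = int(np.floor(n * trim_m)) + 1
        hi_m = n + 1 - lo_m
        lo_a = int(np.floor(n * trim_a)) + 1
        hi_a = n + 1 - lo_a
        rM = rankdata(M, method="ordinal")
        rA = rankdata(A, method="ordinal")
        keep = (rM >= lo_m) & (rM <= hi_m) & (rA >= lo_a) & (rA <= hi_a)
        if keep.sum() < 2:
            raise ValueError(
                f"sample {s!r}: only {int(keep.sum())} genes survive trimming")
        if keep.sum() < 10:
            import logging
            logging.getLogger(__name__).warning(
                "sample %r: only %d genes survive trimming; factor unstable",
                s, int(keep.sum()))
        var = (n_x - xs[keep]) / (n_x * xs[keep]) + (n_ref - rs[keep]) / (n_ref * rs[keep])
        w = 1.0 / var
        factors[s] = float(2.0 ** (np.sum(w * M[keep]) / np.sum(w)))
    f = pd.Series(factors).loc[samples]
    return f / np.exp(np.log(f).mean())


def rank_product(
    values: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    direction: str = "up",
    n_perm: int = 100,
    seed: int = 0,
    comparison_id: str | None = None,
    pseudocount: float = 1e-8,
) -> RankProductResult:
    """Rank-product differential expression of group A against group B.

    For every (a, b) sample combination genes are ranked by fold change in
    the requested direction (rank 1 = strongest); the rank product is the
    geometric mean of a gene's ranks over all combinations.  The pfp
    (expected proportion of false positives) is estimated by ``n_perm``
    permutations in which each sample's gene labels are shuffled
    independently; ties in fold change receive average ranks.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10 for a stable pfp")
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    A = values[list(group_a)].to_numpy(dtype=float)
    Bm = values[list(group_b)].to_numpy(dtype=float)
    G = values.shape[0]
    sign = 1.0 if direction == "up" else -1.0

    def _log_rp(Am: np.ndarray, Bmat: np.ndarray) -> np.ndarray:
        la = np.log2(Am + pseudocount)
        lb = np.log2(Bmat + pseudocount)
        # G x (nA*nB) fold-change matrix over all sample combinations
        fc = sign * (la[:, :, None] - lb[:, None, :]).reshape(G, -1)
        ranks = rankdata(-fc, method="average", axis=0)
        return np.log(ranks).mean(axis=1)

    log_rp_obs = _log_rp(A, Bm)
    rp_obs = np.exp(log_rp_obs)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([A, Bm], axis=1)
    n_a = A.shape[1]
    exceed = np.zeros(G)
    order = np.argsort(log_rp_obs, kind="stable")
    sorted_obs = log_rp_obs[order]
    for _ in range(n_perm):
        shuf = np.argsort(rng.random((G, pooled.shape[1])), axis=0)
        perm = np.take_along_axis(pooled, shuf, axis=0)
        null = _log_rp(perm[:, :n_a], perm[:, n_a:])
        # count, for each observed RP (ascending), how many null RPs are <=
        exceed += np.searchsorted(np.sort(null), sorted_obs, side="right")
    expected_fp = exceed / n_perm
    pfp_sorted = expected_fp / np.arange(1, G + 1)
    pfp_sorted = np.maximum.accumulate(pfp_sorted)  # enforce monotonicity
    pfp = np.empty(G)
    pfp[order] = pfp_sorted
    table = pd.DataFrame(
        {"rank_product": rp_obs, "pfp": pfp}, index=values.index)
    return RankProductResult(
        comparison_id or f"{group_a[0]}_vs_{group_b[0]}", direction, table, n_perm)


def call_enriched(
    results: dict[str, RankProductResult],
    fdr_cutoff: float = 0.15,
    required: list[str] | None = None,
) -> set[str]:
    """Genes significantly up (pfp <= cutoff, direction 'up') in *every*
    comparison — the intersection across all supplied results."""
    if required is not None:
        missing = [c for c in required if c not in results]
        if missing:
            raise ValueError(f"missing comparisons: {missing}")
    if not results:
        raise ValueError("no comparisons supplied")
    wrong = [c for c, r in results.items() if r.direction != "up"]
    if wrong:
        raise ValueError(f"comparisons not run with direction='up': {wrong}")
    return set.intersection(*(r.significant(fdr_cutoff) for r in results.values()))
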