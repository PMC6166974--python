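"""Binomial test for TE over-representation near enriched genes.

The background rate p0 is the fraction of all genes with at least one
nearby TE; the test asks whether the enriched-gene set carries TE-adjacent
genes more often than Binomial(n_enriched, p0) predicts (one-sided upper
tail by default, since the hypothesis is over-representation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "binom_upper_tail", "binomial_enrichment"]


@dataclass
class EnrichmentResult:
    n_all_genes: int
    n_all_with_te: int
    background_rate: float
    n_enriched: int
    k_enriched_with_te: int
    p_value: float
    fold: float
    alternative: str = "greater"

    def to_dict(self) -> dict:
        return {
            "n_all_genes": self.n_all_genes,
            "n_all_with_te": self.n_all_with_te,
            "background_rate": self.background_rate,
            "n_enriched": self.n_enriched,
            "k_enriched_with_te": self.k_enriched_with_te,
            "p_value": self.p_value,
            "fold": self.fold,
            "alternative": self.alternative,
        }


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by exact log-space summation of
    the tail terms (no normal approximation)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if k == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    j = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
        + j * np.log(p) + (n - j) * np.log1p(-p)
    )
    m = log_terms.max()
    return float(min(1.0, np.exp(m) * np.exp(log_terms - m).sum()))


def binomial_enrichment(
    indicator: pd.Series,
    enriched,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Test TE over-representation in ``enriched`` against the whole-universe
    background rate.

    Parameters
    ----------
    indicator : pandas.Series of bool
        Per-gene "has >=1 nearby TE" over the full gene universe.
    enriched : iterable of gene ids
        Gene set to test; must be a subset of the indicator's index.
    alternative : {"greater", "two-sided"}
        Upper-tail (over-representation) by default.
    """
    enriched = list(dict.fromkeys(enriched))
    unknown = [g for g in enriched if g not in indicator.index]
    if unknown:
        raise ValueError(f"enriched genes outside the universe: {unknown[:5]}")
    if not enriched:
        raise ValueError("enriched set is empty")
    n_all = int(indicator.size)
    n_with = int(indicator.sum())
    p0 = n_with / n_all
    n = len(enriched)
    k = int(indicator.loc[enriched].sum())
    if p0 == 0.0 and k > 0:
        logger.warning("background rate is 0 but enriched set has TE genes; "
                       "binomial model violated, reporting p=0")
        p = 0.0
    else:
        p = binom_upper_tail(k, n, p0)
        if alternative == "two-sided":
            lower = 1.0 - binom_upper_tail(k + 1, n, p0) if k < n else 1.0
            p = min(1.0, 2 * min(p, lower))
        elif alternative != "greater":
            raise ValueError(f"unknown alternative {alternative!r}")
    fold = (k / n) / p0 if p0 > 0 else float("inf")
    return EnrichmentResult(n_all, n_with, p0, n, k, p, fold, alternative)
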