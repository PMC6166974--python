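"""Calibration experiments at the package's standard study conditions.

Each function runs a replicated synthetic experiment end to end — generate
a bundle, run the statistic under test, score against the bundle's truth
record — and returns summary numbers.  They power the statistical
validation suite and the reproduction script; problem sizes are the
package's standard conditions (see docs/methods.md) and every function is
fully seeded.

Seeding: each replicate r of an experiment with base seed s uses bundle
seed ``child_seed(s, tag, r)`` and an independent test seed, so experiments
are reproducible and replicates independent.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest

from .coexpression import odds_ratio_matrix, relative_coexpr_test
from .enriched import OrthologMap
from .pipeline import tissue_enriched_genes
from .simulate import SimulationConfig, simulate_bundle

__all__ = [
    "child_seed",
    "null_coexpression_calibration",
    "focal_pattern_recovery",
    "enriched_gene_recovery",
    "null_enriched_calls",
]

_MOD = 2**31


def child_seed(base: int, tag: str, replicate: int) -> int:
    """Deterministic per-replicate seed below 2^31."""
    h = np.uint64(base)
    for ch in f"{tag}:{replicate}":
        h = np.uint64((int(h) * 1000003 + ord(ch)) % (2**61 - 1))
    return int(h % _MOD)


def null_coexpression_calibration(
    seed: int,
    n_bundles: int = 200,
    n_genes: int = 1000,
    n_tissues: int = 5,
    n_resamples: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Type-I behaviour of the relative-coexpression test.

    Simulates ``n_bundles`` null bundles (effect_size=0) and runs the test,
    recording the empirical p of one fixed tissue pair per bundle (the
    first pair, so draws are independent Bernoulli under the null).
    Returns the rejection rate at ``alpha`` and a Kolmogorov-Smirnov
    uniformity p-value over the collected p-values.
    """
    ps = []
    for r in range(n_bundles):
        cfg = SimulationConfig(seed=child_seed(seed, "nullsim", r),
                               n_genes=n_genes, n_tissues=n_tissues,
                               te_fraction=0.1, effect_size=0.0)
        bundle = simulate_bundle(cfg)
        res = relative_coexpr_test(
            bundle.expression, bundle.truth_genes,
            n_resamples=n_resamples, seed=child_seed(seed, "nulltest", r))
        ps.append(res[0].p_empirical)
    ps = np.asarray(ps)
    return {
        "p_values": ps,
        "rejection_rate": float(np.mean(ps <= alpha)),
        "ks_uniform_p": float(kstest(ps, "uniform").pvalue),
    }


def focal_pattern_recovery(
    seed: int,
    n_replicates: int = 50,
    n_genes: int = 2000,
    n_tissues: int = 5,
    te_fraction: float = 0.1,
    effect_size: float = 2.0,
    n_resamples: int = 500,
    p_threshold: float = 0.01,
) -> dict:
    """Power of the relative-coexpression test to recover the focal-tissue
    pattern: in each replicate, success means every tissue pair involving
    the focal tissue has empirical p <= ``p_threshold`` AND the focal
    tissue's row of the odds-ratio matrix has the largest row mean."""
    n_success = n_p_ok = n_row_ok = 0
    for r in range(n_replicates):
        cfg = SimulationConfig(seed=child_seed(seed, "powsim", r),
                               n_genes=n_genes, n_tissues=n_tissues,
                               te_fraction=te_fraction, effect_size=effect_size)
        bundle = simulate_bundle(cfg)
        res = relative_coexpr_test(
            bundle.expression, bundle.truth_genes,
            n_resamples=n_resamples, seed=child_seed(seed, "powtest", r))
        focal = cfg.focal_tissue
        p_ok = all(x.p_empirical <= p_threshold for x in res
                   if focal in (x.tissue_a, x.tissue_b))
        matrix = odds_ratio_matrix(res)
        row_ok = matrix.mean(axis=1).idxmax() == focal
        n_p_ok += p_ok
        n_row_ok += row_ok
        n_success += p_ok and row_ok
    return {"n_replicates": n_replicates, "n_success": n_success,
            "n_all_focal_p_significant": n_p_ok, "n_focal_row_maximal": n_row_ok}


def _recovery_replicate(seed_sim: int, seed_test: int, effect_size: float,
                        n_genes: int, fdr_cutoff: float, n_perm: int):
    cfg = SimulationConfig(seed=seed_sim, n_genes=n_genes, n_tissues=5,
                           n_samples_per_tissue=8, te_fraction=0.05,
                           effect_size=effect_size)
    bundle = simulate_bundle(cfg)
    enriched, _, _ = tissue_enriched_genes(
        bundle.expression, bundle.expression_b,
        OrthologMap(bundle.ortholog_map), cfg.focal_tissue,
        fdr_cutoff=fdr_cutoff, n_perm=n_perm, seed=seed_test)
    truth = set(bundle.truth.loc[bundle.truth["te_associated"], "gene_id"])
    return enriched, truth


def enriched_gene_recovery(
    seed: int,
    n_replicates: int = 50,
    n_genes: int = 1000,
    effect_size: float = 2.0,
    fdr_cutoff: float = 0.15,
    n_perm: int = 100,
) -> dict:
    """Precision/recall of cross-species enriched-gene calling against the
    planted truth set (50 planted genes at the standard conditions)."""
    precs, recs = [], []
    for r in range(n_replicates):
        enriched, truth = _recovery_replicate(
            child_seed(seed, "desim", r), child_seed(seed, "detest", r),
            effect_size, n_genes, fdr_cutoff, n_perm)
        tp = len(enriched & truth)
        precs.append(tp / len(enriched) if enriched else 1.0)
        recs.append(tp / len(truth))
    return {"median_precision": float(np.median(precs)),
            "median_recall": float(np.median(recs)),
            "n_replicates": n_replicates}


def null_enriched_calls(
    seed: int,
    n_replicates: int = 15,
    n_genes: int = 1000,
    fdr_cutoff: float = 0.15,
    n_perm: int = 100,
) -> dict:
    """Number of enriched-gene calls when no effect is planted."""
    counts = []
    for r in range(n_replicates):
        enriched, truth = _recovery_replicate(
            child_seed(seed, "de0sim", r), child_seed(seed, "de0test", r),
            0.0, n_genes, fdr_cutoff, n_perm)
        counts.append(len(enriched))
    return {"median_calls": float(np.median(counts)),
            "planted_count": 50, "n_replicates": n_replicates}
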