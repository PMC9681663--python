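"""Permutation-based spatial modulation test and place-cell classification.

For each unit, the observed statistic per bin is the trial-averaged
firing rate over the 18 spatio-temporal bins. Each surrogate shuffles the
18 (occupancy, spike-count) bin pairs independently within every trial —
occupancy travels with its spike count, so surrogate rates remain valid
rates — and re-averages across trials. One-sided p-values use the add-one
estimator p = (1 + #{surrogate >= observed}) / (1 + n_perm), so the
smallest attainable p is 1/(n_perm + 1).

Significance across a unit's 18 bins is corrected with the
Benjamini-Hochberg step-up at q = 0.05 (the FDR family is the single
unit's bins). A unit is a place cell if at least one of the 15 spatial
bins — the reward-lock temporal bins do not count — survives correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .units import N_SPATIAL_BINS, RateMap18


@dataclass
class PermutationResult:
    observed: np.ndarray       # trial-mean rate per bin
    pvalues: np.ndarray        # one-sided, per bin
    n_permutations: int
    rejected: np.ndarray       # FDR mask per bin
    is_place_cell: bool
    seed: int


def permutation_pvalues(
    rate_map: RateMap18, n_perm: int = 10_000, seed: int = 0
) -> np.ndarray:
    """One-sided per-bin p-values from within-trial bin shuffles."""
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    occ, cnt = rate_map.occupancy, rate_map.counts
    n_tr, n_bins = occ.shape
    if n_tr < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(occ > 0, cnt / occ, np.nan)
    observed = np.nanmean(rates, axis=0)

    # valid bins per trial travel together under the shuffle; NaN bins are
    # excluded pairwise from the across-trial average
    exceed = np.zeros(n_bins)
    # permute bin indices per (surrogate, trial); chunk surrogates to bound memory
    chunk = max(1, min(n_perm, 2_000_000 // (n_tr * n_bins)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(
            np.broadcast_to(np.arange(n_bins), (m, n_tr, n_bins)).copy(), axis=2
        )
        occ_s = np.take_along_axis(np.broadcast_to(occ, (m, n_tr, n_bins)), perm, axis=2)
        cnt_s = np.take_along_axis(np.broadcast_to(cnt, (m, n_tr, n_bins)), perm, axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_s = np.where(occ_s > 0, cnt_s / occ_s, np.nan)
        surrogate = np.nanmean(r_s, axis=1)  # (m, 18)
        exceed += np.nansum(surrogate >= observed[None, :], axis=0)
        done += m
    return (1.0 + exceed) / (1.0 + n_perm)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def classify_place_cell(rejected: np.ndarray) -> bool:
    """Place cell iff any of the 15 spatial bins is rejected."""
    rejected = np.asarray(rejected, dtype=bool)
    return bool(rejected[:N_SPATIAL_BINS].any())


def place_cell_test(
    rate_map: RateMap18, n_perm: int = 10_000, q: float = 0.05, seed: int = 0
) -> PermutationResult:
    """Full pipeline: permutation p-values -> BH FDR -> place-cell flag."""
    p = permutation_pvalues(rate_map, n_perm=n_perm, seed=seed)
    rejected = bh_fdr(p, q=q)
    return PermutationResult(
        observed=rate_map.trial_mean,
        pvalues=p,
        n_permutations=n_perm,
        rejected=rejected,
        is_place_cell=classify_place_cell(rejected),
        seed=seed,
    )
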