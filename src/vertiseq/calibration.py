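"""Replicate-cohort calibration experiments for the WR statistic.

These helpers run the full simulate -> per-OTU Fisher scan -> WR chain over
many replicate cohorts.  They back both the test suite's calibration checks
and the reproduction script.
"""

from __future__ import annotations

import math

import numpy as np

from .synthetic import CohortConfig, simulate_cohort
from .transfer import transfer_scan, weighted_ratio, wr_permutation_test


def _cohort_tables(cfg: CohortConfig, compartment: str):
    table, _, _, _ = simulate_cohort(cfg)
    vaginal_birth = table.select(compartment="vaginal", timepoint="birth")
    child = table.select(compartment=compartment)
    return vaginal_birth, child


def observed_wr(cfg: CohortConfig, compartment: str = "feces") -> float:
    """Simulate one cohort and compute the observed WR for one compartment."""
    vaginal_birth, child = _cohort_tables(cfg, compartment)
    return weighted_ratio(transfer_scan(vaginal_birth, child))


def replicate_seeds(seed: int, n_reps: int) -> np.ndarray:
    """Derive per-replicate seeds (< 2^31) from one master seed."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n_reps)


def null_wr_replicates(n_reps: int = 200, seed: int = 1,
                       compartment: str = "feces",
                       n_perm: int | None = None,
                       **config_overrides) -> dict:
    """Observed WR (and optionally permutation p) across null cohorts.

    Cohorts use the shallow-depth preset (median 2000 reads), 57 dyads and
    300 OTUs with transfer_pi = 0 unless overridden.  When ``n_perm`` is
    given, the full permutation test runs per replicate and its p-values are
    returned alongside the observed WR values.
    """
    seeds = replicate_seeds(seed, n_reps)
    wrs, pvals = [], []
    for s in seeds:
        cfg = CohortConfig.test_preset(transfer_pi=0.0, seed=int(s), **config_overrides)
        vaginal_birth, child = _cohort_tables(cfg, compartment)
        if n_perm is None:
            wrs.append(weighted_ratio(transfer_scan(vaginal_birth, child)))
        else:
            res = wr_permutation_test(vaginal_birth, child, n_perm=n_perm, seed=int(s))
            wrs.append(res.observed)
            pvals.append(res.p_value)
    wrs = np.asarray(wrs)
    finite = wrs[np.isfinite(wrs)]
    out = {"wr": wrs, "mean_wr": float(finite.mean()), "n": n_reps}
    if n_perm is not None:
        out["p_values"] = np.asarray(pvals)
    return out


def wr_recovery(n_pairs: int = 50, seed: int = 1, transfer_pi: float = 0.3,
                compartment: str = "feces", n_perm: int | None = None,
                **config_overrides) -> dict:
    """Paired null/signal cohorts sharing seeds: does WR rise with transfer?

    Returns per-pair WR under transfer_pi = 0 and under the signal mixing
    weight, plus the fraction of pairs where the signal WR is larger.
    """
    seeds = replicate_seeds(seed, n_pairs)
    wr0, wr1, p0, p1 = [], [], [], []
    for s in seeds:
        for pi, wr_list, p_list in ((0.0, wr0, p0), (transfer_pi, wr1, p1)):
            cfg = CohortConfig.test_preset(transfer_pi=pi, seed=int(s), **config_overrides)
            vaginal_birth, child = _cohort_tables(cfg, compartment)
            if n_perm is None:
                wr_list.append(weighted_ratio(transfer_scan(vaginal_birth, child)))
            else:
                res = wr_permutation_test(vaginal_birth, child, n_perm=n_perm, seed=int(s))
                wr_list.append(res.observed)
                p_list.append(res.p_value)
    wr0, wr1 = np.asarray(wr0), np.asarray(wr1)
    wins = wr1 > wr0
    out = {"wr_null": wr0, "wr_signal": wr1,
           "fraction_signal_wins": float(wins.mean()), "n_pairs": n_pairs}
    if n_perm is not None:
        out["p_null"] = np.asarray(p0)
        out["p_signal"] = np.asarray(p1)
        out["median_p_null"] = float(np.median(p0))
        out["median_p_signal"] = float(np.median(p1))
    return out
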