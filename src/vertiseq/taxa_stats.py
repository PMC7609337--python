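"""Genus-level abundance testing across pregnancy timepoints with FDR control.

Rank-based tests only: Kruskal-Wallis across the three vaginal timepoints,
paired Wilcoxon signed-rank (within mother) for two-timepoint contrasts,
and Benjamini-Hochberg q-values computed within the selected top-abundance
genus set.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sst
from statsmodels.stats.multitest import multipletests

from .data_model import CompositionTable, VAGINAL_TIMEPOINTS
from .diversity import DistanceMatrix, permanova

log = logging.getLogger(__name__)


@dataclass
class TaxonTestResult:
    """Per-genus timepoint comparison."""

    taxon: str
    summaries: dict[str, tuple[float, float, float]]  # timepoint -> (median, q1, q3)
    test: str
    p_value: float
    q_value: float
    direction: str                                    # increasing | decreasing | none
    pairwise: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.q_value <= 1):
            raise ValueError("q must lie in [0, 1]")


def _paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired signed-rank p; exact for n <= 25 (zeros dropped)."""
    diff = x - y
    diff = diff[diff != 0]
    if diff.size == 0:
        return 1.0
    method = "exact" if diff.size <= 25 else "approx"
    try:
        return float(sst.wilcoxon(diff, method=method, correction=(method == "approx")).pvalue)
    except ValueError:
        return 1.0


def genus_timepoint_tests(comp: CompositionTable, top_n: int = 15) -> list[TaxonTestResult]:
    """Kruskal-Wallis + paired Wilcoxon for the most abundant vaginal genera.

    ``comp`` must be a genus-aggregated vaginal composition table covering
    all three timepoints.  The ``top_n`` genera by mean relative abundance
    define the test family for Benjamini-Hochberg q-values.  Mothers lacking
    a timepoint are dropped from the affected paired contrast (logged).
    """
    meta = comp.metadata
    present_tp = [tp for tp in VAGINAL_TIMEPOINTS if (meta["timepoint"] == tp).any()]
    if len(present_tp) < 3:
        raise ValueError("need samples at w24, w36 and birth")
    props = comp.proportions
    top = props.mean(axis=1).sort_values(ascending=False).head(top_n).index.tolist()

    by_tp = {tp: meta.index[meta["timepoint"] == tp] for tp in VAGINAL_TIMEPOINTS}
    results: list[TaxonTestResult] = []
    pvals = []
    for taxon in top:
        groups = [props.loc[taxon, by_tp[tp]].to_numpy() for tp in VAGINAL_TIMEPOINTS]
        if np.ptp(np.concatenate(groups)) == 0:
            p = 1.0
        else:
            p = float(sst.kruskal(*groups).pvalue)
        pvals.append(p)
        summaries = {}
        for tp, g in zip(VAGINAL_TIMEPOINTS, groups):
            summaries[tp] = (float(np.median(g)), float(np.quantile(g, 0.25)),
                             float(np.quantile(g, 0.75)))
        medians = [summaries[tp][0] for tp in VAGINAL_TIMEPOINTS]
        if medians[0] < medians[1] < medians[2]:
            direction = "increasing"
        elif medians[0] > medians[1] > medians[2]:
            direction = "decreasing"
        else:
            direction = "none"
        pairwise = {}
        for tp_a, tp_b in itertools.combinations(VAGINAL_TIMEPOINTS, 2):
            sub_a = meta.loc[by_tp[tp_a]]
            sub_b = meta.loc[by_tp[tp_b]]
            shared = sorted(set(sub_a["subject_id"]) & set(sub_b["subject_id"]))
            dropped = (set(sub_a["subject_id"]) | set(sub_b["subject_id"])) - set(shared)
            if dropped:
                log.info("pairwise %s vs %s: dropped mothers without both samples: %s",
                         tp_a, tp_b, sorted(dropped))
            xa = np.array([float(props.loc[taxon, sub_a.index[sub_a["subject_id"] == s][0]])
                           for s in shared])
            xb = np.array([float(props.loc[taxon, sub_b.index[sub_b["subject_id"] == s][0]])
                           for s in shared])
            pairwise[f"{tp_a}_vs_{tp_b}"] = _paired_wilcoxon(xa, xb)
        results.append(TaxonTestResult(taxon, summaries, "kruskal_wallis", p, 1.0,
                                       direction, pairwise))
    qvals = multipletests(pvals, method="fdr_bh")[1]
    for res, q in zip(results, qvals):
        res.q_value = float(q)
    return results


def log_display_transform(x: float | np.ndarray, pseudocount: float = 1e-6):
    """log10(x + pseudocount); display-only transform, never used in tests."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    out = np.log10(x + pseudocount)
    return float(out) if out.ndim == 0 else out


@dataclass
class CovariateAssociation:
    """Per-genus, alpha and beta associations of one maternal covariate."""

    genus_table: pd.DataFrame        # genus, test, statistic, p, q
    alpha_table: pd.DataFrame | None  # metric, test, statistic, p
    beta_result: pd.DataFrame | None  # single-term permanova table


def covariate_association(comp: CompositionTable, covariate: pd.Series,
                          alpha_values: pd.DataFrame | None = None,
                          dist: DistanceMatrix | None = None,
                          n_perm: int = 999, seed: int = 0) -> CovariateAssociation:
    """Associate a per-mother covariate with birth-sample microbiota.

    Numeric covariates use Spearman correlation; categorical ones use
    Kruskal-Wallis.  BH q-values are computed across the tested genera.
    ``alpha_values`` (samples x metrics) and ``dist`` extend the report to
    alpha diversity and to a single-term PERMANOVA on beta diversity.
    """
    cov = covariate.loc[[c for c in comp.sample_ids]]
    numeric = pd.api.types.is_numeric_dtype(cov)
    if cov.nunique() < 2:
        raise ValueError("constant covariate")

    def _assoc(values: np.ndarray) -> tuple[str, float, float]:
        if numeric:
            rho, p = sst.spearmanr(cov.to_numpy(dtype=float), values)
            return "spearman", float(rho), float(p)
        groups = [values[(cov == lev).to_numpy()] for lev in cov.unique()]
        try:
            stat = sst.kruskal(*groups)
            return "kruskal_wallis", float(stat.statistic), float(stat.pvalue)
        except ValueError:
            return "kruskal_wallis", float("nan"), 1.0

    rows = []
    for genus in comp.proportions.index:
        test, statv, p = _assoc(comp.proportions.loc[genus].to_numpy())
        rows.append((genus, test, statv, p))
    gt = pd.DataFrame(rows, columns=["genus", "test", "statistic", "p"])
    gt["q"] = multipletests(gt["p"].fillna(1.0), method="fdr_bh")[1]

    at = None
    if alpha_values is not None:
        arows = []
        for metric in alpha_values.columns:
            test, statv, p = _assoc(alpha_values.loc[comp.sample_ids, metric].to_numpy())
            arows.append((metric, test, statv, p))
        at = pd.DataFrame(arows, columns=["metric", "test", "statistic", "p"])

    bt = None
    if dist is not None:
        term = cov if numeric else cov.astype(str)
        vd = permanova(dist, {"covariate": term}, n_perm=n_perm, seed=seed)
        bt = vd.table
    return CovariateAssociation(gt, at, bt)
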