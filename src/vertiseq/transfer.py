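"""Mother-to-child vertical-transfer analysis.

For one child compartment (feces or airway), every OTU whose presence count
lies strictly between 0 and n on both the maternal (vaginal-at-birth) and
child margins gets a 2x2 dyad table (mother presence x child presence), a
sample odds ratio (Haldane-Anscombe corrected when a cell is zero) and a
two-sided Fisher exact p-value.  The per-OTU results are summarized by the
weighted ratio

    WR = sum_{OR_i > 1} log(OR_i) * log(p_i)
         / sum_{OR_i < 1} -log(OR_i) * log(p_i)

whose expectation is 1 when mother and child carriage are unrelated.  A
null distribution is built by scrambling the mother-child pairing (uniform
permutations, identity allowed) and re-running the full scan; the one-sided
upper-tail p is (1 + #{WR_null >= WR_obs}) / (B + 1).

Fisher p-values use exact integer hypergeometric enumeration (probability
mass <= observed rule), cached per margin pair so the permutation null costs
one table lookup per OTU per draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.stats as sst
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix as _SkbioDM
from skbio.stats.distance import mantel as _skbio_mantel

from .data_model import CountTable, CompositionTable
from .diversity import distance_matrix

OR_DISPLAY_BOUNDS = (0.01, 100.0)


@dataclass
class TransferScan:
    """Per-OTU 2x2 transfer tables for one child compartment.

    ``results`` is indexed by OTU id with columns a, b, c, d (dyad counts:
    mother+child+, mother+child-, mother-child+, mother-child-), odds_ratio,
    p_value and n_children (children carrying the OTU).
    """

    compartment: str
    n_dyads: int
    results: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.results) and {"a", "b", "c", "d"} <= set(self.results.columns):
            sums = self.results[["a", "b", "c", "d"]].sum(axis=1)
            if not (sums == self.n_dyads).all():
                raise ValueError("2x2 cells must sum to the number of dyads")


@dataclass
class EnrichmentResult:
    """Observed WR with its permutation null."""

    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int
    seed: int


@dataclass
class DyadDistanceResult:
    """Mean matched mother-child distance against the scrambled-pair null."""

    metric: str
    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int
    seed: int


# -- exact Fisher machinery ----------------------------------------------

@lru_cache(maxsize=100_000)
def _fisher_tables(n: int, m: int, c: int) -> tuple[int, tuple[float, ...]]:
    """Two-sided Fisher p for every feasible a given margins (n, m, c).

    Returns (a_min, p-values) where entry k is the p-value of a = a_min + k.
    Exact integer arithmetic: a table is counted when its hypergeometric
    mass is <= that of the observed table.
    """
    a_min = max(0, m + c - n)
    a_max = min(m, c)
    weights = [math.comb(m, a) * math.comb(n - m, c - a) for a in range(a_min, a_max + 1)]
    total = math.comb(n, c)
    pvals = []
    for w_obs in weights:
        acc = sum(w for w in weights if w <= w_obs)
        pvals.append(float(Fraction(acc, total)))
    return a_min, tuple(pvals)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p (probability-mass <= observed rule)."""
    n, m, col = a + b + c + d, a + b, a + c
    a_min, pvals = _fisher_tables(n, m, col)
    return pvals[a - a_min]


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio; +0.5 on all cells iff any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


# -- scan -----------------------------------------------------------------

def _dyad_arrays(vaginal_birth: CountTable, child: CountTable,
                 dyads: dict[str, str] | None):
    """Align mother and child samples by dyad; returns bool presence arrays."""
    vmeta = vaginal_birth.metadata
    cmeta = child.metadata
    if not ((vmeta["compartment"] == "vaginal") & (vmeta["timepoint"] == "birth")).all():
        raise ValueError("maternal table must contain vaginal birth samples only")
    comps = cmeta["compartment"].unique().tolist()
    if len(comps) != 1 or comps[0] not in ("feces", "airway"):
        raise ValueError("child table must contain a single child compartment")
    if list(vaginal_birth.otu_ids) != list(child.otu_ids):
        raise ValueError("mother and child tables must share the OTU universe")

    def _one_per_subject(meta: pd.DataFrame, what: str) -> dict[str, str]:
        groups = meta.groupby("subject_id").groups
        out = {}
        for subj, idx in groups.items():
            if len(idx) != 1:
                raise ValueError(f"subject {subj} has {len(idx)} {what} samples; expected 1")
            out[subj] = idx[0]
        return out

    msamp = _one_per_subject(vmeta, "maternal")
    csamp = _one_per_subject(cmeta, "child")
    if dyads is None:
        shared = sorted(set(msamp) & set(csamp))
        dyads = {s: s for s in shared}
    missing = [m for m in dyads if m not in msamp] + [c for c in dyads.values() if c not in csamp]
    if missing:
        raise ValueError(f"dyad subjects without samples: {sorted(set(missing))}")
    mothers = list(dyads.keys())
    if len(mothers) < 3:
        raise ValueError("need at least 3 dyads")
    mcols = [msamp[m] for m in mothers]
    ccols = [csamp[dyads[m]] for m in mothers]
    M = vaginal_birth.counts[mcols].to_numpy() > 0
    C = child.counts[ccols].to_numpy() > 0
    return M, C, mothers, comps[0]


def transfer_scan(vaginal_birth: CountTable, child: CountTable,
                  dyads: dict[str, str] | None = None) -> TransferScan:
    """Per-OTU Fisher scan of mother-to-child presence association.

    Eligibility: the OTU's presence count must lie in [1, n-1] on both the
    maternal and child margins (margins are invariant under permutation of
    the pairing, so the eligible set is fixed across null draws).
    """
    M, C, mothers, comp = _dyad_arrays(vaginal_birth, child, dyads)
    n = len(mothers)
    otus = np.asarray(vaginal_birth.otu_ids)
    m = M.sum(axis=1)
    c = C.sum(axis=1)
    eligible = (m >= 1) & (m <= n - 1) & (c >= 1) & (c <= n - 1)
    rows = []
    for i in np.flatnonzero(eligible):
        a = int((M[i] & C[i]).sum())
        b, cc, d = int(m[i]) - a, int(c[i]) - a, n - int(m[i]) - int(c[i]) + a
        rows.append((otus[i], a, b, cc, d,
                     odds_ratio_2x2(a, b, cc, d),
                     fisher_exact_2x2(a, b, cc, d),
                     int(c[i])))
    results = pd.DataFrame(rows, columns=["otu", "a", "b", "c", "d",
                                          "odds_ratio", "p_value", "n_children"]).set_index("otu")
    return TransferScan(comp, n, results)


def weighted_ratio(scan: TransferScan) -> float:
    """The WR enrichment statistic (natural logs).

    OTUs with OR exactly 1 enter neither sum; p = 1 gives weight 0.  Empty
    denominator with nonzero numerator -> +inf; the mirror case -> 0.0;
    both zero -> NaN.
    """
    if not len(scan.results):
        raise ValueError("empty transfer scan")
    return _wr_from_arrays(scan.results["odds_ratio"].to_numpy(),
                           scan.results["p_value"].to_numpy())


def _wr_from_arrays(or_vals: np.ndarray, p_vals: np.ndarray) -> float:
    log_or = np.log(or_vals)
    log_p = np.log(p_vals)
    num = float((log_or[log_or > 0] * log_p[log_or > 0]).sum())
    den = float((-log_or[log_or < 0] * log_p[log_or < 0]).sum())
    # both sums carry the sign of log p (<= 0); the ratio is >= 0
    if den == 0.0 and num == 0.0:
        return float("nan")
    if den == 0.0:
        return float("inf")
    if num == 0.0:
        return 0.0
    return num / den


def wr_permutation_test(vaginal_birth: CountTable, child: CountTable,
                        dyads: dict[str, str] | None = None,
                        n_perm: int = 999, seed: int = 0) -> EnrichmentResult:
    """Permutation null for WR by scrambling the mother-child pairing.

    Each draw reassigns children to mothers uniformly at random (identity
    allowed), re-runs the per-OTU Fisher scan on the fixed eligible set and
    recomputes WR.  One-sided upper-tail p with the add-one rule.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    M, C, mothers, _ = _dyad_arrays(vaginal_birth, child, dyads)
    n = len(mothers)
    m = M.sum(axis=1)
    c = C.sum(axis=1)
    eligible = np.flatnonzero((m >= 1) & (m <= n - 1) & (c >= 1) & (c <= n - 1))
    if eligible.size == 0:
        raise ValueError("no eligible OTUs")
    Me = M[eligible]
    Ce = C[eligible]
    me, ce = m[eligible], c[eligible]

    # per-OTU lookup tables over the feasible range of a
    or_tabs, p_tabs, a_mins = [], [], []
    for mi, ci in zip(me, ce):
        a_min, pvals = _fisher_tables(n, int(mi), int(ci))
        a_max = a_min + len(pvals) - 1
        ors = [odds_ratio_2x2(a, int(mi) - a, int(ci) - a, n - int(mi) - int(ci) + a)
               for a in range(a_min, a_max + 1)]
        or_tabs.append(np.asarray(ors))
        p_tabs.append(np.asarray(pvals))
        a_mins.append(a_min)
    a_mins = np.asarray(a_mins)

    def _wr_for(Cperm: np.ndarray) -> float:
        a = (Me & Cperm).sum(axis=1) - a_mins
        ors = np.array([t[k] for t, k in zip(or_tabs, a)])
        ps = np.array([t[k] for t, k in zip(p_tabs, a)])
        return _wr_from_arrays(ors, ps)

    observed = _wr_for(Ce)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = _wr_for(Ce[:, perm])
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return EnrichmentResult(observed, null, float(p), n_perm, seed)


# -- descriptors ----------------------------------------------------------

def abundance_odds_correlation(scan: TransferScan,
                               vaginal_birth: CompositionTable) -> tuple[float, float]:
    """Spearman correlation of mean maternal abundance with ln OR."""
    otus = scan.results.index.tolist()
    if len(otus) < 4:
        raise ValueError("need >= 4 eligible OTUs")
    missing = [o for o in otus if o not in vaginal_birth.proportions.index]
    if missing:
        raise ValueError(f"scan OTUs absent from composition table: {missing}")
    mean_ab = vaginal_birth.proportions.loc[otus].mean(axis=1)
    ln_or = np.log(scan.results["odds_ratio"].to_numpy())
    rho, p = sst.spearmanr(mean_ab.to_numpy(), ln_or)
    return float(rho), float(p)


def phylo_signal_of_transfer(scan: TransferScan, tree: TreeNode,
                             n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Phylogenetic signal in the transfer odds (Mantel test).

    Spearman Mantel correlation between patristic distances and pairwise
    |delta ln OR| over scanned OTUs; returns (squared correlation, one-sided
    upper-tail p from leaf-label permutations).
    """
    otus = scan.results.index.tolist()
    leaves = {t.name for t in tree.tips()}
    missing = [o for o in otus if o not in leaves]
    if missing:
        raise ValueError(f"scan OTUs missing from tree: {missing}")
    sub = tree.shear(otus)
    patristic = sub.tip_tip_distances(otus)
    ln_or = np.log(scan.results["odds_ratio"].to_numpy())
    delta = np.abs(ln_or[:, None] - ln_or[None, :])
    if np.allclose(delta, 0):
        return 0.0, 1.0
    dm_or = _SkbioDM(delta, ids=otus)
    r, p, _ = _skbio_mantel(_SkbioDM(patristic.data, ids=otus), dm_or,
                            method="spearman", permutations=n_perm,
                            alternative="greater", seed=seed)
    return float(r) ** 2, float(p)


def dyad_distance_test(vaginal_birth: CountTable, child: CountTable,
                       dyads: dict[str, str] | None = None,
                       metric: str = "jsd", tree: TreeNode | None = None,
                       n_perm: int = 999, seed: int = 0) -> DyadDistanceResult:
    """Are matched mother-child pairs closer than scrambled pairs?

    Observed statistic: mean beta distance over matched dyads.  The null
    reassigns children to mothers uniformly; one-sided lower-tail p.
    """
    _dyad_arrays(vaginal_birth, child, dyads)  # validation
    vmeta = vaginal_birth.metadata
    cmeta = child.metadata
    if dyads is None:
        shared = sorted(set(vmeta["subject_id"]) & set(cmeta["subject_id"]))
        dyads = {s: s for s in shared}
    mother_cols = [vmeta.index[vmeta["subject_id"] == m][0] for m in dyads]
    child_cols = [cmeta.index[cmeta["subject_id"] == dyads[m]][0] for m in dyads]
    n = len(mother_cols)

    combined = pd.concat([vaginal_birth.counts[mother_cols], child.counts[child_cols]], axis=1)
    meta = pd.concat([vaginal_birth.metadata.loc[mother_cols], child.metadata.loc[child_cols]])
    big = CountTable(combined, meta)
    dm = distance_matrix(big, metric, tree=tree)
    cross = dm.values()[:n, n:]  # mothers x children

    observed = float(np.mean(np.diag(cross)))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    idx = np.arange(n)
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = float(np.mean(cross[idx, perm]))
    p = (1.0 + np.sum(null <= observed)) / (n_perm + 1.0)
    return DyadDistanceResult(metric, observed, null, float(p), n_perm, seed)


def truncate_or_for_display(or_value: float) -> float:
    """Clip an odds ratio to [0.01, 100] for volcano-plot export."""
    lo, hi = OR_DISPLAY_BOUNDS
    if math.isinf(or_value):
        return hi
    if or_value <= 0 and not math.isinf(or_value):
        raise ValueError("odds ratio must be positive")
    return float(min(max(or_value, lo), hi))
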