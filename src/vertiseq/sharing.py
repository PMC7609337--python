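"""OTU sharing across compartments, SparCC co-occurrence, birth-unique OTUs.

The sharing partition places every OTU in one of the seven regions of the
three-set Venn diagram over compartments (vaginal, feces, airway) and
attributes the corresponding fraction of all reads to each region.
Co-occurrence uses the SparCC estimator within each compartment, combined
pairwise as the maximum correlation across compartments and pruned at
r > 0.2.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CountTable, COMPARTMENTS

log = logging.getLogger(__name__)

VENN_REGIONS = (
    ("vaginal",), ("feces",), ("airway",),
    ("vaginal", "feces"), ("vaginal", "airway"), ("feces", "airway"),
    ("vaginal", "feces", "airway"),
)


@dataclass
class SharingPartition:
    """OTU counts, ids and read fractions per Venn region of the compartments."""

    regions: dict[tuple[str, ...], dict]  # region -> {otu_ids, n_otus, read_fraction}
    total_otus: int
    total_reads: int

    def region(self, *compartments: str) -> dict:
        return self.regions[tuple(sorted(compartments, key=COMPARTMENTS.index))]

    def to_json_dict(self) -> dict:
        return {
            "total_otus": self.total_otus,
            "total_reads": self.total_reads,
            "regions": {"+".join(k): {"n_otus": v["n_otus"],
                                      "read_fraction": v["read_fraction"],
                                      "otu_ids": v["otu_ids"]}
                        for k, v in self.regions.items()},
        }


@dataclass
class EdgeList:
    """Undirected OTU co-occurrence edges above the pruning threshold."""

    edges: pd.DataFrame  # columns otu_a, otu_b, r, compartment
    threshold: float


def compartment_partition(table: CountTable) -> SharingPartition:
    """Partition OTUs by the set of compartments in which they occur.

    An OTU belongs to a compartment iff it has count > 0 in at least one
    sample of that compartment; OTUs present nowhere are excluded.  Read
    fractions are over the grand total of reads in all compartments.
    """
    present = {}
    for comp in COMPARTMENTS:
        samples = table.metadata.index[table.metadata["compartment"] == comp]
        if len(samples) == 0:
            raise ValueError(f"no samples from compartment {comp!r}")
        present[comp] = table.counts[samples].sum(axis=1) > 0
    membership = pd.DataFrame(present)
    observed = membership.any(axis=1)
    total_reads = int(table.counts.to_numpy().sum())
    otu_reads = table.counts.sum(axis=1)
    regions = {}
    for region in VENN_REGIONS:
        in_region = observed.copy()
        for comp in COMPARTMENTS:
            if comp in region:
                in_region &= membership[comp]
            else:
                in_region &= ~membership[comp]
        ids = membership.index[in_region].tolist()
        regions[region] = {
            "otu_ids": ids,
            "n_otus": len(ids),
            "read_fraction": float(otu_reads.loc[ids].sum()) / total_reads,
        }
    return SharingPartition(regions, int(observed.sum()), total_reads)


# -- SparCC ---------------------------------------------------------------

def _sparcc_basis(t: np.ndarray, included: np.ndarray) -> np.ndarray:
    """Solve for basis variances under the sparsity approximation."""
    d = t.shape[0]
    a = included.astype(float)
    np.fill_diagonal(a, 0.0)
    diag = a.sum(axis=1)
    m = a.copy()
    np.fill_diagonal(m, diag)
    ti = (t * a).sum(axis=1)
    omega = np.linalg.solve(m, ti)
    return np.clip(omega, 1e-12, None)


def _sparcc_single(frac: np.ndarray, n_exclude: int, exclusion_threshold: float = 0.1,
                   ) -> np.ndarray:
    """One SparCC estimate from a fraction matrix (otus x samples)."""
    d = frac.shape[0]
    logf = np.log(frac)
    # t_ij = var(log(x_i / x_j)) across samples
    var = logf.var(axis=1, ddof=1)
    cov = np.cov(logf, ddof=1)
    t = var[:, None] + var[None, :] - 2 * cov
    np.fill_diagonal(t, 0.0)
    included = np.ones((d, d), dtype=bool)
    np.fill_diagonal(included, False)
    corr = None
    for _ in range(n_exclude + 1):
        omega = _sparcc_basis(t, included)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        corr = (omega[:, None] + omega[None, :] - t) / denom
        corr = np.clip(corr, -1.0, 1.0)
        np.fill_diagonal(corr, 1.0)
        masked = np.where(included, np.abs(corr), -np.inf)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        included[i, j] = included[j, i] = False
        if (included.sum(axis=1) < 2).any():
            break
    return corr


def sparcc_correlation(table: CountTable, n_inner: int = 20, n_exclude: int = 10,
                       seed: int = 0) -> pd.DataFrame:
    """SparCC correlations among OTUs of one compartment.

    Per inner iteration, sample fractions are drawn Dirichlet(count + 1) per
    sample; log-ratio variances give basis variances under the sparsity
    assumption, with up to ``n_exclude`` rounds of excluding the most
    strongly correlated pair.  The returned matrix is the elementwise median
    over inner iterations, clipped to [-1, 1].  Constant OTUs get
    correlation 0 (with a warning).
    """
    if table.n_samples < 4:
        raise ValueError("need >= 4 samples")
    if table.n_otus < 4:
        raise ValueError("need >= 4 OTUs")
    counts = table.counts.to_numpy().astype(float)
    constant = np.array([len(np.unique(row)) == 1 for row in counts])
    if constant.any():
        log.warning("sparcc: %d constant OTUs get correlation 0", int(constant.sum()))
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_inner):
        frac = np.empty_like(counts)
        for j in range(counts.shape[1]):
            frac[:, j] = rng.dirichlet(counts[:, j] + 1.0)
        estimates.append(_sparcc_single(frac, n_exclude))
    corr = np.median(np.stack(estimates), axis=0)
    corr = np.clip(corr, -1.0, 1.0)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = 0.5 * (corr + corr.T)
    return pd.DataFrame(corr, index=table.otu_ids, columns=table.otu_ids)


def cooccurrence_edges(corr_by_compartment: dict[str, pd.DataFrame],
                       threshold: float = 0.2) -> EdgeList:
    """Combine per-compartment correlations as the pairwise maximum.

    For every OTU pair estimable in at least one compartment, r is the
    maximum across compartments; edges with r > threshold are kept along
    with the argmax compartment.
    """
    all_otus = sorted({o for m in corr_by_compartment.values() for o in m.index})
    rows = []
    for oa, ob in itertools.combinations(all_otus, 2):
        best_r, best_comp = None, None
        for comp, mat in corr_by_compartment.items():
            if oa in mat.index and ob in mat.index:
                r = float(mat.loc[oa, ob])
                if best_r is None or r > best_r:
                    best_r, best_comp = r, comp
        if best_r is not None and best_r > threshold:
            rows.append((oa, ob, best_r, best_comp))
    edges = pd.DataFrame(rows, columns=["otu_a", "otu_b", "r", "compartment"])
    return EdgeList(edges, threshold)


def birth_unique_otus(vaginal: CountTable, min_birth_samples: int = 5,
                      ) -> tuple[set[str], pd.DataFrame, dict]:
    """OTUs seen at birth but never at week 24 or week 36.

    Returns (the full set, per-birth-sample combined relative abundance of
    set members, and a summary dict with the prevalent subset present in at
    least ``min_birth_samples`` birth samples plus the median/IQR of the
    combined relative abundance).
    """
    meta = vaginal.metadata
    for tp in ("w24", "w36", "birth"):
        if not (meta["timepoint"] == tp).any():
            raise ValueError(f"no samples at timepoint {tp!r}")
    early = meta.index[meta["timepoint"].isin(["w24", "w36"])]
    birth = meta.index[meta["timepoint"] == "birth"]
    early_present = vaginal.counts[early].sum(axis=1) > 0
    birth_counts = vaginal.counts[birth]
    birth_present = birth_counts > 0
    unique = vaginal.counts.index[(~early_present) & birth_present.any(axis=1)]
    prevalent = [o for o in unique if int(birth_present.loc[o].sum()) >= min_birth_samples]
    depths = birth_counts.sum(axis=0)
    combined = birth_counts.loc[unique].sum(axis=0) / depths
    combined.name = "combined_relative_abundance"
    summary = {
        "n_unique": len(unique),
        "prevalent_otus": prevalent,
        "min_birth_samples": min_birth_samples,
        "median": float(combined.median()),
        "iqr": (float(combined.quantile(0.25)), float(combined.quantile(0.75))),
    }
    return set(unique), combined.to_frame(), summary
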