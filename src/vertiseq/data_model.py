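"""Core containers and I/O for OTU count data, sample metadata, taxonomy and trees.

The package works on 16S amplicon OTU tables from a longitudinal mother-child
design: vaginal samples at pregnancy week 24, week 36 and at birth, and the
child's feces and airway samples at one week of age.  Counts are held as an
OTU x sample integer matrix with per-sample metadata (subject, compartment,
timepoint).  All interchange formats are plain text (TSV, Newick, JSON).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

log = logging.getLogger(__name__)

COMPARTMENTS = ("vaginal", "feces", "airway")
TIMEPOINTS = ("w24", "w36", "birth", "week1")
VAGINAL_TIMEPOINTS = ("w24", "w36", "birth")
CHILD_COMPARTMENTS = ("feces", "airway")
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: metadata columns that every sample must carry
META_COLS = ("subject_id", "compartment", "timepoint")

_UNASSIGNED = {"", "unassigned", "unclassified", "na", "nan"}


def _is_unassigned(value) -> bool:
    return pd.isna(value) or str(value).strip().lower() in _UNASSIGNED


@dataclass
class CountTable:
    """OTU x sample matrix of read counts with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by OTU id with sample ids as columns; nonnegative
        integers.
    metadata
        DataFrame indexed by sample id with at least the columns
        ``subject_id``, ``compartment`` and ``timepoint``.  Extra columns
        (e.g. ``delivery_mode``) are preserved.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        counts, meta = self.counts, self.metadata
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dup}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (arr < 0).any():
            bad = counts.columns[(arr < 0).any(axis=0)].tolist()
            raise ValueError(f"negative counts in samples: {bad}")
        if not np.allclose(arr, np.round(arr)):
            bad = counts.columns[(arr != np.round(arr)).any(axis=0)].tolist()
            raise ValueError(f"non-integer counts in samples: {bad}")
        self.counts = counts.astype(np.int64)
        missing = [s for s in counts.columns if s not in meta.index]
        if missing:
            raise ValueError(f"samples missing metadata: {missing}")
        for col in META_COLS:
            if col not in meta.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        meta = meta.loc[counts.columns]
        bad = meta.index[~meta["compartment"].isin(COMPARTMENTS)].tolist()
        if bad:
            raise ValueError(f"unknown compartment for samples: {bad}")
        bad = meta.index[~meta["timepoint"].isin(TIMEPOINTS)].tolist()
        if bad:
            raise ValueError(f"unknown timepoint for samples: {bad}")
        vaginal = meta["compartment"] == "vaginal"
        bad = meta.index[vaginal & ~meta["timepoint"].isin(VAGINAL_TIMEPOINTS)].tolist()
        bad += meta.index[~vaginal & (meta["timepoint"] != "week1")].tolist()
        if bad:
            raise ValueError(f"compartment/timepoint mismatch for samples: {bad}")
        self.metadata = meta

    # -- accessors ------------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample read depth (column sums)."""
        return self.counts.sum(axis=0)

    def presence(self) -> pd.DataFrame:
        """Boolean OTU x sample presence matrix (count > 0)."""
        return self.counts > 0

    def subset_samples(self, sample_ids) -> "CountTable":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return CountTable(self.counts[sample_ids].copy(), self.metadata.loc[sample_ids].copy())

    def select(self, compartment: str | None = None, timepoint: str | None = None) -> "CountTable":
        """Subset by compartment and/or timepoint."""
        keep = pd.Series(True, index=self.metadata.index)
        if compartment is not None:
            keep &= self.metadata["compartment"] == compartment
        if timepoint is not None:
            keep &= self.metadata["timepoint"] == timepoint
        return self.subset_samples(self.metadata.index[keep])

    # -- I/O ------------------------------------------------------------
    def write(self, counts_path, metadata_path) -> None:
        write_count_table(self, counts_path, metadata_path)


@dataclass
class CompositionTable:
    """Relative-abundance analogue of :class:`CountTable` (columns sum to 1)."""

    proportions: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy(dtype=float)
        if (arr < 0).any() or (arr > 1 + 1e-12).any():
            raise ValueError("relative abundances must lie in [0, 1]")
        sums = arr.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = self.proportions.columns[~np.isclose(sums, 1.0, atol=1e-9)].tolist()
            raise ValueError(f"sample columns do not sum to 1: {bad}")

    @property
    def otu_ids(self) -> list[str]:
        return self.proportions.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.proportions.columns.tolist()


@dataclass
class Taxonomy:
    """Per-OTU lineage from kingdom down to genus.

    Unassigned levels may be empty strings or NaN; they are pooled under the
    deepest assigned ancestor when aggregating.
    """

    lineage: pd.DataFrame  # index otu_id, columns RANKS

    def __post_init__(self) -> None:
        for rank in RANKS:
            if rank not in self.lineage.columns:
                raise ValueError(f"taxonomy lacks rank {rank!r}")
        if self.lineage.index.has_duplicates:
            raise ValueError("duplicate OTU ids in taxonomy")
        self.lineage = self.lineage[list(RANKS)].astype(object)

    def effective_lineage(self) -> pd.DataFrame:
        """Lineage with unassigned levels replaced by ``unclassified_<ancestor>``.

        Once a rank is unassigned, that rank and all deeper ranks inherit the
        pooled label (mirrors 'Family Enterobacteriaceae'-style display names).
        """
        out = {}
        for otu, row in self.lineage.iterrows():
            eff, deepest = [], None
            pooled = None
            for rank in RANKS:
                val = row[rank]
                if pooled is None and not _is_unassigned(val):
                    deepest = str(val)
                    eff.append(deepest)
                else:
                    if pooled is None:
                        pooled = f"unclassified_{deepest}" if deepest else "unclassified"
                    eff.append(pooled)
            out[otu] = eff
        return pd.DataFrame.from_dict(out, orient="index", columns=list(RANKS))


# -- tree -----------------------------------------------------------------

PhyloTree = TreeNode


def validate_tree(tree: TreeNode) -> TreeNode:
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf labels: {dup}")
    if any(n is None for n in names):
        raise ValueError("unlabeled leaf in tree")
    for node in tree.traverse():
        if node is tree:
            if node.length is None:
                node.length = 0.0
            continue
        if node.length is None:
            node.length = 0.0
        if not np.isfinite(node.length) or node.length < 0:
            raise ValueError(f"invalid branch length on node {node.name!r}: {node.length}")
    return tree


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree with branch lengths and validate it."""
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree)


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# -- readers / writers ----------------------------------------------------

def read_count_table(path, metadata_path, format: str = "tsv") -> CountTable:
    """Read an OTU table plus its companion metadata TSV.

    ``format='tsv'``: first column is the OTU id (header ``#OTU_ID``), the
    remaining columns are samples.  ``format='biom'``: BIOM v1 JSON (dense or
    sparse matrix_type).
    """
    if format == "tsv":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        counts.index.name = None
    elif format == "biom":
        counts = _read_biom_json(path)
    else:
        raise ValueError(f"unknown count-table format {format!r}")
    meta = read_metadata(metadata_path)
    return CountTable(counts, meta)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must have a sample_id column")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dup}")
    return meta.set_index("sample_id")


def _read_biom_json(path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    otus = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(otus), len(samples)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    return pd.DataFrame(mat, index=otus, columns=samples)


def write_count_table(table: CountTable, counts_path, metadata_path) -> None:
    df = table.counts.copy()
    df.index.name = "#OTU_ID"
    df.to_csv(counts_path, sep="\t", lineterminator="\n")
    meta = table.metadata.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t", lineterminator="\n")


def read_taxonomy(path) -> Taxonomy:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "otu_id" not in df.columns:
        raise ValueError("taxonomy must have an otu_id column")
    return Taxonomy(df.set_index("otu_id"))


def write_taxonomy(tax: Taxonomy, path) -> None:
    df = tax.lineage.copy()
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


# -- sample-level filters and transforms ----------------------------------

def filter_low_depth(table: CountTable, min_reads: int = 2000) -> CountTable:
    """Drop samples with fewer than ``min_reads`` total reads.

    The boundary is strict: a sample with exactly ``min_reads`` reads is kept.
    Removed samples are logged.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    depths = table.depths()
    keep = depths[depths >= min_reads].index.tolist()
    dropped = [s for s in table.sample_ids if s not in keep]
    if dropped:
        log.info("filter_low_depth: removed %d samples below %d reads: %s",
                 len(dropped), min_reads, dropped)
    if not keep:
        raise ValueError(f"all samples fall below {min_reads} reads")
    return table.subset_samples(keep)


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Each column becomes one multivariate-hypergeometric draw; reproducible
    under ``seed``.  Samples shallower than ``depth`` raise (filter first).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    depths = table.depths()
    shallow = depths[depths < depth].index.tolist()
    if shallow:
        raise ValueError(f"samples shallower than {depth} reads: {shallow}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for j, sample in enumerate(table.sample_ids):
        col = table.counts[sample].to_numpy()
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return CountTable(counts, table.metadata.copy())


def relative_abundance(table: CountTable) -> CompositionTable:
    """Column-normalize counts to relative abundances."""
    depths = table.depths()
    empty = depths[depths == 0].index.tolist()
    if empty:
        raise ValueError(f"zero-depth samples: {empty}")
    props = table.counts / depths
    return CompositionTable(props, table.metadata.copy())


def _aggregate_frame(df: pd.DataFrame, tax: Taxonomy, rank: str) -> pd.DataFrame:
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    missing = [o for o in df.index if o not in tax.lineage.index]
    if missing:
        raise ValueError(f"OTUs absent from taxonomy: {missing}")
    eff = tax.effective_lineage().loc[df.index]
    upto = list(RANKS[: RANKS.index(rank) + 1])
    key = eff[upto].agg(tuple, axis=1)
    # label rows by the rank value; disambiguate identical labels arising
    # from different lineage prefixes with the parent level
    grouped = df.groupby(key.values, sort=False).sum()
    labels = []
    seen: dict[str, tuple] = {}
    for prefix in grouped.index:
        label = prefix[-1]
        if label in seen and seen[label] != prefix:
            label = f"{prefix[-2]}|{label}" if len(prefix) > 1 else label
        seen.setdefault(prefix[-1], prefix)
        labels.append(label)
    grouped.index = labels
    return grouped.groupby(level=0, sort=False).sum()


def aggregate_by_rank(table: CountTable, tax: Taxonomy, rank: str) -> CountTable:
    """Sum OTU rows sharing the same lineage prefix up to ``rank``.

    Unassigned taxa pool under their deepest assigned ancestor as
    ``unclassified_<ancestor>``.  Column sums are conserved.
    """
    return CountTable(_aggregate_frame(table.counts, tax, rank), table.metadata.copy())


def aggregate_composition(comp: CompositionTable, tax: Taxonomy, rank: str) -> CompositionTable:
    """Rank aggregation on relative abundances (commutes with normalization)."""
    return CompositionTable(_aggregate_frame(comp.proportions, tax, rank), comp.metadata.copy())
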