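import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from vertiseq.data_model import CountTable, Taxonomy, RANKS
from vertiseq.synthetic import CohortConfig, simulate_cohort


def make_table(counts, otu_ids, sample_ids, compartments, timepoints, subjects=None):
    """Assemble a CountTable from plain lists."""
    if subjects is None:
        subjects = [f"S{i}" for i in range(len(sample_ids))]
    meta = pd.DataFrame({
        "subject_id": subjects,
        "compartment": compartments,
        "timepoint": timepoints,
    }, index=pd.Index(sample_ids, name="sample_id"))
    return CountTable(pd.DataFrame(counts, index=otu_ids, columns=sample_ids), meta)


@pytest.fixture(scope="session")
def small_cohort():
    """12-dyad, 60-OTU null cohort at shallow depth (shared across tests)."""
    cfg = CohortConfig.test_preset(n_dyads=12, n_otus=60, transfer_pi=0.0, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def signal_cohort():
    """Same size cohort with a strong transfer component."""
    cfg = CohortConfig.test_preset(n_dyads=12, n_otus=60, transfer_pi=0.5, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture
def toy_tree():
    return TreeNode.read(["((A:1,B:1):0.5,C:2):0;"])


@pytest.fixture
def toy_taxonomy():
    rows = {
        "O1": ["Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"],
        "O2": ["Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"],
        "O3": ["Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae", ""],
        "O4": ["Bacteria", "Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae", "Staphylococcus"],
    }
    return Taxonomy(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))


def random_bifurcating_tree(n_leaves: int, rng: np.random.Generator) -> TreeNode:
    """Random rooted bifurcating tree with exponential branch lengths."""
    nodes = [TreeNode(name=f"L{i}", length=float(rng.exponential(1.0)))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(length=float(rng.exponential(1.0)), children=[a, b]))
    nodes[0].length = 0.0
    return nodes[0]
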