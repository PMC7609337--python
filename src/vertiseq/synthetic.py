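"""Synthetic mother-child cohort generator with ground truth.

Emulates the statistical structure of a pregnancy/birth 16S study: ~57
mother-child dyads, three vaginal timepoints (week 24, week 36, birth) plus
child feces and airway samples at one week, Lactobacillus-dominated vaginal
communities whose dominance declines toward birth on the logit scale,
subject-specific compositional signatures, and an optional vertical-transfer
component in which the child community is a mixture of the mother's birth
community (masked to transfer-prone clades) and a compartment-specific
environmental pool.  Counts are Dirichlet-multinomial at lognormal depths.

All randomness flows from a single integer seed; identical configuration and
seed give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from skbio import TreeNode

from .data_model import CountTable, Taxonomy, RANKS, validate_tree

CLADE_NAMES = (
    "Lactobacillales",
    "Clostridiales",
    "Enterobacteriales",
    "Bacteroidales",
    "Bacillales",
)

#: clade -> (phylum, class, family, candidate genera)
_CLADE_TAXONOMY = {
    "Lactobacillales": ("Firmicutes", "Bacilli", "Lactobacillaceae",
                        ("Lactobacillus", "Enterococcus", "Streptococcus")),
    "Clostridiales": ("Firmicutes", "Clostridia", "Lachnospiraceae",
                      ("Blautia", "Clostridium", "Faecalibacterium")),
    "Enterobacteriales": ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriaceae",
                          ("Escherichia", "Klebsiella", "Enterobacter")),
    "Bacteroidales": ("Bacteroidetes", "Bacteroidia", "Bacteroidaceae",
                      ("Bacteroides", "Prevotella", "Parabacteroides")),
    "Bacillales": ("Firmicutes", "Bacilli", "Staphylococcaceae",
                   ("Staphylococcus", "Gemella", "Moraxella")),
}

DEFAULT_TRANSFER_CLADES = ("Lactobacillales", "Clostridiales", "Enterobacteriales")


@dataclass
class CohortConfig:
    """Parameters of the simulated study design.

    Defaults reproduce the full-scale design (57 dyads, median depth 40k);
    :meth:`test_preset` scales the depth down to a median of 2000 reads.
    """

    n_dyads: int = 57
    n_otus: int = 300
    depth_log_mean: float = math.log(40000.0)
    depth_log_sd: float = 0.35
    lacto_frac_w24: float = 0.8
    lacto_decline: float = 0.5
    subject_sd: float = 1.0
    transfer_pi: float = 0.0
    transfer_clades: tuple[str, ...] = DEFAULT_TRANSFER_CLADES
    overdispersion: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 2:
            raise ValueError("n_dyads must be >= 2")
        if self.n_otus < 10:
            raise ValueError("n_otus must be >= 10")
        for name in ("lacto_frac_w24", "transfer_pi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.transfer_pi > 0 and not self.transfer_clades:
            raise ValueError("transfer_pi > 0 requires non-empty transfer_clades")
        unknown = set(self.transfer_clades) - set(CLADE_NAMES)
        if unknown:
            raise ValueError(f"unknown transfer clades: {sorted(unknown)}")

    @classmethod
    def test_preset(cls, **overrides) -> "CohortConfig":
        """Shallow-depth preset (median ~2000 reads) for fast runs."""
        kw = dict(depth_log_mean=math.log(2000.0))
        kw.update(overrides)
        return cls(**kw)


@dataclass
class CohortTruth:
    """Simulator ground truth for recovery tests."""

    transfer_pi: float
    transfer_prone: pd.Series       # bool per OTU
    clade_labels: pd.Series         # clade name per OTU
    subject_effects: pd.DataFrame   # subject x OTU log-abundance offsets

    def to_json_dict(self) -> dict:
        return {
            "transfer_pi": self.transfer_pi,
            "transfer_prone": {k: bool(v) for k, v in self.transfer_prone.items()},
            "clade_labels": self.clade_labels.to_dict(),
            "subject_effects": {s: row.tolist() for s, row in self.subject_effects.iterrows()},
        }


def simulate_tree(n_otus: int, seed: int) -> tuple[TreeNode, pd.Series]:
    """Random rooted bifurcating tree with five named monophyletic clades.

    Branch lengths are exponential; every leaf belongs to exactly one clade.
    Returns the tree and a Series mapping OTU id to clade name.
    """
    if n_otus < 10:
        raise ValueError("n_otus must be >= 10")
    rng = np.random.default_rng(seed)
    sizes = np.ones(len(CLADE_NAMES), dtype=int)
    sizes += rng.multinomial(n_otus - len(CLADE_NAMES),
                             [0.30, 0.25, 0.20, 0.15, 0.10])
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(n_otus)]
    labels, roots = {}, []
    pos = 0
    for clade, size in zip(CLADE_NAMES, sizes):
        leaves = []
        for _ in range(size):
            leaf = TreeNode(name=otu_ids[pos], length=float(rng.exponential(0.1)))
            labels[otu_ids[pos]] = clade
            leaves.append(leaf)
            pos += 1
        roots.append(_random_join(leaves, rng, scale=0.1))
    root = _random_join(roots, rng, scale=0.5)
    root.length = 0.0
    tree = validate_tree(root)
    return tree, pd.Series(labels, name="clade")


def _random_join(nodes: list[TreeNode], rng: np.random.Generator, scale: float) -> TreeNode:
    """Repeatedly join random pairs into bifurcating internal nodes."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(scale)), children=[a, b])
        nodes.append(parent)
    return nodes[0]


def _simulate_taxonomy(clades: pd.Series, rng: np.random.Generator) -> Taxonomy:
    rows = {}
    for otu, clade in clades.items():
        phylum, cls, family, genera = _CLADE_TAXONOMY[clade]
        genus = str(rng.choice(genera))
        if rng.random() < 0.1:          # some OTUs unresolved at genus
            genus = ""
        rows[otu] = ["Bacteria", phylum, cls, clade, family, genus]
    return Taxonomy(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))


def simulate_cohort(config: CohortConfig) -> tuple[CountTable, TreeNode, Taxonomy, CohortTruth]:
    """Simulate one full cohort.

    Vaginal samples: the Lactobacillales-clade share follows
    ``expit(logit(lacto_frac_w24) - lacto_decline * t)`` for t = 0, 1, 2
    (week 24, week 36, birth); within-clade weights are softmax of a cohort
    base profile plus subject offsets ~ N(0, subject_sd^2) shared across that
    subject's timepoints.  Child samples: expected composition is
    ``transfer_pi * (mother's birth composition masked to transfer-prone
    OTUs, renormalized) + (1 - transfer_pi) * environmental pool``; the
    airway pool is sparser than the feces pool.  Counts are
    Dirichlet-multinomial with the configured precision at lognormal depths.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tree_seed = int(rng.integers(0, 2**31 - 1))
    tree, clades = simulate_tree(cfg.n_otus, tree_seed)
    otu_ids = [t.name for t in tree.tips()]
    clades = clades.loc[otu_ids]
    tax = _simulate_taxonomy(clades, rng)

    lacto = (clades == "Lactobacillales").to_numpy()
    transfer_prone = clades.isin(cfg.transfer_clades)

    base = rng.normal(0.0, 1.0, cfg.n_otus)  # cohort-level log profile
    subjects = [f"M{i + 1:03d}" for i in range(cfg.n_dyads)]
    subj_eff = rng.normal(0.0, cfg.subject_sd, (cfg.n_dyads, cfg.n_otus))

    # environmental pools: feces richer than airway
    feces_support = rng.random(cfg.n_otus) < 0.6
    airway_support = rng.random(cfg.n_otus) < 0.3
    feces_support[np.argmax(~lacto)] = True     # guarantee non-empty
    airway_support[np.argmax(~lacto)] = True
    feces_pool = _pool(rng, feces_support)
    airway_pool = _pool(rng, airway_support)

    lacto_share = expit(logit(cfg.lacto_frac_w24) - cfg.lacto_decline * np.arange(3))

    records, columns, ids = [], [], []

    def _softmax_comp(logw: np.ndarray, mask: np.ndarray) -> np.ndarray:
        w = np.zeros_like(logw)
        sel = logw[mask]
        w[mask] = np.exp(sel - sel.max())
        w[mask] /= w[mask].sum()
        return w

    birth_comp = {}
    for si, subj in enumerate(subjects):
        logw = base + subj_eff[si]
        w_lacto = _softmax_comp(logw, lacto)
        w_other = _softmax_comp(logw, ~lacto)
        for t, tp in enumerate(("w24", "w36", "birth")):
            p = lacto_share[t] * w_lacto + (1 - lacto_share[t]) * w_other
            if tp == "birth":
                birth_comp[subj] = p
            sid = f"{subj}_{tp}"
            ids.append(sid)
            columns.append(_draw_counts(rng, p, cfg))
            records.append((sid, subj, "vaginal", tp))

    for subj in subjects:
        mother = birth_comp[subj]
        masked = mother * transfer_prone.to_numpy()
        if cfg.transfer_pi > 0:
            masked = masked / masked.sum()
        for comp_name, pool in (("feces", feces_pool), ("airway", airway_pool)):
            p = cfg.transfer_pi * masked + (1 - cfg.transfer_pi) * pool
            sid = f"{subj}_child_{comp_name}"
            ids.append(sid)
            columns.append(_draw_counts(rng, p, cfg))
            records.append((sid, subj, comp_name, "week1"))

    counts = pd.DataFrame(np.column_stack(columns), index=otu_ids, columns=ids)
    meta = pd.DataFrame(records, columns=["sample_id", "subject_id", "compartment", "timepoint"])
    meta["delivery_mode"] = "vaginal"
    table = CountTable(counts, meta.set_index("sample_id"))
    truth = CohortTruth(
        transfer_pi=cfg.transfer_pi,
        transfer_prone=transfer_prone,
        clade_labels=clades,
        subject_effects=pd.DataFrame(subj_eff, index=subjects, columns=otu_ids),
    )
    return table, tree, tax, truth


def _pool(rng: np.random.Generator, support: np.ndarray) -> np.ndarray:
    p = np.zeros(support.size)
    p[support] = rng.dirichlet(np.full(int(support.sum()), 0.5))
    return p


def _draw_counts(rng: np.random.Generator, p: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    depth = max(1, int(round(rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd))))
    alpha = cfg.overdispersion * p
    pos = alpha > 0
    comp = np.zeros_like(p)
    comp[pos] = rng.dirichlet(alpha[pos])
    return rng.multinomial(depth, comp)
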