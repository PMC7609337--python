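"""Alpha/beta diversity, ordination and distance-based variance decomposition.

Alpha metrics: richness, Shannon entropy (natural log) and Faith's
phylogenetic diversity (rooted-inclusive).  Beta metrics: unweighted and
normalized weighted UniFrac, Jaccard on presence sets, Bray-Curtis on
counts, and Jensen-Shannon divergence (natural log, no square root).
Ordination is classical PCoA; inference is a sequential-sums-of-squares
PERMANOVA in the style of vegan's adonis, with free sample permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.spatial.distance as ssd
import scipy.stats as sst
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.diversity.beta import unweighted_unifrac as _uw_unifrac
from skbio.diversity.beta import weighted_unifrac as _w_unifrac
from skbio.diversity import beta_diversity as _skbio_beta_diversity

from .data_model import CountTable

BETA_METRICS = ("unweighted_unifrac", "weighted_unifrac", "jaccard", "bray_curtis", "jsd")
ALPHA_METRICS = ("richness", "shannon", "faith_pd")


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with zero diagonal."""

    data: pd.DataFrame
    metric: str

    def __post_init__(self) -> None:
        arr = self.data.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1] or list(self.data.index) != list(self.data.columns):
            raise ValueError("distance matrix must be square with matching ids")
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(arr) != 0).any():
            raise ValueError("distance matrix diagonal must be exactly zero")
        if (arr < 0).any():
            raise ValueError("distances must be nonnegative")

    @property
    def ids(self) -> list[str]:
        return self.data.index.tolist()

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class Ordination:
    """PCoA result: sample coordinates on positive-eigenvalue axes."""

    coordinates: pd.DataFrame      # samples x axes
    eigenvalues: np.ndarray        # descending, positive axes only
    proportion_explained: np.ndarray


@dataclass
class VarianceDecomposition:
    """Per-term SS split of a (distance-based) ANOVA, plus residual row.

    ``table`` has rows per term then 'residual' and 'total', with columns
    ss, df, r2, F, p.  ``degenerate`` marks an all-constant response.
    """

    table: pd.DataFrame
    degenerate: bool = False


# -- alpha ----------------------------------------------------------------

def alpha_diversity(sample: np.ndarray | pd.Series, metric: str,
                    tree: TreeNode | None = None,
                    otu_ids: list[str] | None = None) -> float:
    """Single-sample alpha diversity.

    ``sample`` is a count vector; ``otu_ids`` labels it (required for
    faith_pd, defaults to a Series' index).
    """
    if isinstance(sample, pd.Series):
        if otu_ids is None:
            otu_ids = sample.index.tolist()
        sample = sample.to_numpy()
    sample = np.asarray(sample, dtype=float)
    if sample.sum() <= 0:
        raise ValueError("sample has zero depth")
    if metric == "richness":
        return float((sample > 0).sum())
    if metric == "shannon":
        p = sample[sample > 0] / sample.sum()
        return float(-(p * np.log(p)).sum())
    if metric == "faith_pd":
        if tree is None or otu_ids is None:
            raise ValueError("faith_pd requires a tree and OTU ids")
        leaves = {t.name for t in tree.tips()}
        observed = [o for o, c in zip(otu_ids, sample) if c > 0]
        missing = [o for o in observed if o not in leaves]
        if missing:
            raise ValueError(f"observed OTUs missing from tree: {missing}")
        return float(_skbio_faith_pd(sample, taxa=otu_ids, tree=tree))
    raise ValueError(f"unknown alpha metric {metric!r}")


def alpha_diversity_table(table: CountTable, metrics=ALPHA_METRICS,
                          tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity for several metrics at once."""
    rows = {}
    for sid in table.sample_ids:
        col = table.counts[sid]
        rows[sid] = {m: alpha_diversity(col, m, tree=tree) for m in metrics}
    return pd.DataFrame.from_dict(rows, orient="index")[list(metrics)]


# -- beta -----------------------------------------------------------------

def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence, natural log; 0*log 0 := 0."""
    m = 0.5 * (p + q)

    def _kl(a, b):
        sel = a > 0
        return float((a[sel] * np.log(a[sel] / b[sel])).sum())

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def beta_distance(a, b, metric: str, tree: TreeNode | None = None,
                  otu_ids: list[str] | None = None) -> float:
    """Pairwise distance between two count vectors over the same OTU universe."""
    if isinstance(a, pd.Series):
        if otu_ids is None:
            otu_ids = a.index.tolist()
        a = a.to_numpy()
    if isinstance(b, pd.Series):
        b = b.to_numpy()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must share the OTU universe")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("both samples are empty")
    if metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None or otu_ids is None:
            raise ValueError(f"{metric} requires a tree and OTU ids")
        if metric == "unweighted_unifrac":
            return float(_uw_unifrac(a, b, taxa=otu_ids, tree=tree))
        return float(_w_unifrac(a, b, taxa=otu_ids, tree=tree, normalized=True))
    if metric == "jaccard":
        return float(ssd.jaccard(a > 0, b > 0))
    if metric == "bray_curtis":
        return float(ssd.braycurtis(a, b))
    if metric == "jsd":
        return _jsd(a / a.sum(), b / b.sum())
    raise ValueError(f"unknown beta metric {metric!r}")


def distance_matrix(table: CountTable, metric: str,
                    tree: TreeNode | None = None) -> DistanceMatrix:
    """All-pairs distance matrix for one metric."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    ids = table.sample_ids
    X = table.counts.to_numpy(dtype=float).T  # samples x otus
    if metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None:
            raise ValueError(f"{metric} requires a tree")
        kw = {"taxa": table.otu_ids, "tree": tree}
        if metric == "weighted_unifrac":
            kw["normalized"] = True
        dm = _skbio_beta_diversity(metric, X, ids=ids, **kw)
        mat = pd.DataFrame(dm.data, index=ids, columns=ids)
    elif metric == "jaccard":
        mat = pd.DataFrame(ssd.squareform(ssd.pdist(X > 0, metric="jaccard")),
                           index=ids, columns=ids)
    elif metric == "bray_curtis":
        mat = pd.DataFrame(ssd.squareform(ssd.pdist(X, metric="braycurtis")),
                           index=ids, columns=ids)
    elif metric == "jsd":
        P = X / X.sum(axis=1, keepdims=True)
        n = len(ids)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = _jsd(P[i], P[j])
        mat = pd.DataFrame(out, index=ids, columns=ids)
    else:
        raise ValueError(f"unknown beta metric {metric!r}")
    arr = mat.to_numpy()
    arr = 0.5 * (arr + arr.T)
    np.fill_diagonal(arr, 0.0)
    return DistanceMatrix(pd.DataFrame(arr, index=ids, columns=ids), metric)


# -- ordination -----------------------------------------------------------

_EIG_REL_TOL = 1e-10


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(d: DistanceMatrix) -> Ordination:
    """Classical PCoA: eigendecomposition of the double-centered matrix.

    Axes with eigenvalue <= tol * max eigenvalue are dropped; proportion
    explained is over the positive eigenvalues.
    """
    arr = d.values()
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 samples for ordination")
    g = _gower_center(arr)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals[0] <= 0:  # all-zero distances
        coords = pd.DataFrame(np.zeros((arr.shape[0], 1)), index=d.ids, columns=["PCo1"])
        return Ordination(coords, np.array([0.0]), np.array([0.0]))
    keep = vals > _EIG_REL_TOL * vals[0]
    vals_k, vecs_k = vals[keep], vecs[:, keep]
    coords = vecs_k * np.sqrt(vals_k)
    pos_sum = vals[vals > 0].sum()
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return Ordination(pd.DataFrame(coords, index=d.ids, columns=cols),
                      vals_k, vals_k / pos_sum)


# -- PERMANOVA ------------------------------------------------------------

def _dummy(values: pd.Series) -> np.ndarray:
    """Term columns: numeric covariates enter as-is, factors dummy-coded."""
    s = pd.Series(values)
    if pd.api.types.is_numeric_dtype(s):
        return s.to_numpy(dtype=float)[:, None]
    return pd.get_dummies(s.astype("category"), drop_first=True).to_numpy(dtype=float)


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())).sum())
    q = q[:, :rank]
    return q @ q.T


def permanova(d: DistanceMatrix, terms: dict[str, pd.Series] | pd.DataFrame,
              n_perm: int = 999, seed: int = 0) -> VarianceDecomposition:
    """Sequential-SS PERMANOVA (adonis-style) with free sample permutation.

    ``terms`` is an ordered mapping of term name to per-sample factor; sums
    of squares are sequential in that order.  Pseudo-F per term uses the
    residual of the full model; p-values permute rows of the Gower-centered
    matrix.
    """
    if isinstance(terms, pd.DataFrame):
        terms = {c: terms[c] for c in terms.columns}
    ids = d.ids
    n = len(ids)
    factors = {}
    for name, f in terms.items():
        f = pd.Series(f)
        if not set(ids).issubset(f.index):
            raise ValueError(f"term {name!r} missing samples")
        f = f.loc[ids]
        if f.nunique() < 2:
            raise ValueError(f"term {name!r} has a single level")
        factors[name] = f
    g = _gower_center(d.values())
    ss_total = float(np.trace(g))

    # sequential hat matrices
    design = np.ones((n, 1))
    hats, dfs = [], []
    prev_rank = 1
    for name, f in factors.items():
        design = np.hstack([design, _dummy(f)])
        h = _hat(design)
        rank = int(round(np.trace(h)))
        dfs.append(rank - prev_rank)
        prev_rank = rank
        hats.append(h)
    if prev_rank >= n:
        raise ValueError("more model parameters than samples")
    df_res = n - prev_rank

    def _stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_seq = []
        prev = 0.0
        for h in hats:
            cur = float(np.trace(h @ gmat))
            ss_seq.append(cur - prev)
            prev = cur
        ss_res = float(np.trace(gmat)) - prev
        return np.array(ss_seq), ss_res

    ss_terms, ss_res = _stats(g)
    ms_res = ss_res / df_res
    f_obs = (ss_terms / np.array(dfs)) / ms_res

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(hats))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = _stats(gp)
        f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)
        exceed += f_p >= f_obs
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    rows = []
    for name, ss, df, f, p in zip(factors, ss_terms, dfs, f_obs, pvals):
        rows.append((name, ss, df, ss / ss_total, f, p))
    rows.append(("residual", ss_res, df_res, ss_res / ss_total, np.nan, np.nan))
    rows.append(("total", ss_total, n - 1, 1.0, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "ss", "df", "r2", "F", "p"]).set_index("term")
    return VarianceDecomposition(table)


# -- univariate decompositions -------------------------------------------

def alpha_variance_decomposition(values: pd.Series, subject: pd.Series,
                                 timepoint: pd.Series,
                                 order: tuple[str, str] = ("subject", "timepoint"),
                                 ) -> VarianceDecomposition:
    """Two-way sequential ANOVA of an alpha-diversity value.

    Default order fits the subject (individual mother) first, then the
    timepoint (pregnancy week); fractions are SS/SS_total.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"value": values, "subject": subject.loc[values.index],
                       "timepoint": timepoint.loc[values.index]})
    if df["timepoint"].nunique() < 2:
        raise ValueError("need >= 2 timepoints")
    # confounding check: the second factor must add rank beyond the first
    ones = np.ones((len(df), 1))
    x1 = np.hstack([ones, _dummy(df[order[0]])])
    x2 = np.hstack([x1, _dummy(df[order[1]])])
    if np.linalg.matrix_rank(x2) <= np.linalg.matrix_rank(x1):
        raise ValueError(f"{order[1]} is confounded with {order[0]}")
    ss_total = float(((df["value"] - df["value"].mean()) ** 2).sum())
    if ss_total == 0:
        table = pd.DataFrame(
            [(order[0], 0.0, np.nan, 0.0, np.nan, np.nan),
             (order[1], 0.0, np.nan, 0.0, np.nan, np.nan),
             ("residual", 0.0, np.nan, 1.0, np.nan, np.nan),
             ("total", 0.0, len(df) - 1, 1.0, np.nan, np.nan)],
            columns=["term", "ss", "df", "r2", "F", "p"]).set_index("term")
        return VarianceDecomposition(table, degenerate=True)
    formula = f"value ~ C({order[0]}) + C({order[1]})"
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=1)
    rows = []
    for term in order:
        row = anova.loc[f"C({term})"]
        rows.append((term, float(row["sum_sq"]), float(row["df"]),
                     float(row["sum_sq"]) / ss_total, float(row["F"]), float(row["PR(>F)"])))
    res = anova.loc["Residual"]
    rows.append(("residual", float(res["sum_sq"]), float(res["df"]),
                 float(res["sum_sq"]) / ss_total, np.nan, np.nan))
    rows.append(("total", ss_total, len(df) - 1, 1.0, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "ss", "df", "r2", "F", "p"]).set_index("term")
    return VarianceDecomposition(table)


def coordinate_factor_r2(ordination: Ordination, axis: int,
                         factor: pd.Series) -> tuple[float, float]:
    """One-way ANOVA R^2 of one ordination axis on a factor.

    ``axis`` is 1-based (PCo1 = 1).  Returns (R^2, p); p is NaN when the
    model is saturated or the scores are constant.
    """
    if not 1 <= axis <= ordination.coordinates.shape[1]:
        raise ValueError(f"axis {axis} not present")
    scores = ordination.coordinates.iloc[:, axis - 1]
    f = pd.Series(factor).loc[scores.index].astype(str)
    k = f.nunique()
    if k < 2:
        raise ValueError("factor must have >= 2 levels")
    n = len(scores)
    ss_total = float(((scores - scores.mean()) ** 2).sum())
    if ss_total == 0:
        return 0.0, float("nan")
    means = scores.groupby(f).transform("mean")
    ss_between = float(((means - scores.mean()) ** 2).sum())
    r2 = ss_between / ss_total
    df1, df2 = k - 1, n - k
    if df2 <= 0:
        return r2, float("nan")
    ss_within = ss_total - ss_between
    if ss_within <= 0:
        return r2, 0.0
    fstat = (ss_between / df1) / (ss_within / df2)
    return r2, float(sst.f.sf(fstat, df1, df2))
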