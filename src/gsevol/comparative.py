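"""Comparative regression: OLS and phylogenetic GLS under Brownian motion.

Species are not independent samples — shared ancestry correlates their
traits.  Under a Brownian-motion model of trait evolution the expected
covariance between two species equals the branch length they share from the
root to their most recent common ancestor.  PGLS fits the same linear model
as OLS but with that covariance as the residual structure:

    beta = (X' V^-1 X)^-1 X' V^-1 y

The correlation suite regresses genome-size fold (GF) on each per-species
factor (repeat-class percentages, polyploidization fold, mean LTR insertion
time) with both OLS and PGLS on the pruned tree, plus a multiple regression
of LTR abundance on species age and insertion time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .metrics import SpeciesTable

logger = logging.getLogger(__name__)

#: factors regressed against genome-size fold by the suite
SUITE_FACTORS = (
    "tandem_pct", "LTR_pct", "LINE_pct", "SINE_pct", "DNA_pct",
    "pf", "mean_insertion_myr",
)

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class RegressionResult:
    """Coefficients and fit statistics of one OLS or PGLS model."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r_squared: float
    n: int
    df_resid: int
    method: str  # "OLS" | "PGLS"
    sigma2: float

    def __post_init__(self) -> None:
        if self.df_resid != self.n - len(self.params):
            raise ValueError("df_resid must equal n - number of coefficients")

    @property
    def slope(self) -> float:
        """Coefficient of the single non-intercept predictor."""
        others = [k for k in self.params.index if k != "intercept"]
        if len(others) != 1:
            raise ValueError("slope is defined only for single-predictor fits")
        return float(self.params[others[0]])

    @property
    def intercept(self) -> float:
        return float(self.params["intercept"])

    def significant(self, alpha: float = SIGNIFICANCE_LEVEL) -> bool:
        others = [k for k in self.params.index if k != "intercept"]
        return bool((self.pvalues[others] < alpha).any())


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def normalize_label(label: str) -> str:
    return "_".join(str(label).strip().split()).replace(" ", "_")


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def prune_tree(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    """Induced subtree on ``keep``; root-to-tip path lengths are preserved.

    Unary internal nodes created by pruning are suppressed with their branch
    lengths summed (dendropy's extraction semantics).
    """
    keep_norm = {normalize_label(k) for k in keep}
    if len(keep_norm) < 3:
        raise ValueError("need at least 3 tip labels to prune to")
    tips = {normalize_label(t.label): t.label for t in tree.taxon_namespace}
    missing = sorted(keep_norm - set(tips))
    if missing:
        raise ValueError(f"labels not in tree: {missing}")
    pruned = tree.extract_tree_with_taxa_labels(
        labels={tips[k] for k in keep_norm}
    )
    pruned.taxon_namespace = dendropy.TaxonNamespace(
        [t.label for t in pruned.taxon_namespace]
    )
    return pruned


def bm_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance: V[i, j] = root-to-MRCA(i, j) path length.

    Returns the matrix and tip labels in its row order.  Branch lengths must
    be non-negative; the root's own edge (above the root) is ignored.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    idx = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))

    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length if node.edge.length is not None else 0.0
        if bl < 0:
            raise ValueError(f"negative branch length {bl} in tree")
        depth[id(node)] = depth[id(node.parent_node)] + bl

    # tips below each node, accumulated postorder
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [idx[id(node)]]
            V[idx[id(node)], idx[id(node)]] = depth[id(node)]
        else:
            children = [below[id(c)] for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            V[i, j] = V[j, i] = d
            below[id(node)] = [i for ch in children for i in ch]
    return V, labels


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length per tip label."""
    out: dict[str, float] = {}
    for lf in tree.leaf_node_iter():
        d = 0.0
        node = lf
        while node is not tree.seed_node:
            d += node.edge.length or 0.0
            node = node.parent_node
        out[lf.taxon.label] = d
    return out


def terminal_branch_lengths(tree: dendropy.Tree) -> dict[str, float]:
    """Length of each tip's terminal branch: time since its last divergence.

    On an ultrametric tree this is the natural per-species 'age' proxy
    (root-to-tip depth is constant there and carries no signal).
    """
    return {
        lf.taxon.label: (lf.edge.length or 0.0) for lf in tree.leaf_node_iter()
    }


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

def _design(x: Mapping[str, Sequence[float]] | pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(x)
    if "intercept" not in X.columns:
        X.insert(0, "intercept", 1.0)
    return X


def ols_fit(x, y) -> RegressionResult:
    """Ordinary least squares with intercept; classical t-based inference."""
    X = _design(x)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than coefficients ({k})")
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        r_squared=float(fit.rsquared),
        n=n,
        df_resid=int(fit.df_resid),
        method="OLS",
        sigma2=float(fit.scale),
    )


def pgls_fit(x, y, V: np.ndarray) -> RegressionResult:
    """Phylogenetic GLS with a fixed Brownian-motion covariance V.

    Equivalent to OLS on data whitened by any square root L of V
    (y* = L^-1 y, X* = L^-1 X).  The reported R-squared is a pseudo-R²:
    1 - (r' V^-1 r) / (yc' V^-1 yc) with yc centred at the V-weighted mean.
    """
    X = _design(x)
    y = np.asarray(y, dtype=float)
    V = np.asarray(V, dtype=float)
    n, k = X.shape
    if V.shape != (n, n):
        raise ValueError(f"V must be {n}x{n}, got {V.shape}")
    if n <= k:
        raise ValueError(f"need more observations ({n}) than coefficients ({k})")
    try:
        np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        zero = list(np.where(np.diag(V) <= 0)[0])
        raise ValueError(
            f"covariance not positive definite (zero-variance rows: {zero})"
        )
    fit = sm.GLS(y, X, sigma=V).fit()
    resid = y - X.to_numpy() @ fit.params.to_numpy()
    Vi_r = np.linalg.solve(V, resid)
    ones = np.ones(n)
    Vi_1 = np.linalg.solve(V, ones)
    Vi_y = np.linalg.solve(V, y)
    mu = (ones @ Vi_y) / (ones @ Vi_1)
    yc = y - mu
    denom = yc @ np.linalg.solve(V, yc)
    pseudo_r2 = float(1.0 - (resid @ Vi_r) / denom) if denom > 0 else math.nan
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        r_squared=pseudo_r2,
        n=n,
        df_resid=int(fit.df_resid),
        method="PGLS",
        sigma2=float(fit.scale),
    )


# ---------------------------------------------------------------------------
# the correlation suite
# ---------------------------------------------------------------------------

@dataclass
class LabeledResult:
    factor: str
    method: str
    result: RegressionResult


def run_correlation_suite(
    table: SpeciesTable, tree: dendropy.Tree
) -> list[LabeledResult]:
    """OLS and PGLS of GF on every factor, plus the LTR multiple regression.

    Genome-size fold is the response; proportions enter as percentages.
    Species missing a factor are dropped pairwise per regression; factors
    with fewer than 3 complete observations are skipped with a log entry.
    The multiple regression models LTR percentage on species age (terminal
    branch length, i.e. time since the last divergence) and mean insertion
    time.
    """
    df = table.to_frame()
    df["species_norm"] = df["species"].map(normalize_label)
    tree_tips = {normalize_label(t.label): t.label for t in tree.taxon_namespace}
    shared = [s for s in df["species_norm"] if s in tree_tips]
    dropped = sorted(set(df["species_norm"]) - set(shared))
    if dropped:
        logger.info("species not in tree, dropped from PGLS: %s", dropped)
    if len(shared) < 4:
        raise ValueError("need at least 4 species shared between table and tree")
    pruned = prune_tree(tree, set(shared))
    V_all, v_labels = bm_covariance(pruned)
    v_pos = {normalize_label(l): i for i, l in enumerate(v_labels)}
    df = df[df["species_norm"].isin(v_pos)].copy()
    df["v_index"] = df["species_norm"].map(v_pos)

    results: list[LabeledResult] = []
    for factor in SUITE_FACTORS:
        sub = df[["v_index", factor, "gf"]].dropna()
        if len(sub) < 3:
            logger.info("factor %s: only %d observations, skipped", factor, len(sub))
            continue
        if np.ptp(sub[factor].to_numpy(dtype=float)) == 0:
            logger.info("factor %s: no variation across species, skipped", factor)
            continue
        x = {factor: sub[factor].to_numpy(dtype=float)}
        y = sub["gf"].to_numpy(dtype=float)
        results.append(LabeledResult(factor, "OLS", ols_fit(x, y)))
        vi = sub["v_index"].to_numpy()
        results.append(
            LabeledResult(factor, "PGLS", pgls_fit(x, y, V_all[np.ix_(vi, vi)]))
        )

    # LTR abundance vs (species age, insertion time); age = terminal branch
    ages = terminal_branch_lengths(pruned)
    df["age"] = df["species_norm"].map(
        {normalize_label(k): v for k, v in ages.items()}
    )
    sub = df[["LTR_pct", "age", "mean_insertion_myr"]].dropna()
    if len(sub) >= 4:
        results.append(
            LabeledResult(
                "LTR_pct~age+insertion",
                "OLS-multiple",
                ols_fit(
                    {
                        "age": sub["age"].to_numpy(dtype=float),
                        "mean_insertion_myr": sub["mean_insertion_myr"].to_numpy(dtype=float),
                    },
                    sub["LTR_pct"].to_numpy(dtype=float),
                ),
            )
        )
    else:
        logger.info("multiple regression skipped: %d complete observations", len(sub))
    return results


def results_to_frame(results: Sequence[LabeledResult]) -> pd.DataFrame:
    """Flatten suite results into the tabular report (one row per predictor)."""
    rows = []
    for lr in results:
        r = lr.result
        for name in r.params.index:
            if name == "intercept":
                continue
            rows.append(
                {
                    "factor": lr.factor,
                    "method": lr.method,
                    "predictor": name,
                    "slope": r.params[name],
                    "intercept": r.params["intercept"],
                    "se": r.bse[name],
                    "t": r.tvalues[name],
                    "p": r.pvalues[name],
                    "r_squared": r.r_squared,
                    "n": r.n,
                }
            )
    return pd.DataFrame(rows)
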