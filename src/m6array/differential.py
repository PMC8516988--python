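"""Differential methylation/expression between patient (T) and control (N) groups.

For every probe the analyzer computes, from a :class:`MethylationProfile`:

* ``fc_meth_ratio`` — mean_T(meth level) / mean_N(meth level), a linear ratio;
* ``fc_m6a_log2``  — mean_T(log2 m6A quantity) - mean_N(log2 m6A quantity);
* ``fc_ge_log2``   — the same contrast on log2 expression;
* two-sided unpaired t-test p-values for each of the three quantities;
* a regulation class combining the methylation axis (Hyper/Hypo) with the
  expression axis (-up/-down): a probe is Hypo when its methylation signal is
  significantly lower in T than N, Hyper when higher; the suffix comes from
  the expression contrast. Probes failing significance on either axis are
  ``ns``.

Fold changes are always T relative to N, so a negative log2 FC means lower
in patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .datatypes import REGULATION_LABELS, Locus, MethylationProfile

FC_BASES = ("quantity", "meth_level")
TOP_TABLE_KEYS = {
    "m6a_fc_asc": ("fc_m6a_log2", True),
    "m6a_fc_desc": ("fc_m6a_log2", False),
    "meth_ratio_asc": ("fc_meth_ratio", True),
    "meth_ratio_desc": ("fc_meth_ratio", False),
    "ge_fc_asc": ("fc_ge_log2", True),
    "ge_fc_desc": ("fc_ge_log2", False),
    "p_m6a_asc": ("p_m6a", True),
    "p_meth_asc": ("p_meth", True),
}


@dataclass
class ClassificationThresholds:
    """Cutoffs for the hyper/hypo x up/down call.

    Defaults are significance at ``alpha = 0.05`` with sign-only fold-change
    requirements (``fc_log2_min = 0`` and ``meth_ratio_bounds = (1, 1)``),
    i.e. any significant shift counts, since the study reports p < 0.05 as
    its significance rule without printed fold-change cutoffs.
    """

    alpha: float = 0.05
    fc_log2_min: float = 0.0
    meth_ratio_bounds: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_log2_min < 0:
            raise ValueError("fc_log2_min must be non-negative")
        lo, hi = self.meth_ratio_bounds
        if not 0 < lo <= hi:
            raise ValueError("meth_ratio_bounds must satisfy 0 < lo <= hi")


def unpaired_t_test(x, y, variant: str = "student") -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns ``(t, df, p)``.

    ``variant='student'`` is the pooled-variance test, ``'welch'`` the
    unequal-variance form. Degenerate zero-variance inputs follow the
    documented limits: equal constant groups give p = 1, unequal constant
    groups give p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    equal_var = variant == "student"
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        df = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        return float("inf") * np.sign(x.mean() - y.mean()), df, 0.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


class TwoGroupTTest(BaseEstimator):
    """Feature-wise two-sample t-test in the scikit-learn estimator idiom.

    ``fit(X, y)`` takes ``X`` of shape (n_samples, n_features) and a binary
    group vector ``y``; afterwards ``statistic_``, ``pvalue_`` and
    ``mean_difference_`` (group1 - group0 feature means) are available.
    NaN cells are omitted pairwise; features with fewer than two finite
    observations in either group get NaN results.
    """

    def __init__(self, variant: str = "student"):
        self.variant = variant

    def fit(self, X, y):
        X = check_array(X, dtype=float, ensure_all_finite="allow-nan")
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.shape[0] != 2:
            raise ValueError("y must contain exactly two groups")
        if self.variant not in ("student", "welch"):
            raise ValueError(f"unknown variant {self.variant!r}")
        a, b = X[y == classes[1]], X[y == classes[0]]
        na = np.sum(np.isfinite(a), axis=0)
        nb = np.sum(np.isfinite(b), axis=0)
        valid = (na >= 2) & (nb >= 2)
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # zero-variance features trip scipy's precision-loss warning; the
            # degenerate limits are assigned explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(
                a, b, equal_var=self.variant == "student", nan_policy="omit", axis=0
            )
            stat = np.asarray(res.statistic, dtype=float)
            pval = np.asarray(res.pvalue, dtype=float)
            mean_a = np.nanmean(np.where(np.isfinite(a), a, np.nan), axis=0)
            mean_b = np.nanmean(np.where(np.isfinite(b), b, np.nan), axis=0)
        # degenerate zero-variance features: documented limit values
        va = np.nanvar(a, axis=0, ddof=1)
        vb = np.nanvar(b, axis=0, ddof=1)
        degen = valid & np.isclose(va + vb, 0.0)
        eq = degen & np.isclose(mean_a, mean_b)
        pval[degen] = 0.0
        pval[eq] = 1.0
        stat[eq] = 0.0
        stat[~valid] = np.nan
        pval[~valid] = np.nan
        self.classes_ = classes
        self.statistic_ = stat
        self.pvalue_ = pval
        self.mean_difference_ = mean_a - mean_b
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X, y):  # convenience: p-values as the "transform"
        return self.fit(X, y).pvalue_


def fold_changes(profile: MethylationProfile) -> pd.DataFrame:
    """Per-probe T-vs-N fold changes on all three quantities.

    Probes with a zero control-group mean methylation level, or with fewer
    than two finite observations in either group, get NaN (missing) entries.
    """
    t_cols = profile.group_samples("T")
    n_cols = profile.group_samples("N")
    if len(t_cols) < 2 or len(n_cols) < 2:
        raise ValueError("need at least two samples per group")

    def _group_mean(mat: pd.DataFrame, cols) -> pd.Series:
        sub = mat[cols]
        ok = sub.notna().sum(axis=1) >= 2
        m = sub.mean(axis=1, skipna=True)
        return m.where(ok)

    meth_t = _group_mean(profile.meth_level, t_cols)
    meth_n = _group_mean(profile.meth_level, n_cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = meth_t / meth_n.where(meth_n > 0)

    log_q = np.log2(profile.m6a_quantity)
    log_e = np.log2(profile.expression)
    fc_m6a = _group_mean(log_q, t_cols) - _group_mean(log_q, n_cols)
    fc_ge = _group_mean(log_e, t_cols) - _group_mean(log_e, n_cols)

    return pd.DataFrame(
        {"fc_meth_ratio": ratio, "fc_m6a_log2": fc_m6a, "fc_ge_log2": fc_ge}
    )


def classify_regulation(
    table: pd.DataFrame,
    thresholds: ClassificationThresholds | None = None,
    fc_basis: str = "quantity",
) -> pd.Series:
    """Assign each record exactly one label in {Hyper-up, Hyper-down, Hypo-up, Hypo-down, ns}.

    The methylation axis uses the m6A-quantity contrast by default
    (``fc_m6a_log2`` with ``p_m6a``); ``fc_basis='meth_level'`` switches it to
    the methylation-ratio contrast (``fc_meth_ratio`` against
    ``meth_ratio_bounds`` with ``p_meth``). The expression axis always uses
    ``fc_ge_log2`` with ``p_ge``. Both axes must be individually significant
    for a combined label; anything else is ``ns``.
    """
    thr = thresholds or ClassificationThresholds()
    if fc_basis not in FC_BASES:
        raise ValueError(f"fc_basis must be one of {FC_BASES}")

    if fc_basis == "quantity":
        fc, p = table["fc_m6a_log2"], table["p_m6a"]
        hypo = (p <= thr.alpha) & (fc < 0) & (fc.abs() >= thr.fc_log2_min) & (fc != 0)
        hyper = (p <= thr.alpha) & (fc > 0) & (fc.abs() >= thr.fc_log2_min)
    else:
        ratio, p = table["fc_meth_ratio"], table["p_meth"]
        lo, hi = thr.meth_ratio_bounds
        hypo = (p <= thr.alpha) & (ratio < lo)
        hyper = (p <= thr.alpha) & (ratio > hi)

    ge_fc, ge_p = table["fc_ge_log2"], table["p_ge"]
    down = (ge_p <= thr.alpha) & (ge_fc < 0) & (ge_fc.abs() >= thr.fc_log2_min)
    up = (ge_p <= thr.alpha) & (ge_fc > 0) & (ge_fc.abs() >= thr.fc_log2_min)

    labels = pd.Series("ns", index=table.index, dtype=object)
    labels[hypo & down] = "Hypo-down"
    labels[hypo & up] = "Hypo-up"
    labels[hyper & down] = "Hyper-down"
    labels[hyper & up] = "Hyper-up"
    assert labels.isin(REGULATION_LABELS).all()
    return labels


class DifferentialAnalyzer(BaseEstimator):
    """Fit the full T-vs-N differential table from a methylation profile.

    Parameters
    ----------
    variant : 'student' (pooled variance, default) or 'welch'.
    fc_basis : which contrast defines the Hyper/Hypo axis
        ('quantity' default, 'meth_level' alternative).
    alpha, fc_log2_min, meth_ratio_bounds : see :class:`ClassificationThresholds`.
    bh : add Benjamini-Hochberg adjusted q-value columns (raw p-values are
        always reported; the adjustment is an extra column, never a filter).

    After ``fit(profile)`` the differential table is in ``results_``.
    """

    def __init__(self, variant: str = "student", fc_basis: str = "quantity",
                 alpha: float = 0.05, fc_log2_min: float = 0.0,
                 meth_ratio_bounds: tuple[float, float] = (1.0, 1.0),
                 bh: bool = False):
        self.variant = variant
        self.fc_basis = fc_basis
        self.alpha = alpha
        self.fc_log2_min = fc_log2_min
        self.meth_ratio_bounds = meth_ratio_bounds
        self.bh = bh

    def fit(self, profile: MethylationProfile, y=None):
        thr = ClassificationThresholds(
            alpha=self.alpha, fc_log2_min=self.fc_log2_min,
            meth_ratio_bounds=tuple(self.meth_ratio_bounds),
        )
        groups = (profile.samples["group"] == "T").to_numpy().astype(int)
        table = fold_changes(profile)

        tester = TwoGroupTTest(variant=self.variant)
        table["p_meth"] = tester.fit_transform(profile.meth_level.to_numpy().T, groups)
        table["p_m6a"] = tester.fit_transform(
            np.log2(profile.m6a_quantity.to_numpy()).T, groups
        )
        table["p_ge"] = tester.fit_transform(
            np.log2(profile.expression.to_numpy()).T, groups
        )
        if self.bh:
            for col in ("p_meth", "p_m6a", "p_ge"):
                q = np.full(len(table), np.nan)
                ok = table[col].notna().to_numpy()
                if ok.any():
                    q[ok] = stats.false_discovery_control(table[col].to_numpy()[ok])
                table[col.replace("p_", "q_")] = q

        table["regulation"] = classify_regulation(table, thr, fc_basis=self.fc_basis)
        table.insert(0, "gene_symbol", profile.probes["gene_symbol"])
        table.insert(1, "rna_type", profile.probes["rna_type"])
        table["locus"] = [
            str(Locus(r.chrom, int(r.start), int(r.end), r.strand))
            for r in profile.probes.itertuples()
        ]
        self.results_ = table
        self.thresholds_ = thr
        return self

    def predict(self, profile: MethylationProfile = None) -> pd.Series:
        if profile is not None:
            return DifferentialAnalyzer(**self.get_params()).fit(profile).results_["regulation"]
        check_is_fitted(self, "results_")
        return self.results_["regulation"]


def differential_table(profile: MethylationProfile, **params) -> pd.DataFrame:
    """Functional wrapper over :class:`DifferentialAnalyzer`."""
    return DifferentialAnalyzer(**params).fit(profile).results_


def top_table(
    records: pd.DataFrame,
    n: int,
    key: str = "m6a_fc_asc",
    regulation_filter: set[str] | None = None,
) -> pd.DataFrame:
    """Select the top ``n`` records by a sort key, within a regulation subset.

    Sorting is stable with ties broken by probe id (the index), so repeated
    runs and permuted inputs produce the same table. ``n`` larger than the
    filtered table returns everything.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if key not in TOP_TABLE_KEYS:
        raise ValueError(f"unknown sort key {key!r}; choose from {sorted(TOP_TABLE_KEYS)}")
    column, ascending = TOP_TABLE_KEYS[key]
    sub = records
    if regulation_filter is not None:
        sub = sub[sub["regulation"].isin(set(regulation_filter))]
    sub = sub[sub[column].notna()]
    order = sub.reset_index().sort_values(
        [column, sub.index.name or "index"],
        ascending=[ascending, True], kind="mergesort",
    )
    return order.set_index(sub.index.name or "index").head(n)


@dataclass
class ClusterResult:
    """Agglomerative clustering output: linkage matrix, leaf order, newick tree."""

    linkage_matrix: np.ndarray
    labels: list[str]
    leaf_order: list[str] = field(init=False)
    newick: str = field(init=False)

    def __post_init__(self) -> None:
        leaves = hierarchy.leaves_list(self.linkage_matrix)
        self.leaf_order = [self.labels[i] for i in leaves]
        self.newick = _to_newick(self.linkage_matrix, self.labels)


def hierarchical_cluster(
    matrix: pd.DataFrame, distance: str = "euclidean", linkage: str = "average"
) -> ClusterResult:
    """Agglomerative clustering of the matrix rows.

    Rows are sorted by label before linkage so that distance ties are broken
    by item id and the tree topology is independent of input order.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two items to cluster")
    ordered = matrix.sort_index(kind="mergesort")
    values = ordered.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("clustering input contains non-finite values")
    z = hierarchy.linkage(values, method=linkage, metric=distance)
    return ClusterResult(linkage_matrix=z, labels=[str(x) for x in ordered.index])


def _to_newick(z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
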