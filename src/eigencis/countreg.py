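"""Grouped weighted least-squares regression of loadings on motif counts.

Single-gene loadings are far from normal, so inference runs on *group
means*: genes are grouped by exact integer motif (or CNS) count, the group
mean loading is the response, and weighted least squares with weights equal
to group sizes handles the heteroskedasticity that shrinking group sizes
induce (group-mean variance ~ sigma^2 / n_g).  A Goldfeld-Quandt test
quantifies that heteroskedasticity and a Shapiro-Wilk test reports (never
gates on) residual normality.  Eligibility follows the counting semantics:
regressions on a motif count use only genes with at least one CNS, while
regressions on the CNS count include zero-CNS genes.

The bivariate path analysis decomposes the CNS-count effect on loadings
into a direct part and an indirect part mediated by the motif count:

        CNS count --(3)--> motif count
            \\  (1,4)          |  (2,5)
             \\---------> loading

edges 1-3 are univariate grouped WLS fits, edges 4-5 the two coefficients
of one bivariate grouped WLS fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DataContractError, NumericalError


@dataclass
class CountGroups:
    """Group statistics keyed by integer count value(s)."""

    table: pd.DataFrame  # columns: count columns..., n, mean, sd
    count_cols: list[str]
    n_genes: int

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class WLSFit:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rsquared: float
    df_resid: int
    residuals: np.ndarray
    weights: np.ndarray
    fitted: np.ndarray
    groups: CountGroups | None = None

    @property
    def slope(self) -> float:
        return float(self.params.iloc[1])

    @property
    def slope_se(self) -> float:
        return float(self.bse.iloc[1])


@dataclass
class GQResult:
    statistic: float
    pvalue: float
    split: str


@dataclass
class PathGraph:
    """Five-edge path diagram: each edge carries (alpha, p)."""

    edges: dict[str, dict] = field(default_factory=dict)


def group_by_count(
    loadings, counts, eligibility=None
) -> CountGroups:
    """Mean/SD/size of loadings per exact integer count value.

    ``counts`` may be a Series (univariate) or DataFrame with two columns
    (bivariate grouping on count pairs).  ``eligibility`` is an optional
    boolean mask applied before grouping (e.g. CNS count >= 1 in
    motif-regressor mode).  Singleton groups keep SD as NaN.
    """
    y = pd.Series(loadings).astype(float)
    c = pd.DataFrame(counts)
    c = c.set_index(y.index) if len(c) == len(y) else c.reindex(y.index)
    if eligibility is not None:
        mask = pd.Series(eligibility, index=y.index).astype(bool)
        y, c = y[mask], c[mask]
    if len(y) == 0:
        raise DataContractError("no eligible genes to group")
    count_cols = list(c.columns)
    df = c.copy()
    df["_y"] = y
    g = df.groupby(count_cols)["_y"]
    table = g.agg(n="count", mean="mean", sd="std").reset_index()
    return CountGroups(table=table, count_cols=count_cols, n_genes=int(len(y)))


def wls_fit(groups: CountGroups) -> WLSFit:
    """WLS of group-mean loading on count(s); weights = group sizes."""
    t = groups.table
    n_params = len(groups.count_cols) + 1
    if len(t) < n_params + 1:
        raise DataContractError(
            f"need >= {n_params + 1} groups for {n_params - 1} regressor(s), got {len(t)}"
        )
    X = sm.add_constant(t[groups.count_cols].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise NumericalError(
            f"collinear regressors {groups.count_cols}: design matrix is rank deficient"
        )
    res = sm.WLS(t["mean"].astype(float), X, weights=t["n"].astype(float)).fit()
    return WLSFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        rsquared=float(res.rsquared),
        df_resid=int(res.df_resid),
        residuals=np.asarray(res.resid),
        weights=t["n"].to_numpy(dtype=float),
        fitted=np.asarray(res.fittedvalues),
        groups=groups,
    )


def gq_test(y, x, split_frac: float = 1.0 / 3.0) -> GQResult:
    """Goldfeld-Quandt heteroskedasticity test on observations ordered by x.

    The lower and upper ``split_frac`` segments (middle excluded) are fitted
    separately by OLS; the statistic is the upper/lower residual-variance
    ratio, with a one-sided F p-value.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    y, x = y[order], x[order]
    n = len(y)
    n_seg = int(np.floor(n * split_frac))
    if n_seg < 3:
        raise DataContractError("fewer than 3 observations per GQ segment")
    from statsmodels.stats.diagnostic import het_goldfeldquandt

    X = sm.add_constant(x)
    stat, p, _ = het_goldfeldquandt(
        y, X, split=n_seg, drop=n - 2 * n_seg, alternative="increasing"
    )
    return GQResult(
        statistic=float(stat),
        pvalue=float(p),
        split=f"lower/upper {split_frac:.3f} segments, middle excluded",
    )


def residual_normality(fit: WLSFit):
    """Shapiro-Wilk on sqrt(weight)-scaled residuals; (W, p) or flagged None."""
    r = fit.residuals * np.sqrt(fit.weights)
    if len(r) < 3:
        raise DataContractError("need >= 3 residuals for a normality check")
    if np.allclose(r, r[0]):
        return None, None  # degenerate: identical residuals, p omitted
    w, p = stats.shapiro(r)
    return float(w), float(p)


def path_analysis(loadings, cns_counts, motif_counts) -> PathGraph:
    """Univariate + bivariate grouped WLS path analysis.

    Edge 1: loading ~ CNS count (all genes, zero-CNS included).
    Edge 2: loading ~ motif count (genes with >= 1 CNS).
    Edge 3: motif count ~ CNS count (genes with >= 1 CNS).
    Edges 4, 5: loading ~ CNS count + motif count (bivariate, all genes).
    """
    y = pd.Series(loadings).astype(float)
    cns = pd.Series(cns_counts).reindex(y.index).astype(int)
    mot = pd.Series(motif_counts).reindex(y.index).astype(int)
    has_cns = cns >= 1

    g1 = group_by_count(y, cns.rename("cns_count"))
    f1 = wls_fit(g1)
    g2 = group_by_count(y, mot.rename("motif_count"), eligibility=has_cns)
    f2 = wls_fit(g2)
    g3 = group_by_count(mot.astype(float), cns.rename("cns_count"), eligibility=has_cns)
    f3 = wls_fit(g3)
    g45 = group_by_count(
        y, pd.DataFrame({"cns_count": cns, "motif_count": mot})
    )
    f45 = wls_fit(g45)

    graph = PathGraph()
    graph.edges["1_loading_on_cns"] = {
        "alpha": f1.slope, "p": float(f1.pvalues.iloc[1]), "fit": f1}
    graph.edges["2_loading_on_motif"] = {
        "alpha": f2.slope, "p": float(f2.pvalues.iloc[1]), "fit": f2}
    graph.edges["3_motif_on_cns"] = {
        "alpha": f3.slope, "p": float(f3.pvalues.iloc[1]), "fit": f3}
    graph.edges["4_loading_on_cns_given_motif"] = {
        "alpha": float(f45.params["cns_count"]),
        "p": float(f45.pvalues["cns_count"]), "fit": f45}
    graph.edges["5_loading_on_motif_given_cns"] = {
        "alpha": float(f45.params["motif_count"]),
        "p": float(f45.pvalues["motif_count"]), "fit": f45}
    return graph


class GroupedCountRegression(BaseEstimator, RegressorMixin):
    """sklearn-style wrapper: loadings regressed on integer counts via
    grouped WLS (groups = exact count values, weights = group sizes).

    Parameters
    ----------
    require_cns : bool
        Motif-regressor eligibility rule — drop genes whose CNS count (the
        ``eligibility_counts`` argument of ``fit``) is zero.

    Fitted attributes: ``groups_``, ``coef_``, ``intercept_``, ``stderr_``,
    ``pvalues_``, ``rsquared_``, ``gq_``, ``normality_``.
    """

    def __init__(self, require_cns: bool = False, gq_split: float = 1.0 / 3.0):
        self.require_cns = require_cns
        self.gq_split = gq_split

    def fit(self, X, y, eligibility_counts=None):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        elig = None
        if self.require_cns:
            if eligibility_counts is None:
                raise DataContractError(
                    "require_cns=True needs eligibility_counts (per-gene CNS counts)"
                )
            elig = pd.Series(eligibility_counts, index=X.index).astype(int) >= 1
        self.groups_ = group_by_count(y, X, eligibility=elig)
        fit = wls_fit(self.groups_)
        self.fit_ = fit
        self.intercept_ = float(fit.params.iloc[0])
        self.coef_ = fit.params.iloc[1:].to_numpy()
        self.stderr_ = fit.bse.iloc[1:].to_numpy()
        self.pvalues_ = fit.pvalues.iloc[1:].to_numpy()
        self.rsquared_ = fit.rsquared
        t = self.groups_.table
        try:
            self.gq_ = gq_test(
                t["mean"], t[self.groups_.count_cols[0]], split_frac=self.gq_split
            )
        except DataContractError:
            self.gq_ = None
        self.normality_ = residual_normality(fit)
        return self

    def predict(self, X):
        X = pd.DataFrame(X).astype(float).to_numpy()
        return self.intercept_ + X @ self.coef_
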