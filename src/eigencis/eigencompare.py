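"""Per-system SVD and cross-system eigenarray conservation testing.

Each genes x conditions matrix X is decomposed as X = U diag(s) V^T (thin
SVD).  Columns of U are *eigenarrays* (per-gene loadings), columns of V are
*eigengenes* (temporal activity patterns).  Conservation between two systems
is measured by the Pearson correlation of matched eigenarrays restricted to
the common genes; its significance comes from the classic correlation t test
t = r * sqrt(d / (1 - r^2)) with d = n - 2 degrees of freedom, evaluated in
log space so astronomically small p-values keep a meaningful magnitude.

Sign convention: every eigensystem is oriented so the eigengene entry of
largest magnitude is positive (ties broken by earliest condition index).
SVD signs are arbitrary; a fixed convention makes outputs reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataContractError, NumericalError

from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class EigenDecomposition:
    """Thin SVD of one system's gene-expression matrix."""

    gene_ids: list[str]
    condition_ids: list[str]
    eigenarrays: pd.DataFrame  # genes x K, orthonormal columns (U)
    singular_values: np.ndarray  # length K, descending
    eigengenes: pd.DataFrame  # conditions x K, orthonormal columns (V)

    @property
    def k(self) -> int:
        return len(self.singular_values)

    def reconstruct(self) -> pd.DataFrame:
        x = self.eigenarrays.to_numpy() @ np.diag(self.singular_values)
        x = x @ self.eigengenes.to_numpy().T
        return pd.DataFrame(x, index=self.gene_ids, columns=self.condition_ids)


@dataclass
class EigensystemMatch:
    k_a: int  # 1-based eigensystem indices
    k_b: int
    r: float
    n: int
    d: int
    t: float
    p: float
    log10_p: float
    sign_flip: bool


@dataclass
class SignedLoadings:
    gene_ids: list[str]
    eigensystem: int
    loadings: pd.Series
    labels: pd.Series  # +1 up / -1 down, exact zeros excluded
    n_zero_excluded: int


class EigenDecomposer(BaseEstimator, TransformerMixin):
    """SVD transformer with a deterministic sign convention.

    Parameters
    ----------
    n_components : int or None
        Number of eigensystems to keep; ``None`` keeps all (= number of
        conditions for a genes >= conditions matrix).

    Attributes (after ``fit``)
    --------------------------
    loadings_ : DataFrame, genes x K — eigenarrays (columns of U).
    singular_values_ : ndarray, descending.
    eigengenes_ : DataFrame, conditions x K (columns of V).
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None) -> "EigenDecomposer":
        X = pd.DataFrame(X)
        arr = X.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = X.index[~np.isfinite(arr).all(axis=1)]
            raise NumericalError(f"non-finite expression values for genes: {list(bad[:5])}")
        u, s, vt = np.linalg.svd(arr, full_matrices=False)
        k = s.shape[0] if self.n_components is None else min(self.n_components, s.shape[0])
        u, s, v = u[:, :k], s[:k], vt[:k].T
        # orient: largest-magnitude eigengene entry positive (ties: earliest)
        for j in range(k):
            i = int(np.argmax(np.abs(v[:, j])))
            if v[i, j] < 0:
                v[:, j] = -v[:, j]
                u[:, j] = -u[:, j]
        cols = [f"E{j + 1}" for j in range(k)]
        self.loadings_ = pd.DataFrame(u, index=X.index, columns=cols)
        self.singular_values_ = s
        self.eigengenes_ = pd.DataFrame(v, index=X.columns, columns=cols)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Project (possibly new) gene profiles onto the eigengene basis."""
        X = pd.DataFrame(X)
        with np.errstate(divide="ignore"):
            inv_s = np.where(self.singular_values_ > 0, 1.0 / self.singular_values_, 0.0)
        proj = X.to_numpy(dtype=float) @ self.eigengenes_.to_numpy() * inv_s
        return pd.DataFrame(proj, index=X.index, columns=self.loadings_.columns)


def _as_frame(X) -> pd.DataFrame:
    """Unwrap a GeneExpressionMatrix-like object or pass a DataFrame through."""
    if isinstance(X, pd.DataFrame):
        return X
    inner = getattr(X, "values", None)
    if isinstance(inner, pd.DataFrame):
        return inner
    return pd.DataFrame(X)


def decompose(X) -> EigenDecomposition:
    """Thin SVD of a gene-expression matrix (genes x conditions)."""
    values = _as_frame(X)
    est = EigenDecomposer().fit(values)
    return EigenDecomposition(
        gene_ids=list(values.index),
        condition_ids=list(values.columns),
        eigenarrays=est.loadings_,
        singular_values=est.singular_values_,
        eigengenes=est.eigengenes_,
    )


def correlation_pvalue(r: float, n: int):
    """Two-sided p-value for a Pearson correlation on n pairs.

    Returns ``(t, p, log10_p, degenerate)``.  ``log10_p`` stays finite down
    to magnitudes ~1e-300 and below (computed from the log survival
    function), so the power of ten is always reportable; ``p`` itself may
    underflow to 0.  ``degenerate`` flags |r| = 1, where p is reported as 0.
    """
    if n < 3:
        raise DataContractError("correlation p-value needs n >= 3")
    d = n - 2
    if abs(r) >= 1.0:
        return np.inf if r > 0 else -np.inf, 0.0, -np.inf, True
    t = r * np.sqrt(d / (1.0 - r * r))
    log_p = stats.t.logsf(abs(t), d) + np.log(2.0)
    if not np.isfinite(log_p):
        # beyond double underflow (~1e-323): exact tail via the regularized
        # incomplete beta in arbitrary precision, keeping the power of ten
        import mpmath as mp

        x = mp.mpf(d) / (mp.mpf(d) + mp.mpf(t) ** 2)
        sf = mp.betainc(mp.mpf(d) / 2, mp.mpf("0.5"), 0, x, regularized=True) / 2
        log_p = float(mp.log(2 * sf))
    log10_p = log_p / np.log(10.0)
    return float(t), float(np.exp(log_p)), float(log10_p), False


def match_eigenarrays(
    e_a: EigenDecomposition, e_b: EigenDecomposition, k_max: int | None = None
) -> tuple[list[EigensystemMatch], pd.DataFrame]:
    """Greedy one-to-one eigenarray matching on |r| over the common genes.

    Returns the ordered matches plus the full K_A x K_B correlation grid.
    ``sign_flip`` is set when r < 0; downstream consumers should negate the
    system-B loadings of that eigensystem.
    """
    common = [g for g in e_a.gene_ids if g in set(e_b.gene_ids)]
    if len(common) < 3:
        raise DataContractError(
            f"need >= 3 common genes to compare eigenarrays, got {len(common)}"
        )
    ka = e_a.k if k_max is None else min(k_max, e_a.k)
    kb = e_b.k if k_max is None else min(k_max, e_b.k)
    ua = e_a.eigenarrays.loc[common].to_numpy()[:, :ka]
    ub = e_b.eigenarrays.loc[common].to_numpy()[:, :kb]
    n = len(common)
    za = (ua - ua.mean(0)) / np.maximum(ua.std(0), 1e-300)
    zb = (ub - ub.mean(0)) / np.maximum(ub.std(0), 1e-300)
    grid = za.T @ zb / n
    grid_df = pd.DataFrame(
        grid,
        index=[f"A{j + 1}" for j in range(ka)],
        columns=[f"B{j + 1}" for j in range(kb)],
    )

    matches: list[EigensystemMatch] = []
    remaining = np.abs(grid).copy()
    for _ in range(min(ka, kb)):
        i, j = np.unravel_index(np.argmax(remaining), remaining.shape)
        r = float(grid[i, j])
        t, p, lp, _ = correlation_pvalue(r, n)
        matches.append(
            EigensystemMatch(
                k_a=int(i) + 1,
                k_b=int(j) + 1,
                r=r,
                n=n,
                d=n - 2,
                t=t,
                p=p,
                log10_p=lp,
                sign_flip=r < 0,
            )
        )
        remaining[i, :] = -np.inf
        remaining[:, j] = -np.inf
    return matches, grid_df


def binarize_loadings(e: EigenDecomposition, k: int) -> SignedLoadings:
    """Label genes up/down by the sign of their loading on eigensystem k (1-based)."""
    if not 1 <= k <= e.k:
        raise DataContractError(f"eigensystem index {k} out of range 1..{e.k}")
    col = e.eigenarrays.iloc[:, k - 1]
    nonzero = col[col != 0.0]
    labels = np.sign(nonzero).astype(int)
    return SignedLoadings(
        gene_ids=list(nonzero.index),
        eigensystem=k,
        loadings=nonzero,
        labels=pd.Series(labels, index=nonzero.index),
        n_zero_excluded=int((col == 0.0).sum()),
    )


def robustness_check(
    x_loose: pd.DataFrame, x_strict: pd.DataFrame, k_max: int = 3
) -> pd.Series:
    """Correlate top-k eigenarrays from a loose vs strict gene filtering.

    The strict gene set must be a subset of the loose one; correlations are
    computed on the strict (shared) genes, sign-insensitively.
    """
    loose_vals = _as_frame(x_loose)
    strict_vals = _as_frame(x_strict)
    loose_genes = set(loose_vals.index)
    strict_genes = list(strict_vals.index)
    if not set(strict_genes) <= loose_genes:
        raise DataContractError("strict gene set is not a subset of the loose gene set")
    e_loose = decompose(loose_vals)
    e_strict = decompose(strict_vals)
    k = min(k_max, e_loose.k, e_strict.k)
    out = {}
    for j in range(k):
        a = e_loose.eigenarrays.loc[strict_genes].iloc[:, j].to_numpy()
        b = e_strict.eigenarrays.iloc[:, j].to_numpy()
        out[f"E{j + 1}"] = float(abs(np.corrcoef(a, b)[0, 1]))
    return pd.Series(out, name="r_loose_vs_strict")


def write_decomposition(e: EigenDecomposition, outdir, prefix: str) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    e.eigenarrays.to_csv(out / f"{prefix}_eigenarrays.tsv", sep="\t", index_label="gene_id")
    e.eigengenes.to_csv(out / f"{prefix}_eigengenes.tsv", sep="\t", index_label="condition_id")
    pd.Series(e.singular_values, name="singular_value").to_csv(
        out / f"{prefix}_singular_values.tsv", sep="\t", index_label="k"
    )


def match_report(matches: list[EigensystemMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "k_a": m.k_a,
                "k_b": m.k_b,
                "r": m.r,
                "n": m.n,
                "t": m.t,
                "p_log10": m.log10_p,
                "sign_flip": m.sign_flip,
            }
            for m in matches
        ]
    )
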