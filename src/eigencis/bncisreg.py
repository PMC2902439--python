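"""Bayesian parent-set selection for cis-regulation of loading signs.

The model has one binary expression node (the sign of a gene's loading on a
chosen conserved eigensystem) and one binary node per composite motif; all
edges point from motifs to the expression node, so structure learning
reduces to choosing the best parent set.  Parent sets are scored by the
Bayesian-Dirichlet equivalence (BDeu) marginal likelihood times a structure
prior proportional to kappa^(total motif-family count of the set), kappa < 1,
which penalises larger composites.  The *BN score* of a set is the ratio of
its posterior to the posterior of the empty set.

Search is a two-step procedure: Step 1 ranks every composite as a singleton
parent and keeps a candidate pool; Step 2 exhaustively scores every subset
of the pool with at most ``max_parents`` members — exact by construction.
Significance comes from permutation q-values: the labels are permuted
against the feature table, the full two-step search is rerun, and the
optimal score per permutation forms the null; q(s) is the fraction of
permutation optima >= s.  Cross-system validation scores the top training
features on the other system's data (Step-2 candidate pools are the union
of both systems' Step-1 selections) and assigns test q-values from the test
system's own permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from ._kernel import make_luts, search_batch
from .errors import ConfigError, DataContractError


@dataclass(frozen=True)
class BDeConfig:
    """Settings of the BN analysis (equivalent sample size, penalty, search)."""

    ess: float = 1.0  # equivalent sample size of the BDeu prior
    kappa: float = 0.1  # per-motif-family structure penalty base, in (0,1)
    step1_pool_size: int = 120
    max_parents: int = 3
    n_permutations: int = 1000
    q_threshold: float = 0.05
    top_features_for_test: int = 10
    min_gene_support: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.ess <= 0:
            raise ConfigError("ess must be positive")
        if not 0.0 < self.kappa < 1.0:
            raise ConfigError("kappa must lie in (0, 1) so larger composites are penalised")
        for name in ("step1_pool_size", "max_parents", "n_permutations", "top_features_for_test"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.max_parents > 3:
            raise ConfigError("max_parents is capped at 3")


# ---------------------------------------------------------------------------
# reference scoring (readable path; the kernel must agree with it)


def _as_binary(y) -> np.ndarray:
    y = np.asarray(pd.Series(y).to_numpy())
    return (y > 0).astype(np.uint8)


def bde_score(signs, parents, ess: float = 1.0, max_parents: int = 3):
    """BDeu log marginal likelihood of a parent set, plus its CPT.

    ``signs``: per-gene binary labels (positive truthy / negative falsy).
    ``parents``: sequence of aligned binary feature vectors (0-3 of them).
    Pseudocounts are alpha_jc = ESS / (2 q) with q = 2^{#parents}.

    Returns ``(log_ml, cpt)`` where ``cpt`` has one row per parent
    configuration with the gene count and the posterior-mean probability of
    a positive sign, (N_j,up + alpha_j/2) / (N_j + alpha_j).
    """
    if len(parents) > max_parents:
        raise ConfigError(f"parent set of size {len(parents)} exceeds max_parents={max_parents}")
    y = _as_binary(signs)
    n = y.shape[0]
    npar = len(parents)
    q = 2**npar
    a = ess / (2.0 * q)
    config = np.zeros(n, dtype=np.int64)
    for b, p in enumerate(parents):
        p = np.asarray(pd.Series(p).to_numpy()).astype(bool)
        if p.shape[0] != n:
            raise DataContractError("parent features not aligned to the labelled genes")
        config |= p.astype(np.int64) << b
    n_j = np.bincount(config, minlength=q).astype(float)
    n_up = np.bincount(config, weights=y.astype(float), minlength=q)
    n_dn = n_j - n_up
    log_ml = float(
        np.sum(
            gammaln(2 * a)
            - gammaln(2 * a + n_j)
            + gammaln(a + n_up)
            + gammaln(a + n_dn)
            - 2 * gammaln(a)
        )
    )
    rows = []
    for j in range(q):
        bits = {f"parent_{b + 1}": (j >> b) & 1 for b in range(npar)}
        rows.append(
            {
                **bits,
                "n_genes": int(n_j[j]),
                "p_positive": (n_up[j] + a) / (n_j[j] + 2 * a),
            }
        )
    return log_ml, pd.DataFrame(rows)


def structure_log_prior(parent_sizes, kappa: float = 0.1) -> float:
    """log prior of a parent set: sum over parents of size * log(kappa)."""
    return float(sum(parent_sizes)) * float(np.log(kappa))


def permutation_qvalues(scores, null_scores) -> np.ndarray:
    """q(s) = #{permutation optima >= s} / n_permutations, per score."""
    null = np.sort(np.asarray(null_scores, dtype=float))
    s = np.asarray(scores, dtype=float)
    ge = len(null) - np.searchsorted(null, s, side="left")
    return ge / len(null)


# ---------------------------------------------------------------------------
# estimator


class ParentSetSelector(BaseEstimator):
    """Exact BDe parent-set selection with permutation q-values.

    ``fit(X, y)`` takes a genes x composite-motifs boolean table and per-gene
    sign labels (+1/-1).  The feature universe is restricted to composites
    carried by >= ``min_gene_support`` labelled genes and ordered
    lexicographically (the Step-1 tie-break).

    Fitted attributes: ``universe_`` (composite ids), ``pool_`` (Step-1
    selection), ``report_`` (ranked nonempty parent sets with BN scores and
    q-values), ``null_scores_`` (optimal score per permutation),
    ``best_set_``, ``best_score_log_``.
    """

    def __init__(
        self,
        ess: float = 1.0,
        kappa: float = 0.1,
        step1_pool_size: int = 120,
        max_parents: int = 3,
        n_permutations: int = 1000,
        q_threshold: float = 0.05,
        top_features_for_test: int = 10,
        min_gene_support: int = 5,
        random_state: int = 0,
        top_report: int = 64,
    ):
        self.ess = ess
        self.kappa = kappa
        self.step1_pool_size = step1_pool_size
        self.max_parents = max_parents
        self.n_permutations = n_permutations
        self.q_threshold = q_threshold
        self.top_features_for_test = top_features_for_test
        self.min_gene_support = min_gene_support
        self.random_state = random_state
        self.top_report = top_report

    # -- configuration plumbing ------------------------------------------
    @property
    def config(self) -> BDeConfig:
        cfg = BDeConfig(
            ess=self.ess,
            kappa=self.kappa,
            step1_pool_size=self.step1_pool_size,
            max_parents=self.max_parents,
            n_permutations=self.n_permutations,
            q_threshold=self.q_threshold,
            top_features_for_test=self.top_features_for_test,
            min_gene_support=self.min_gene_support,
            seed=self.random_state,
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_config(cls, cfg: BDeConfig, **kw) -> "ParentSetSelector":
        return cls(
            ess=cfg.ess,
            kappa=cfg.kappa,
            step1_pool_size=cfg.step1_pool_size,
            max_parents=cfg.max_parents,
            n_permutations=cfg.n_permutations,
            q_threshold=cfg.q_threshold,
            top_features_for_test=cfg.top_features_for_test,
            min_gene_support=cfg.min_gene_support,
            random_state=cfg.seed,
            **kw,
        )

    # -- fitting ----------------------------------------------------------
    def _prepare(self, X: pd.DataFrame, y) -> tuple[pd.DataFrame, np.ndarray]:
        X = pd.DataFrame(X).astype(bool)
        y = pd.Series(y)
        if len(y) != len(X):
            y = y.reindex(X.index)
            if y.isna().any():
                raise DataContractError("labels not aligned to the feature-table genes")
        labels = _as_binary(y)
        support = X.sum(axis=0)
        universe = sorted(support.index[support >= self.min_gene_support])
        self.n_features_dropped_ = int((support < self.min_gene_support).sum())
        return X[universe], labels

    def _csr(self, X: pd.DataFrame):
        arr = X.to_numpy()
        indptr = np.zeros(arr.shape[0] + 1, dtype=np.int64)
        cols: list[np.ndarray] = []
        for i in range(arr.shape[0]):
            idx = np.flatnonzero(arr[i]).astype(np.int32)
            cols.append(idx)
            indptr[i + 1] = indptr[i] + len(idx)
        findex = np.concatenate(cols) if cols else np.zeros(0, dtype=np.int32)
        return indptr, findex.astype(np.int32)

    def fit(self, X: pd.DataFrame, y) -> "ParentSetSelector":
        cfg = self.config
        Xu, labels = self._prepare(X, y)
        if labels.shape[0] < 1:
            raise DataContractError("need at least one labelled gene")
        self.X_, self.y_ = Xu, labels
        universe = list(Xu.columns)
        self.universe_ = universe
        sizes = np.array([cid.count("_") + 1 for cid in universe], dtype=np.int32)
        self.universe_sizes_ = sizes
        n = labels.shape[0]

        pool_cap = min(cfg.step1_pool_size, len(universe))
        n_subsets = (
            pool_cap
            + pool_cap * (pool_cap - 1) // 2
            + pool_cap * (pool_cap - 1) * (pool_cap - 2) // 6
        )
        if n_subsets > 10_000_000:
            raise ConfigError(
                f"pool of {pool_cap} gives {n_subsets} subsets at max_parents="
                f"{cfg.max_parents}; use a smaller step1_pool_size"
            )

        perm_labels = np.empty((cfg.n_permutations + 1, n), dtype=np.uint8)
        perm_labels[0] = labels
        for i in range(cfg.n_permutations):
            # stream keyed by (seed, permutation index) for reproducibility
            rng = np.random.default_rng((cfg.seed, i + 1))
            perm_labels[i + 1] = labels[rng.permutation(n)]

        indptr, findex = self._csr(Xu)
        c_univ = Xu.sum(axis=0).to_numpy().astype(np.int64)
        lg_a, lg_t = make_luts(n, cfg.ess)
        best, top_scores, top_sets, pool0, s1_obs = search_batch(
            indptr,
            findex,
            sizes,
            c_univ,
            perm_labels,
            cfg.step1_pool_size,
            cfg.max_parents,
            lg_a,
            lg_t,
            float(np.log(cfg.kappa)),
            np.zeros(0, dtype=np.int32),
            False,
            self.top_report,
        )
        self.null_scores_ = best[1:]
        self.best_score_log_ = float(best[0])
        self.pool_ = [universe[i] for i in pool0]
        self.step1_scores_ = pd.Series(s1_obs, index=universe, name="bn_score_log")
        self.report_ = self._make_report(top_scores, top_sets, self.pool_)
        self.best_set_ = (
            tuple(self.report_.iloc[0]["parents"]) if len(self.report_) else ()
        )
        return self

    def _make_report(self, top_scores, top_sets, pool: list[str]) -> pd.DataFrame:
        rows = []
        for sc, (i, j, k) in zip(top_scores, top_sets):
            if not np.isfinite(sc):
                continue
            parents = tuple(pool[x] for x in (i, j, k) if x >= 0)
            rows.append(
                {
                    "feature": " + ".join(parents),
                    "parents": parents,
                    "n_parents": len(parents),
                    "score_log": float(sc),
                    "bn_score_log10": float(sc) / np.log(10.0),
                }
            )
        rep = pd.DataFrame(rows)
        if len(rep) and hasattr(self, "null_scores_"):
            rep["q"] = permutation_qvalues(rep["score_log"], self.null_scores_)
        return rep

    # -- scoring given sets on (possibly other) data ----------------------
    def _feature_vector(self, X: pd.DataFrame, composite: str) -> tuple[np.ndarray, bool]:
        if composite in X.columns:
            return X[composite].to_numpy().astype(bool), False
        return np.zeros(len(X), dtype=bool), True

    def score_sets(self, parent_sets, X: pd.DataFrame | None = None, y=None) -> pd.DataFrame:
        """BN scores of explicit parent sets on given (default: fitted) data.

        Composites absent from the feature table are scored with presence 0
        for every gene and flagged in the ``missing_features`` column.
        """
        cfg = self.config
        X = self.X_ if X is None else pd.DataFrame(X).astype(bool)
        labels = self.y_ if y is None else _as_binary(pd.Series(y))
        lme, _ = bde_score(labels, [], ess=cfg.ess)
        rows = []
        for parents in parent_sets:
            parents = tuple(parents)
            vecs, missing = [], []
            for cid in parents:
                v, miss = self._feature_vector(X, cid)
                vecs.append(v)
                if miss:
                    missing.append(cid)
            lml, cpt = bde_score(labels, vecs, ess=cfg.ess, max_parents=cfg.max_parents)
            sizes = [cid.count("_") + 1 for cid in parents]
            sc = lml + structure_log_prior(sizes, cfg.kappa) - lme
            rows.append(
                {
                    "feature": " + ".join(parents),
                    "parents": parents,
                    "score_log": sc,
                    "bn_score_log10": sc / np.log(10.0),
                    "missing_features": missing,
                    "cpt": cpt,
                }
            )
        return pd.DataFrame(rows)

    def cpt(self, parents) -> pd.DataFrame:
        """Conditional probability table of a parent set on the fitted data."""
        vecs = [self._feature_vector(self.X_, cid)[0] for cid in parents]
        _, cpt = bde_score(self.y_, vecs, ess=self.ess)
        named = cpt.rename(
            columns={f"parent_{b + 1}": cid for b, cid in enumerate(parents)}
        )
        return named

    # -- sklearn-style prediction via the best set's CPT ------------------
    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        parents = self.best_set_
        vecs = [self._feature_vector(X, cid)[0] for cid in parents]
        _, cpt = bde_score(self.y_, [self._feature_vector(self.X_, c)[0] for c in parents],
                           ess=self.ess)
        config = np.zeros(len(X), dtype=np.int64)
        for b, v in enumerate(vecs):
            config |= v.astype(np.int64) << b
        p_pos = cpt["p_positive"].to_numpy()[config]
        return np.column_stack([1.0 - p_pos, p_pos])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.where(self.predict_proba(X)[:, 1] >= 0.5, 1, -1)


# ---------------------------------------------------------------------------
# functional surface mirroring the analysis steps


def step1_select(features: pd.DataFrame, signs, cfg: BDeConfig) -> list[str]:
    """Top composites by singleton BN score (ties broken lexicographically)."""
    sel = ParentSetSelector.from_config(replace(cfg, n_permutations=1)).fit(features, signs)
    return sel.pool_


def step2_search(features: pd.DataFrame, signs, cfg: BDeConfig, pool=None) -> pd.DataFrame:
    """Exhaustive exact search over subsets (size <= max_parents) of the pool."""
    sel = ParentSetSelector.from_config(replace(cfg, n_permutations=1))
    if pool is None:
        sel.fit(features, signs)
        return sel.report_
    Xu, labels = sel._prepare(features, signs)
    sel.X_, sel.y_ = Xu, labels
    universe = list(Xu.columns)
    pool_idx = np.array(
        sorted(universe.index(c) for c in pool if c in universe), dtype=np.int32
    )
    sizes = np.array([c.count("_") + 1 for c in universe], dtype=np.int32)
    indptr, findex = sel._csr(Xu)
    lg_a, lg_t = make_luts(len(labels), cfg.ess)
    obs = labels[None, :].astype(np.uint8)
    best, top_scores, top_sets, pool0, _ = search_batch(
        indptr,
        findex,
        sizes,
        Xu.sum(axis=0).to_numpy().astype(np.int64),
        obs,
        cfg.step1_pool_size,
        cfg.max_parents,
        lg_a,
        lg_t,
        float(np.log(cfg.kappa)),
        pool_idx,
        True,
        sel.top_report,
    )
    return sel._make_report(top_scores, top_sets, [universe[i] for i in pool0])


def fit_system(features: pd.DataFrame, signs, cfg: BDeConfig) -> ParentSetSelector:
    """Two-step search + permutation null for one system/eigensystem."""
    return ParentSetSelector.from_config(cfg).fit(features, signs)


def cross_validate(
    train: ParentSetSelector, test: ParentSetSelector, cfg: BDeConfig | None = None
) -> pd.DataFrame:
    """Train-side selection rescored on the test system.

    Step-2 candidate pools are the union of both systems' Step-1 pools; the
    top <= ``top_features_for_test`` training features with q below the
    threshold are scored on the test data and assigned q-values from the
    test system's own permutation null.
    """
    cfg = train.config if cfg is None else cfg
    union = sorted(set(train.pool_) | set(test.pool_))
    train_X = train.X_.copy()
    for cid in union:
        if cid not in train_X.columns:
            train_X[cid] = False
    rep = step2_search(train_X, train.y_, replace(cfg, min_gene_support=0), pool=union)
    rep = rep[rep["n_parents"] > 0].reset_index(drop=True)
    rep["train_q"] = permutation_qvalues(rep["score_log"], train.null_scores_)
    top = rep[rep["train_q"] < cfg.q_threshold].head(cfg.top_features_for_test).copy()
    if len(top) == 0:
        for col in ("test_score_log", "test_bn_score_log10", "test_q"):
            top[col] = pd.Series(dtype=float)
        top["test_missing_features"] = pd.Series(dtype=object)
        top["cross_validated"] = pd.Series(dtype=bool)
        return top.reset_index(drop=True)

    scored = test.score_sets(list(top["parents"]))
    top["test_score_log"] = scored["score_log"].to_numpy()
    top["test_bn_score_log10"] = scored["bn_score_log10"].to_numpy()
    top["test_missing_features"] = scored["missing_features"].to_numpy()
    top["test_q"] = permutation_qvalues(top["test_score_log"], test.null_scores_)
    top["cross_validated"] = (top["train_q"] < cfg.q_threshold) & (
        top["test_q"] < cfg.q_threshold
    )
    return top.reset_index(drop=True)
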