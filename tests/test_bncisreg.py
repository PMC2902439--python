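import itertools
import math

import numpy as np
import pandas as pd
import pytest

from eigencis import bncisreg as bn
from eigencis.errors import ConfigError, DataContractError


def oracle_log_ml(table, ess):
    """Independent BDeu oracle: rising-factorial products, no gammaln.

    ``table``: list of (n_up, n_down) per parent configuration; q = len.
    Uses Gamma(a+N)/Gamma(a) = prod_{i<N} (a+i) directly.
    """
    q = len(table)
    a = ess / (2.0 * q)
    total = 0.0
    for n_up, n_dn in table:
        for i in range(n_up):
            total += math.log(a + i)
        for i in range(n_dn):
            total += math.log(a + i)
        for i in range(n_up + n_dn):
            total -= math.log(2.0 * a + i)
    return total


def table_to_vectors(table):
    """Expand a contingency table into label/parent vectors."""
    npar = int(np.log2(len(table)))
    y, parents = [], [[] for _ in range(npar)]
    for j, (n_up, n_dn) in enumerate(table):
        for lab, count in ((1, n_up), (-1, n_dn)):
            for _ in range(count):
                y.append(lab)
                for b in range(npar):
                    parents[b].append(bool((j >> b) & 1))
    return np.array(y), [np.array(p) for p in parents]


class TestBdeScore:
    def test_closed_form_no_parents(self):
        # N_up=3, N_down=1, ESS=1: ML = (1/2 * 3/4 * 5/6 * 1/8) ... = 5/128
        log_ml, cpt = bn.bde_score([1, 1, 1, -1], [], ess=1.0)
        assert np.exp(log_ml) == pytest.approx(5.0 / 128.0, rel=1e-12)
        assert cpt.loc[0, "n_genes"] == 4

    def test_zero_genes_empty_product(self):
        log_ml, _ = bn.bde_score([], [], ess=1.0)
        assert log_ml == 0.0  # likelihood 1

    def test_perfect_separation_beats_empty(self):
        y = [1, 1, -1, -1]
        parent = [True, True, False, False]
        lml_empty, _ = bn.bde_score(y, [], ess=1.0)
        lml_parent, _ = bn.bde_score(y, [parent], ess=1.0)
        assert lml_parent > lml_empty
        # frozen from the rising-factorial oracle before implementation:
        # configs (2 up, 0 dn) and (0 up, 2 dn) at a = 1/4
        expected = oracle_log_ml([(0, 2), (2, 0)], ess=1.0)
        assert lml_parent == pytest.approx(expected, abs=1e-9)

    def test_max_parents_enforced(self):
        y = [1, -1]
        p = [True, False]
        with pytest.raises(ConfigError):
            bn.bde_score(y, [p, p, p, p])

    def test_misaligned_parent_rejected(self):
        with pytest.raises(DataContractError):
            bn.bde_score([1, -1, 1], [[True, False]])

    def test_exhaustive_oracle_sweep_one_parent(self):
        for tbl in itertools.product(range(5), repeat=4):
            table = [(tbl[0], tbl[1]), (tbl[2], tbl[3])]
            y, parents = table_to_vectors(table)
            if len(y) == 0:
                continue
            log_ml, _ = bn.bde_score(y, parents, ess=1.0)
            assert log_ml == pytest.approx(oracle_log_ml(table, 1.0), abs=1e-9)

    @pytest.mark.parametrize("ess", [0.5, 1.0, 4.0])
    def test_oracle_sweep_random_two_three_parents(self, ess, rng):
        for npar in (2, 3):
            q = 2**npar
            for _ in range(150):
                flat = rng.integers(0, 7, size=2 * q)
                table = [(int(flat[2 * j]), int(flat[2 * j + 1])) for j in range(q)]
                if sum(a + b for a, b in table) == 0 or sum(a + b for a, b in table) > 50:
                    continue
                y, parents = table_to_vectors(table)
                log_ml, _ = bn.bde_score(y, parents, ess=ess)
                assert log_ml == pytest.approx(oracle_log_ml(table, ess), abs=1e-9)

    def test_cpt_probabilities_and_counts(self):
        y = [1, 1, -1, -1, 1]
        parent = [True, True, True, False, False]
        _, cpt = bn.bde_score(y, [parent], ess=1.0)
        assert cpt["n_genes"].sum() == 5
        assert ((cpt["p_positive"] >= 0) & (cpt["p_positive"] <= 1)).all()
        # config parent=1: 2 up, 1 down, a = 1/4 -> (2 + 1/4) / (3 + 1/2)
        assert cpt.loc[1, "p_positive"] == pytest.approx(2.25 / 3.5)


class TestStructurePrior:
    def test_values(self):
        assert bn.structure_log_prior([], 0.5) == 0.0
        assert bn.structure_log_prior([1], 0.5) == pytest.approx(np.log(0.5))
        # parent set {X_Y, Z}: sizes 2 + 1
        assert bn.structure_log_prior([2, 1], 0.5) == pytest.approx(3 * np.log(0.5))


class TestQValues:
    def test_exceedance_arithmetic(self):
        null = np.concatenate([np.linspace(0, 1, 950), np.linspace(2, 3, 50)])
        assert bn.permutation_qvalues([3.5], null)[0] == 0.0
        assert bn.permutation_qvalues([-1.0], null)[0] == 1.0
        assert bn.permutation_qvalues([2.0 - 1e-12], null)[0] == pytest.approx(0.05)

    def test_monotone_in_score(self, rng):
        null = rng.normal(size=500)
        scores = np.sort(rng.normal(size=20))[::-1]
        q = bn.permutation_qvalues(scores, null)
        assert (np.diff(q) >= 0).all()


def _random_dataset(rng, n=80, f=10, p=0.3):
    X = pd.DataFrame(
        rng.random((n, f)) < p, columns=[f"F{i:02d}" for i in range(f)]
    )
    y = pd.Series(np.where(rng.random(n) < 0.5, 1, -1), index=X.index)
    return X, y


class TestSelector:
    def test_kernel_agrees_with_reference_scoring(self, rng):
        X, y = _random_dataset(rng)
        sel = bn.ParentSetSelector(
            n_permutations=2, min_gene_support=0, step1_pool_size=10, random_state=3
        ).fit(X, y)
        ref = sel.score_sets(list(sel.report_["parents"]))
        np.testing.assert_allclose(
            ref["score_log"].to_numpy(),
            sel.report_["score_log"].to_numpy(),
            atol=1e-9,
        )

    def test_exhaustive_search_is_optimal(self, rng):
        X, y = _random_dataset(rng, n=50, f=8)
        sel = bn.ParentSetSelector(
            n_permutations=1, min_gene_support=0, step1_pool_size=8, random_state=0
        ).fit(X, y)
        best = 0.0
        for k in range(1, 4):
            for comb in itertools.combinations(X.columns, k):
                sc = sel.score_sets([comb])["score_log"].iloc[0]
                best = max(best, sc)
        assert sel.best_score_log_ == pytest.approx(best, abs=1e-9)

    def test_score_invariant_under_joint_row_permutation(self, rng):
        X, y = _random_dataset(rng)
        perm = rng.permutation(len(X))
        s1 = bn.ParentSetSelector(n_permutations=1, min_gene_support=0,
                                  random_state=0).fit(X, y)
        s2 = bn.ParentSetSelector(n_permutations=1, min_gene_support=0,
                                  random_state=0).fit(X.iloc[perm], y.iloc[perm])
        assert s1.best_score_log_ == pytest.approx(s2.best_score_log_, abs=1e-9)
        assert s1.pool_ == s2.pool_

    def test_pool_clipped_to_universe(self, rng):
        X, y = _random_dataset(rng, f=6)
        sel = bn.ParentSetSelector(
            n_permutations=1, min_gene_support=0, step1_pool_size=120
        ).fit(X, y)
        assert sorted(sel.pool_) == sorted(X.columns)

    def test_empty_universe_yields_empty_report(self, rng):
        X, y = _random_dataset(rng, f=4)
        sel = bn.ParentSetSelector(n_permutations=1, min_gene_support=1000).fit(X, y)
        assert len(sel.report_) == 0
        assert sel.best_score_log_ == 0.0
        assert sel.best_set_ == ()

    def test_support_filter_drops_rare_composites(self, rng):
        X, y = _random_dataset(rng, n=60, f=6, p=0.02)
        sel = bn.ParentSetSelector(n_permutations=1, min_gene_support=5).fit(X, y)
        assert all(X[c].sum() >= 5 for c in sel.universe_)

    def test_oversized_pool_request_rejected(self, rng):
        X = pd.DataFrame(
            rng.random((20, 500)) < 0.5, columns=[f"F{i:03d}" for i in range(500)]
        )
        y = pd.Series(np.where(rng.random(20) < 0.5, 1, -1))
        sel = bn.ParentSetSelector(
            step1_pool_size=500, n_permutations=1, min_gene_support=0
        )
        with pytest.raises(ConfigError, match="smaller step1_pool_size"):
            sel.fit(X, y)

    def test_predict_proba_uses_best_cpt(self, rng):
        n = 200
        parent = rng.random(n) < 0.4
        y = np.where(parent, 1, -1)  # perfectly separating feature
        X = pd.DataFrame({"AP1F": parent, "ZZZZ": rng.random(n) < 0.5})
        sel = bn.ParentSetSelector(n_permutations=5, min_gene_support=0,
                                   random_state=0).fit(X, pd.Series(y))
        assert sel.best_set_ == ("AP1F",)
        proba = sel.predict_proba(X)
        assert (np.sign(proba[:, 1] - 0.5) == y).all()


class TestCrossValidation:
    def test_identical_train_test_scores_match(self, rng):
        n = 150
        parent = rng.random(n) < 0.4
        flip = rng.random(n) < 0.15
        y = pd.Series(np.where(parent ^ flip, 1, -1))
        X = pd.DataFrame(
            {"AP1F": parent, **{f"N{i}": rng.random(n) < 0.3 for i in range(5)}}
        )
        cfg = bn.BDeConfig(n_permutations=50, min_gene_support=0, seed=1)
        sel = bn.fit_system(X, y, cfg)
        rep = bn.cross_validate(sel, sel, cfg)
        assert len(rep) > 0
        np.testing.assert_allclose(
            rep["score_log"].to_numpy(), rep["test_score_log"].to_numpy(), atol=1e-9
        )
        assert (rep["train_q"] == rep["test_q"]).all()

    def test_missing_test_feature_scored_as_absent_and_flagged(self, rng):
        n = 120
        parent = rng.random(n) < 0.5
        y = pd.Series(np.where(parent, 1, -1))
        X_train = pd.DataFrame(
            {"AP1F": parent, "N1": rng.random(n) < 0.3, "N2": rng.random(n) < 0.3}
        )
        cfg = bn.BDeConfig(n_permutations=30, min_gene_support=0, seed=2)
        train = bn.fit_system(X_train, y, cfg)
        test = bn.fit_system(X_train[["N1", "N2"]], y, cfg)
        rep = bn.cross_validate(train, test, cfg)
        flagged = [m for m in rep["test_missing_features"] if m]
        assert any("AP1F" in m for m in flagged)
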