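import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eigencis import cisfeatures, exprprep, synthdata
from eigencis.errors import ConfigError
from eigencis.synthdata import CountEffect, SignFeature, SynthConfig


class TestConfigValidation:
    def test_k_shared_exceeding_conditions_rejected(self):
        cfg = SynthConfig(
            n_genes_a=100, n_genes_b=100, n_conditions_a=4, n_conditions_b=4,
            k_shared=4, singular_values=(10, 5, 3, 2),
        )
        with pytest.raises(ConfigError, match="k_shared"):
            cfg.validate()

    def test_oversized_planted_composite_rejected(self):
        cfg = SynthConfig(
            n_genes_a=100,
            n_genes_b=100,
            planted_sign_features=(SignFeature(("AP1F", "SATB", "CREB", "EGRF"), 2.0),),
        )
        with pytest.raises(ConfigError, match="size"):
            cfg.validate()

    @pytest.mark.parametrize(
        "kw",
        [
            {"frac_shared": 1.5},
            {"frac_shared": 0.0},
            {"noise_sd": -0.1},
            {"singular_values": (10.0, 20.0, 5.0)},
            {"n_replicates": 0},
        ],
    )
    def test_bad_parameters_rejected(self, kw):
        with pytest.raises(ConfigError):
            SynthConfig(n_genes_a=100, n_genes_b=100, **kw).validate()


class TestPairedExpression:
    def test_shapes_and_shared_gene_count(self):
        cfg = SynthConfig(
            seed=1, n_genes_a=200, n_genes_b=180, frac_shared=0.4,
            n_conditions_a=5, n_conditions_b=10, n_replicates=3,
        )
        (sig_a, calls_a, _), (sig_b, _, _), da, db, truth = (
            synthdata.generate_paired_expression(cfg)
        )
        assert sig_a.shape == (200, 15)
        assert sig_b.shape == (180, 30)
        assert len(truth.shared_genes) == 72  # 0.4 * min(200, 180)
        assert calls_a.isin(["P"]).all().all()
        assert len(da) == 15 and len(db) == 30

    def test_noiseless_svd_recovers_planted_singular_values(self):
        cfg = SynthConfig(seed=2, n_genes_a=200, n_genes_b=180, noise_sd=0.0)
        b = synthdata.simulate(cfg)
        gem = exprprep.preprocess(
            b.signal_a, b.calls_a, b.design_a, b.probeset_map_a, alpha=1.0
        )
        s = np.linalg.svd(gem.values.to_numpy(), compute_uv=False)
        np.testing.assert_allclose(
            np.sort(s)[::-1][:3], np.asarray(cfg.singular_values), rtol=1e-6
        )

    def test_shared_genes_carry_identical_loadings(self, small_bundle):
        t = small_bundle.truth
        pd.testing.assert_frame_equal(
            t.eigenarrays_a.loc[t.shared_genes], t.eigenarrays_b.loc[t.shared_genes]
        )

    def test_base_eigenarrays_orthonormal(self, small_bundle):
        for u in (small_bundle.truth.eigenarrays_a, small_bundle.truth.eigenarrays_b):
            g = u.to_numpy().T @ u.to_numpy()
            np.testing.assert_allclose(g, np.eye(u.shape[1]), atol=1e-10)

    def test_first_eigensystem_is_magnitude_like(self, small_bundle):
        t = small_bundle.truth
        assert (t.eigenarrays_a["E1"] > 0).all()
        v1 = t.eigengenes_a["E1"].to_numpy()
        np.testing.assert_allclose(v1, v1[0], rtol=1e-10)  # constant in time

    def test_multi_probeset_flag_duplicates_some_genes(self):
        cfg = SynthConfig(seed=3, n_genes_a=150, n_genes_b=120, multi_probeset_frac=0.2)
        b = synthdata.simulate(cfg)
        per_gene = b.probeset_map_a.groupby("gene_id").size()
        assert (per_gene == 2).sum() > 0
        assert set(b.probeset_map_a["probeset_id"]) == set(b.signal_a.index)


class TestCisTables:
    def test_total_cns_count_in_poisson_band(self):
        cfg = SynthConfig(seed=4, n_genes_a=600, n_genes_b=500, frac_shared=0.2,
                          cns_per_gene_mean=2.0)
        b = synthdata.simulate(cfg)
        n_union = len(set(b.truth.genes_a) | set(b.truth.genes_b))
        n_cns = b.cns_table["cns_id"].nunique()
        lo, hi = stats.poisson.ppf([0.005, 0.995], 2.0 * n_union)
        assert lo <= n_cns <= hi

    def test_null_odds_multiplier_leaves_sign_frequency_flat(self):
        cfg = SynthConfig(
            seed=5, n_genes_a=900, n_genes_b=800, frac_shared=0.2,
            planted_sign_features=(SignFeature(("AP1F",), odds=1.0, eigensystem=2),),
        )
        b = synthdata.simulate(cfg)
        ft = cisfeatures.build_feature_table(
            b.cns_table, b.motif_table, genes=list(b.truth.genes_a)
        )
        carriers = ft.presence["AP1F"].reindex(b.truth.genes_a).fillna(False)
        pos = b.truth.loadings_a["E2"] > 0
        p_c, p_n = pos[carriers].mean(), pos[~carriers].mean()
        se = np.sqrt(0.25 / carriers.sum() + 0.25 / (~carriers).sum())
        assert abs(p_c - p_n) < 3.5 * se

    def test_decoy_instances_are_not_conserved(self, small_bundle):
        accepted, rejected = cisfeatures.validate_cns(small_bundle.cns_table)
        conserved = cisfeatures.conserved_motifs(
            accepted, small_bundle.motif_table, rejected_ids=set(rejected["cns_id"])
        )
        per = small_bundle.motif_table.groupby(["cns_id", "family_id"])["species"].nunique()
        single_species = per[per == 1].reset_index()[["cns_id", "family_id"]]
        assert len(single_species) > 0  # decoys were emitted
        merged = single_species.merge(conserved, on=["cns_id", "family_id"], how="inner")
        assert merged.empty

    def test_emitted_tables_satisfy_downstream_contracts(self, small_bundle):
        gem = exprprep.preprocess(
            small_bundle.signal_a,
            small_bundle.calls_a,
            small_bundle.design_a,
            small_bundle.probeset_map_a,
        )
        assert len(gem.values) > 0
        ft = cisfeatures.build_feature_table(
            small_bundle.cns_table, small_bundle.motif_table, genes=gem.genes
        )
        assert list(ft.presence.index) == gem.genes


class TestPlantedEffects:
    def test_count_effect_adds_beta_per_count(self):
        cfg = SynthConfig(
            seed=6, n_genes_a=400, n_genes_b=300, frac_shared=0.25,
            planted_count_effect=(CountEffect("CREB", 0.05, eigensystem=3),),
        )
        b = synthdata.simulate(cfg)
        ft = cisfeatures.build_feature_table(
            b.cns_table, b.motif_table,
            genes=sorted(set(b.truth.genes_a) | set(b.truth.genes_b)),
        )
        counts = ft.counts["CREB"].reindex(b.truth.genes_a).fillna(0)
        delta = b.truth.loadings_a["E3"] - b.truth.eigenarrays_a["E3"]
        np.testing.assert_allclose(delta.to_numpy(), 0.05 * counts.to_numpy(), atol=1e-12)

    def test_antagonist_blocker_suppresses_count_effect(self):
        cfg = SynthConfig(seed=7, n_genes_a=500, n_genes_b=400,
                          antagonist_pair=("AP1F", "SATB"))
        b = synthdata.simulate(cfg)
        ft = cisfeatures.build_feature_table(
            b.cns_table, b.motif_table,
            genes=sorted(set(b.truth.genes_a) | set(b.truth.genes_b)),
        )
        satb = ft.presence["SATB"].reindex(b.truth.genes_a).fillna(False)
        ap1_count = ft.counts["AP1F"].reindex(b.truth.genes_a).fillna(0)
        delta = b.truth.loadings_a["E2"] - b.truth.eigenarrays_a["E2"]
        # blocker carriers: no count effect, just the constant repression shift
        np.testing.assert_allclose(
            delta[satb].to_numpy(), -cfg.antagonist_blocker_shift, atol=1e-12
        )
        free = ~satb
        np.testing.assert_allclose(
            delta[free].to_numpy(), cfg.antagonist_beta * ap1_count[free].to_numpy(),
            atol=1e-12,
        )

    def test_system_specific_feature_leaves_other_system_untouched(self):
        cfg = SynthConfig(
            seed=8, n_genes_a=400, n_genes_b=400, frac_shared=0.3,
            planted_sign_features=(SignFeature(("NFKB",), 4.0, eigensystem=2, systems="A"),),
        )
        b = synthdata.simulate(cfg)
        pd.testing.assert_frame_equal(b.truth.loadings_b, b.truth.eigenarrays_b)
        assert not b.truth.loadings_a.equals(b.truth.eigenarrays_a)


class TestRoundTripAndDeterminism:
    def test_truth_json_round_trip(self, small_bundle, tmp_path):
        p = tmp_path / "truth.json"
        small_bundle.truth.save_json(p)
        loaded = synthdata.GroundTruth.load_json(p)
        assert loaded.equals(small_bundle.truth, tol=1e-12)

    def test_same_seed_bit_identical(self):
        cfg = SynthConfig(seed=9, n_genes_a=120, n_genes_b=100)
        b1, b2 = synthdata.simulate(cfg), synthdata.simulate(cfg)
        pd.testing.assert_frame_equal(b1.signal_a, b2.signal_a)
        pd.testing.assert_frame_equal(b1.motif_table, b2.motif_table)
        assert b1.truth.equals(b2.truth, tol=0.0)

    def test_different_seeds_differ(self):
        b1 = synthdata.simulate(SynthConfig(seed=10, n_genes_a=120, n_genes_b=100))
        b2 = synthdata.simulate(SynthConfig(seed=11, n_genes_a=120, n_genes_b=100))
        assert not b1.signal_a.equals(b2.signal_a)
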