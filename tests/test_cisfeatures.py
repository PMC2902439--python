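import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eigencis import cisfeatures as cf
from eigencis.errors import ConfigError, DataContractError


def _cns_rows(cns_id, gene, length=150, identity=0.9):
    return [
        (cns_id, gene, "human", "chr1", 1000, 1000 + length, identity),
        (cns_id, gene, "rat", "chr2", 5000, 5000 + length, identity),
    ]


def _cns(rows):
    return pd.DataFrame(rows, columns=cf.CNS_COLUMNS)


def _motifs(rows):
    return pd.DataFrame(rows, columns=cf.MOTIF_COLUMNS)


class TestValidateCns:
    def test_short_cns_rejected_inclusive_bounds_accepted(self):
        table = _cns(
            _cns_rows("c1", "g1", length=99, identity=0.80)
            + _cns_rows("c2", "g1", length=100, identity=0.75)
        )
        accepted, rejected = cf.validate_cns(table)
        assert set(accepted["cns_id"]) == {"c2"}
        assert set(rejected["cns_id"]) == {"c1"}
        assert (rejected["reason"] == "length<100").all()

    def test_low_identity_rejected(self):
        accepted, rejected = cf.validate_cns(
            _cns(_cns_rows("c1", "g1", identity=0.74))
        )
        assert accepted.empty and len(rejected) == 2

    def test_missing_species_track_rejected(self):
        rows = _cns_rows("c1", "g1")[:1]  # human only
        accepted, rejected = cf.validate_cns(_cns(rows))
        assert accepted.empty
        assert (rejected["reason"] == "missing species track").all()

    def test_summary_reports_mean_length(self):
        table = _cns(_cns_rows("c1", "g1", length=150) + _cns_rows("c2", "g2", length=250))
        accepted, _ = cf.validate_cns(table)
        s = cf.cns_summary(accepted)
        assert s["n_cns"] == 2 and s["n_genes"] == 2
        assert s["mean_length_bp"] == pytest.approx(200.0)

    def test_inverted_interval_rejected(self):
        rows = [("c1", "g1", "human", "chr1", 1000, 900, 0.9),
                ("c1", "g1", "rat", "chr1", 1000, 1100, 0.9)]
        accepted, rejected = cf.validate_cns(_cns(rows))
        assert accepted.empty


class TestConservedMotifs:
    def test_both_tracks_required_positions_irrelevant(self):
        cns = _cns(_cns_rows("c1", "g1"))
        inst = _motifs([
            ("c1", "human", "F", 10, "+"),
            ("c1", "rat", "F", 50, "-"),   # different position: still conserved
            ("c1", "human", "G", 5, "+"),  # human only: not conserved
        ])
        cons = cf.conserved_motifs(cns, inst)
        assert set(cons["family_id"]) == {"F"}

    def test_instance_count_semantics(self):
        cns = _cns(_cns_rows("c1", "g1"))
        inst = _motifs([
            ("c1", "human", "SATB", 10, "+"),
            ("c1", "rat", "SATB", 20, "+"),
            ("c1", "rat", "SATB", 40, "-"),
        ])
        cons = cf.conserved_motifs(cns, inst)
        counts = cf.count_features(cns, cons, inst, genes=["g1"])
        assert counts.loc["g1", "SATB"] == 2  # rat-track instances

    def test_unknown_cns_id_raises_listing_ids(self):
        cns = _cns(_cns_rows("c1", "g1"))
        inst = _motifs([("cX", "human", "F", 1, "+")])
        with pytest.raises(DataContractError, match="cX"):
            cf.conserved_motifs(cns, inst)


class TestEnumerateComposites:
    def _conserved(self, cns_families):
        rows = [
            (cns_id, gene, fam)
            for cns_id, gene, fams in cns_families
            for fam in fams
        ]
        return pd.DataFrame(rows, columns=["cns_id", "gene_id", "family_id"])

    def test_three_families_give_seven_composites(self):
        cons = self._conserved([("c1", "g1", ["A", "B", "C"])])
        presence, comps = cf.enumerate_composites(cons)
        assert len(comps) == 7
        assert presence.loc["g1"].all()

    @pytest.mark.parametrize("m,max_size", [(2, 3), (4, 2), (5, 3)])
    def test_composite_count_is_binomial_sum(self, m, max_size):
        from math import comb

        fams = [f"F{i}" for i in range(m)]
        cons = self._conserved([("c1", "g1", fams)])
        _, comps = cf.enumerate_composites(cons, max_size=max_size)
        assert len(comps) == sum(comb(m, k) for k in range(1, max_size + 1))

    def test_pairs_require_cooccurrence_in_one_cns(self):
        cons = self._conserved([("c1", "g1", ["A", "B"]), ("c2", "g1", ["B", "C"])])
        presence, comps = cf.enumerate_composites(cons)
        assert set(comps) == {"A", "B", "C", "A_B", "B_C"}
        assert "A_C" not in comps  # A and C never share a CNS

    def test_empty_conserved_set(self):
        cons = self._conserved([])
        presence, comps = cf.enumerate_composites(cons)
        assert presence.empty and comps == {}

    def test_invalid_max_size_rejected(self):
        with pytest.raises(ConfigError):
            cf.enumerate_composites(self._conserved([]), max_size=4)

    def test_downward_closure_on_generated_data(self, small_bundle):
        ft = cf.build_feature_table(
            small_bundle.cns_table,
            small_bundle.motif_table,
            genes=list(small_bundle.truth.genes_a),
        )
        multi = [cid for cid, fams in ft.composites.items() if len(fams) > 1]
        assert multi
        for cid in multi[:40]:
            sub_ok = np.ones(len(ft.presence), dtype=bool)
            for fam in ft.composites[cid]:
                sub_ok &= ft.presence[fam].to_numpy()
            assert (~ft.presence[cid].to_numpy() | sub_ok).all()


class TestCountFeatures:
    def test_counts_sum_over_cns(self):
        cns = _cns(_cns_rows("c1", "g1") + _cns_rows("c2", "g1"))
        inst = _motifs(
            [("c1", "human", "SATB", 1, "+")]
            + [("c1", "rat", "SATB", p, "+") for p in (1, 2, 3)]
            + [("c2", "human", "SATB", 1, "+")]
            + [("c2", "rat", "SATB", p, "+") for p in (1, 2, 3)]
        )
        cons = cf.conserved_motifs(cns, inst)
        counts = cf.count_features(cns, cons, inst, genes=["g1"])
        assert counts.loc["g1", "SATB"] == 6
        assert counts.loc["g1", "cns_count"] == 2

    def test_non_conserved_instances_excluded(self):
        cns = _cns(_cns_rows("c1", "g1"))
        inst = _motifs([("c1", "rat", "EGRF", 1, "+")] * 3)  # rat-only
        cons = cf.conserved_motifs(cns, inst)
        counts = cf.count_features(cns, cons, inst, genes=["g1"], families=["EGRF"])
        assert counts.loc["g1", "EGRF"] == 0

    def test_zero_cns_gene_remains_addressable(self):
        cns = _cns(_cns_rows("c1", "g1"))
        inst = _motifs([("c1", "human", "F", 1, "+"), ("c1", "rat", "F", 2, "+")])
        cons = cf.conserved_motifs(cns, inst)
        counts = cf.count_features(cns, cons, inst, genes=["g1", "g_lonely"])
        assert counts.loc["g_lonely", "cns_count"] == 0
        assert counts.loc["g_lonely", "F"] == 0

    def test_count_species_configurable(self):
        cns = _cns(_cns_rows("c1", "g1"))
        inst = _motifs(
            [("c1", "human", "F", p, "+") for p in (1, 2)]
            + [("c1", "rat", "F", 5, "+")]
        )
        cons = cf.conserved_motifs(cns, inst)
        rat = cf.count_features(cns, cons, inst, genes=["g1"])
        hum = cf.count_features(cns, cons, inst, genes=["g1"], count_species="human")
        assert rat.loc["g1", "F"] == 1 and hum.loc["g1", "F"] == 2


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    fams_per_cns=st.lists(
        st.lists(st.sampled_from(["A", "B", "C", "D", "E"]), min_size=1, max_size=5,
                 unique=True),
        min_size=1,
        max_size=4,
    )
)
def test_gene_presence_is_union_of_cns_presence(fams_per_cns):
    """A gene carries a composite iff at least one of its CNSs carries it."""
    rows = [
        (f"c{i}", "g1", fam)
        for i, fams in enumerate(fams_per_cns)
        for fam in fams
    ]
    cons = pd.DataFrame(rows, columns=["cns_id", "gene_id", "family_id"])
    presence, comps = cf.enumerate_composites(cons)
    for cid, fams in comps.items():
        expected = any(set(fams) <= set(cns_f) for cns_f in fams_per_cns)
        assert bool(presence.loc["g1", cid]) == expected
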