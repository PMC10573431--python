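import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from opreact import (
    AdductGroup,
    AdductRecord,
    ClassificationError,
    PoseRecord,
    RankingCriterion,
    classify_adduct,
    coulomb_energy,
    delta_e_el,
    dg_from_kd,
    filter_productive_poses,
    kd_from_dg,
    rank_adducts,
)


class TestCoulombEnergy:
    def test_unit_charges_give_exact_round_number(self):
        # r chosen so k/r = 100 exactly
        assert coulomb_energy(1.0, -1.0, 3.320637, 1.0) == pytest.approx(
            -100.0, rel=1e-12
        )

    def test_zero_charge_gives_zero(self):
        assert coulomb_energy(0.0, -0.7, 2.5, 4.0) == 0.0

    def test_reference_pair_energy(self):
        # P–F pair of the dimethylamido adduct: published value −50.540
        assert coulomb_energy(2.240, -0.748, 2.753, 4.0) == pytest.approx(
            -50.54, abs=0.05
        )

    @pytest.mark.parametrize("bad_r", [0.0, -1.0])
    def test_nonpositive_distance_rejected(self, bad_r):
        with pytest.raises(ValueError):
            coulomb_energy(1.0, -1.0, bad_r)

    @settings(derandomize=True, max_examples=100)
    @given(
        q1=st.floats(0.1, 3), q2=st.floats(-1, -0.1),
        r=st.floats(0.5, 10), eps=st.floats(0.5, 80),
        scale=st.floats(1.1, 5),
    )
    def test_homogeneity_in_r_and_epsilon(self, q1, q2, r, eps, scale):
        base = coulomb_energy(q1, q2, r, eps)
        assert coulomb_energy(q1, q2, r * scale, eps) == pytest.approx(base / scale)
        assert coulomb_energy(q1, q2, r, eps * scale) == pytest.approx(base / scale)


class TestDeltaEEl:
    def test_recomputes_published_energies(self, bche_am1_table):
        """Both pair energies and ΔE_el match the published reference
        values within 0.05 kcal/mol for every adduct row."""
        for _, row in bche_am1_table.iterrows():
            record = AdductRecord(
                adduct_id=row["adduct_id"], q_P=row["q_P"], q_O=row["q_O"],
                q_F=row["q_F"], dist_P_O=row["dist_P_O"], dist_P_F=row["dist_P_F"],
            )
            result = delta_e_el(record)
            assert result.e_el_P_O == pytest.approx(row["e_el_P_O_ref"], abs=0.05)
            assert result.e_el_P_F == pytest.approx(row["e_el_P_F_ref"], abs=0.05)
            assert result.delta_e_el == pytest.approx(row["delta_e_el_ref"], abs=0.05)

    def test_symmetric_record_has_zero_barrier(self):
        record = AdductRecord(
            adduct_id="X", q_P=2.3, q_O=-0.7, q_F=-0.7, dist_P_O=1.7, dist_P_F=1.7
        )
        assert delta_e_el(record).delta_e_el == 0.0

    def test_swapping_partners_negates_delta(self):
        record = AdductRecord(
            adduct_id="X", q_P=2.3, q_O=-0.6, q_F=-0.75, dist_P_O=1.69, dist_P_F=3.0
        )
        swapped = AdductRecord(
            adduct_id="X", q_P=2.3, q_O=-0.75, q_F=-0.6, dist_P_O=3.0, dist_P_F=1.69,
            validate=False,  # swapped roles put the probe where the bond was
        )
        assert delta_e_el(swapped).delta_e_el == pytest.approx(
            -delta_e_el(record).delta_e_el
        )

    def test_missing_field_is_an_error(self):
        record = AdductRecord(adduct_id="X", q_P=2.3, q_O=-0.6, q_F=-0.7,
                              dist_P_O=1.7, dist_P_F=float("nan"), validate=False)
        with pytest.raises(ValueError, match="dist_P_F"):
            delta_e_el(record)

    def test_charge_sign_validation(self):
        with pytest.raises(ValueError, match="q_P"):
            AdductRecord(adduct_id="X", q_P=-1.0, q_O=-0.6, q_F=-0.7,
                         dist_P_O=1.7, dist_P_F=3.0)
        # override flag admits unphysical exploratory records
        AdductRecord(adduct_id="X", q_P=-1.0, q_O=-0.6, q_F=-0.7,
                     dist_P_O=1.7, dist_P_F=3.0, validate=False)


class TestThermodynamics:
    def test_standard_state_identity(self):
        assert kd_from_dg(0.0) == 1.0

    def test_seven_kcal_is_about_seven_micromolar(self):
        kd = kd_from_dg(-7.0, 298.15)
        assert kd == pytest.approx(7e-6, rel=0.1)

    def test_analytic_micromolar_point(self):
        dg = -_rt() * math.log(1e6)
        assert kd_from_dg(dg) == pytest.approx(1e-6, rel=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(dg=st.floats(-15, 5), t=st.floats(270, 320))
    def test_round_trip_with_inverse(self, dg, t):
        assert dg_from_kd(kd_from_dg(dg, t), t) == pytest.approx(dg, abs=1e-9)


def _rt(t=298.15):
    from opreact.scoring import R_KCAL

    return R_KCAL * t


class TestClassification:
    @pytest.mark.parametrize(
        "r1,r2,expected",
        [
            ("C2H5", "N-(CH3)2", AdductGroup.GROUP_I),
            ("C2H5", "O-C2H5", AdductGroup.GROUP_I),
            ("C2H5", "C2H5", AdductGroup.TRANSITIONAL),
            ("C2H5", "CH3", AdductGroup.GROUP_III),
            ("CH(CH3)2", "CH3", AdductGroup.GROUP_II),
            ("CH2-CH(CH3)2", "CH3", AdductGroup.GROUP_III),
            ("nC4H9", "CH3", AdductGroup.GROUP_III),
            ("cC6H11", "CH3", AdductGroup.GROUP_II),
            ("C*H(CH3)-C(CH3)3", "CH3", AdductGroup.GROUP_II),
            ("C6H4-CH3", "O-CH2-C6H4-OH", AdductGroup.SPECIAL),
        ],
    )
    def test_controlled_vocabulary_groups(self, r1, r2, expected):
        assert classify_adduct(r1, r2) is expected

    def test_unknown_token_is_an_error(self):
        with pytest.raises(ClassificationError):
            classify_adduct("CH2=CH2", "CH3")
        with pytest.raises(ClassificationError):
            classify_adduct("C2H5", "SMILES(CCO)")

    def test_every_packaged_adduct_classifies(self, bche_adducts):
        groups = {r.adduct_id: classify_adduct(r.r1, r.r2) for r in bche_adducts}
        assert groups["Ad1"] is AdductGroup.GROUP_I
        assert groups["Ad2"] is AdductGroup.GROUP_I
        assert groups["Ad3"] is AdductGroup.TRANSITIONAL
        assert {k for k, g in groups.items() if g is AdductGroup.GROUP_II} == {
            "Ad5", "Ad8", "Ad9", "Ad10",
        }
        assert {k for k, g in groups.items() if g is AdductGroup.GROUP_III} == {
            "Ad4", "Ad6", "Ad7",
        }
        assert groups["Ad11"] is AdductGroup.SPECIAL


class TestRanking:
    def test_electrostatic_ranking_of_reference_adducts(self, bche_adducts):
        """Ranking by recomputed ΔE_el: easiest (lowest barrier) first."""
        scores = [delta_e_el(r).delta_e_el for r in bche_adducts]
        table = rank_adducts(bche_adducts, RankingCriterion.AM1_DELTA_E, scores)
        assert table.order == (
            "Ad7", "Ad11", "Ad1", "Ad2", "Ad4", "Ad6",
            "Ad3", "Ad5", "Ad8", "Ad10", "Ad9",
        )
        values = [v for _, v in table.entries]
        assert values == sorted(values)

    def test_mean_distance_ranking(self, bche_mm_table):
        records = [
            AdductRecord(adduct_id=a, validate=False)
            for a in bche_mm_table["adduct_id"]
        ]
        table = rank_adducts(
            records, RankingCriterion.MM_DISTANCE,
            bche_mm_table["mean_dist_P_F"].tolist(),
        )
        assert table.order == (
            "Ad1", "Ad11", "Ad2", "Ad7", "Ad4", "Ad5",
            "Ad6", "Ad10", "Ad3", "Ad8", "Ad9",
        )

    def test_order_invariant_under_input_permutation(self, bche_adducts, rng):
        scores = [delta_e_el(r).delta_e_el for r in bche_adducts]
        baseline = rank_adducts(bche_adducts, RankingCriterion.AM1_DELTA_E, scores)
        for _ in range(5):
            perm = rng.permutation(len(bche_adducts))
            shuffled = rank_adducts(
                [bche_adducts[i] for i in perm],
                RankingCriterion.AM1_DELTA_E,
                [scores[i] for i in perm],
            )
            assert shuffled.entries == baseline.entries

    def test_singleton(self):
        record = AdductRecord(adduct_id="only", validate=False)
        table = rank_adducts([record], RankingCriterion.MM_DISTANCE, [3.0])
        assert table.entries == (("only", 3.0),)

    def test_length_mismatch(self):
        record = AdductRecord(adduct_id="only", validate=False)
        with pytest.raises(ValueError):
            rank_adducts([record], RankingCriterion.MM_DISTANCE, [1.0, 2.0])

    def test_tie_broken_lexicographically(self):
        records = [AdductRecord(adduct_id=a, validate=False) for a in ("Ad8", "Ad3")]
        table = rank_adducts(records, RankingCriterion.MM_DISTANCE, [3.52, 3.52])
        assert table.order == ("Ad3", "Ad8")


class TestPoseFilter:
    def test_reference_docking_table_retains_eleven(self, cbdp_poses):
        kept = filter_productive_poses(cbdp_poses)
        assert len(kept) == 11
        assert {p.site_label for p in cbdp_poses} - {p.site_label for p in kept} == {
            "Tyr138", "Lys432",
        }

    def test_boundary_pose_retained(self):
        kept = filter_productive_poses([PoseRecord("X", 4.0), PoseRecord("Y", 4.01)])
        assert [p.site_label for p in kept] == ["X"]

    def test_all_far_gives_empty(self):
        assert filter_productive_poses([PoseRecord("X", 6.0)]) == []
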