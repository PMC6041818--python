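"""Unit tests for the summary measures against hand-computed oracles."""

import math

import numpy as np
import pytest

from healthineq.measures import (MeasureUnavailable, aci_rci, applicable_measures,
                                 bgv, compute_stratum, difference, idis_idisw,
                                 mdb_mdm, mld_theil, par_paf, rank_midpoints,
                                 ratio, setting_average, sii_rii)

from conftest import make_stratum


class TestSettingAverage:
    def test_symmetric_weighted_mean(self):
        s = make_stratum([40, 60], populations=[50, 50])
        assert setting_average(s) == pytest.approx(50)

    def test_asymmetric_weighted_mean(self):
        s = make_stratum([20, 80], populations=[30, 70])
        assert setting_average(s) == pytest.approx(0.3 * 20 + 0.7 * 80)

    def test_provided_average_takes_precedence(self):
        s = make_stratum([40, 60], populations=[50, 50], setting_average=55.0)
        assert setting_average(s) == 55.0

    def test_unavailable_without_population(self):
        assert setting_average(make_stratum([40, 60])) is None


class TestRankMidpoints:
    def test_two_halves(self):
        s = make_stratum([1, 2], dimension_type="ordered", populations=[50, 50])
        assert rank_midpoints(s) == pytest.approx([0.25, 0.75])

    def test_unequal_shares(self):
        s = make_stratum([1, 2, 3], dimension_type="ordered",
                         populations=[20, 30, 50])
        assert rank_midpoints(s) == pytest.approx([0.10, 0.35, 0.75])

    @pytest.mark.parametrize("J", [2, 3, 5, 8])
    def test_equal_population_closed_form(self, J):
        s = make_stratum(range(J), dimension_type="ordered", populations=[10] * J)
        expect = [(2 * j - 1) / (2 * J) for j in range(1, J + 1)]
        assert rank_midpoints(s) == pytest.approx(expect)

    def test_missing_population(self):
        s = make_stratum([1, 2], dimension_type="ordered")
        assert rank_midpoints(s) is None


class TestPairwise:
    def test_difference_ordered_favourable(self):
        s = make_stratum([20, 50, 80], dimension_type="ordered")
        assert difference(s).value == pytest.approx(60)

    def test_difference_zero_when_equal(self):
        s = make_stratum([30, 30, 30])
        assert difference(s).value == 0

    def test_difference_ordered_adverse(self):
        s = make_stratum([30, 20, 10], dimension_type="ordered", favourable=False)
        assert difference(s).value == pytest.approx(20)

    def test_difference_reference_subgroup(self):
        # extreme vs designated reference, sign kept
        s = make_stratum([50, 20, 60], names=["Capital", "Far", "Near"],
                         reference="Capital")
        res = difference(s)
        assert res.value == pytest.approx(20 - 50)
        assert any("reference" in n for n in res.notes)

    def test_ratio_ordered_favourable(self):
        s = make_stratum([20, 50, 80], dimension_type="ordered")
        assert ratio(s).value == pytest.approx(4.0)

    def test_ratio_one_when_equal(self):
        assert ratio(make_stratum([30, 30])).value == pytest.approx(1.0)

    def test_ratio_zero_denominator_skipped(self):
        with pytest.raises(MeasureUnavailable, match="zero_denominator"):
            ratio(make_stratum([0, 10, 20]))


class TestParPaf:
    def test_binary_favourable(self):
        s = make_stratum([40, 60], populations=[50, 50])
        par, paf = par_paf(s, 50.0)
        assert par.value == pytest.approx(10)
        assert paf.value == pytest.approx(20)

    def test_ordered_adverse_negative(self):
        s = make_stratum([30, 20, 10], dimension_type="ordered",
                         favourable=False, populations=[1, 1, 1])
        par, paf = par_paf(s, 20.0)
        assert par.value == pytest.approx(-10)
        assert paf.value == pytest.approx(-50)

    def test_truncated_to_zero_on_contrary_sign(self):
        # most-advantaged subgroup sits below the average: no attainable gain
        s = make_stratum([50, 80, 40], dimension_type="ordered",
                         populations=[1, 1, 1])
        par, paf = par_paf(s, 170 / 3)
        assert par.value == 0.0
        assert paf.value == 0.0
        assert any("truncated" in n for n in par.notes)

    def test_nonordered_designated_reference(self):
        s = make_stratum([40, 60, 80], names=["a", "b", "c"], reference="b",
                         populations=[1, 1, 1])
        par, _ = par_paf(s, 60.0)
        assert par.value == 0.0  # reference 60 equals the mean


class TestDispersion:
    def test_bgv_symmetric(self):
        s = make_stratum([40, 60], populations=[50, 50])
        assert bgv(s, 50.0).value == pytest.approx(100)

    def test_bgv_asymmetric(self):
        s = make_stratum([20, 80], populations=[30, 70])
        assert bgv(s, 62.0).value == pytest.approx(756)

    def test_mdb_mdm_favourable(self):
        s = make_stratum([40, 60], populations=[50, 50])
        mdb, mdm = mdb_mdm(s, 50.0)
        assert mdb.value == pytest.approx(10)
        assert mdm.value == pytest.approx(10)

    def test_mdb_adverse_best_is_min(self):
        s = make_stratum([40, 60], populations=[50, 50], favourable=False)
        mdb, _ = mdb_mdm(s, 50.0)
        assert mdb.value == pytest.approx(10)
        assert "g0" in mdb.notes[0]

    def test_idis_idisw_equal_weights(self):
        s = make_stratum([40, 60], populations=[50, 50])
        idis, idisw = idis_idisw(s, 50.0)
        assert idis.value == pytest.approx(20)
        assert idisw.value == pytest.approx(20)

    def test_idisw_unequal_weights(self):
        s = make_stratum([20, 80], populations=[30, 70])
        _, idisw = idis_idisw(s, 62.0)
        assert idisw.value == pytest.approx(100 * (0.3 * 42 + 0.7 * 18) / 62)

    def test_mld_theil_hand_values(self):
        s = make_stratum([25, 75], populations=[50, 50])
        mld, ti = mld_theil(s, 50.0)
        assert mld.value == pytest.approx(1000 * 0.5 * (math.log(2) + math.log(2 / 3)))
        assert ti.value == pytest.approx(
            1000 * 0.5 * (0.5 * math.log(0.5) + 1.5 * math.log(1.5)))
        # the stated reporting-scale values
        assert mld.value == pytest.approx(143.84, abs=0.01)
        assert ti.value == pytest.approx(130.81, abs=0.01)

    def test_mld_skipped_on_zero_estimate(self):
        s = make_stratum([0, 50, 100], populations=[1, 1, 1])
        with pytest.raises(MeasureUnavailable, match="nonpositive_estimate"):
            mld_theil(s, 50.0)

    @pytest.mark.parametrize("fn", [bgv, mdb_mdm, mld_theil])
    def test_zero_on_equal_estimates(self, fn):
        s = make_stratum([30, 30, 30], populations=[1, 2, 3])
        out = fn(s, 30.0)
        for res in (out if isinstance(out, tuple) else (out,)):
            assert res.value == pytest.approx(0.0, abs=1e-12)


class TestGradient:
    def test_aci_rci_two_groups(self):
        s = make_stratum([40, 60], dimension_type="ordered", populations=[50, 50])
        aci, rci = aci_rci(s, 50.0)
        assert aci.value == pytest.approx(5)
        assert rci.value == pytest.approx(10)

    def test_aci_zero_on_equal_estimates(self):
        s = make_stratum([50, 50, 50], dimension_type="ordered",
                         populations=[10, 20, 30])
        aci, _ = aci_rci(s, 50.0)
        assert aci.value == pytest.approx(0.0, abs=1e-12)

    def test_sii_rii_two_points(self):
        s = make_stratum([40, 60], dimension_type="ordered",
                         populations=[50, 50], ses=[1, 1])
        sii, rii = sii_rii(s)
        assert sii.value == pytest.approx(40)
        assert rii.value == pytest.approx(70 / 30)

    def test_sii_rii_equal_estimates(self):
        s = make_stratum([50, 50, 50], dimension_type="ordered",
                         populations=[1, 1, 1], ses=[1, 1, 1])
        sii, rii = sii_rii(s)
        assert sii.value == pytest.approx(0.0, abs=1e-9)
        assert rii.value == pytest.approx(1.0)

    def test_sii_rii_collinear(self):
        s = make_stratum([20, 50, 80], dimension_type="ordered",
                         populations=[1, 1, 1], ses=[1, 1, 1])
        sii, rii = sii_rii(s)
        assert sii.value == pytest.approx(90)
        assert rii.value == pytest.approx(19)

    def test_sii_requires_se(self):
        s = make_stratum([40, 60, 80], dimension_type="ordered",
                         populations=[1, 1, 1])
        with pytest.raises(MeasureUnavailable, match="se_missing"):
            sii_rii(s)

    def test_aci_person_level_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            J = rng.integers(3, 7)
            pops = rng.integers(1, 1000 // J, size=J)
            y = rng.uniform(1, 99, size=J)
            s = make_stratum(y, dimension_type="ordered", populations=pops)
            aci, _ = aci_rci(s, setting_average(s))
            # expand to individuals ranked disadvantaged-first
            persons = np.repeat(y, pops)
            n = len(persons)
            ranks = (2 * np.arange(1, n + 1) - 1) / (2 * n)
            brute = np.mean((2 * ranks - 1) * persons)
            assert aci.value == pytest.approx(brute, abs=1e-9)


class TestApplicability:
    def test_binary_full_data(self):
        s = make_stratum([40, 60], populations=[1, 1], ses=[1, 1])
        assert applicable_measures(s) == {"D", "R", "PAR", "PAF"}

    def test_no_population_means_unweighted_only(self):
        for dt, J in (("binary", 2), ("nonordered", 4), ("ordered", 4)):
            s = make_stratum(range(1, J + 1), dimension_type=dt)
            assert applicable_measures(s) == {"D", "R"}

    def test_nonordered_full_data(self):
        s = make_stratum([10, 20, 30, 40], populations=[1] * 4, ses=[1] * 4)
        assert applicable_measures(s) == {"D", "R", "PAR", "PAF", "BGV", "MDB",
                                          "MDM", "IDIS", "IDISW", "MLD", "TI"}

    def test_ordered_full_data(self):
        s = make_stratum([10, 20, 30, 40], dimension_type="ordered",
                         populations=[1] * 4, ses=[1] * 4)
        assert applicable_measures(s) == {"D", "R", "PAR", "PAF", "ACI", "RCI",
                                          "SII", "RII"}

    def test_ordered_without_se_drops_gradient_regression(self):
        s = make_stratum([10, 20, 30], dimension_type="ordered",
                         populations=[1] * 3)
        assert applicable_measures(s) == {"D", "R", "PAR", "PAF", "ACI", "RCI"}

    def test_union_is_fifteen_measures(self):
        binary = make_stratum([40, 60], populations=[1, 1], ses=[1, 1])
        non = make_stratum([10, 20, 30, 40], populations=[1] * 4, ses=[1] * 4)
        ordered = make_stratum([10, 20, 30, 40], dimension_type="ordered",
                               populations=[1] * 4, ses=[1] * 4)
        union = (applicable_measures(binary) | applicable_measures(non)
                 | applicable_measures(ordered))
        assert len(union) == 15


class TestComputeStratum:
    def test_ordered_full_yields_eight(self):
        s = make_stratum([10, 20, 30, 40], dimension_type="ordered",
                         populations=[1] * 4, ses=[1] * 4)
        res = compute_stratum(s)
        assert res.measures == {"D", "R", "PAR", "PAF", "ACI", "RCI", "SII", "RII"}

    def test_nonordered_full_yields_eleven(self):
        s = make_stratum([10, 20, 30, 40], populations=[1] * 4, ses=[1] * 4)
        assert len(compute_stratum(s)) == 11

    def test_no_population_yields_d_r_only(self):
        s = make_stratum([10, 20, 30, 40])
        assert compute_stratum(s).measures == {"D", "R"}

    def test_degenerate_data_becomes_skips_not_errors(self):
        s = make_stratum([0, 20, 30, 40], populations=[1] * 4)
        res = compute_stratum(s)
        assert res.skipped.get("R") == "zero_denominator"
        assert res.skipped.get("MLD") == "nonpositive_estimate"
        assert "BGV" in res.measures  # unaffected measures still computed
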