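import numpy as np
import pytest
from hypothesis import given, strategies as st

from invpetdose import compare, constants, dosimetry, kinetics


LAM = constants.CU64_LAMBDA_PER_H


def make_tac(times, values, corrected=False, inj=14.8):
    return dosimetry.TimeActivityCurve(
        "tumor", np.asarray(times, float), np.asarray(values, float),
        decay_corrected=corrected, injected_activity_MBq=inj,
    )


class TestTimeActivityCurve:
    def test_validation(self):
        with pytest.raises(ValueError):
            make_tac([2, 1], [1, 1])
        with pytest.raises(ValueError):
            make_tac([1, 2, 3], [1, 1])
        with pytest.raises(ValueError):
            make_tac([1, 2], [1, np.nan])
        with pytest.raises(ValueError):
            make_tac([1, 2], [1, 1], inj=0.0)

    def test_decay_round_trip(self):
        t = np.array([2.0, 15.0, 40.0, 64.0])
        tac = make_tac(t, [5.0, 8.0, 6.0, 4.0], corrected=True)
        back = dosimetry.decay_correct(dosimetry.decay_uncorrect(tac))
        np.testing.assert_allclose(back.values, tac.values, rtol=1e-12)

    def test_decay_uncorrect_halves_at_half_life(self):
        tac = make_tac([0.0001, constants.CU64_HALF_LIFE_H], [10.0, 10.0],
                       corrected=True)
        out = dosimetry.decay_uncorrect(tac)
        assert out.values[1] == pytest.approx(5.0, rel=1e-4)

    def test_direction_guards(self):
        tac = make_tac([1, 2], [1, 1], corrected=False)
        with pytest.raises(ValueError):
            dosimetry.decay_uncorrect(tac)
        with pytest.raises(ValueError):
            dosimetry.decay_correct(dosimetry.decay_correct(tac))


class TestCumulatedActivity:
    def test_pure_decay_matches_closed_form(self):
        # A(t) = A0 exp(-lambda t) integrates to exactly A0/lambda
        t = np.arange(0.25, 127.0, 0.25)
        tac = make_tac(t, 10.0 * np.exp(-LAM * t))
        auc = dosimetry.cumulated_activity(tac)
        assert auc == pytest.approx(10.0 / LAM, rel=1e-3)

    def test_requires_uncorrected(self):
        with pytest.raises(ValueError):
            dosimetry.cumulated_activity(make_tac([1, 2], [1, 1], corrected=True))

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError):
            dosimetry.cumulated_activity(make_tac([1, 2], [1, -1]))

    def test_head_body_tail_decomposition(self):
        # hand-computed: head 2*4, trapezoid (4+2)/2*(6-2), tail 2/lambda
        auc = dosimetry.cumulated_activity(make_tac([2.0, 6.0], [4.0, 2.0]))
        assert auc == pytest.approx(8.0 + 12.0 + 2.0 / LAM, rel=1e-12)

    def test_monotone_in_values(self):
        lo = dosimetry.cumulated_activity(make_tac([2, 6], [4.0, 2.0]))
        hi = dosimetry.cumulated_activity(make_tac([2, 6], [5.0, 2.5]))
        assert hi > lo


class TestResidenceTime:
    def test_ratio_definition(self):
        assert dosimetry.residence_time(29.6, 14.8) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            dosimetry.residence_time(1.0, 0.0)

    def test_from_percent_id_per_gram_tac(self):
        # constant 100 %ID/g in a 1 g region holds the full injected
        # activity, so tau equals the AUC of exp(-lambda t): 1/lambda
        t = np.arange(0.25, 500.0, 0.25)
        tac = make_tac(t, 100.0 * np.exp(-LAM * t))
        tau = dosimetry.residence_time_from_tac(tac, 1.0)
        assert tau == pytest.approx(1.0 / LAM, rel=1e-3)

    def test_physical_bound_enforced(self):
        with pytest.raises(ValueError):
            dosimetry.ResidenceTimeSet({"a": 1.0 / LAM, "b": 1.0}, 14.8)
        ok = dosimetry.ResidenceTimeSet({"a": 1.0, "b": 2.0}, 14.8)
        assert sum(ok.taus_h.values()) == 3.0

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            dosimetry.ResidenceTimeSet({"a": -0.1}, 14.8)


class TestSphereSValues:
    def test_power_law_recovered_exactly(self):
        m = np.array([0.05, 0.1, 0.5, 1.0, 5.0])
        table = dosimetry.SphereSValueTable(m, 70.0 * m**-0.95)
        fit = dosimetry.fit_sphere_svalue(table)
        assert fit.a == pytest.approx(70.0, rel=1e-9)
        assert fit.b == pytest.approx(-0.95, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_table_validation(self):
        with pytest.raises(ValueError):
            dosimetry.SphereSValueTable(np.array([1.0, 0.5]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            dosimetry.SphereSValueTable(np.array([0.5, 1.0]), np.array([1.0, 2.0]))

    def test_packaged_table_loads_and_fits_well(self):
        table = compare.load_sphere_svalue_table()
        fit = dosimetry.fit_sphere_svalue(table)
        assert fit.b < 0
        assert fit.r_squared > 0.99

    def test_tumor_dose_and_extrapolation_flag(self):
        table = compare.load_sphere_svalue_table()
        fit = dosimetry.fit_sphere_svalue(table)
        dose, extrap = dosimetry.tumor_absorbed_dose(2.0, 0.2, table)
        assert dose == pytest.approx(2.0 * fit(0.2), rel=1e-12)
        assert extrap is False
        _, extrap_hi = dosimetry.tumor_absorbed_dose(2.0, 1e4, table)
        assert extrap_hi is True

    @given(tau=st.floats(0.01, 10.0), mass=st.floats(0.05, 5.0))
    def test_dose_linear_in_tau_and_decreasing_in_mass(self, tau, mass):
        table = compare.load_sphere_svalue_table()
        d1, _ = dosimetry.tumor_absorbed_dose(tau, mass, table)
        d2, _ = dosimetry.tumor_absorbed_dose(2 * tau, mass, table)
        d3, _ = dosimetry.tumor_absorbed_dose(tau, 2 * mass, table)
        assert d2 == pytest.approx(2 * d1, rel=1e-9)
        assert d3 < d1


class TestOrganDose:
    def test_hand_computed_two_organ_case(self):
        import pandas as pd

        s = pd.DataFrame(
            [[2.0, 0.5], [0.4, 3.0]], index=["liver", "kidneys"],
            columns=["liver", "kidneys"],
        )
        smat = dosimetry.OrganSMatrix(
            s, {"liver": 1.3, "kidneys": 0.4},
            {"liver": 0.6, "kidneys": 0.4},
        )
        res = dosimetry.ResidenceTimeSet({"liver": 1.0, "kidneys": 2.0}, 14.8)
        rep = dosimetry.organ_dose(res, smat)
        assert rep.organ_doses["liver"] == pytest.approx(1 * 2.0 + 2 * 0.5)
        assert rep.organ_doses["kidneys"] == pytest.approx(1 * 0.4 + 2 * 3.0)
        assert rep.effective_dose_mSv_per_MBq == pytest.approx(
            0.6 * 3.0 + 0.4 * 6.4
        )

    def test_missing_source_raises(self):
        smat = compare.load_organ_smatrix()
        res = dosimetry.ResidenceTimeSet({"nonexistent_organ": 1.0}, 14.8)
        with pytest.raises(KeyError):
            dosimetry.organ_dose(res, smat)

    def test_packaged_smatrix_properties(self):
        smat = compare.load_organ_smatrix()
        assert sum(smat.tissue_weights.values()) == pytest.approx(1.0, abs=1e-9)
        for t in smat.s.index:
            assert smat.s.loc[t, t] >= smat.s.loc[t].drop(t).max()

    def test_effective_dose_with_packaged_fixtures(self):
        smat = compare.load_organ_smatrix()
        taus = {c: 0.5 for c in smat.s.columns}
        rep = dosimetry.organ_dose(dosimetry.ResidenceTimeSet(taus, 14.8), smat)
        manual = sum(
            smat.tissue_weights.get(t, 0.0) * rep.organ_doses[t]
            for t in smat.s.index
        )
        assert rep.effective_dose_mSv_per_MBq == pytest.approx(manual, rel=1e-12)


class TestMouseToHumanScaling:
    def test_relative_mass_rule(self):
        res = dosimetry.ResidenceTimeSet({"liver": 1.0}, 14.8)
        out = dosimetry.scale_mouse_to_human(
            res, {"liver": 1.3}, {"liver": 1800.0}
        )
        expected = 1.0 * (1800.0 / 73000.0) / (1.3 / 25.0)
        assert out.taus_h["liver"] == pytest.approx(expected, rel=1e-12)

    def test_proportional_organ_unchanged(self):
        # organ that is the same fraction of body mass in both species
        res = dosimetry.ResidenceTimeSet({"x": 2.0}, 14.8)
        out = dosimetry.scale_mouse_to_human(res, {"x": 0.25}, {"x": 730.0})
        assert out.taus_h["x"] == pytest.approx(2.0, rel=1e-12)

    def test_missing_mass_and_bad_strategy(self):
        res = dosimetry.ResidenceTimeSet({"liver": 1.0}, 14.8)
        with pytest.raises(KeyError):
            dosimetry.scale_mouse_to_human(res, {}, {"liver": 1800.0})
        with pytest.raises(ValueError):
            dosimetry.scale_mouse_to_human(
                res, {"liver": 1.3}, {"liver": 1800.0}, strategy="allometric"
            )


class TestRoiHelpers:
    def test_roi_max_and_position(self):
        img = np.zeros((4, 4, 4))
        img[1, 2, 3] = 9.0
        mask = np.ones_like(img, dtype=bool)
        val, pos = dosimetry.roi_max_concentration(
            img, dosimetry.ROISpec("tumor", mask=mask)
        )
        assert val == 9.0 and pos == (1, 2, 3)

    def test_roi_max_respects_mask(self):
        img = np.zeros((3, 3, 1))
        img[0, 0, 0] = 5.0
        img[2, 2, 0] = 1.0
        mask = np.zeros_like(img, dtype=bool)
        mask[2, 2, 0] = True
        val, _ = dosimetry.roi_max_concentration(
            img, dosimetry.ROISpec("r", mask=mask)
        )
        assert val == 1.0

    def test_empty_or_mismatched_roi(self):
        img = np.zeros((3, 3, 1))
        with pytest.raises(ValueError):
            dosimetry.roi_max_concentration(
                img, dosimetry.ROISpec("r", mask=np.zeros_like(img, dtype=bool))
            )
        with pytest.raises(ValueError):
            dosimetry.roi_max_concentration(
                img, dosimetry.ROISpec("r", mask=np.ones((2, 2), dtype=bool))
            )

    def test_percent_id_per_gram(self):
        assert dosimetry.percent_id_per_gram(148.0, 14800.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            dosimetry.percent_id_per_gram(1.0, 0.0)
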