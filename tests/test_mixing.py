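import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import monofilm as mf
from monofilm.errors import ConventionError, PressureOutOfRangeError


class TestMoleFractions:
    @pytest.mark.parametrize(
        "lipid,polymer,x_polymer",
        [(10, 1, 1 / 11), (1, 1, 0.5), (100, 1, 1 / 101)],
    )
    def test_known_ratios(self, lipid, polymer, x_polymer):
        mix = mf.mole_fractions(lipid, polymer)
        assert mix.x_polymer == pytest.approx(x_polymer, abs=1e-12)
        assert mix.x_lipid + mix.x_polymer == 1.0  # exact complement

    def test_pure_lipid_limit(self):
        mix = mf.mole_fractions(5, 0)
        assert mix.x_polymer == 0.0
        assert mix.x_lipid == 1.0

    def test_rejects_nonpositive_lipid(self):
        with pytest.raises(ValueError):
            mf.mole_fractions(0, 1)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=0.1, max_value=1e4),
        st.floats(min_value=0.0, max_value=1e4),
    )
    def test_exact_sum_property(self, lipid, polymer):
        mix = mf.mole_fractions(lipid, polymer)
        assert mix.x_lipid + mix.x_polymer == 1.0
        assert 0.0 < mix.x_lipid <= 1.0


class TestIdealAdditiveIsotherm:
    def test_hand_arithmetic(self):
        lipid = mf.IsothermCurve(areas=np.array([90.0, 80.0]), pressures=np.array([5.0, 10.0]))
        polymer = mf.IsothermCurve(areas=np.array([1400.0, 1200.0]), pressures=np.array([5.0, 10.0]))
        mix = mf.mole_fractions(10, 1)
        ideal = mf.ideal_additive_isotherm(lipid, polymer, mix, [7.5, 10.0])
        # A_lipid(10) = 80, A_polymer(10) = 1200:
        # (10/11)*80 + (1/11)*1200 = 2000/11 = 181.8181...
        assert ideal.pressures[-1] == 10.0
        assert ideal.areas[-1] == pytest.approx(2000.0 / 11.0, abs=1e-9)
        assert ideal.convention == "per_molecule"

    def test_pure_lipid_identity(self, lipid_mono, gp_mono):
        mix = mf.mole_fractions(10, 0)
        grid = np.linspace(2, 30, 50)
        ideal = mf.ideal_additive_isotherm(lipid_mono, gp_mono, mix, grid)
        np.testing.assert_allclose(
            ideal.areas, mf.area_at_pressure(lipid_mono, grid), atol=1e-12
        )

    def test_identical_curves_fixed_point(self, lipid_mono):
        mix = mf.mole_fractions(10, 1)
        grid = np.linspace(2, 30, 50)
        ideal = mf.ideal_additive_isotherm(lipid_mono, lipid_mono, mix, grid)
        np.testing.assert_allclose(
            ideal.areas, mf.area_at_pressure(lipid_mono, grid), atol=1e-12
        )

    def test_grid_outside_overlap(self, lipid_mono, gp_mono):
        mix = mf.mole_fractions(10, 1)
        hi = min(lipid_mono.pressures[-1], gp_mono.pressures[-1])
        with pytest.raises(PressureOutOfRangeError):
            mf.ideal_additive_isotherm(lipid_mono, gp_mono, mix, [1.0, hi + 1.0])

    def test_rejects_per_lipid_inputs(self, lipid_mono, gp_mono):
        mix = mf.mole_fractions(10, 1)
        per_lipid = mf.to_per_lipid(lipid_mono, mix)
        with pytest.raises(ConventionError):
            mf.ideal_additive_isotherm(per_lipid, gp_mono, mix, [5.0, 10.0])

    def test_matches_brute_force_oracle(self, lipid_mono, gp_mono):
        # independent re-computation: bisect-based interpolation, scalar loop
        import bisect

        def interp_scalar(curve, p):
            ps = curve.pressures.tolist()
            As = curve.areas.tolist()
            i = bisect.bisect_left(ps, p)
            if i == 0:
                return As[0]
            if ps[i - 1] == p:
                return As[i - 1]
            f = (p - ps[i - 1]) / (ps[i] - ps[i - 1])
            return As[i - 1] + f * (As[i] - As[i - 1])

        mix = mf.mole_fractions(10, 1)
        lo = max(lipid_mono.pressures[0], gp_mono.pressures[0]) + 0.01
        hi = min(lipid_mono.pressures[-1], gp_mono.pressures[-1]) - 0.01
        grid = np.linspace(lo, hi, 200)
        ideal = mf.ideal_additive_isotherm(lipid_mono, gp_mono, mix, grid)
        for p, a in zip(ideal.pressures, ideal.areas):
            expected = mix.x_lipid * interp_scalar(lipid_mono, p) + mix.x_polymer * interp_scalar(gp_mono, p)
            assert a == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_composition(self, lipid_mono, gp_mono):
        grid = np.array([5.0, 10.0, 20.0])
        areas = []
        for polymer_count in [0.0, 0.5, 1.0, 2.0, 5.0]:
            mix = mf.mole_fractions(10, polymer_count)
            ideal = mf.ideal_additive_isotherm(lipid_mono, gp_mono, mix, grid)
            areas.append(ideal.areas)
        stacked = np.array(areas)
        assert (np.diff(stacked, axis=0) > 0).all()  # polymer area > lipid area
        a_lip = mf.area_at_pressure(lipid_mono, grid)
        a_pol = mf.area_at_pressure(gp_mono, grid)
        assert (stacked >= a_lip - 1e-9).all() and (stacked <= a_pol + 1e-9).all()


class TestToPerLipid:
    def test_hand_value(self):
        mix = mf.mole_fractions(10, 1)
        c = mf.IsothermCurve(
            areas=np.array([181.8181818181818, 150.0]),
            pressures=np.array([10.0, 20.0]),
        )
        per_lipid = mf.to_per_lipid(c, mix)
        assert per_lipid.areas[0] == pytest.approx(200.0, abs=1e-9)
        assert per_lipid.convention == "per_lipid"

    def test_pure_lipid_unchanged(self, lipid_mono):
        mix = mf.mole_fractions(10, 0)
        out = mf.to_per_lipid(lipid_mono, mix)
        np.testing.assert_array_equal(out.areas, lipid_mono.areas)

    def test_round_trip(self, lipid_mono, mix_10_1):
        out = mf.to_per_lipid(lipid_mono, mix_10_1)
        back = out.areas * mix_10_1.x_lipid
        np.testing.assert_allclose(back, lipid_mono.areas, atol=1e-12)

    def test_rejects_per_lipid_input(self, lipid_mono, mix_10_1):
        out = mf.to_per_lipid(lipid_mono, mix_10_1)
        with pytest.raises(ConventionError):
            mf.to_per_lipid(out, mix_10_1)


class TestAreaShiftVsLipid:
    def test_subtraction(self, mix_10_1):
        mix_curve = mf.IsothermCurve(
            areas=np.array([200.0, 180.0]), pressures=np.array([10.0, 20.0]),
            convention="per_lipid",
        )
        pure = mf.IsothermCurve(areas=np.array([80.0, 70.0]), pressures=np.array([10.0, 20.0]))
        series = mf.area_shift_vs_lipid(mix_curve, pure, [10.0], mixture=mix_10_1)
        assert series.delta_area[0] == pytest.approx(120.0)
        assert series.reference == "pure_lipid"

    def test_pure_vs_itself_is_zero(self, lipid_mono, mix_10_1):
        as_per_lipid = mf.IsothermCurve(
            areas=lipid_mono.areas, pressures=lipid_mono.pressures,
            convention="per_lipid",
        )
        series = mf.area_shift_vs_lipid(as_per_lipid, lipid_mono, np.linspace(2, 30, 40))
        np.testing.assert_allclose(series.delta_area, 0.0, atol=1e-12)

    def test_out_of_range_pressures_skipped_with_warning(self, lipid_mono):
        as_per_lipid = mf.IsothermCurve(
            areas=lipid_mono.areas, pressures=lipid_mono.pressures,
            convention="per_lipid",
        )
        with pytest.warns(UserWarning, match="skipped"):
            series = mf.area_shift_vs_lipid(as_per_lipid, lipid_mono, [10.0, 500.0])
        assert series.skipped_pressures == (500.0,)
        assert series.pressures.tolist() == [10.0]

    def test_increases_with_polymer_content(self, lipid_curve, lipid_mono, gp_curve):
        # fixed polymer curve, increasing mole fraction -> strictly larger dA
        shifts = []
        for polymer_count in [0.1, 0.5, 1.0, 2.0]:
            mix = mf.mole_fractions(10, polymer_count)
            mixed, _ = mf.simulate_mixed_isotherm(lipid_curve, gp_curve, mix)
            series = mf.area_shift_vs_lipid(
                mf.monotonize(mixed), lipid_mono, [4.0, 9.0, 15.0, 25.0], mixture=mix
            )
            shifts.append(series.delta_area)
        stacked = np.array(shifts)
        assert (np.diff(stacked, axis=0) > 0).all()


class TestExcessAreaOfMixing:
    def test_additivity_self_consistency(self, lipid_curve, lipid_mono, gp_curve, gp_mono, mix_10_1):
        mixed, _ = mf.simulate_mixed_isotherm(lipid_curve, gp_curve, mix_10_1)
        mono = mf.monotonize(mixed)
        # query on the mixed curve's own sample pressures: interpolation exact
        sel = (mono.pressures > 1.0) & (mono.pressures < 30.0)
        grid = mono.pressures[sel]
        ideal = mf.to_per_lipid(
            mf.ideal_additive_isotherm(lipid_mono, gp_mono, mix_10_1, grid), mix_10_1
        )
        series = mf.excess_area_of_mixing(mono, ideal, grid, mixture=mix_10_1)
        np.testing.assert_allclose(series.delta_area, 0.0, atol=1e-6)

    def test_gaussian_bump_recovery(self, lipid_curve, lipid_mono, gp_curve, gp_mono, mix_10_1):
        bump = mf.gaussian_excess(15.0, 12.0, 5.0)
        mixed, _ = mf.simulate_mixed_isotherm(
            lipid_curve, gp_curve, mix_10_1, excess_profile=bump,
            noise_sd_pressure=0.1, seed=123,
        )
        grid = np.linspace(10.0, 28.0, 150)
        ideal = mf.to_per_lipid(
            mf.ideal_additive_isotherm(lipid_mono, gp_mono, mix_10_1, grid), mix_10_1
        )
        series = mf.excess_area_of_mixing(mf.monotonize(mixed), ideal, grid)
        smoothed = np.convolve(series.delta_area, np.ones(9) / 9, mode="valid")
        assert smoothed.max() == pytest.approx(15.0, abs=2.0)

    def test_negative_beyond_squeeze_out(self, lipid_curve, lipid_mono, gp_curve, gp_mono, mix_10_1):
        # construct an experimental film that loses its polymer faster than
        # the ideal curve predicts: calculated > experimental at high pressure
        squeeze_early = mf.gp_like_params(squeeze_out_pressure=20.0, squeeze_width=0.5)
        pol_early, _ = mf.simulate_polymer_isotherm(squeeze_early, n_points=400, max_pressure=36.0)
        mixed, _ = mf.simulate_mixed_isotherm(lipid_curve, pol_early, mix_10_1)
        grid = np.linspace(25.0, 34.0, 30)
        ideal = mf.to_per_lipid(
            mf.ideal_additive_isotherm(lipid_mono, gp_mono, mix_10_1, grid), mix_10_1
        )
        series = mf.excess_area_of_mixing(mf.monotonize(mixed), ideal, grid)
        assert (series.delta_area < 0).all()


class TestConvergencePressure:
    def test_identical_curves_converge_at_range_start(self, lipid_mono):
        as_per_lipid = mf.IsothermCurve(
            areas=lipid_mono.areas, pressures=lipid_mono.pressures,
            convention="per_lipid",
        )
        conv = mf.convergence_pressure(as_per_lipid, lipid_mono)
        assert conv == pytest.approx(lipid_mono.pressures[0], abs=1e-9)

    @pytest.mark.parametrize("squeeze,expected", [(30.0, 30.0), (45.0, 45.0)])
    def test_programmed_squeeze_out(self, lipid_curve, lipid_mono, mix_10_1, squeeze, expected):
        params = mf.gp_like_params(squeeze_out_pressure=squeeze)
        polymer, _ = mf.simulate_polymer_isotherm(params, n_points=400)
        mixed, _ = mf.simulate_mixed_isotherm(lipid_curve, polymer, mix_10_1)
        conv = mf.convergence_pressure(mf.monotonize(mixed), lipid_mono)
        assert conv == pytest.approx(expected, abs=1.0)

    def test_ordering_gp_below_fgp(self, lipid_curve, lipid_mono, gp_curve, fgp_mono, mix_10_1):
        mixed_gp, _ = mf.simulate_mixed_isotherm(lipid_curve, gp_curve, mix_10_1)
        curve_fgp, _ = mf.simulate_polymer_isotherm(mf.fgp_like_params(), n_points=400)
        mixed_fgp, _ = mf.simulate_mixed_isotherm(lipid_curve, curve_fgp, mix_10_1)
        conv_gp = mf.convergence_pressure(mf.monotonize(mixed_gp), lipid_mono)
        conv_fgp = mf.convergence_pressure(mf.monotonize(mixed_fgp), lipid_mono)
        assert conv_gp < conv_fgp

    def test_absent_when_never_sustained(self, lipid_mono):
        shifted = mf.IsothermCurve(
            areas=lipid_mono.areas + 10.0, pressures=lipid_mono.pressures,
            convention="per_lipid",
        )
        assert mf.convergence_pressure(shifted, lipid_mono) is None
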