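"""Performance measures: closed-form examples on synthetic fields plus
consistency checks on real sweeps."""

import numpy as np
import pytest

from earbench import GreenwoodParams, greenwood_place
from earbench.cochlea import HarmonicSolution
from earbench.measures import (MeasureCurve, TonotopyMap, abg,
                               extract_tonotopy, icp, inner_ear_impedance,
                               max_bm_displacement, measure_curve, metf,
                               refine_peak_log, relative_bm_motion,
                               tonotopy_rmse, volume_displacements)

TWO_PI = 2.0 * np.pi


def synthetic_solution(frequency=1000.0, n=200, length=0.0319, peak_station=None,
                       bm_scale=1e-9, drive_velocity=None, p_ec=1.0 + 0j,
                       drive_area=2.8e-6):
    """Hand-built harmonic 'solution' with a controlled BM field."""
    dx = length / n
    x = (np.arange(n) + 0.5) * dx
    if peak_station is None:
        bm = np.full(n, bm_scale, dtype=complex)
    else:
        bm = bm_scale * np.exp(-0.5 * ((x - x[peak_station]) / (3 * dx)) ** 2) \
            .astype(complex)
    w = TWO_PI * frequency
    v = drive_velocity if drive_velocity is not None else 1j * w * 1e-9
    return HarmonicSolution(
        frequency=frequency, x=x, bm_displacement=bm,
        p_sv=np.ones(n, dtype=complex), p_st=np.ones(n, dtype=complex),
        p_vestibule=1.0 + 0j, q_ow=v * drive_area, q_rw=v * drive_area,
        q_gap=0.0 + 0j, drive_area=drive_area, drive_velocity=v,
        p_ec_inlet=p_ec)


class TestABG:
    def _curve(self, values):
        return MeasureCurve("m", [100.0, 1000.0, 10000.0],
                            np.asarray(values, dtype=complex), "m")

    def test_identical_curves_zero(self):
        c = self._curve([1e-9, 2e-9, 3e-9])
        assert np.allclose(abg(c, c).values, 0.0)

    def test_half_magnitude_is_minus_six_db(self):
        a = self._curve([1e-9, 1e-9, 1e-9])
        b = self._curve([2e-9, 2e-9, 2e-9])
        assert np.allclose(abg(a, b).values, -6.0206, atol=1e-3)

    def test_antisymmetry(self):
        a = self._curve([1e-9, 5e-9, 2e-9])
        b = self._curve([3e-9, 1e-9, 4e-9])
        assert np.allclose(abg(a, b).values, -abg(b, a).values)

    def test_grid_mismatch_rejected(self):
        a = self._curve([1, 1, 1])
        b = MeasureCurve("m", [100.0, 1000.0, 9000.0],
                         np.ones(3, dtype=complex), "m")
        with pytest.raises(ValueError):
            abg(a, b)


class TestRelativeBMMotion:
    @pytest.mark.parametrize("ratio, expected_db", [
        (1.0, 0.0), (10.0, 20.0), (0.5, -6.0206),
    ])
    def test_closed_form_levels(self, ratio, expected_db):
        w = TWO_PI * 1000.0
        disp_sf = 1e-9
        sol = synthetic_solution(bm_scale=ratio * disp_sf,
                                 drive_velocity=1j * w * disp_sf)
        curve = relative_bm_motion([sol, synthetic_solution(
            frequency=2000.0, bm_scale=ratio * disp_sf,
            drive_velocity=1j * 2 * w * disp_sf)])
        assert curve.values[0] == pytest.approx(expected_db, abs=1e-3)

    def test_zero_footplate_displacement_rejected(self):
        sol = synthetic_solution(drive_velocity=0.0)
        with pytest.raises(ValueError):
            relative_bm_motion([sol])

    def test_probe_is_interpolated_not_nearest_station(self, small_cochlea):
        sweep = [small_cochlea.solve(1000.0, velocity=1e-3)]
        levels = [relative_bm_motion(sweep, x_probe=x).values[0]
                  for x in (12.00e-3, 12.02e-3, 12.04e-3)]
        assert len(set(levels)) == 3  # sub-grid probes resolve distinctly
        assert max(levels) - min(levels) < 1.0  # and vary smoothly


class TestTonotopy:
    def test_forced_peak_station_recovered(self):
        sols = [synthetic_solution(frequency=f, peak_station=j)
                for f, j in [(4000.0, 50), (1000.0, 120)]]
        tmap = extract_tonotopy(sols)
        assert tmap.place_m[0] == pytest.approx(sols[1].x[120], abs=1e-6)
        assert tmap.place_m[1] == pytest.approx(sols[0].x[50], abs=1e-6)

    def test_boundary_peak_excluded_with_warning(self):
        good = [synthetic_solution(frequency=f, peak_station=j)
                for f, j in [(4000.0, 50), (1000.0, 120)]]
        flat = synthetic_solution(frequency=500.0, peak_station=199)
        with pytest.warns(UserWarning, match="excluded"):
            tmap = extract_tonotopy(good + [flat])
        assert len(tmap.frequencies) == 2

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            extract_tonotopy([synthetic_solution()])

    def test_higher_frequency_peaks_closer_to_base(self, small_cochlea):
        sweep = small_cochlea.sweep(np.geomspace(1000.0, 10000.0, 8),
                                    velocity=1e-3)
        tmap = extract_tonotopy(sweep)
        assert np.all(np.diff(tmap.place_m) < 0)  # f ascending, place to base

    def test_cf_inverts_place(self):
        gp = GreenwoodParams()
        f = np.geomspace(300.0, 8000.0, 20)
        tmap = TonotopyMap(frequencies=f, place_m=greenwood_place(f, gp))
        x = tmap.place_m[5]
        assert tmap.cf_at(x) == pytest.approx(f[5], rel=1e-9)


class TestTonotopyRMSE:
    def _greenwood_map(self, gp, shift_m=0.0):
        # map nodes on the evaluation grid itself, so interpolation is exact
        f = np.geomspace(200.0, 10000.0, 30)
        return TonotopyMap(frequencies=f,
                           place_m=greenwood_place(f, gp) + shift_m)

    def test_identical_map_gives_zero(self):
        gp = GreenwoodParams()
        assert tonotopy_rmse(self._greenwood_map(gp), gp, n_eval=30) < 1e-9

    def test_uniform_shift_gives_shift(self):
        gp = GreenwoodParams()
        rmse = tonotopy_rmse(self._greenwood_map(gp, shift_m=1e-3), gp,
                             n_eval=30)
        assert rmse == pytest.approx(1.0, rel=1e-9)  # mm

    def test_nonnegative(self):
        gp = GreenwoodParams()
        assert tonotopy_rmse(self._greenwood_map(gp, shift_m=-0.5e-3), gp,
                             n_eval=30) > 0


class TestScalarMeasures:
    def test_max_bm_displacement_zero_field(self):
        sol = synthetic_solution(bm_scale=0.0)
        assert max_bm_displacement(sol) == 0.0

    def test_max_bm_displacement_scales_with_drive(self, small_cochlea):
        a = small_cochlea.solve(2000.0, q_ow=1.0)
        b = small_cochlea.solve(2000.0, q_ow=3.0)
        assert max_bm_displacement(b) == pytest.approx(
            3.0 * max_bm_displacement(a), rel=1e-9)

    def test_icp_zero_for_symmetric_pressures(self):
        assert icp(synthetic_solution()) == 0.0

    def test_icp_exceeds_st_pressure_at_low_frequency(self, small_cochlea):
        """In the natural ear the drive across the BM dominates the scala
        tympani pressure at low frequencies."""
        for f in (125.0, 250.0, 500.0):
            s = small_cochlea.solve(f, q_ow=1.0)
            assert abs(icp(s)) >= abs(s.p_st[0])

    def test_volume_displacements_zero_drive(self, small_cochlea):
        s = small_cochlea.solve(1000.0, q_ow=0.0)
        vd_ow, vd_rw = volume_displacements(s)
        assert vd_ow == 0 and vd_rw == 0

    def test_inner_ear_impedance_unit_ratio(self):
        sol = synthetic_solution(drive_velocity=1.0 / 2.8e-6)  # q_ow = 1
        curve = inner_ear_impedance([sol])
        assert curve.values[0] == pytest.approx(1.0)

    def test_impedance_drive_invariance(self, small_cochlea):
        za = inner_ear_impedance([small_cochlea.solve(700.0, q_ow=1.0)])
        zb = inner_ear_impedance([small_cochlea.solve(700.0, q_ow=2.5j)])
        assert np.allclose(za.values, zb.values, rtol=1e-9)


class TestMETF:
    def test_flat_transfer_recovered(self):
        w = TWO_PI
        sols = [synthetic_solution(frequency=f, drive_velocity=1j * w * f * c,
                                   p_ec=1.0 + 0j)
                for f, c in [(500.0, 3e-9), (1000.0, 3e-9)]]
        curve = metf(sols)
        assert np.allclose(curve.values, 3e-9)

    def test_needs_coupled_sweep(self, small_cochlea):
        with pytest.raises(ValueError, match="coupled"):
            metf([small_cochlea.solve(1000.0, q_ow=1.0)])

    def test_amplitude_invariance(self, config):
        from earbench import CoupledEar

        a = metf(CoupledEar(config, n_sections=64).sweep([500.0, 2000.0]))
        config.middle_ear.excitation_velocity_m_s *= 7.0
        b = metf(CoupledEar(config, n_sections=64).sweep([500.0, 2000.0]))
        assert np.allclose(a.values, b.values, rtol=1e-9)


class TestCurveUtilities:
    def test_refine_peak_recovers_log_parabola(self):
        x = np.geomspace(100.0, 10000.0, 40)
        x0 = 777.0
        y = np.exp(-(np.log(x / x0)) ** 2)
        assert refine_peak_log(x, y) == pytest.approx(x0, rel=1e-3)

    def test_refine_peak_edge_fallback(self):
        x = np.geomspace(100.0, 1000.0, 10)
        y = np.linspace(1.0, 10.0, 10)  # maximum at the edge
        assert refine_peak_log(x, y) == x[-1]

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            MeasureCurve("bad", [100.0, 50.0], np.ones(2), "m")
        with pytest.raises(ValueError):
            MeasureCurve("bad", [100.0, 200.0], np.array([1.0, np.nan]), "m")

    def test_measure_curve_unknown_name(self, small_cochlea):
        with pytest.raises(KeyError):
            measure_curve([small_cochlea.solve(440.0, q_ow=1.0)], "loudness")

    def test_measure_curve_sorts_frequencies(self, small_cochlea):
        sweep = small_cochlea.sweep([2000.0, 500.0, 1000.0], q_ow=1.0)
        curve = measure_curve(sweep, "max_bm_displacement")
        assert np.all(np.diff(curve.frequencies) > 0)
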