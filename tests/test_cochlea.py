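"""Two-duct cochlear model: assembly, invariants and harmonic solutions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from earbench import CochleaModel, build_default_config
from earbench.cochlea import SolverError

TWO_PI = 2.0 * np.pi


class TestSectionImpedance:
    def test_stiffness_dominated_is_reactive_negative_imag(self, config):
        config.bm.n_sections = 64
        m = CochleaModel(config)
        m.beta[:] = 0.0
        z = (1j * TWO_PI * 50.0 * m.m_areal + m.k_areal * m.beta
             + m.k_areal / (1j * TWO_PI * 50.0))
        # far below resonance: stiffness branch k''/(i w) dominates
        assert np.all(z.real == 0)
        assert np.all(z.imag < 0)

    def test_resistive_at_section_resonance(self, small_cochlea):
        i = 40
        f_res = np.sqrt(small_cochlea.k_areal[i] / small_cochlea.m_areal[i]) / TWO_PI
        z = small_cochlea.section_bm_impedance(i, f_res)
        assert z.real > 0
        assert abs(z.imag) < 1e-6 * abs(z.real)

    def test_plate_strip_scaling_with_thickness(self, config):
        m1 = CochleaModel(config)
        config.bm.thickness_base_m *= 2
        config.bm.thickness_apex_m *= 2
        m2 = CochleaModel(config)
        assert np.allclose(m2.k_areal, 8.0 * m1.k_areal)
        assert np.allclose(m2.m_areal, 2.0 * m1.m_areal)

    def test_station_bounds(self, small_cochlea):
        with pytest.raises(IndexError):
            small_cochlea.section_bm_impedance(10_000, 1000.0)
        with pytest.raises(ValueError):
            small_cochlea.section_bm_impedance(3, -5.0)


class TestAssembly:
    @pytest.mark.parametrize("compressible", [True, False])
    def test_symmetric_system_matrix(self, config, compressible):
        m = CochleaModel(config, n_sections=64, compressible=compressible)
        a = m.assemble(973.0)
        assert abs(a - a.T).max() == 0.0

    def test_grid_size_floor(self, config):
        with pytest.raises(ValueError):
            CochleaModel(config, n_sections=8)

    def test_nonpositive_frequency_rejected(self, small_cochlea):
        with pytest.raises(ValueError):
            small_cochlea.assemble(0.0)


class TestConservationAndPassivity:
    @pytest.mark.parametrize("f", [125.0, 1000.0, 9000.0])
    def test_incompressible_window_volume_equality(self, config, f):
        m = CochleaModel(config, n_sections=200, compressible=False)
        s = m.solve(f, q_ow=1.0)
        assert abs(abs(s.vd_rw / s.vd_ow) - 1.0) < 1e-6

    def test_compressible_divergence_grows_with_frequency(self, config):
        m = CochleaModel(config, n_sections=200, compressible=True)
        dev = [abs(abs(m.solve(f, q_ow=1.0).vd_rw
                       / m.solve(f, q_ow=1.0).vd_ow) - 1.0)
               for f in (2000.0, 4000.0, 8000.0, 10000.0)]
        assert all(a < b for a, b in zip(dev, dev[1:]))

    def test_drive_point_passivity(self, small_cochlea):
        for f in np.geomspace(100.0, 10000.0, 25):
            assert small_cochlea.drive_point_impedance(f).real >= 0.0

    def test_rigid_bm_routes_all_flow_through_helicotrema(self, config):
        m = CochleaModel(config, n_sections=100, compressible=False)
        m._quad_k *= 1e12  # E -> infinity limit
        s = m.solve(500.0, q_ow=1.0)
        assert abs(s.q_rw) == pytest.approx(1.0, rel=1e-9)
        # opposite sign through the loop: RW flow leaves the cochlea
        assert s.q_gap == 0.0

    def test_impedance_magnitude_in_measured_corridor(self, small_cochlea):
        # order-of-magnitude band of published cochlear input impedances
        mags = [abs(small_cochlea.sv_inlet_impedance(f))
                for f in np.geomspace(100.0, 10000.0, 15)]
        assert all(1e9 < m < 1e12 for m in mags)


class TestSolve:
    def test_zero_drive_gives_zero_field(self, small_cochlea):
        s = small_cochlea.solve(1000.0, q_ow=0.0)
        assert np.all(s.bm_displacement == 0)
        assert np.all(s.p_sv == 0) and np.all(s.p_st == 0)

    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(scale=st.complex_numbers(min_magnitude=1e-3, max_magnitude=1e3,
                                    allow_nan=False, allow_infinity=False))
    def test_linearity_in_excitation(self, small_cochlea, scale):
        base = small_cochlea.solve(1500.0, q_ow=1.0)
        scaled = small_cochlea.solve(1500.0, q_ow=scale)
        expected = scale * base.bm_displacement
        # absolute floor: the overdamped apical tail sits at the direct
        # solver's noise level, ~1e-14 of the field maximum
        floor = 1e-12 * np.abs(expected).max()
        assert np.allclose(scaled.bm_displacement, expected,
                           rtol=1e-7, atol=floor)
        assert np.isclose(scaled.q_rw, scale * base.q_rw, rtol=1e-9)

    def test_velocity_drive_uses_port_area(self, small_cochlea):
        s = small_cochlea.solve(1000.0, velocity=1e-3)
        assert s.q_ow == pytest.approx(1e-3 * small_cochlea.drive_area)
        assert s.drive_displacement == pytest.approx(
            1e-3 / (1j * TWO_PI * 1000.0))

    def test_drive_argument_validation(self, small_cochlea):
        with pytest.raises(ValueError):
            small_cochlea.solve(1000.0)
        with pytest.raises(ValueError):
            small_cochlea.solve(1000.0, q_ow=1.0, velocity=1.0)
        with pytest.raises(ValueError):
            small_cochlea.solve(1000.0, q_ow=np.inf)

    def test_mechanical_load_shape(self, small_cochlea):
        z = small_cochlea.mechanical_load(800.0)
        assert z.shape == (3, 3)
        assert z[0, 0] != 0
        assert np.all(z[1:, :] == 0) and np.all(z[:, 1:] == 0)


class TestSweep:
    def test_singleton_grid(self, small_cochlea):
        sols = small_cochlea.sweep([440.0], q_ow=1.0)
        assert len(sols) == 1 and sols[0].frequency == 440.0

    def test_order_invariance(self, small_cochlea):
        grid = [300.0, 1200.0, 4800.0]
        fwd = small_cochlea.sweep(grid, q_ow=1.0)
        rev = small_cochlea.sweep(grid[::-1], q_ow=1.0)
        for a, b in zip(fwd, rev[::-1]):
            assert a.frequency == b.frequency
            assert np.array_equal(a.bm_displacement, b.bm_displacement)

    def test_invalid_grid(self, small_cochlea):
        with pytest.raises(ValueError):
            small_cochlea.sweep([], q_ow=1.0)
        with pytest.raises(ValueError):
            small_cochlea.sweep([-100.0], q_ow=1.0)


def test_grid_convergence_at_finest_grids(default_config):
    """Drive-point impedance converges under grid refinement (finest grids)."""
    z1 = CochleaModel(default_config, n_sections=1024).drive_point_impedance(1000.0)
    z2 = CochleaModel(default_config, n_sections=2048).drive_point_impedance(1000.0)
    assert abs(z2 - z1) / abs(z2) < 0.02


def test_hdf5_sweep_roundtrip(small_cochlea, tmp_path):
    from earbench.cochlea import load_sweep_hdf5, save_sweep_hdf5

    sweep = small_cochlea.sweep([500.0, 2000.0], q_ow=1.0)
    path = tmp_path / "sweep.h5"
    save_sweep_hdf5(sweep, path)
    back = load_sweep_hdf5(path)
    assert len(back) == 2
    for a, b in zip(sweep, back):
        assert a.frequency == b.frequency
        assert np.array_equal(a.bm_displacement, b.bm_displacement)
        assert a.q_rw == b.q_rw and a.drive_area == b.drive_area
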