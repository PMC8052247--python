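"""Lattice-Boltzmann solver: unit mapping, conservation, benchmarks."""

import numpy as np
import pytest

from rhinoflow.imaging import domain_from_mask
from rhinoflow.lbm import (
    InstabilityError,
    LBMSolver,
    SolverConfig,
    UnitMapping,
    _equilibrium,
    physical_to_lattice,
    reynolds_number,
)


def closed_box_solver(n=16, spacing=0.5):
    mask = np.zeros((n, n, n), bool)
    mask[1:-1, 1:-1, 1:-1] = True
    dom = domain_from_mask(mask, spacing)
    cfg = SolverConfig(flow_rate_ml_s=1.0, spacing_mm=spacing)
    return LBMSolver(dom, cfg)


def poiseuille_solver(n_gap=21, tau0=0.9, force=1e-6):
    """Plane channel: walls on axis 1, periodic along axes 0 and 2."""
    mask = np.ones((4, n_gap + 2, 1), bool)
    mask[:, 0, :] = False
    mask[:, -1, :] = False
    dom = domain_from_mask(mask, 0.5, periodic_axes=(0, 2))
    dx = 5e-4
    nu_lat = (tau0 - 0.5) / 3.0
    mapping = UnitMapping(dx_m=dx, dt_s=nu_lat * dx**2 / 1.5e-5, tau0=tau0, air_density=1.2)
    cfg = SolverConfig(flow_rate_ml_s=1.0, spacing_mm=0.5, body_force_lat=(force, 0.0, 0.0))
    return LBMSolver(dom, cfg, mapping=mapping)


class TestUnitMapping:
    def test_tau_from_lattice_viscosity(self):
        """tau0 = 3 nu_lat + 0.5 and nu_lat = nu_phys dt / dx^2."""
        cfg = SolverConfig(flow_rate_ml_s=100.0, spacing_mm=0.5, char_area_mm2=30.0)
        m = physical_to_lattice(cfg)
        nu_lat = cfg.air_kinematic_viscosity * m.dt_s / m.dx_m**2
        assert m.tau0 == pytest.approx(3.0 * nu_lat + 0.5, rel=1e-12)
        assert 0.5 < m.tau0 <= 1.99

    def test_velocity_roundtrip_machine_precision(self):
        m = physical_to_lattice(SolverConfig(flow_rate_ml_s=60.0, spacing_mm=0.5,
                                             char_area_mm2=28.0))
        u = np.array([0.05, -0.01, 0.002])
        np.testing.assert_allclose(m.vel_to_lat(m.vel_to_phys(u)), u, rtol=1e-15)

    def test_diffusive_scaling_doubling_dx_quadruples_dt(self):
        """When the viscous constraint binds (fixed tau0), dt scales as dx^2."""
        big_area = 1e9  # velocity cap never binds
        m1 = physical_to_lattice(SolverConfig(flow_rate_ml_s=1.0, spacing_mm=0.5,
                                              char_area_mm2=big_area))
        m2 = physical_to_lattice(SolverConfig(flow_rate_ml_s=1.0, spacing_mm=1.0,
                                              char_area_mm2=big_area))
        assert m1.tau0 == pytest.approx(m2.tau0)
        assert m2.dt_s == pytest.approx(4.0 * m1.dt_s, rel=1e-12)

    def test_velocity_cap_respected(self):
        cfg = SolverConfig(flow_rate_ml_s=600.0, spacing_mm=0.5, char_area_mm2=28.0)
        m = physical_to_lattice(cfg)
        u_char = (cfg.flow_rate_ml_s * 1e-6) / (28.0 * 1e-6)
        assert m.vel_to_lat(u_char) <= cfg.max_lattice_velocity * (1 + 1e-12)

    def test_missing_area_rejected(self):
        with pytest.raises(ValueError, match="char_area"):
            physical_to_lattice(SolverConfig(flow_rate_ml_s=60.0, spacing_mm=0.5))


class TestConservationAndEquilibrium:
    def test_equilibrium_fixed_point_bitwise(self):
        """Uniform density at rest is exactly stationary, bit for bit."""
        solver = closed_box_solver()
        st = solver.equilibrium_state()
        f0 = st.f.copy()
        for _ in range(20):
            st = solver.step_state(st)
        assert np.array_equal(st.f, f0)

    def test_closed_box_mass_conserved_1000_steps(self):
        """Bounce-back + BGK conserve mass to 1e-12 relative over 1000 steps."""
        solver = closed_box_solver()
        rng = np.random.default_rng(7)
        rho = 1.0 + 0.05 * rng.standard_normal(solver.n)
        u = 0.02 * rng.standard_normal((3, solver.n))
        st = solver.equilibrium_state()
        st.f = _equilibrium(rho, u)
        m0 = st.f.sum()
        for _ in range(1000):
            st = solver.step_state(st)
        assert abs(st.f.sum() - m0) / m0 < 1e-12

    def test_determinism_bit_identical(self):
        solver = closed_box_solver(n=10)
        rng = np.random.default_rng(3)
        st1 = solver.equilibrium_state()
        st1.f = _equilibrium(1 + 0.02 * rng.standard_normal(solver.n),
                             0.01 * rng.standard_normal((3, solver.n)))
        st2 = st1.f.copy()
        a = st1
        for _ in range(50):
            a = solver.step_state(a)
        b = solver.equilibrium_state()
        b.f = st2
        for _ in range(50):
            b = solver.step_state(b)
        assert np.array_equal(a.f, b.f)


@pytest.fixture(scope="module")
def steady_profile():
    solver = poiseuille_solver()
    st = solver.equilibrium_state()
    for _ in range(6000):
        st = solver.step_state(st)
    return st.velocity_field(prefer_mean=False)[0, 1:-1, 0, 0]


class TestPoiseuille:
    def test_centerline_to_mean_ratio(self, steady_profile):
        """Parabolic duct flow: max/mean = 1.5 within 2% at 21 nodes."""
        v = steady_profile
        assert v.size == 21
        assert v.max() / v.mean() == pytest.approx(1.5, rel=0.02)

    def test_profile_is_parabolic(self, steady_profile):
        """L2 distance to the analytic parabola (walls at the halfway
        planes) below 2%."""
        v = steady_profile
        y = np.arange(v.size) - (v.size - 1) / 2.0
        half = v.size / 2.0  # halfway bounce-back: walls half a cell past the end nodes
        parabola = v.max() * (1.0 - (y / half) ** 2)
        assert np.linalg.norm(v - parabola) / np.linalg.norm(parabola) < 0.02

    def test_axis_permutation_symmetry(self):
        """The same duct built along another lattice axis gives the same
        profile (D3Q19 axis-permutation symmetry)."""
        ref = poiseuille_solver()
        st = ref.equilibrium_state()
        for _ in range(2000):
            st = ref.step_state(st)
        v_ref = st.velocity_field(prefer_mean=False)[0, 1:-1, 0, 0]

        mask = np.ones((1, 4, 23), bool)
        mask[:, :, 0] = False
        mask[:, :, -1] = False
        dom = domain_from_mask(mask, 0.5, periodic_axes=(0, 1))
        cfg = SolverConfig(flow_rate_ml_s=1.0, spacing_mm=0.5, body_force_lat=(0.0, 1e-6, 0.0))
        rot = LBMSolver(dom, cfg, mapping=ref.mapping)
        st2 = rot.equilibrium_state()
        for _ in range(2000):
            st2 = rot.step_state(st2)
        v_rot = st2.velocity_field(prefer_mean=False)[0, 0, 1:-1, 1]
        np.testing.assert_allclose(v_rot, v_ref, rtol=1e-10, atol=1e-18)


class TestRun:
    def test_step_count_arithmetic(self):
        m = physical_to_lattice(SolverConfig(flow_rate_ml_s=60.0, spacing_mm=0.5,
                                             char_area_mm2=28.0))
        assert m.steps_for(0.0125) == round(0.0125 / m.dt_s)

    def test_instability_reported(self):
        solver = closed_box_solver(n=8)
        st = solver.equilibrium_state()
        st.f[:, 0] = np.nan
        st = solver.step_state(st)
        with pytest.raises(InstabilityError, match="step"):
            solver._check(st)


class TestReynolds:
    def test_circular_section(self):
        """D_h of a circle is its diameter."""
        r = 5.0
        area = np.pi * r**2
        perim = 2 * np.pi * r
        v = 600e-6 / (area * 1e-6)
        expected = v * (2 * r * 1e-3) / 1.5e-5
        assert reynolds_number(area, perim, 600.0) == pytest.approx(expected, rel=1e-12)

    def test_square_section(self):
        """D_h of a square duct is its side."""
        a = 6.0
        re = reynolds_number(a * a, 4 * a, 100.0)
        v = 100e-6 / (a * a * 1e-6)
        assert re == pytest.approx(v * a * 1e-3 / 1.5e-5, rel=1e-12)

    def test_hand_arithmetic(self):
        """area 100 mm^2, perimeter 40 mm, 600 ml/s -> Re = 4000."""
        assert reynolds_number(100.0, 40.0, 600.0, 1.5e-5) == pytest.approx(4000.0, rel=1e-12)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            reynolds_number(0.0, 40.0, 600.0)
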