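"""Streamline seeding, integration and pressure sampling on analytic fields."""

import numpy as np
import pytest

from rhinoflow.streamlines import (
    StreamlineTracer,
    Termination,
    sample_pressure,
    seed_in_sphere,
    trace,
)


def uniform_field(shape=(40, 20, 20), v=(1.0, 0.0, 0.0)):
    out = np.zeros((*shape, 3))
    out[...] = v
    return out


def rotation_field(shape=(41, 41, 5), omega=1.0, spacing=1.0):
    """Solid-body rotation about the axis-2 line through the grid centre."""
    n0, n1, _ = shape
    c0, c1 = (n0 - 1) / 2.0 * spacing, (n1 - 1) / 2.0 * spacing
    x0 = np.arange(n0)[:, None, None] * spacing - c0
    x1 = np.arange(n1)[None, :, None] * spacing - c1
    out = np.zeros((*shape, 3))
    out[..., 0] = -omega * x1
    out[..., 1] = omega * x0
    return out


class TestSeeding:
    def test_reproducible_from_seed(self):
        a = seed_in_sphere(532, (10.0, 10.0, 10.0), 8.0, rng_seed=42)
        b = seed_in_sphere(532, (10.0, 10.0, 10.0), 8.0, rng_seed=42)
        np.testing.assert_array_equal(a, b)
        c = seed_in_sphere(532, (10.0, 10.0, 10.0), 8.0, rng_seed=43)
        assert not np.array_equal(a, c)

    def test_all_points_inside_ball(self):
        center = np.array([5.0, 6.0, 7.0])
        pts = seed_in_sphere(2000, center, 10.0, rng_seed=1)
        assert (np.linalg.norm(pts - center, axis=1) <= 5.0 + 1e-12).all()

    def test_empirical_mean_near_center(self):
        """Law of large numbers: per-axis mean within 1% of the radius."""
        center = np.array([0.0, 0.0, 0.0])
        pts = seed_in_sphere(10_000, center, 2.0, rng_seed=0)
        assert (np.abs(pts.mean(axis=0)) < 0.01 * 1.0).all()

    def test_rejection_respects_fluid_mask(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[:, :10, :] = True
        pts = seed_in_sphere(200, (9.5, 9.5, 9.5), 10.0, 5, fluid_mask=mask, spacing=1.0)
        idx = np.rint(pts).astype(int)
        assert mask[idx[:, 0], idx[:, 1], idx[:, 2]].all()

    def test_empty_sphere_rejected(self):
        mask = np.zeros((20, 20, 20), bool)
        with pytest.raises(ValueError, match="no fluid"):
            seed_in_sphere(10, (10.0, 10.0, 10.0), 4.0, 0, fluid_mask=mask, spacing=1.0)


class TestTrace:
    def test_uniform_field_straight_segment(self):
        """Constant velocity: forward trace is a straight segment of the
        requested length."""
        line = trace(uniform_field(), 1.0, (5.0, 10.0, 10.0), direction="forward",
                     max_length_mm=10.0)
        assert line.termination_reason == Termination.MAX_LENGTH
        assert line.arc_length[-1] == pytest.approx(10.0, abs=1e-6)
        np.testing.assert_allclose(line.vertices[-1], [15.0, 10.0, 10.0], atol=1e-6)
        # straightness: lateral coordinates constant
        np.testing.assert_allclose(line.vertices[:, 1:], 10.0, atol=1e-9)

    def test_rotation_closed_orbit_arc_length(self):
        """One revolution of a solid-body rotation has arc length 2 pi r."""
        r = 8.0
        field = rotation_field()
        seed = (20.0 + r, 20.0, 2.0)
        circumference = 2 * np.pi * r
        line = trace(field, 1.0, seed, direction="forward", max_length_mm=circumference)
        assert line.arc_length[-1] == pytest.approx(circumference, rel=1e-6)
        np.testing.assert_allclose(line.vertices[-1], seed, atol=0.01 * r)

    def test_forward_backward_reversibility(self):
        """Tracing back from the forward endpoint returns to the seed
        within 1% of the path length."""
        field = rotation_field()
        seed = np.array([26.0, 20.0, 2.0])
        fwd = trace(field, 1.0, seed, direction="forward", max_length_mm=15.0)
        end = fwd.vertices[-1]
        back = trace(field, 1.0, end, direction="backward", max_length_mm=15.0)
        assert np.linalg.norm(back.vertices[-1] - seed) < 0.01 * 15.0

    def test_both_concatenates_through_seed(self):
        line = trace(uniform_field(), 1.0, (20.0, 10.0, 10.0), direction="both",
                     max_length_mm=10.0)
        # seed is an interior vertex, arc length non-decreasing
        d = np.linalg.norm(line.vertices - [20.0, 10.0, 10.0], axis=1)
        assert d.min() < 1e-6 and np.argmin(d) not in (0, len(d) - 1)
        assert (np.diff(line.arc_length) > 0).all()

    def test_zero_field_stagnates_at_seed(self):
        field = np.zeros((10, 10, 10, 3))
        line = trace(field, 1.0, (5.0, 5.0, 5.0))
        assert line.termination_reason == Termination.STAGNATION
        assert len(line.vertices) == 1

    def test_arc_length_never_exceeds_budget(self):
        field = rotation_field()
        for ml in (5.0, 20.0, 60.0):
            line = trace(field, 1.0, (30.0, 20.0, 2.0), direction="forward", max_length_mm=ml)
            assert line.arc_length[-1] <= ml + 5.0  # one max_step of slack

    def test_seed_outside_fluid_rejected(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[:5] = True
        with pytest.raises(ValueError, match="outside"):
            trace(uniform_field((10, 10, 10)), 1.0, (8.0, 5.0, 5.0), fluid_mask=mask)

    def test_domain_exit_terminates(self):
        line = trace(uniform_field((10, 10, 10)), 1.0, (5.0, 5.0, 5.0), direction="forward",
                     max_length_mm=100.0)
        assert line.termination_reason in (Termination.LEFT_DOMAIN, Termination.STAGNATION)
        assert line.vertices[-1, 0] <= 9.0 + 1e-9


class TestSamplePressure:
    def test_constant_field(self):
        line = trace(uniform_field(), 1.0, (5.0, 10.0, 10.0), direction="forward",
                     max_length_mm=8.0)
        p = np.full((40, 20, 20), 3.5)
        out = sample_pressure(line, p, 1.0)
        np.testing.assert_allclose(out.pressure, 3.5, atol=1e-12)

    def test_linear_field_gradient_recovered(self):
        """dp/dl along an x-aligned line through p = a*x equals a."""
        a = -2.0
        shape = (40, 20, 20)
        x = np.arange(shape[0])[:, None, None] * 1.0
        p = np.broadcast_to(a * x, shape).copy()
        line = trace(uniform_field(shape), 1.0, (5.0, 10.0, 10.0), direction="forward",
                     max_length_mm=20.0)
        out = sample_pressure(line, p, 1.0)
        grads = np.diff(out.pressure) / np.diff(out.arc_length)
        np.testing.assert_allclose(grads, a, rtol=1e-6)

    def test_idempotent(self):
        line = trace(uniform_field(), 1.0, (5.0, 10.0, 10.0), direction="forward",
                     max_length_mm=5.0)
        p = np.random.default_rng(0).normal(size=(40, 20, 20))
        once = sample_pressure(line, p, 1.0)
        twice = sample_pressure(once, p, 1.0)
        np.testing.assert_array_equal(once.pressure, twice.pressure)
        np.testing.assert_array_equal(once.vertices, twice.vertices)
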