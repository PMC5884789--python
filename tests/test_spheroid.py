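"""Spheroid partial-g model: quadrature map, sampler, drivers, convergence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from rpmsim.exceptions import InvalidArgumentError
from rpmsim.kinematics import time_averaged_gravity
from rpmsim.spheroid import (
    PartialGTarget,
    SpheroidSpec,
    axial_component,
    band_weight,
    convergence_report,
    eccentricity_for_mean_g,
    focal_distance,
    generate_sw_trajectory,
    mean_g_from_eccentricity,
    sample_spheroid_directions,
    transverse_component,
    two_state_trajectory,
)

DOWN = np.array([0.0, 0.0, -1.0])


def surface_mean_g_oracle(e: float, n_grid: int = 200_001) -> float:
    """Brute-force mean gravity factor from explicit 3D spheroid geometry.

    Builds the surface point P(z) = (b sqrt(1-z^2), 0, z) with the focus at
    (0, 0, e), takes the axial component of the unit focus-to-surface
    direction from coordinates (no algebraic simplification), and weights by
    the surface-area element obtained by finite differences of the meridian
    curve. Independent of the quadrature's simplified integrand.
    """
    b = math.sqrt(1.0 - e * e)
    z = np.linspace(-1.0, 1.0, n_grid)
    zc = 0.5 * (z[1:] + z[:-1])
    rho = b * np.sqrt(1.0 - zc**2)
    dist = np.sqrt(rho**2 + (zc - e) ** 2)
    axial = (zc - e) / dist
    # meridian arc length per z step, from finite differences
    rho_edge = b * np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    darc = np.sqrt(np.diff(rho_edge) ** 2 + np.diff(z) ** 2)
    area = rho * darc  # ring area up to the constant 2*pi
    return abs(np.sum(axial * area) / np.sum(area))


class TestMeanGFromEccentricity:
    def test_sphere_gives_zero(self):
        assert mean_g_from_eccentricity(0.0) == 0.0

    @pytest.mark.parametrize(
        "ecc,expected",
        [(0.25, 0.17), (0.53, 0.38), (0.66, 0.50), (0.87, 0.75)],
    )
    def test_standard_planning_pairs(self, ecc, expected):
        assert mean_g_from_eccentricity(ecc) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize("ecc", [0.1, 0.3, 0.53, 0.7, 0.9])
    def test_agrees_with_geometric_surface_oracle(self, ecc):
        assert mean_g_from_eccentricity(ecc) == pytest.approx(
            surface_mean_g_oracle(ecc), abs=1e-4
        )

    def test_strictly_increasing_and_limits(self):
        grid = np.linspace(0.0, 0.999, 60)
        vals = [mean_g_from_eccentricity(e) for e in grid]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] > 0.99

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5, math.nan])
    def test_domain_errors(self, bad):
        with pytest.raises(InvalidArgumentError):
            mean_g_from_eccentricity(bad)


class TestEccentricityForMeanG:
    def test_zero_maps_to_zero(self):
        assert eccentricity_for_mean_g(0.0) == 0.0

    @pytest.mark.parametrize("p,expected", [(0.38, 0.53), (0.75, 0.87)])
    def test_standard_inverse_pairs(self, p, expected):
        assert eccentricity_for_mean_g(p) == pytest.approx(expected, abs=0.01)

    def test_round_trip_identity(self):
        for e in np.linspace(0.0, 0.95, 20):
            p = mean_g_from_eccentricity(e)
            assert eccentricity_for_mean_g(p) == pytest.approx(e, abs=1e-5)

    @pytest.mark.parametrize("bad", [-0.01, 1.0, 1.2])
    def test_domain_errors(self, bad):
        with pytest.raises(InvalidArgumentError):
            eccentricity_for_mean_g(bad)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    e=st.floats(0.0, 0.999, allow_nan=False),
    z=st.floats(-1.0, 1.0, allow_nan=False),
)
def test_direction_components_are_unit_norm(e, z):
    """Axial² + transverse² = 1 identically over the whole (e, z) domain."""
    a = float(axial_component(e, z))
    tr = float(transverse_component(e, z))
    assert a * a + tr * tr == pytest.approx(1.0, abs=1e-12)


def test_geometry_contract_against_explicit_surface(rng):
    """Focal distance and area element match brute-force 3D geometry."""
    for _ in range(200):
        e = rng.uniform(0.0, 0.99)
        z = rng.uniform(-0.999, 0.999)
        b = math.sqrt(1.0 - e * e)
        p = np.array([b * math.sqrt(1.0 - z * z), 0.0, z])
        focus = np.array([0.0, 0.0, e])
        assert np.linalg.norm(p - focus) == pytest.approx(float(focal_distance(e, z)), abs=1e-12)
        # area element ∝ sqrt(1 - e² z²): compare ratios at two heights
        h = 1e-6
        pz = np.array([b * math.sqrt(1.0 - (z + h) ** 2), 0.0, z + h])
        darc = np.linalg.norm(pz - p)
        ring = p[0] * darc  # ∝ rho * d(arc)
        expected = b * float(band_weight(e, z)) * h
        assert ring == pytest.approx(expected, rel=1e-3)


class TestSampler:
    def test_unit_norm_draws(self):
        d = sample_spheroid_directions(SpheroidSpec(0.7), 10_000, seed=0)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-9)

    def test_uniform_sphere_mean_near_zero(self):
        n = 10**6
        d = sample_spheroid_directions(SpheroidSpec(0.0), n, seed=1)
        assert np.linalg.norm(d.mean(axis=0)) < 3.0 / math.sqrt(n / 3.0)

    def test_mars_eccentricity_mean_axial_matches_quadrature(self):
        n = 10**6
        spec = SpheroidSpec(0.53)
        d = sample_spheroid_directions(spec, n, seed=2)
        axial = d @ spec.symmetry_axis
        se = axial.std(ddof=1) / math.sqrt(n)
        assert abs(axial.mean() - mean_g_from_eccentricity(0.53)) < 3.0 * se

    def test_custom_symmetry_axis_respected(self):
        axis = np.array([1.0, 0.0, 0.0])
        spec = SpheroidSpec(0.53, symmetry_axis=axis)
        d = sample_spheroid_directions(spec, 200_000, seed=3)
        assert (d @ axis).mean() == pytest.approx(0.383, abs=0.01)

    def test_invalid_count_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sample_spheroid_directions(SpheroidSpec(0.5), 0)


class TestSpheroidSpec:
    def test_derived_quantities(self):
        s = SpheroidSpec(0.6)
        assert s.semi_major == 1.0
        assert s.semi_minor == pytest.approx(0.8)
        assert s.focal_distance == 0.6
        assert s.semi_minor**2 + s.eccentricity**2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.2, 1.0, 1.3])
    def test_eccentricity_domain(self, bad):
        with pytest.raises(InvalidArgumentError):
            SpheroidSpec(bad)

    def test_axis_must_be_unit(self):
        with pytest.raises(InvalidArgumentError):
            SpheroidSpec(0.5, symmetry_axis=np.array([0.0, 0.0, -2.0]))


class TestPartialGTarget:
    @pytest.mark.parametrize("p,q", [(0.0, 0.5), (0.38, 0.69), (1.0, 1.0)])
    def test_two_state_fraction(self, p, q):
        assert PartialGTarget(p).q == pytest.approx(q)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_domain(self, bad):
        with pytest.raises(InvalidArgumentError):
            PartialGTarget(bad)


class TestTwoStateTrajectory:
    @pytest.mark.parametrize("p", [0.0, 0.38, 1.0])
    def test_mean_magnitude_matches_target(self, p):
        duration, dt = 3600.0, 0.5
        trace = two_state_trajectory(PartialGTarget(p), duration, dt)
        _, mag = time_averaged_gravity(trace)
        assert mag == pytest.approx(p, abs=dt / duration + 1e-12)

    def test_invalid_duration(self):
        with pytest.raises(InvalidArgumentError):
            two_state_trajectory(PartialGTarget(0.5), duration=0.0, dt=0.1)


class TestSwTrajectory:
    def test_invalid_arguments(self):
        spec = SpheroidSpec(0.53)
        with pytest.raises(InvalidArgumentError):
            generate_sw_trajectory(spec, duration=10.0, dt=0.0)
        with pytest.raises(InvalidArgumentError):
            generate_sw_trajectory(spec, duration=10.0, dt=0.1, max_rate=0.0)

    def test_trace_shape_seed_and_metadata(self):
        trace = generate_sw_trajectory(SpheroidSpec(0.53), 60.0, 0.1, seed=9)
        assert len(trace) == 601
        assert trace.metadata["seed"] == 9
        assert trace.metadata["eccentricity"] == 0.53
        assert np.allclose(np.linalg.norm(trace.u, axis=1), 1.0, atol=1e-9)

    def test_same_seed_reproduces_trace(self):
        a = generate_sw_trajectory(SpheroidSpec(0.53), 120.0, 0.1, seed=4)
        b = generate_sw_trajectory(SpheroidSpec(0.53), 120.0, 0.1, seed=4)
        assert np.array_equal(a.u, b.u)

    def test_axis_rates_stay_within_limit(self):
        # successive directions can never move faster than both axes at max
        rate = math.radians(60.0)
        trace = generate_sw_trajectory(SpheroidSpec(0.53), 300.0, 0.1, max_rate=rate, seed=5)
        cosang = np.clip(np.sum(trace.u[1:] * trace.u[:-1], axis=1), -1, 1)
        assert np.all(np.arccos(cosang) <= math.sqrt(2.0) * rate * 0.1 + 1e-9)
        assert trace.metadata["rates_clipped"] is False

    def test_one_hour_runs_converge_near_target(self):
        # simulated microgravity and the 0.38 g level both settle to within
        # a few hundredths of the target after one hour of rotation
        for ecc, target in [(0.0, 0.0), (0.53, mean_g_from_eccentricity(0.53))]:
            trace = generate_sw_trajectory(SpheroidSpec(ecc), 3600.0, 0.1, seed=5)
            _, mag = time_averaged_gravity(trace)
            assert abs(mag - target) < 0.05


class TestConvergenceReport:
    def test_constant_down_trace_has_zero_error(self):
        trace = two_state_trajectory(PartialGTarget(1.0), 100.0, 1.0)
        rep = convergence_report(trace, 1.0)
        assert np.all(rep.errors < 1e-12)

    def test_two_state_end_error_bounded_by_discretization(self):
        duration, dt = 2000.0, 0.5
        trace = two_state_trajectory(PartialGTarget(0.38), duration, dt)
        rep = convergence_report(trace, 0.38)
        assert rep.final_error <= dt / duration + 1e-12

    def test_error_decays_on_log_grid_for_seeded_run(self):
        target = mean_g_from_eccentricity(0.53)
        trace = generate_sw_trajectory(SpheroidSpec(0.53), 4 * 3600.0, 0.1, seed=42)
        rep = convergence_report(trace, target)
        grid = np.unique(
            np.searchsorted(rep.times, np.logspace(np.log10(60), np.log10(rep.times[-1]), 10))
        )
        errs = rep.errors[np.minimum(grid, rep.errors.size - 1)]
        rho = spearmanr(np.arange(errs.size), errs).statistic
        assert rho < 0
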