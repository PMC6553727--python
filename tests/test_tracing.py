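import numpy as np
import pytest

from keratrace.cornea import ConicSurface, CornealModel, OpticalConstants
from keratrace.errors import (
    DomainError,
    InsufficientCoverageError,
    TotalInternalReflectionError,
)
from keratrace.tracing import (
    GridSpec,
    PowerMap,
    build_power_map,
    gaussian_equivalent_power,
    snell_refract,
    tcrp_ring,
    tcrp_zone,
    trace_power_at,
)

from .conftest import physiologic_model
from .oracles import meridional_trace_power


class TestSnellRefract:
    def test_normal_incidence_unchanged(self):
        d = np.array([0.0, 0.0, 1.0])
        out = snell_refract(d, np.array([0.0, 0.0, -1.0]), 1.0, 1.376)
        assert np.allclose(out, d, atol=1e-15)

    def test_thirty_degrees_air_to_cornea(self):
        th = np.radians(30.0)
        d = np.array([np.sin(th), 0.0, np.cos(th)])
        out = snell_refract(d, np.array([0.0, 0.0, -1.0]), 1.0, 1.376)
        angle = np.degrees(np.arcsin(np.hypot(out[0], out[1])))
        assert angle == pytest.approx(np.degrees(np.arcsin(0.5 / 1.376)), abs=1e-9)
        assert angle == pytest.approx(21.31, abs=0.005)

    def test_invariant_conserved_random(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n_in, n_out = rng.uniform(1.0, 1.8, 2)
            # random incident direction and opposing normal
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            if np.dot(d, n) > 0:
                n = -n
            sin_in = np.sqrt(max(0.0, 1.0 - np.dot(d, n) ** 2))
            if n_in * sin_in / n_out >= 1.0:
                continue  # would be total internal reflection
            t = snell_refract(d, n, n_in, n_out)
            sin_out = np.sqrt(max(0.0, 1.0 - np.dot(t, n) ** 2))
            assert abs(n_in * sin_in - n_out * sin_out) < 1e-12
            assert np.linalg.norm(t) == pytest.approx(1.0, abs=1e-12)
            # plane of incidence preserved: t lies in span(d, n)
            cross = np.cross(d, n)
            if np.linalg.norm(cross) > 1e-12:
                assert abs(np.dot(t, cross / np.linalg.norm(cross))) < 1e-12

    def test_total_internal_reflection_raises(self):
        th = np.radians(80.0)
        d = np.array([np.sin(th), 0.0, np.cos(th)])
        with pytest.raises(TotalInternalReflectionError):
            snell_refract(d, np.array([0.0, 0.0, -1.0]), 1.376, 1.0)


class TestGaussianEquivalentPower:
    def test_worked_example(self, standard_model):
        # 48.8312 - 6.25 + 0.1109
        assert gaussian_equivalent_power(standard_model) == pytest.approx(42.692, abs=5e-4)

    def test_thin_lens_limit(self):
        m = CornealModel(ConicSurface(7.7), ConicSurface(6.4, 0.0, 0.201), 0.201)
        p1 = 0.376 / 0.0077
        p2 = -0.040 / 0.0064
        thick = gaussian_equivalent_power(m)
        assert thick == pytest.approx(p1 + p2 + (0.000201 / 1.376) * abs(p1 * p2), abs=1e-9)

    def test_matches_paraxial_trace_on_random_models(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            m = physiologic_model(rng)
            assert trace_power_at(m, 0.005) == pytest.approx(
                gaussian_equivalent_power(m), abs=1e-4
            )


class TestTracePowerAt:
    def test_paraxial_limit(self, standard_model):
        assert trace_power_at(standard_model, 0.01) == pytest.approx(
            gaussian_equivalent_power(standard_model), abs=1e-3
        )

    def test_single_surface_closed_form(self):
        consts = OpticalConstants(n_aqueous=1.376 - 1e-9)  # posterior refraction off
        m = CornealModel(
            ConicSurface(7.7), ConicSurface(6.4, 0.0, 0.5), 0.5, constants=consts
        )
        assert trace_power_at(m, 0.01) == pytest.approx(0.376 / 0.0077, abs=1e-3)

    def test_agrees_with_meridional_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            m = physiologic_model(rng)
            h = rng.uniform(0.5, 3.0)
            assert trace_power_at(m, h) == pytest.approx(
                meridional_trace_power(m, h), abs=1e-9
            )

    def test_meridian_rotation_invariance(self, standard_model):
        p0 = trace_power_at(standard_model, 3.0, 0.0)
        for th in (45.0, 133.7, 290.0):
            assert trace_power_at(standard_model, 3.0, th) == pytest.approx(p0, abs=1e-9)

    def test_crossing_definition_paraxial_back_vertex(self, standard_model):
        # with the axial-crossing convention the paraxial limit is the back
        # vertex power P / (1 - (d/n) P1)
        p1 = 0.376 / 0.0077
        expected = gaussian_equivalent_power(standard_model) / (1 - 0.0005 / 1.376 * p1)
        assert trace_power_at(standard_model, 0.01, definition="crossing") == pytest.approx(
            expected, abs=1e-3
        )

    @pytest.mark.parametrize("h", [0.0, -1.0, 4.6])
    def test_invalid_height(self, standard_model, h):
        with pytest.raises(DomainError):
            trace_power_at(standard_model, h)


class TestPowerMap:
    def test_zero_offset_apex_equals_pupil(self, standard_model):
        grid = GridSpec(radial_step=0.25, meridians=16)
        a = build_power_map(standard_model, "apex", grid)
        p = build_power_map(standard_model, "pupil", grid)
        assert np.allclose(a.power, p.power, atol=0, rtol=0)

    def test_symmetric_model_meridian_independent(self, standard_model):
        pm = build_power_map(standard_model, "apex", GridSpec(radial_step=0.5, meridians=32))
        assert np.all(np.ptp(pm.power, axis=1) < 1e-9)

    def test_matches_single_trace(self, standard_model):
        grid = GridSpec(radial_step=0.05, meridians=16)
        pm = build_power_map(standard_model, "apex", grid)
        j, i = 40, 3  # r = 2.05 mm, theta = 67.5 deg
        direct = trace_power_at(standard_model, pm.r[j], pm.theta_deg[i])
        assert pm.power[j, i] == pytest.approx(direct, abs=1e-12)

    def test_grid_covers_aperture_and_counts(self, standard_model):
        grid = GridSpec(radial_step=0.05, meridians=16)
        pm = build_power_map(standard_model, "apex", grid)
        assert pm.r[-1] >= 4.0
        assert pm.power.shape == (len(grid.radii()), 16)

    def test_too_few_meridians_rejected(self, standard_model):
        with pytest.raises(DomainError):
            build_power_map(standard_model, "apex", GridSpec(meridians=4))


def _analytic_map(fn, step=0.01, meridians=32, rmax=4.0):
    grid = GridSpec(radial_step=step, meridians=meridians, max_radius=rmax)
    r = grid.radii()
    th = grid.thetas_deg()
    power = np.repeat(fn(r)[:, None], meridians, axis=1)
    return PowerMap(r=r, theta_deg=th, power=power, center_ref="apex",
                    center=(0.0, 0.0), radial_step=step)


class TestRingZoneAggregation:
    def test_uniform_map_identity(self):
        pm = _analytic_map(lambda r: np.full_like(r, 43.0))
        for d in (1.0, 3.0, 6.0, 8.0):
            assert tcrp_ring(pm, d) == pytest.approx(43.0, abs=1e-12)
            assert tcrp_zone(pm, d) == pytest.approx(43.0, abs=1e-12)

    def test_quadratic_map_closed_forms(self):
        pm = _analytic_map(lambda r: 40.0 + r**2)
        assert tcrp_ring(pm, 6.0) == pytest.approx(49.0, abs=1e-9)
        # area mean of 40 + r^2 over a disc of radius 3 is 40 + 9/2
        assert tcrp_zone(pm, 6.0) == pytest.approx(44.5, abs=1e-3)

    def test_ring_interpolates_between_nodes(self):
        pm = _analytic_map(lambda r: 40.0 + r**2, step=0.05)
        assert tcrp_ring(pm, 5.13) == pytest.approx(40.0 + 2.565**2, abs=1e-3)

    def test_zone_below_ring_for_increasing_profiles(self):
        pm = _analytic_map(lambda r: 40.0 + r**2)
        for d in (2.0, 4.0, 8.0):
            assert tcrp_zone(pm, d) < tcrp_ring(pm, d)

    def test_zone_above_ring_for_decreasing_profiles(self):
        pm = _analytic_map(lambda r: 45.0 - r**2)
        for d in (2.0, 4.0, 8.0):
            assert tcrp_zone(pm, d) > tcrp_ring(pm, d)

    def test_ring_value_stable_in_meridian_count(self, standard_model):
        vals = [
            tcrp_ring(build_power_map(standard_model, "apex", GridSpec(meridians=m)), 6.0)
            for m in (32, 64, 256)
        ]
        assert np.ptp(vals) < 1e-6

    def test_insufficient_coverage_raises(self):
        pm = _analytic_map(lambda r: 40.0 + r, step=0.1)
        power = pm.power.copy()
        power[:, : pm.power.shape[1] // 2] = np.nan  # half the meridians lost
        broken = PowerMap(pm.r, pm.theta_deg, power, "apex", (0.0, 0.0), 0.1)
        with pytest.raises(InsufficientCoverageError):
            tcrp_ring(broken, 6.0)
        with pytest.raises(InsufficientCoverageError):
            tcrp_zone(broken, 6.0)

    def test_zone_small_diameter_limits_to_central_power(self, standard_model):
        pm = build_power_map(standard_model, "apex", GridSpec(radial_step=0.02, meridians=16))
        assert tcrp_zone(pm, 0.08) == pytest.approx(
            gaussian_equivalent_power(standard_model), abs=5e-3
        )
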