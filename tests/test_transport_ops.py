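"""Unit and property tests for the photon-level transport operations."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from qsense import Medium, SlabGeometry, SphereSpec, mie_amplitudes, scattering_elements
from qsense.transport import (
    STATUS_ABSORBED,
    STATUS_ALIVE,
    STATUS_EVENT_CAP,
    STATUS_REFLECTED_UNDETECTED,
    STATUS_TRANSMITTED,
    DetectorConfig,
    StokesVector,
    check_termination,
    detect,
    launch_photon,
    propagate,
    rotate_qu,
    sample_step,
    scatter_update,
)


class FixedRng:
    """Deterministic stand-in yielding a prescribed uniform sequence."""

    def __init__(self, values):
        self._values = list(values)

    def random(self):
        return self._values.pop(0)


@pytest.fixture(scope="module")
def elements():
    return scattering_elements(
        mie_amplitudes(SphereSpec(radius_nm=150.0, wavelength_nm=632.8))
    )


GEOM = SlabGeometry(thickness_mm=5.0)


class TestLaunch:
    def test_horizontal_stokes_and_oblique_direction(self):
        ph = launch_photon(GEOM)
        np.testing.assert_array_equal(ph.stokes, [1.0, 1.0, 0.0, 0.0])
        assert ph.direction[2] == pytest.approx(math.cos(math.radians(45)))
        assert ph.direction[1] == 0.0  # incidence meridian is the x-z plane
        assert ph.weight == 1.0 and ph.n_events == 0 and ph.status == STATUS_ALIVE
        np.testing.assert_array_equal(ph.position, np.zeros(3))

    def test_launch_is_deterministic(self):
        a, b = launch_photon(GEOM), launch_photon(GEOM)
        np.testing.assert_array_equal(a.direction, b.direction)
        np.testing.assert_array_equal(a.stokes, b.stokes)

    def test_frame_is_orthonormal_and_right_handed(self):
        ph = launch_photon(GEOM)
        np.testing.assert_allclose(np.cross(ph.e_par, ph.e_perp), ph.direction,
                                   atol=1e-15)
        assert abs(np.linalg.norm(ph.direction) - 1) < 1e-12


class TestSampleStep:
    def test_unit_uniform_gives_zero_step(self):
        assert sample_step(0.0, 2.0, FixedRng([0.0])) == 0.0

    def test_zero_mu_t_fails(self):
        with pytest.raises(ValueError):
            sample_step(0.0, 0.0, FixedRng([0.5]))

    def test_exponential_mean(self):
        rng = np.random.default_rng(3)
        n = 200_000
        s = np.array([sample_step(0.5, 1.5, rng) for _ in range(n)])
        se = 0.5 / math.sqrt(n)
        assert abs(s.mean() - 0.5) < 3 * se

    def test_distribution_matches_exponential(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        s = np.array([sample_step(0.0, 2.0, rng) for _ in range(5000)])
        assert stats.kstest(s, "expon", args=(0, 0.5)).pvalue > 1e-3


class TestPropagate:
    def test_zero_step_is_identity(self):
        ph = launch_photon(GEOM)
        out = propagate(ph, 0.0)
        np.testing.assert_array_equal(out.position, ph.position)

    def test_depth_advance_along_z(self):
        ph = launch_photon(SlabGeometry(5.0, incidence_deg=0.0))
        out = propagate(ph, 2.0)
        assert out.position[2] == pytest.approx(2.0, abs=1e-15)

    @given(st.floats(0.0, 10.0), st.integers(0, 1000))
    def test_euclidean_step_length(self, s, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        ph = launch_photon(GEOM)
        ph.direction = v
        out = propagate(ph, s)
        assert np.linalg.norm(out.position - ph.position) == pytest.approx(
            s, abs=1e-12
        )


class TestScatterUpdate:
    def test_forward_scattering_is_a_mueller_no_op(self, elements):
        """theta = psi = 0: direction unchanged, Stokes scaled forward only."""
        ph = launch_photon(GEOM)
        out = scatter_update(ph, 0.0, 0.0, elements)
        np.testing.assert_allclose(out.direction, ph.direction, atol=1e-12)
        s11 = elements.s11[0]
        np.testing.assert_allclose(out.stokes, s11 * ph.stokes, rtol=1e-9)
        assert out.n_events == 1

    @given(st.floats(1e-3, np.pi - 1e-3), st.floats(0.0, 2 * np.pi,
                                                    exclude_max=True))
    def test_full_polarization_preserved(self, elements, theta, psi):
        """Pure Mueller-Jones chain: DOP stays 1 for every (theta, psi)."""
        ph = launch_photon(GEOM)
        out = scatter_update(ph, theta, psi, elements)
        i, q, u, v = out.stokes
        assert q * q + u * u + v * v == pytest.approx(i * i, rel=1e-9)
        assert abs(np.linalg.norm(out.direction) - 1) < 1e-12

    def test_scattering_angle_realized(self, elements):
        ph = launch_photon(GEOM)
        theta = 0.7
        out = scatter_update(ph, theta, 1.3, elements)
        assert float(ph.direction @ out.direction) == pytest.approx(
            math.cos(theta), abs=1e-12
        )

    def test_pole_crossing_has_no_nan(self, elements):
        """Exact backscatter through the pole uses the limiting convention."""
        ph = launch_photon(SlabGeometry(5.0, incidence_deg=0.0))
        out = scatter_update(ph, np.pi, 0.4, elements)
        assert np.all(np.isfinite(out.stokes))
        assert np.all(np.isfinite(out.direction))
        assert out.direction[2] == pytest.approx(-1.0, abs=1e-12)

    def test_dead_photon_rejected(self, elements):
        ph = launch_photon(GEOM)
        ph.status = STATUS_TRANSMITTED
        with pytest.raises(ValueError):
            scatter_update(ph, 0.3, 0.3, elements)


class TestMeridianRotation:
    @given(
        st.floats(-1.0, 1.0), st.floats(-1.0, 1.0), st.floats(-1.0, 1.0),
        st.floats(0.0, 2 * np.pi),
    )
    def test_rotation_invariants(self, q, u, v, angle):
        """Frame rotations leave I and V alone and preserve Q^2 + U^2."""
        s = np.array([2.0, q, u, v])
        out = rotate_qu(s, math.cos(angle), math.sin(angle))
        assert out[0] == s[0] and out[3] == s[3]
        assert out[1] ** 2 + out[2] ** 2 == pytest.approx(q * q + u * u,
                                                          abs=1e-12)


class TestTermination:
    def test_exit_classification(self):
        medium = Medium.from_mu_s(1.0, 0.5)
        ph = launch_photon(GEOM)
        ph.position[2] = GEOM.thickness_mm + 1e-9
        assert check_termination(ph, GEOM, medium).status == STATUS_TRANSMITTED
        ph2 = launch_photon(GEOM)
        ph2.position[2] = -1e-9
        assert (check_termination(ph2, GEOM, medium).status
                == STATUS_REFLECTED_UNDETECTED)

    def test_event_cap(self):
        medium = Medium.from_mu_s(1.0, 0.5)
        ph = launch_photon(GEOM)
        ph.n_events = 1001
        assert (check_termination(ph, GEOM, medium, event_cap=1000).status
                == STATUS_EVENT_CAP)
        ph.n_events = 1000
        assert (check_termination(ph, GEOM, medium, event_cap=1000).status
                == STATUS_ALIVE)

    def test_binary_absorption_draw(self):
        medium = Medium.from_mu_s(3.0, 0.5, mu_a=1.0)  # absorb prob 0.25
        ph = launch_photon(GEOM)
        ph.position[2] = 1.0
        hit = check_termination(ph, GEOM, medium, rng=FixedRng([0.2]))
        miss = check_termination(ph, GEOM, medium, rng=FixedRng([0.3]))
        assert hit.status == STATUS_ABSORBED and miss.status == STATUS_ALIVE

    def test_no_absorption_without_mu_a(self):
        medium = Medium.from_mu_s(3.0, 0.5)
        ph = launch_photon(GEOM)
        ph.position[2] = 1.0
        assert check_termination(ph, GEOM, medium).status == STATUS_ALIVE


class TestDetect:
    def _exited(self, direction):
        ph = launch_photon(GEOM)
        ph.position = np.array([0.0, 0.0, 0.0])
        ph.direction = np.asarray(direction, float)
        ph.direction /= np.linalg.norm(ph.direction)
        from qsense.transport import meridian_frame

        ph.e_par, ph.e_perp = meridian_frame(ph.direction,
                                             fallback=(ph.e_par, ph.e_perp))
        return ph

    def test_axial_exit_at_entry_point_accepted(self):
        rec = detect(self._exited([0.0, 0.0, -1.0]), DetectorConfig())
        assert rec is not None
        assert rec.weight == 1.0

    def test_exit_beyond_collection_radius_rejected(self):
        ph = self._exited([0.0, 0.0, -1.0])
        ph.position = np.array([2.5, 0.0, 0.0])
        assert detect(ph, DetectorConfig(collect_radius_mm=2.0)) is None

    def test_exit_outside_acceptance_cone_rejected(self):
        ph = self._exited([0.9, 0.0, -0.436])  # ~64 deg from the normal
        assert detect(ph, DetectorConfig(accept_half_angle_deg=30.0)) is None
        assert detect(ph, DetectorConfig(accept_half_angle_deg=90.0)) is not None

    def test_detection_preserves_polarization_magnitude(self):
        ph = self._exited([0.3, 0.2, -0.93])
        ph.stokes = np.array([1.0, 0.3, 0.4, math.sqrt(1 - 0.25)])
        rec = detect(ph, DetectorConfig())
        i, q, u, v = rec.stokes
        assert q * q + u * u + v * v == pytest.approx(
            0.3**2 + 0.4**2 + (1 - 0.25), rel=1e-12
        )
        assert i == pytest.approx(1.0, rel=1e-15)

    def test_photon_below_surface_rejected(self):
        ph = launch_photon(GEOM)
        ph.position[2] = 1.0
        with pytest.raises(ValueError):
            detect(ph, DetectorConfig())


def test_stokes_vector_dop():
    assert StokesVector(1.0, 1.0, 0.0, 0.0).dop == pytest.approx(1.0)
    assert StokesVector(2.0, 0.6, 0.8, 0.0).dop == pytest.approx(0.5)
    with pytest.raises(ValueError):
        StokesVector(-1.0)
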