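"""Unit and property tests for the Mie optics module."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from qsense.mie import (
    AmplitudeTable,
    MieConvergenceError,
    ScatteringElementTable,
    SphereSpec,
    default_theta_grid,
    elements_at,
    mie_amplitudes,
    mie_efficiencies,
    phase_function_value,
    scattering_elements,
)


@pytest.fixture(scope="module")
def soy_table():
    """200 nm soybean-oil droplet in water at 632.8 nm."""
    spec = SphereSpec(radius_nm=200.0, wavelength_nm=632.8)
    return scattering_elements(mie_amplitudes(spec))


class TestSphereSpec:
    def test_size_parameter_formula(self):
        spec = SphereSpec(radius_nm=100.0, wavelength_nm=632.8, n_medium=1.33)
        assert spec.x == pytest.approx(2 * np.pi * 100.0 * 1.33 / 632.8, rel=1e-14)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"radius_nm": -1.0, "wavelength_nm": 632.8},
            {"radius_nm": 100.0, "wavelength_nm": 0.0},
            {"radius_nm": 100.0, "wavelength_nm": 632.8, "n_medium": 0.9},
            {"radius_nm": 1e9, "wavelength_nm": 632.8},  # x beyond safe range
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SphereSpec(**kwargs)

    def test_series_truncation_failure_is_explicit(self):
        spec = SphereSpec(radius_nm=5000.0, wavelength_nm=632.8)
        with pytest.raises(MieConvergenceError):
            mie_amplitudes(spec, max_terms=10)


class TestAmplitudes:
    @pytest.mark.parametrize("radius", [20.0, 100.0, 200.0, 700.0])
    def test_forward_amplitude_equality(self, radius):
        """S1(0) = S2(0): forward scattering cannot distinguish polarizations."""
        amps = mie_amplitudes(SphereSpec(radius_nm=radius, wavelength_nm=632.8))
        assert amps.S1[0] == pytest.approx(amps.S2[0], rel=1e-13)

    def test_rayleigh_polarization_limit(self):
        """x << 1: degree of linear polarization is sin^2/(1+cos^2) (dipole)."""
        r = 0.01 * 632.8 / (2 * np.pi * 1.33)
        spec = SphereSpec(radius_nm=r, wavelength_nm=632.8,
                          n_particle=1.1 * 1.33)
        table = scattering_elements(mie_amplitudes(spec))
        th = table.theta
        expected = np.sin(th) ** 2 / (1 + np.cos(th) ** 2)
        assert np.max(np.abs(-table.s12 / table.s11 - expected)) < 1e-3
        assert abs(table.g) < 1e-3  # symmetric dipole pattern

    def test_grid_validation(self):
        spec = SphereSpec(radius_nm=100.0, wavelength_nm=632.8)
        with pytest.raises(ValueError):
            mie_amplitudes(spec, np.array([-0.1, 0.5]))
        with pytest.raises(ValueError):
            AmplitudeTable(theta=np.array([0.5, 0.2]),
                           S1=np.zeros(2, complex), S2=np.zeros(2, complex))


class TestScatteringElements:
    def test_forward_row_has_no_linear_or_circular_coupling(self, soy_table):
        assert abs(soy_table.s12[0]) < 1e-12 * soy_table.s11[0]
        assert abs(soy_table.s34[0]) < 1e-12 * soy_table.s11[0]

    def test_purity_identity_pointwise(self, soy_table):
        lhs = soy_table.s11**2
        rhs = soy_table.s12**2 + soy_table.s33**2 + soy_table.s34**2
        assert np.max(np.abs(lhs - rhs) / lhs) < 1e-9

    def test_purity_survives_interpolation_between_nodes(self, soy_table):
        mid = 0.5 * (soy_table.theta[:-1] + soy_table.theta[1:])
        s11, s12, s33, s34 = elements_at(soy_table, mid)
        rel = np.abs(s11**2 - (s12**2 + s33**2 + s34**2)) / s11**2
        assert np.max(rel) < 1e-9

    def test_anisotropy_grid_converged(self):
        """Doubling the theta grid moves the quadrature g by < 1e-6."""
        spec = SphereSpec(radius_nm=700.0, wavelength_nm=632.8)
        g1 = scattering_elements(mie_amplitudes(spec, default_theta_grid(1000))).g
        g2 = scattering_elements(mie_amplitudes(spec, default_theta_grid(2000))).g
        assert abs(g1 - g2) < 1e-6

    @pytest.mark.parametrize("radius", [50.0, 200.0, 700.0])
    def test_anisotropy_matches_coefficient_sum(self, radius):
        """Quadrature g equals the closed-form partial-wave asymmetry sum."""
        spec = SphereSpec(radius_nm=radius, wavelength_nm=632.8)
        g_quad = scattering_elements(mie_amplitudes(spec)).g
        _, _, g_closed = mie_efficiencies(spec)
        assert g_quad == pytest.approx(g_closed, abs=1e-8)

    def test_degenerate_scatterer_rejected(self):
        th = default_theta_grid(16)
        amps = AmplitudeTable(theta=th, S1=np.zeros(16, complex),
                              S2=np.zeros(16, complex))
        with pytest.raises(ValueError, match="degenerate"):
            scattering_elements(amps)

    def test_phase_function_normalization(self, soy_table):
        """norm makes the unpolarized phase function integrate to 1."""
        from scipy.integrate import simpson

        th = soy_table.theta
        total = 2 * np.pi * simpson(soy_table.s11 / soy_table.norm * np.sin(th),
                                    x=th)
        assert total == pytest.approx(1.0, rel=1e-8)

    def test_export_roundtrip(self, soy_table, tmp_path):
        import pandas as pd

        path = tmp_path / "elements.tsv"
        soy_table.to_csv(path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == ["theta", "s11", "s12", "s33", "s34"]
        np.testing.assert_allclose(back["s11"], soy_table.s11, rtol=1e-12)


class TestPhaseFunction:
    def test_unpolarized_input_gives_s11(self, soy_table):
        th = 1.1
        s11 = elements_at(soy_table, th)[0]
        for psi in (0.0, 1.0, 3.0, 6.0):
            assert phase_function_value(soy_table, th, psi, (1, 0, 0, 0)) == (
                pytest.approx(float(s11), rel=1e-12)
            )

    def test_azimuthal_integral_is_2pi_s11(self, soy_table):
        th = 2.0
        psi = np.linspace(0, 2 * np.pi, 4001, endpoint=False)
        vals = phase_function_value(soy_table, th, psi, (1.0, 0.6, -0.5, 0.2))
        s11 = elements_at(soy_table, th)[0]
        assert np.mean(vals) == pytest.approx(float(s11), rel=1e-6)

    def test_horizontal_polarization_extremes(self, soy_table):
        """psi = 0 vs pi/2 for (1,1,0,0) bracket s11 +/- s12."""
        th = 1.7
        s11, s12, _, _ = (float(v) for v in elements_at(soy_table, th))
        assert phase_function_value(soy_table, th, 0.0, (1, 1, 0, 0)) == (
            pytest.approx(s11 + s12, rel=1e-12)
        )
        assert phase_function_value(soy_table, th, np.pi / 2, (1, 1, 0, 0)) == (
            pytest.approx(s11 - s12, rel=1e-12)
        )

    @given(
        theta=st.floats(0.0, np.pi),
        psi=st.floats(0.0, 2 * np.pi, exclude_max=True),
        q=st.floats(-1.0, 1.0),
        u=st.floats(-1.0, 1.0),
    )
    def test_never_negative_for_physical_stokes(self, soy_table, theta, psi, q, u):
        lin = np.hypot(q, u)
        if lin > 1.0:  # keep the Stokes vector physical
            q, u = q / lin, u / lin
        assert phase_function_value(soy_table, theta, psi, (1.0, q, u, 0.0)) >= 0.0

    def test_out_of_range_angles_rejected(self, soy_table):
        with pytest.raises(ValueError):
            phase_function_value(soy_table, 3.5, 0.0, (1, 0, 0, 0))
        with pytest.raises(ValueError):
            phase_function_value(soy_table, 1.0, -0.1, (1, 0, 0, 0))
        with pytest.raises(ValueError):
            phase_function_value(soy_table, 1.0, 2 * np.pi, (1, 0, 0, 0))


def test_element_table_invariant_validation():
    th = default_theta_grid(8)
    ones = np.ones(8)
    with pytest.raises(ValueError):
        ScatteringElementTable(theta=th, s11=ones, s12=1.5 * ones,
                               s33=ones, s34=ones, g=0.0, norm=1.0)
    with pytest.raises(ValueError):
        ScatteringElementTable(theta=th, s11=ones, s12=0 * ones,
                               s33=ones, s34=0 * ones, g=1.5, norm=1.0)
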