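"""Mie amplitudes and scattering-matrix elements for homogeneous spheres.

Single scattering by a sphere is described by two complex amplitude
functions S1(theta), S2(theta).  For Stokes-vector transport the relevant
real quantities are the four scattering elements

    s11 = (|S2|^2 + |S1|^2) / 2        s12 = (|S2|^2 - |S1|^2) / 2
    s33 = Re(S2 S1*)                   s34 = Im(S2 S1*)

which form the block-diagonal single-sphere Mueller matrix.  Because they
derive from a single Jones pair, they satisfy the purity identity
``s11**2 == s12**2 + s33**2 + s34**2`` pointwise; the transport core relies
on this to keep individual photons fully polarized.

The series is summed with the standard logarithmic-derivative downward
recurrence for the internal field and upward Riccati-Bessel recurrences for
the external field, truncated at the Wiscombe term count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson

__all__ = [
    "SphereSpec",
    "AmplitudeTable",
    "ScatteringElementTable",
    "MieConvergenceError",
    "default_theta_grid",
    "mie_amplitudes",
    "mie_coefficients",
    "mie_efficiencies",
    "scattering_elements",
    "phase_function_value",
    "elements_at",
]

#: default angular resolution of precomputed element tables
N_THETA_DEFAULT = 1000

#: largest size parameter the series code is allowed to attempt
X_MAX = 1.0e4


class MieConvergenceError(RuntimeError):
    """Raised when the Mie series cannot be summed to convergence."""


@dataclass(frozen=True)
class SphereSpec:
    """One spherical scatterer embedded in a host medium.

    Parameters
    ----------
    radius_nm : float
        Sphere radius in nanometres.
    wavelength_nm : float
        Vacuum wavelength in nanometres.
    n_particle : complex
        Refractive index of the sphere material.
    n_medium : float
        Real refractive index of the host (water: 1.33).
    """

    radius_nm: float
    wavelength_nm: float
    n_particle: complex = 1.46
    n_medium: float = 1.33

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("radius must be positive")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.n_medium < 1.0:
            raise ValueError("host refractive index must be >= 1")
        if self.x <= 0 or self.x > X_MAX:
            raise ValueError(f"size parameter x={self.x:.3g} outside (0, {X_MAX:g}]")

    @property
    def x(self) -> float:
        """Size parameter 2*pi*r*n_medium/lambda (radius in in-medium wavelengths)."""
        return 2.0 * np.pi * self.radius_nm * self.n_medium / self.wavelength_nm

    @property
    def m_relative(self) -> complex:
        """Refractive index of the sphere relative to the host."""
        return complex(self.n_particle) / self.n_medium


@dataclass(frozen=True)
class AmplitudeTable:
    """Complex scattering amplitudes S1, S2 on an angular grid."""

    theta: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    spec: SphereSpec | None = None

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.ndim != 1 or theta.size < 2:
            raise ValueError("theta grid must be a 1-D array with >= 2 angles")
        if np.any(np.diff(theta) <= 0):
            raise ValueError("theta grid must be strictly increasing")
        if theta[0] < 0 or theta[-1] > np.pi + 1e-12:
            raise ValueError("theta grid must lie in [0, pi]")
        if not (np.all(np.isfinite(self.S1)) and np.all(np.isfinite(self.S2))):
            raise ValueError("non-finite amplitude encountered")


def default_theta_grid(n: int = N_THETA_DEFAULT) -> np.ndarray:
    """Uniform angular grid on [0, pi] including both endpoints."""
    return np.linspace(0.0, np.pi, n)


def _wiscombe_nmax(x: float) -> int:
    return int(np.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2.0))


def mie_coefficients(spec: SphereSpec, max_terms: int = 20000):
    """Partial-wave coefficients (a_n, b_n) for n = 1..nmax.

    Uses the downward continued-fraction recurrence for the logarithmic
    derivative D_n(mx) (stable for absorbing spheres) and upward recurrences
    for the Riccati-Bessel functions psi_n(x), chi_n(x).
    """
    x = spec.x
    m = spec.m_relative
    nmax = _wiscombe_nmax(x)
    if nmax > max_terms:
        raise MieConvergenceError(
            f"series needs {nmax} terms for x={x:.3g}, above max_terms={max_terms}"
        )

    mx = m * x
    nstart = nmax + 16 + int(abs(mx) ** 0.5)
    D = np.zeros(nstart + 1, dtype=complex)
    for n in range(nstart, 0, -1):
        rn = n / mx
        D[n - 1] = rn - 1.0 / (D[n] + rn)

    # Riccati-Bessel psi_n = x j_n(x), chi_n = -x y_n(x); index k holds order k-1.
    psi = np.empty(nmax + 2)
    chi = np.empty(nmax + 2)
    psi[0], psi[1] = np.cos(x), np.sin(x)
    chi[0], chi[1] = -np.sin(x), np.cos(x)
    for k in range(2, nmax + 2):
        f = (2 * (k - 1) - 1) / x
        psi[k] = f * psi[k - 1] - psi[k - 2]
        chi[k] = f * chi[k - 1] - chi[k - 2]
    xi = psi - 1j * chi

    n = np.arange(1, nmax + 1)
    Dn = D[1 : nmax + 1]
    psi_n, psi_nm1 = psi[2 : nmax + 2], psi[1 : nmax + 1]
    xi_n, xi_nm1 = xi[2 : nmax + 2], xi[1 : nmax + 1]

    ta = Dn / m + n / x
    tb = Dn * m + n / x
    an = (ta * psi_n - psi_nm1) / (ta * xi_n - xi_nm1)
    bn = (tb * psi_n - psi_nm1) / (tb * xi_n - xi_nm1)
    if not (np.all(np.isfinite(an)) and np.all(np.isfinite(bn))):
        raise MieConvergenceError(f"non-finite Mie coefficient for x={x:.3g}")
    return an, bn


def mie_amplitudes(
    spec: SphereSpec,
    theta_grid: np.ndarray | None = None,
    max_terms: int = 20000,
) -> AmplitudeTable:
    """Sum the Mie series for S1(theta), S2(theta) on a grid of angles."""
    theta = default_theta_grid() if theta_grid is None else np.asarray(theta_grid, float)
    if np.any(theta < 0) or np.any(theta > np.pi + 1e-12):
        raise ValueError("scattering angles must lie in [0, pi]")
    an, bn = mie_coefficients(spec, max_terms=max_terms)
    nmax = an.size

    mu = np.cos(theta)
    S1 = np.zeros_like(mu, dtype=complex)
    S2 = np.zeros_like(mu, dtype=complex)
    pi_nm1 = np.zeros_like(mu)  # pi_0
    pi_n = np.ones_like(mu)     # pi_1
    for n in range(1, nmax + 1):
        tau_n = n * mu * pi_n - (n + 1) * pi_nm1
        fac = (2 * n + 1) / (n * (n + 1))
        S1 += fac * (an[n - 1] * pi_n + bn[n - 1] * tau_n)
        S2 += fac * (an[n - 1] * tau_n + bn[n - 1] * pi_n)
        pi_np1 = ((2 * n + 1) * mu * pi_n - (n + 1) * pi_nm1) / n
        pi_nm1, pi_n = pi_n, pi_np1
    return AmplitudeTable(theta=theta, S1=S1, S2=S2, spec=spec)


def mie_efficiencies(spec: SphereSpec, max_terms: int = 20000):
    """Closed-form efficiencies (Qext, Qsca, g) from the partial waves.

    The asymmetry parameter here comes from the standard coefficient sums,
    independent of any angular grid; :func:`scattering_elements` computes g
    by quadrature instead, and the two agree to grid-quadrature precision.
    """
    an, bn = mie_coefficients(spec, max_terms=max_terms)
    x = spec.x
    n = np.arange(1, an.size + 1)
    qext = (2.0 / x**2) * np.sum((2 * n + 1) * (an + bn).real)
    qsca = (2.0 / x**2) * np.sum((2 * n + 1) * (np.abs(an) ** 2 + np.abs(bn) ** 2))
    t1 = np.sum(
        (n[:-1] * (n[:-1] + 2) / (n[:-1] + 1))
        * (an[:-1] * np.conj(an[1:]) + bn[:-1] * np.conj(bn[1:])).real
    )
    t2 = np.sum(((2 * n + 1) / (n * (n + 1))) * (an * np.conj(bn)).real)
    g = (4.0 / (x**2 * qsca)) * (t1 + t2)
    return qext, qsca, g


@dataclass(frozen=True)
class ScatteringElementTable:
    """Sphere Mueller-matrix elements on an angular grid, plus derived scalars.

    ``g`` is the anisotropy (mean cosine of the scattering angle for
    unpolarized light) and ``norm`` the constant making s11/norm a unit
    phase function over the sphere.  When built from an
    :class:`AmplitudeTable` the source amplitudes are retained so that
    interpolated elements stay an exact Jones pair (purity preserved
    between grid nodes).
    """

    theta: np.ndarray
    s11: np.ndarray
    s12: np.ndarray
    s33: np.ndarray
    s34: np.ndarray
    g: float
    norm: float
    amplitudes: AmplitudeTable | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.any(self.s11 < 0):
            raise ValueError("s11 must be non-negative")
        if np.any(np.abs(self.s12) > self.s11 * (1 + 1e-12) + 1e-300):
            raise ValueError("|s12| must not exceed s11")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy must lie in (-1, 1)")

    @property
    def envelope(self) -> float:
        """Dominating constant for rejection sampling: 1.01 * max(s11 + |s12|)."""
        return 1.01 * float(np.max(self.s11 + np.abs(self.s12)))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "theta": self.theta,
                "s11": self.s11,
                "s12": self.s12,
                "s33": self.s33,
                "s34": self.s34,
            }
        )

    def to_csv(self, path, sep: str = "\t") -> None:
        """Export as plain text for inspection and cross-tool comparison."""
        self.to_dataframe().to_csv(path, sep=sep, index=False)


def scattering_elements(amps: AmplitudeTable) -> ScatteringElementTable:
    """Reduce complex amplitudes to the four real scattering elements.

    Also computes, by Simpson quadrature on the table grid,

    * ``g``    = int s11 cos(theta) sin(theta) dtheta / int s11 sin(theta) dtheta
    * ``norm`` = 2*pi * int s11 sin(theta) dtheta
    """
    S1, S2, theta = amps.S1, amps.S2, amps.theta
    a1 = np.abs(S1) ** 2
    a2 = np.abs(S2) ** 2
    s11 = 0.5 * (a2 + a1)
    s12 = 0.5 * (a2 - a1)
    w = S2 * np.conj(S1)
    s33 = w.real
    s34 = w.imag
    if np.all(s11 == 0):
        raise ValueError("degenerate scatterer: s11 vanishes everywhere")

    sint = np.sin(theta)
    denom = simpson(s11 * sint, x=theta)
    g = float(simpson(s11 * np.cos(theta) * sint, x=theta) / denom)
    norm = float(2.0 * np.pi * denom)
    return ScatteringElementTable(
        theta=theta, s11=s11, s12=s12, s33=s33, s34=s34, g=g, norm=norm,
        amplitudes=amps,
    )


def elements_at(table: ScatteringElementTable, theta):
    """Interpolate (s11, s12, s33, s34) at arbitrary angles in [0, pi].

    When the table carries its source amplitudes, S1 and S2 are
    interpolated linearly and the elements recomputed from the interpolated
    Jones pair, so the purity identity holds exactly between nodes.
    Otherwise the elements themselves are interpolated linearly.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > np.pi + 1e-12):
        raise ValueError("scattering angle outside [0, pi]")
    grid = table.theta
    if table.amplitudes is not None:
        S1 = np.interp(theta, grid, table.amplitudes.S1.real) + 1j * np.interp(
            theta, grid, table.amplitudes.S1.imag
        )
        S2 = np.interp(theta, grid, table.amplitudes.S2.real) + 1j * np.interp(
            theta, grid, table.amplitudes.S2.imag
        )
        a1 = np.abs(S1) ** 2
        a2 = np.abs(S2) ** 2
        w = S2 * np.conj(S1)
        return 0.5 * (a2 + a1), 0.5 * (a2 - a1), w.real, w.imag
    return (
        np.interp(theta, grid, table.s11),
        np.interp(theta, grid, table.s12),
        np.interp(theta, grid, table.s33),
        np.interp(theta, grid, table.s34),
    )


def phase_function_value(table: ScatteringElementTable, theta, psi, stokes):
    """Bivariate single-scattering density P(theta, psi) for a given Stokes state.

    P(theta, psi) = s11(theta) * I + s12(theta) * (Q cos 2psi + U sin 2psi).
    Non-negative for any physical Stokes vector because |s12| <= s11 and
    sqrt(Q^2 + U^2) <= I.
    """
    theta = np.asarray(theta, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if np.any(psi < 0) or np.any(psi >= 2 * np.pi):
        raise ValueError("azimuth psi outside [0, 2*pi)")
    s11, s12, _, _ = elements_at(table, theta)
    I, Q, U, _ = _stokes_components(stokes)
    return s11 * I + s12 * (Q * np.cos(2 * psi) + U * np.sin(2 * psi))


def _stokes_components(stokes):
    """Accept a StokesVector-like object or a length-4 sequence."""
    if hasattr(stokes, "I"):
        return float(stokes.I), float(stokes.Q), float(stokes.U), float(stokes.V)
    arr = np.asarray(stokes, dtype=float)
    if arr.shape != (4,):
        raise ValueError("Stokes vector must have four components")
    return float(arr[0]), float(arr[1]), float(arr[2]), float(arr[3])
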