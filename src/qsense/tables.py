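"""Precomputed per-size Mie tables for the transport core.

The Monte Carlo redraws the scatterer size at every event, so the kernel
needs O(1) access to the angular amplitudes of each radius on the
distribution grid.  Tables store Re/Im of S1 and S2 on a shared uniform
theta grid; scattering elements are reconstructed from the interpolated
Jones pair at sample time, which keeps every single-photon Mueller matrix
exactly pure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mie import (
    N_THETA_DEFAULT,
    ScatteringElementTable,
    SphereSpec,
    default_theta_grid,
    mie_amplitudes,
    mie_efficiencies,
    scattering_elements,
)

__all__ = ["MieTableSet"]

_CACHE: dict = {}


@dataclass(frozen=True)
class MieTableSet:
    """Angular amplitude tables for every radius of a size grid."""

    radii_nm: np.ndarray        # (n_r,)
    theta: np.ndarray           # (n_t,) uniform on [0, pi]
    reS1: np.ndarray            # (n_r, n_t)
    imS1: np.ndarray
    reS2: np.ndarray
    imS2: np.ndarray
    envelope: np.ndarray        # (n_r,) 1.01 * max(s11 + |s12|)
    g_per_size: np.ndarray      # (n_r,) anisotropy by quadrature
    norm_per_size: np.ndarray   # (n_r,) phase-function normalization
    csca_rel: np.ndarray        # (n_r,) relative scattering cross sections
    wavelength_nm: float
    n_particle: complex
    n_medium: float

    @classmethod
    def build(
        cls,
        radii_nm,
        wavelength_nm: float = 632.8,
        n_particle: complex = 1.46,
        n_medium: float = 1.33,
        n_theta: int = N_THETA_DEFAULT,
    ) -> "MieTableSet":
        radii = np.atleast_1d(np.asarray(radii_nm, dtype=float))
        key = (radii.tobytes(), wavelength_nm, complex(n_particle), n_medium, n_theta)
        if key in _CACHE:
            return _CACHE[key]

        theta = default_theta_grid(n_theta)
        n_r = radii.size
        reS1 = np.empty((n_r, n_theta))
        imS1 = np.empty((n_r, n_theta))
        reS2 = np.empty((n_r, n_theta))
        imS2 = np.empty((n_r, n_theta))
        env = np.empty(n_r)
        g = np.empty(n_r)
        norm = np.empty(n_r)
        csca = np.empty(n_r)
        for i, r in enumerate(radii):
            spec = SphereSpec(radius_nm=r, wavelength_nm=wavelength_nm,
                              n_particle=n_particle, n_medium=n_medium)
            amps = mie_amplitudes(spec, theta)
            elems = scattering_elements(amps)
            reS1[i], imS1[i] = amps.S1.real, amps.S1.imag
            reS2[i], imS2[i] = amps.S2.real, amps.S2.imag
            env[i] = elems.envelope
            g[i] = elems.g
            norm[i] = elems.norm
            _, qsca, _ = mie_efficiencies(spec)
            csca[i] = qsca * np.pi * r**2  # nm^2; only ratios are used
        out = cls(
            radii_nm=radii, theta=theta, reS1=reS1, imS1=imS1, reS2=reS2,
            imS2=imS2, envelope=env, g_per_size=g, norm_per_size=norm,
            csca_rel=csca / csca.max(), wavelength_nm=wavelength_nm,
            n_particle=complex(n_particle), n_medium=n_medium,
        )
        _CACHE[key] = out
        return out

    @classmethod
    def for_medium(cls, medium, n_theta: int = N_THETA_DEFAULT) -> "MieTableSet":
        return cls.build(
            medium.distribution.radii_nm,
            wavelength_nm=medium.wavelength_nm,
            n_particle=medium.n_particle,
            n_medium=medium.n_medium,
            n_theta=n_theta,
        )

    def index_of(self, radius_nm: float) -> int:
        i = int(np.argmin(np.abs(self.radii_nm - radius_nm)))
        if abs(self.radii_nm[i] - radius_nm) > 1e-9:
            raise KeyError(f"radius {radius_nm} nm not on the table grid")
        return i

    def element_table(self, radius_nm: float) -> ScatteringElementTable:
        """Full element table for one grid radius (amplitudes attached)."""
        i = self.index_of(radius_nm)
        spec = SphereSpec(radius_nm=float(self.radii_nm[i]),
                          wavelength_nm=self.wavelength_nm,
                          n_particle=self.n_particle, n_medium=self.n_medium)
        amps = mie_amplitudes(spec, self.theta)
        return scattering_elements(amps)

    def sampling_weights(self, distribution, weighting: str = "number") -> np.ndarray:
        """Per-event size-draw weights for a distribution on this radius grid.

        "number" uses the distribution weights as-is; "cross_section"
        re-weights by each size's scattering cross section (larger droplets
        intercept more light per particle).
        """
        if not np.array_equal(distribution.radii_nm, self.radii_nm):
            raise ValueError("distribution radii do not match the table grid")
        if weighting == "number":
            w = distribution.weights.copy()
        elif weighting == "cross_section":
            w = distribution.weights * self.csca_rel
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        return w / w.sum()
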