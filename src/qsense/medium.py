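"""Optical media: particle-size distributions and bulk coefficients.

A turbid slab is summarized by its absorption coefficient mu_a, scattering
coefficient mu_s (both mm^-1), anisotropy g and the reduced scattering
coefficient mu_s' = (1 - g) * mu_s.  Intralipid-style phantoms are
polydisperse: a photon meets a scatterer of a different random size at
every event, drawn from a fixed size distribution, while the step length
is always governed by the single bulk mu_s of the suspension.

Sizes are quoted as radii in nanometres throughout.  The default
polydisperse population spans radii 20-700 nm with an exponentially
decaying number weighting (decay length 80 nm), a discretized stand-in
for the small-droplet-dominated lipid-emulsion distributions reported in
the phantom literature; it is fully overridable from a two-column
(radius_nm, weight) text file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SizeDistribution",
    "Medium",
    "reduced_scattering",
    "il_optical_properties",
    "sample_radius",
    "STUDY_MUS_PRIME_GRID",
]

#: reduced scattering coefficients (mm^-1) of the five study phantoms
STUDY_MUS_PRIME_GRID = (0.5, 1.0, 1.5, 2.0, 3.0)

#: polydisperse support bounds, radii in nm
R_MIN_NM = 20.0
R_MAX_NM = 700.0

#: radius of the monodisperse comparison mode, nm
R_MONO_NM = 200.0


@dataclass(frozen=True)
class SizeDistribution:
    """Discrete particle-size distribution (radii in nm, weights sum to 1)."""

    radii_nm: np.ndarray
    weights: np.ndarray
    mode: str = "polydisperse"  # "polydisperse" | "monodisperse"

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii_nm, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "radii_nm", radii)
        if radii.ndim != 1 or radii.size == 0:
            raise ValueError("radii grid must be a non-empty 1-D array")
        if np.any(np.diff(radii) <= 0):
            raise ValueError("radii grid must be strictly increasing")
        if np.any(radii <= 0):
            raise ValueError("radii must be positive")
        if weights.shape != radii.shape or np.any(weights < 0):
            raise ValueError("weights must be non-negative, one per radius")
        total = weights.sum()
        if total <= 0:
            raise ValueError("weights must not all vanish")
        object.__setattr__(self, "weights", weights / total)
        if self.mode == "monodisperse":
            if radii.size != 1:
                raise ValueError("monodisperse distribution must hold exactly one radius")
        elif self.mode != "polydisperse":
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def monodisperse(cls, radius_nm: float = R_MONO_NM) -> "SizeDistribution":
        return cls(np.array([radius_nm]), np.array([1.0]), mode="monodisperse")

    @classmethod
    def intralipid(
        cls,
        r_min_nm: float = R_MIN_NM,
        r_max_nm: float = R_MAX_NM,
        step_nm: float = 20.0,
        decay_nm: float = 80.0,
    ) -> "SizeDistribution":
        """Default polydisperse population: exponential number weighting.

        p(r) proportional to exp(-(r - r_min)/decay) on [r_min, r_max],
        discretized on a uniform radius grid.
        """
        radii = np.arange(r_min_nm, r_max_nm + 0.5 * step_nm, step_nm)
        weights = np.exp(-(radii - r_min_nm) / decay_nm)
        return cls(radii, weights, mode="polydisperse")

    @classmethod
    def from_file(cls, path) -> "SizeDistribution":
        """Load a two-column (radius_nm, weight) text table."""
        data = np.loadtxt(path, ndmin=2)
        if data.shape[1] != 2:
            raise ValueError("distribution file must have two columns: radius_nm weight")
        order = np.argsort(data[:, 0])
        radii, weights = data[order, 0], data[order, 1]
        mode = "monodisperse" if radii.size == 1 else "polydisperse"
        return cls(radii, weights, mode=mode)

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.weights)


def sample_radius(distribution: SizeDistribution, rng) -> float:
    """Draw one particle radius (nm) with the distribution's weights.

    Consumes exactly one uniform variate from ``rng`` per call (also in
    the monodisperse case, to keep random streams aligned across modes).
    """
    u = rng.random()
    idx = int(np.searchsorted(distribution.cdf, u))
    idx = min(idx, distribution.radii_nm.size - 1)
    return float(distribution.radii_nm[idx])


def reduced_scattering(mu_s: float, g: float) -> float:
    """Reduced scattering coefficient mu_s' = (1 - g) * mu_s (mm^-1).

    Folds the forward-peakedness of single scattering into an equivalent
    isotropic-scattering rate.
    """
    if mu_s <= 0:
        raise ValueError("mu_s must be positive")
    if not -1.0 < g < 1.0:
        raise ValueError("anisotropy must lie in (-1, 1)")
    return (1.0 - g) * mu_s


@dataclass(frozen=True)
class Medium:
    """Bulk optical description of one slab phantom.

    ``mu_s_prime`` is always (1 - g) * mu_s; construct via
    :meth:`from_mus_prime`, :meth:`from_mu_s` or
    :func:`il_optical_properties` to keep the triple consistent.
    """

    mu_a: float
    mu_s: float
    g: float
    mu_s_prime: float
    distribution: SizeDistribution = field(default_factory=SizeDistribution.intralipid)
    n_medium: float = 1.33
    n_particle: complex = 1.46
    wavelength_nm: float = 632.8

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError("mu_a must be non-negative")
        if self.mu_s < 0:
            raise ValueError("mu_s must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy must lie in (-1, 1)")
        expected = (1.0 - self.g) * self.mu_s
        if abs(self.mu_s_prime - expected) > 1e-12 * max(1.0, expected):
            raise ValueError("mu_s_prime must equal (1 - g) * mu_s")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s (mm^-1)."""
        return self.mu_a + self.mu_s

    @classmethod
    def from_mu_s(cls, mu_s: float, g: float, mu_a: float = 0.0, **kwargs) -> "Medium":
        return cls(mu_a=mu_a, mu_s=mu_s, g=g,
                   mu_s_prime=reduced_scattering(mu_s, g), **kwargs)

    @classmethod
    def from_mus_prime(
        cls,
        mus_prime: float,
        distribution: SizeDistribution | None = None,
        mu_a: float = 0.0,
        weighting: str = "number",
        n_medium: float = 1.33,
        n_particle: complex = 1.46,
        wavelength_nm: float = 632.8,
    ) -> "Medium":
        """Medium with a target mu_s', self-consistent with its size distribution.

        The anisotropy is the sampling-weighted mean of the per-size Mie
        anisotropies -- exactly the mean single-scattering cosine the
        transport realizes when it redraws the particle size per event --
        and mu_s = mus_prime / (1 - g).
        """
        from .tables import MieTableSet  # deferred: avoids import cycle

        if mus_prime <= 0:
            raise ValueError("mus_prime must be positive")
        dist = distribution if distribution is not None else SizeDistribution.intralipid()
        tables = MieTableSet.build(
            dist.radii_nm, wavelength_nm=wavelength_nm,
            n_particle=n_particle, n_medium=n_medium,
        )
        w = tables.sampling_weights(dist, weighting=weighting)
        dist = replace(dist, weights=w)
        g_eff = float(np.sum(dist.weights * tables.g_per_size))
        mu_s = mus_prime / (1.0 - g_eff)
        return cls(
            mu_a=mu_a, mu_s=mu_s, g=g_eff, mu_s_prime=reduced_scattering(mu_s, g_eff),
            distribution=dist, n_medium=n_medium, n_particle=n_particle,
            wavelength_nm=wavelength_nm,
        )


def study_media(
    mus_prime_grid=STUDY_MUS_PRIME_GRID,
    distribution: SizeDistribution | None = None,
    **kwargs,
) -> list[Medium]:
    """The phantom set of the study design: one medium per mu_s' value."""
    return [Medium.from_mus_prime(mp, distribution=distribution, **kwargs)
            for mp in mus_prime_grid]


def il_optical_properties(
    concentration: float,
    wavelength_nm: float = 632.8,
    mu_a: float = 0.0,
    distribution: SizeDistribution | None = None,
) -> Medium:
    """Map an Intralipid dilution to bulk optical properties.

    Uses the empirical wavelength fits for Intralipid-10% (van Staveren's
    measurements, as popularized by Jacques):

        mu_s [mm^-1 per (mL stock / L)] = 0.016 * lambda_um^-2.4
        g = 1.1 - 0.58 * lambda_um

    ``concentration`` is the volume fraction of Intralipid-10% stock in the
    final phantom (0.1 == a 10 % dilution == 100 mL/L); scattering scales
    linearly with concentration in this dilute regime.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if not 400.0 <= wavelength_nm <= 1100.0:
        raise ValueError("wavelength outside the fitted visible/NIR range")
    lam_um = wavelength_nm / 1000.0
    g = 1.1 - 0.58 * lam_um
    mu_s = concentration * 1000.0 * 0.016 * lam_um ** (-2.4)
    dist = distribution if distribution is not None else SizeDistribution.intralipid()
    return Medium(
        mu_a=mu_a, mu_s=mu_s, g=g, mu_s_prime=(1.0 - g) * mu_s,
        distribution=dist, wavelength_nm=wavelength_nm,
    )
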