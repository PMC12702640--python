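"""Extraction of mu_s' from a converged Q' reading.

In slabs thick enough for Q' to have reached its plateau, the reading
depends only on the optical properties of the medium, so a simulated
calibration curve Q'(mu_s') at fixed large thickness can be inverted to
estimate mu_s' from a measurement.  The inverse map is a monotone
shape-preserving (PCHIP) interpolant of the calibration knots, which is
single-valued because the curve is verified to be strictly decreasing at
build time.

The extraction assumes the calibration and the measurement share the
same anisotropy and absorption; this caveat is carried in the curve
metadata.  Where the calibration flattens (|dQ'/dmu_s'| below the
sensitivity floor) estimates are flagged low-confidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .medium import STUDY_MUS_PRIME_GRID
from .qsensing import compute_q_prime, mus_prime_sweep

__all__ = [
    "CalibrationCurve",
    "CalibrationError",
    "MusPrimeEstimate",
    "build_calibration",
    "invert_mus_prime",
    "q_prime_from_measurements",
]

#: |dQ'/dmu_s'| (per mm^-1) below which the inverse problem is flagged flat
SENSITIVITY_FLOOR = 0.02

#: half-width multiplier of the reported uncertainty interval (~95% normal)
INTERVAL_Z = 1.96


class CalibrationError(RuntimeError):
    """Raised when a calibration curve violates its monotonicity contract."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Simulated Q'(mu_s') knots at one converged thickness."""

    mus_prime_grid: np.ndarray
    q_prime_values: np.ndarray
    q_prime_errors: np.ndarray
    thickness_mm: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.mus_prime_grid, dtype=float)
        q = np.asarray(self.q_prime_values, dtype=float)
        se = np.asarray(self.q_prime_errors, dtype=float)
        object.__setattr__(self, "mus_prime_grid", grid)
        object.__setattr__(self, "q_prime_values", q)
        object.__setattr__(self, "q_prime_errors", se)
        if grid.size < 2:
            raise ValueError("calibration needs at least two knots")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("mus_prime grid must be strictly increasing")
        if q.shape != grid.shape or se.shape != grid.shape:
            raise ValueError("values and errors must match the grid shape")
        diffs = np.diff(q)
        if np.any(diffs >= 0):
            comb = np.sqrt(se[:-1] ** 2 + se[1:] ** 2)
            worst = float(np.max(diffs / np.maximum(comb, 1e-300)))
            raise CalibrationError(
                "calibration curve is not strictly decreasing "
                f"(worst violation {worst:.2f}x the combined MC error); "
                "increase the photon budget or the thickness"
            )

    @property
    def q_range(self) -> tuple[float, float]:
        return float(self.q_prime_values.min()), float(self.q_prime_values.max())

    def _inverse(self) -> PchipInterpolator:
        # Q' is strictly decreasing in mu_s', so reversing gives ascending knots
        return PchipInterpolator(self.q_prime_values[::-1],
                                 self.mus_prime_grid[::-1])

    def to_json(self, path) -> None:
        payload = {
            "mus_prime_grid": self.mus_prime_grid.tolist(),
            "q_prime_values": self.q_prime_values.tolist(),
            "q_prime_errors": self.q_prime_errors.tolist(),
            "thickness_mm": self.thickness_mm,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            mus_prime_grid=np.array(payload["mus_prime_grid"]),
            q_prime_values=np.array(payload["q_prime_values"]),
            q_prime_errors=np.array(payload["q_prime_errors"]),
            thickness_mm=payload["thickness_mm"],
            metadata=payload.get("metadata", {}),
        )


@dataclass(frozen=True)
class MusPrimeEstimate:
    """Point estimate with a propagated uncertainty interval."""

    mus_prime: float
    interval: tuple[float, float]
    se: float
    sensitivity: float          # |dQ'/dmu_s'| at the query point
    low_confidence: bool        # True in the flat regime of the curve

    def __contains__(self, truth: float) -> bool:
        return self.interval[0] <= truth <= self.interval[1]


def build_calibration(
    mus_prime_grid=STUDY_MUS_PRIME_GRID,
    thickness_mm: float = 10.0,
    n_photons: int = 100_000,
    seed: int = 0,
    convergence_threshold_mm: float = 10.0,
    **sweep_kwargs,
) -> CalibrationCurve:
    """Simulate the Q'(mu_s') calibration at a converged thickness.

    Refuses thicknesses below the convergence threshold (the plateau
    assumption would not hold) and curves whose monotonicity is violated
    beyond MC error.
    """
    if thickness_mm < convergence_threshold_mm:
        raise ValueError(
            f"thickness {thickness_mm} mm is below the convergence "
            f"threshold {convergence_threshold_mm} mm"
        )
    table = mus_prime_sweep(
        mus_prime_grid=mus_prime_grid, thickness_mm=thickness_mm,
        n_photons=n_photons, seed=seed, **sweep_kwargs,
    )
    return CalibrationCurve(
        mus_prime_grid=table["mu_s_prime"].to_numpy(),
        q_prime_values=table["q_prime"].to_numpy(),
        q_prime_errors=table["se_q_prime"].to_numpy(),
        thickness_mm=thickness_mm,
        metadata={
            "n_photons": n_photons,
            "seed": seed,
            "assumes_shared_g_and_mu_a": True,
            **{k: str(v) for k, v in sweep_kwargs.items()},
        },
    )


def _interpolation_error(curve: CalibrationCurve, mus_prime: float) -> float:
    """A-priori interpolation-error scale of the calibration between knots.

    Sparse calibration grids cannot resolve the curvature of Q'(mu_s')
    between knots, which leaves a model error no photon budget removes.
    The standard interpolation remainder (h^2 / 8) * |f''| estimates its
    scale from the knots alone, with f'' taken as the larger of the second
    divided differences of the knot triples adjacent to the query interval.
    """
    x = curve.mus_prime_grid
    q = curve.q_prime_values
    j = int(np.clip(np.searchsorted(x, mus_prime) - 1, 0, x.size - 2))
    h = x[j + 1] - x[j]
    slopes = np.diff(q) / np.diff(x)
    dd2 = 2.0 * np.abs(np.diff(slopes) / (x[2:] - x[:-2]))  # |f''| estimates
    # triples [j-1, j, j+1] and [j, j+1, j+2] flank interval j
    lo_t = max(j - 1, 0)
    hi_t = min(j, dd2.size - 1)
    f2 = float(np.max(dd2[lo_t : hi_t + 1])) if dd2.size else 0.0
    return (h * h / 8.0) * f2


def invert_mus_prime(
    curve: CalibrationCurve,
    q_prime_measured: float,
    q_prime_error: float = 0.0,
    sensitivity_floor: float = SENSITIVITY_FLOOR,
) -> MusPrimeEstimate:
    """Invert a converged Q' reading through the calibration curve.

    The uncertainty interval propagates three error sources through the
    slope of the inverse map: the measured standard error, the local
    calibration MC error, and the a-priori between-knot interpolation
    error of the sparse calibration grid.  Readings outside the
    calibrated Q' range are refused (no extrapolation).
    """
    lo, hi = curve.q_range
    if not lo <= q_prime_measured <= hi:
        raise ValueError(
            f"measured Q'={q_prime_measured:.4f} outside the calibrated "
            f"range [{lo:.4f}, {hi:.4f}]; extrapolation refused"
        )
    inverse = curve._inverse()
    value = float(inverse(q_prime_measured))
    dmu_dq = float(inverse.derivative()(q_prime_measured))
    sensitivity = 1.0 / abs(dmu_dq) if dmu_dq != 0 else float("inf")

    se_curve = float(np.interp(q_prime_measured,
                               curve.q_prime_values[::-1],
                               curve.q_prime_errors[::-1]))
    se_interp = _interpolation_error(curve, value)
    se_total_q = float(np.sqrt(q_prime_error**2 + se_curve**2 + se_interp**2))
    se_mu = abs(dmu_dq) * se_total_q
    half = INTERVAL_Z * se_mu
    return MusPrimeEstimate(
        mus_prime=value,
        interval=(value - half, value + half),
        se=se_mu,
        sensitivity=sensitivity,
        low_confidence=sensitivity < sensitivity_floor,
    )


def q_prime_from_measurements(path) -> tuple[float, float]:
    """Q' (mean, standard error) from a two-column (I_par, I_perp) text file."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != 2:
        raise ValueError("measurement file must have two columns: I_par I_perp")
    qp = np.array([compute_q_prime(ip, ix) for ip, ix in data])
    if qp.size == 1:
        return float(qp[0]), 0.0
    return float(qp.mean()), float(qp.std(ddof=1) / np.sqrt(qp.size))
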