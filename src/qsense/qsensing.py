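"""Q-sensing observables and the sweep experiment designs.

The detector superposes Stokes vectors in a frame whose analyzer axis is
the launch polarization axis, so the co- and cross-polarized channels are
the two linear-analyzer projections

    I_par  = (I + Q) / 2          I_perp = (I - Q) / 2

and the normalized difference

    Q' = (I_par - I_perp) / (I_par + I_perp) = Q / I

isolates the still-polarized superficial reflectance from the diffuse
background (in the two-component picture I_par = Is + Id/2 and
I_perp = Id/2, giving Q' = Is / (Is + Id)).

The two experiment designs are a thickness sweep at fixed optical
properties and a reduced-scattering sweep at fixed (large) thickness; the
latter is the calibration surface for extracting mu_s'.  Monte Carlo
standard errors come from the independent photon batches of each run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .medium import Medium, SizeDistribution, STUDY_MUS_PRIME_GRID
from .tables import MieTableSet
from .transport import (
    DetectorConfig,
    SlabGeometry,
    TransportResult,
    run_transport,
)

__all__ = [
    "QSenseResult",
    "stokes_to_intensities",
    "compute_q_prime",
    "qsense_from_transport",
    "thickness_sweep",
    "mus_prime_sweep",
    "THICKNESS_GRID_FULL",
    "write_sweep",
    "read_sweep",
]

#: the study's 19-thickness grid: 0.6-1.5 mm in 0.1 mm steps, 2-10 mm in 1 mm steps
THICKNESS_GRID_FULL = tuple(np.round(np.arange(0.6, 1.51, 0.1), 10)) + tuple(
    float(t) for t in range(2, 11)
)

SWEEP_COLUMNS = [
    "mu_s_prime", "thickness_mm", "i_par", "i_perp", "i_total", "q",
    "q_prime", "se_q_prime", "n_detected",
]


def stokes_to_intensities(stokes) -> tuple[float, float]:
    """Linear-analyzer projections (I_par, I_perp) of a detector-frame Stokes sum."""
    arr = np.asarray(stokes.asarray() if hasattr(stokes, "asarray") else stokes,
                     dtype=float)
    i, q = arr[0], arr[1]
    if abs(q) > i * (1 + 1e-9) + 1e-300:
        raise ValueError(f"unphysical superposition: |Q|={abs(q)} exceeds I={i}")
    return 0.5 * (i + q), 0.5 * (i - q)


def compute_q_prime(i_par: float, i_perp: float) -> float:
    """Normalized difference Q' = (I_par - I_perp)/(I_par + I_perp)."""
    total = i_par + i_perp
    if total <= 0:
        raise ValueError("total intensity must be positive")
    return (i_par - i_perp) / total


@dataclass(frozen=True)
class QSenseResult:
    """Co/cross-polarized reading for one (medium, thickness) cell.

    Intensities are per launched photon; ``mc_error`` holds batch-derived
    standard errors for the normalized quantities.
    """

    i_par: float
    i_perp: float
    i_total: float
    q: float
    q_prime: float
    mc_error: dict
    n_detected: int

    @property
    def se_q_prime(self) -> float:
        return self.mc_error["q_prime"]


def qsense_from_transport(result: TransportResult) -> QSenseResult:
    """Reduce a transport run to the Q-sensing observables with MC errors."""
    stokes = result.stokes / result.n_photons
    i_par, i_perp = stokes_to_intensities(stokes)
    q_prime = compute_q_prime(i_par, i_perp)

    # per-batch statistics for the normalized quantities
    bi = result.batch_stokes[:, 0]
    bq = result.batch_stokes[:, 1]
    ok = bi > 0
    nb = int(ok.sum())
    if nb >= 2:
        qp_b = bq[ok] / bi[ok]
        se_qp = float(np.std(qp_b, ddof=1) / np.sqrt(nb))
        ipar_b = 0.5 * (1.0 + qp_b)
        se_ipar = float(np.std(ipar_b, ddof=1) / np.sqrt(nb))
    else:
        se_qp = float("nan")
        se_ipar = float("nan")
    return QSenseResult(
        i_par=i_par, i_perp=i_perp, i_total=i_par + i_perp,
        q=i_par - i_perp, q_prime=q_prime,
        mc_error={
            "q_prime": se_qp,
            "i_par_norm": se_ipar,
            "i_perp_norm": se_ipar,
        },
        n_detected=result.tallies["reflected_detected"],
    )


def _row(medium: Medium, thickness: float, res: QSenseResult) -> dict:
    return {
        "mu_s_prime": medium.mu_s_prime,
        "thickness_mm": thickness,
        "i_par": res.i_par,
        "i_perp": res.i_perp,
        "i_total": res.i_total,
        "q": res.q,
        "q_prime": res.q_prime,
        "se_q_prime": res.se_q_prime,
        "n_detected": res.n_detected,
    }


def thickness_sweep(
    medium: Medium,
    thickness_grid,
    n_photons: int,
    seed: int,
    *,
    detector: DetectorConfig | None = None,
    tables: MieTableSet | None = None,
    **transport_kwargs,
) -> pd.DataFrame:
    """One transport run per slab thickness at fixed optical properties.

    Returns a tidy table with one row per thickness (columns
    ``SWEEP_COLUMNS``); each cell gets an independent sub-seed spawned
    from ``seed``.
    """
    grid = [float(t) for t in thickness_grid]
    if len(grid) == 0 or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("thickness grid must be non-empty and increasing")
    tables = tables or MieTableSet.for_medium(medium)
    seeds = [int(s) & 0x7FFFFFFF
             for s in np.random.SeedSequence(seed).generate_state(len(grid))]
    rows = []
    for t, s in zip(grid, seeds):
        res = run_transport(
            medium, SlabGeometry(thickness_mm=t), n_photons, s,
            detector=detector, tables=tables, **transport_kwargs,
        )
        rows.append(_row(medium, t, qsense_from_transport(res)))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def mus_prime_sweep(
    mus_prime_grid=STUDY_MUS_PRIME_GRID,
    thickness_mm: float = 10.0,
    n_photons: int = 100_000,
    seed: int = 0,
    *,
    distribution: SizeDistribution | None = None,
    detector: DetectorConfig | None = None,
    mu_a: float = 0.0,
    weighting: str = "number",
    **transport_kwargs,
) -> pd.DataFrame:
    """One transport run per mu_s' at fixed thickness (the calibration design)."""
    grid = [float(m) for m in mus_prime_grid]
    if len(grid) == 0:
        raise ValueError("mus_prime grid must be non-empty")
    media = [
        Medium.from_mus_prime(m, distribution=distribution, mu_a=mu_a,
                              weighting=weighting)
        for m in grid
    ]
    tables = MieTableSet.for_medium(media[0])
    seeds = [int(s) & 0x7FFFFFFF
             for s in np.random.SeedSequence(seed).generate_state(len(grid))]
    rows = []
    for medium, s in zip(media, seeds):
        res = run_transport(
            medium, SlabGeometry(thickness_mm=thickness_mm), n_photons, s,
            detector=detector, tables=tables, **transport_kwargs,
        )
        rows.append(_row(medium, thickness_mm, qsense_from_transport(res)))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def write_sweep(table: pd.DataFrame, path, sep: str = "\t") -> None:
    table.to_csv(path, sep=sep, index=False)


def read_sweep(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)
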