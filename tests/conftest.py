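"""Shared fixtures: the expensive Monte Carlo runs of the study design.

Heavy transport runs are session-scoped so that trend tests, inversion
tests and acceptance tests share a single set of simulations (1e5
photons per cell, 10 batches — the desk-scale budget).
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qsense import (
    CalibrationCurve,
    DetectorConfig,
    Medium,
    SizeDistribution,
    SlabGeometry,
    invert_mus_prime,
    mus_prime_sweep,
    qsense_from_transport,
    run_transport,
    thickness_sweep,
)
from qsense.transport import UNPOLARIZED

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

N_PHOTONS = 100_000
THICKNESS_GRID = [0.6, 1.0, 2.0, 5.0, 10.0]
MUS_GRID = [0.5, 1.0, 1.5, 2.0, 3.0]
RECOVERY_TRUTHS = [(0.75, 101), (1.25, 202), (2.5, 303)]  # (mu_s', seed)


@pytest.fixture(scope="session")
def detector():
    return DetectorConfig()


@pytest.fixture(scope="session")
def medium15():
    return Medium.from_mus_prime(1.5)


@pytest.fixture(scope="session")
def baseline_run(medium15):
    """Standard study cell: mu_s'=1.5 /mm, 10 mm slab, 1e5 photons."""
    return run_transport(medium15, SlabGeometry(10.0), N_PHOTONS, seed=21)


@pytest.fixture(scope="session")
def thickness_sweeps():
    """Thickness sweeps for the extreme study media (mu_s' = 0.5 and 3)."""
    out = {}
    for mp in (0.5, 3.0):
        medium = Medium.from_mus_prime(mp)
        out[mp] = thickness_sweep(medium, THICKNESS_GRID, N_PHOTONS, seed=5)
    return out


@pytest.fixture(scope="session")
def mus_sweep():
    """Q'(mu_s') at the converged 10 mm thickness (the calibration design)."""
    return mus_prime_sweep(MUS_GRID, 10.0, N_PHOTONS, seed=3)


@pytest.fixture(scope="session")
def calibration(mus_sweep):
    return CalibrationCurve(
        mus_prime_grid=mus_sweep["mu_s_prime"].to_numpy(),
        q_prime_values=mus_sweep["q_prime"].to_numpy(),
        q_prime_errors=mus_sweep["se_q_prime"].to_numpy(),
        thickness_mm=10.0,
        metadata={"n_photons": N_PHOTONS, "seed": 3},
    )


@pytest.fixture(scope="session")
def recovery_estimates(calibration):
    """Fresh-seed synthetic truths inverted through the calibration curve."""
    out = []
    for truth, seed in RECOVERY_TRUTHS:
        medium = Medium.from_mus_prime(truth)
        res = qsense_from_transport(
            run_transport(medium, SlabGeometry(10.0), N_PHOTONS, seed=seed)
        )
        out.append((truth, res, invert_mus_prime(calibration, res.q_prime,
                                                 res.se_q_prime)))
    return out


@pytest.fixture(scope="session")
def mono_poly_runs():
    """Converged Q' at mu_s' = 1.5 for monodisperse 200 nm vs polydisperse."""
    mono = Medium.from_mus_prime(1.5, distribution=SizeDistribution.monodisperse())
    poly = Medium.from_mus_prime(1.5)
    r_mono = qsense_from_transport(
        run_transport(mono, SlabGeometry(10.0), N_PHOTONS, seed=7))
    r_poly = qsense_from_transport(
        run_transport(poly, SlabGeometry(10.0), N_PHOTONS, seed=8))
    return r_mono, r_poly


@pytest.fixture(scope="session")
def unpolarized_normal_run(medium15):
    """Unpolarized launch at normal incidence (exact rotational symmetry)."""
    return qsense_from_transport(
        run_transport(medium15, SlabGeometry(10.0, incidence_deg=0.0),
                      N_PHOTONS, seed=9, launch_stokes=UNPOLARIZED)
    )
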