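"""Meridian-plane polarized Monte Carlo transport in a turbid slab.

Geometry and conventions
------------------------
Right-handed lab frame, depth axis z positive into the slab; the top
surface is z = 0, the bottom z = thickness.  The pencil beam enters at
the origin at 45 deg from the surface normal in the x-z plane, with
horizontal launch polarization S = (1, 1, 0, 0): Q = +1 means linearly
polarized in the photon's meridian plane, which at launch is the x-z
incidence plane.

Each photon carries an explicit orthonormal transverse frame
(e_par, e_perp) alongside its direction; the Stokes vector is referenced
to that frame (meridian-plane bookkeeping).  ``run_transport`` drives the
compiled batch engine; the photon-level operations below implement the
same algebra step by step and are the composable / testable surface.

Detected photons have their Stokes vectors rotated into the fixed
detector frame (analyzer along lab x) and superposed; per-photon full
polarization is preserved exactly, depolarization appears only in the
ensemble sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _engine
from .medium import Medium
from .mie import ScatteringElementTable, elements_at
from .tables import MieTableSet

__all__ = [
    "StokesVector",
    "PhotonState",
    "SlabGeometry",
    "DetectorConfig",
    "DetectionRecord",
    "TransportResult",
    "RejectionFailure",
    "launch_photon",
    "sample_step",
    "propagate",
    "sample_scattering_angles",
    "scatter_update",
    "check_termination",
    "detect",
    "run_transport",
    "HORIZONTAL",
    "UNPOLARIZED",
]

ZHAT = np.array([0.0, 0.0, 1.0])

#: launch states
HORIZONTAL = (1.0, 1.0, 0.0, 0.0)
UNPOLARIZED = (1.0, 0.0, 0.0, 0.0)

STATUS_ALIVE = "alive"
STATUS_ABSORBED = "absorbed"
STATUS_TRANSMITTED = "transmitted"
STATUS_REFLECTED_DETECTED = "reflected_detected"
STATUS_REFLECTED_UNDETECTED = "reflected_undetected"
STATUS_ROULETTE = "roulette_killed"
STATUS_EVENT_CAP = "event_cap_killed"


class RejectionFailure(RuntimeError):
    """Rejection sampler exhausted its proposal budget (broken envelope)."""


@dataclass(frozen=True)
class StokesVector:
    """Polarization state (I, Q, U, V) in arbitrary consistent units."""

    I: float
    Q: float = 0.0
    U: float = 0.0
    V: float = 0.0

    def __post_init__(self) -> None:
        if self.I < 0:
            raise ValueError("Stokes I must be non-negative")

    @classmethod
    def from_array(cls, arr) -> "StokesVector":
        i, q, u, v = np.asarray(arr, dtype=float)
        return cls(i, q, u, v)

    def asarray(self) -> np.ndarray:
        return np.array([self.I, self.Q, self.U, self.V])

    @property
    def dop(self) -> float:
        """Degree of polarization sqrt(Q^2+U^2+V^2)/I."""
        if self.I == 0:
            return 0.0
        return math.sqrt(self.Q**2 + self.U**2 + self.V**2) / self.I


@dataclass(frozen=True)
class SlabGeometry:
    """Laterally unbounded slab: top surface at depth 0, bottom at thickness."""

    thickness_mm: float
    incidence_deg: float = 45.0

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("slab thickness must be positive")
        if not 0.0 <= self.incidence_deg < 90.0:
            raise ValueError("incidence angle must lie in [0, 90) deg")

    def classify_depth(self, z: float) -> str:
        if z < 0:
            return "exited_top"
        if z > self.thickness_mm:
            return "exited_bottom"
        return "inside"


@dataclass(frozen=True)
class DetectorConfig:
    """Collection aperture around the beam entry point on the top surface.

    The default models a lensed photodiode looking down at the centre of
    the illumination spot: a 2 mm collection radius with a 30 deg
    acceptance half-angle about the surface normal.  A finite cone
    matters physically: grazing exits carry a different (weaker, partly
    negative) co-polarized signature than near-normal exits, and an
    instrument with a collection lens never sees them.
    """

    collect_radius_mm: float = 2.0
    accept_half_angle_deg: float = 30.0

    @property
    def cos_accept(self) -> float:
        return math.cos(math.radians(self.accept_half_angle_deg))


@dataclass
class PhotonState:
    position: np.ndarray
    direction: np.ndarray
    e_par: np.ndarray
    e_perp: np.ndarray
    stokes: np.ndarray
    weight: float = 1.0
    n_events: int = 0
    status: str = STATUS_ALIVE

    def copy(self) -> "PhotonState":
        return PhotonState(
            self.position.copy(), self.direction.copy(), self.e_par.copy(),
            self.e_perp.copy(), self.stokes.copy(), self.weight,
            self.n_events, self.status,
        )


@dataclass(frozen=True)
class DetectionRecord:
    position: np.ndarray
    direction: np.ndarray
    stokes: np.ndarray  # rotated into the detector meridian frame
    weight: float


def meridian_frame(k: np.ndarray, fallback=None):
    """Transverse frame (e_par, e_perp) of the meridian plane through k and z.

    e_perp = (k x z)/|k x z|, e_par = e_perp x k; e_par lies in the
    meridian plane and (e_par, e_perp, k) is right-handed.  At the poles
    (|k_z| = 1) the plane is undefined and the supplied fallback frame is
    carried instead.
    """
    cx, cy = k[1], -k[0]  # k x zhat
    n2 = cx * cx + cy * cy
    if n2 <= 1e-24:
        if fallback is None:
            return np.array([1.0, 0.0, 0.0]) * np.sign(k[2]), np.array([0.0, 1.0, 0.0])
        return fallback
    inv = 1.0 / math.sqrt(n2)
    e_perp = np.array([cx * inv, cy * inv, 0.0])
    e_par = np.cross(e_perp, k)
    return e_par, e_perp


def rotate_qu(stokes: np.ndarray, cos_a: float, sin_a: float) -> np.ndarray:
    """Reference-frame rotation by angle a about the propagation direction."""
    c2 = cos_a * cos_a - sin_a * sin_a
    s2 = 2.0 * cos_a * sin_a
    i, q, u, v = stokes
    return np.array([i, q * c2 + u * s2, -q * s2 + u * c2, v])


def launch_photon(
    geometry: SlabGeometry,
    rng=None,
    stokes: Sequence[float] = HORIZONTAL,
) -> PhotonState:
    """Pencil-beam launch at the origin, oblique in the x-z meridian.

    Deterministic (the beam has no transverse or angular spread); the
    ``rng`` argument is accepted for interface symmetry.
    """
    inc = math.radians(geometry.incidence_deg)
    k = np.array([math.sin(inc), 0.0, math.cos(inc)])
    e_par, e_perp = meridian_frame(k)
    return PhotonState(
        position=np.zeros(3), direction=k, e_par=e_par, e_perp=e_perp,
        stokes=np.asarray(stokes, dtype=float).copy(),
    )


def sample_step(mu_a: float, mu_s: float, rng) -> float:
    """Exponential free path s = -ln(z)/(mu_a + mu_s), z uniform on (0, 1]."""
    mu_t = mu_a + mu_s
    if mu_t <= 0:
        raise ValueError("mu_a + mu_s must be positive (infinite step otherwise)")
    z = 1.0 - rng.random()  # in (0, 1]
    return -math.log(z) / mu_t


def propagate(photon: PhotonState, s: float) -> PhotonState:
    """Advance the photon by path length s along its direction."""
    if s < 0:
        raise ValueError("step length must be non-negative")
    out = photon.copy()
    out.position = photon.position + s * photon.direction
    return out


def sample_scattering_angles(
    elements: ScatteringElementTable,
    stokes,
    rng,
    max_proposals: int = 10000,
):
    """Rejection-sample (theta, psi) proportional to P(theta, psi) sin(theta).

    Proposals are uniform in (cos theta, psi), so the sin(theta) Jacobian
    is built into the proposal measure and the acceptance test compares
    P(theta, psi) against the dominating constant
    ``1.01 * max(s11 + |s12|) * I``, which bounds P for every physical
    Stokes vector (|s12| <= s11 and sqrt(Q^2+U^2) <= I).
    """
    from .mie import _stokes_components

    i0, q0, u0, _ = _stokes_components(stokes)
    env = elements.envelope * i0
    for _ in range(max_proposals):
        ct = 1.0 - 2.0 * rng.random()
        psi = 2.0 * math.pi * rng.random()
        u3 = rng.random()
        theta = math.acos(ct)
        s11, s12, _, _ = elements_at(elements, theta)
        p = s11 * i0 + s12 * (q0 * math.cos(2 * psi) + u0 * math.sin(2 * psi))
        if p > 0.0 and u3 * env < p:
            return float(theta), float(psi)
    raise RejectionFailure(
        f"no acceptance after {max_proposals} proposals; envelope broken"
    )


def scatter_update(
    photon: PhotonState,
    theta: float,
    psi: float,
    elements: ScatteringElementTable,
) -> PhotonState:
    """One scattering event: Stokes rotations + Mueller matrix + new direction.

    Applies R(-gamma) M(theta) R(psi) to the Stokes vector, where R(psi)
    rotates into the scattering plane and R(-gamma) into the meridian
    plane of the outgoing direction, and rotates the direction by
    (theta, psi).  The raw Mueller action is kept (no renormalization);
    the run loop renormalizes I after sampling, since the angular draw
    already carries the intensity factor.
    """
    if photon.status != STATUS_ALIVE:
        raise ValueError("cannot scatter a dead photon")
    s11, s12, s33, s34 = (float(v) for v in elements_at(elements, theta))

    out = photon.copy()
    k, e_par, e_perp = photon.direction, photon.e_par, photon.e_perp

    # into the scattering plane
    s_rot = rotate_qu(photon.stokes, math.cos(psi), math.sin(psi))
    i1, q1, u1, v1 = s_rot
    s_mueller = np.array([
        s11 * i1 + s12 * q1,
        s12 * i1 + s11 * q1,
        s33 * u1 + s34 * v1,
        -s34 * u1 + s33 * v1,
    ])

    cp, sp = math.cos(psi), math.sin(psi)
    ct, st = math.cos(theta), math.sin(theta)
    a = cp * e_par + sp * e_perp
    k_new = ct * k + st * a
    k_new /= np.linalg.norm(k_new)
    a_new = ct * a - st * k
    a_new -= (a_new @ k_new) * k_new
    a_new /= np.linalg.norm(a_new)
    b_new = np.cross(k_new, a_new)

    m_par, m_perp = meridian_frame(k_new, fallback=(a_new, b_new))
    cosg = float(m_par @ a_new)
    sing = float(m_par @ b_new)
    rr = math.hypot(cosg, sing)
    s_final = rotate_qu(s_mueller, cosg / rr, sing / rr)

    out.direction = k_new
    out.e_par = m_par
    out.e_perp = m_perp
    out.stokes = s_final
    out.n_events = photon.n_events + 1
    return out


def check_termination(
    photon: PhotonState,
    geometry: SlabGeometry,
    medium: Medium,
    rng=None,
    event_cap: int = 1000,
    absorption: str = "binary",
) -> PhotonState:
    """Apply the death rules after a move or scattering event.

    A photon dies if it leaves the slab, is absorbed (binary draw with
    probability mu_a/mu_t at an interaction), or exceeds the maximum
    event count (default 1000).
    """
    out = photon.copy()
    if out.status != STATUS_ALIVE:
        return out
    z = out.position[2]
    if z > geometry.thickness_mm:
        out.status = STATUS_TRANSMITTED
        return out
    if z < 0:
        out.status = STATUS_REFLECTED_UNDETECTED  # detect() may upgrade
        return out
    if out.n_events > event_cap:
        out.status = STATUS_EVENT_CAP
        return out
    if medium.mu_a > 0 and absorption == "binary":
        if rng is None:
            raise ValueError("binary absorption needs a random generator")
        if rng.random() < medium.mu_a / medium.mu_t:
            out.status = STATUS_ABSORBED
    return out


def detect(
    photon: PhotonState,
    detector: DetectorConfig,
    entry_point=(0.0, 0.0),
) -> DetectionRecord | None:
    """Accept or reject a photon that exited the top surface.

    Accepted photons must exit within the collection radius of the beam
    entry point with a direction inside the acceptance cone about the
    surface normal; their Stokes vector is rotated into the detector
    meridian frame (analyzer parallel to lab x) before superposition.
    """
    if photon.position[2] > 1e-9:
        raise ValueError("detect() expects a photon at or above the top surface")
    k = photon.direction
    if k[2] >= 0:
        return None
    dx = photon.position[0] - entry_point[0]
    dy = photon.position[1] - entry_point[1]
    if dx * dx + dy * dy > detector.collect_radius_mm**2:
        return None
    if -k[2] < detector.cos_accept:
        return None
    d2 = 1.0 - k[0] * k[0]
    if d2 > 1e-18:
        d_par = np.array([d2, -k[0] * k[1], -k[0] * k[2]]) / math.sqrt(d2)
        cosd = float(d_par @ photon.e_par)
        sind = float(d_par @ photon.e_perp)
        rr = math.hypot(cosd, sind)
        stokes = rotate_qu(photon.stokes, cosd / rr, sind / rr)
    else:
        stokes = photon.stokes.copy()
    return DetectionRecord(
        position=photon.position.copy(), direction=k.copy(),
        stokes=stokes, weight=photon.weight,
    )


@dataclass(frozen=True)
class TransportResult:
    """Superposed detector Stokes vector plus exhaustive run tallies."""

    stokes: np.ndarray          # (4,) detector-frame sums over all batches
    batch_stokes: np.ndarray    # (n_batches, 4)
    tallies: dict
    detected_weight: float
    dop_dev_max: float          # max per-photon | DOP - 1 | among detected
    event_bin_stokes: np.ndarray  # (64, 4) detected Stokes by event count
    event_bin_counts: np.ndarray
    n_photons: int
    seed: int
    n_batches: int

    @property
    def total_launched(self) -> int:
        return int(sum(self.tallies.values()))


_TALLY_NAMES = (
    "reflected_detected", "reflected_undetected", "transmitted",
    "absorbed", "event_cap_killed", "roulette_killed", "rejection_failed",
)


def _entry_conditions(medium: Medium, geometry: SlabGeometry, boundary: str):
    """In-medium launch direction and specular entry loss for the boundary model."""
    inc = math.radians(geometry.incidence_deg)
    if boundary == "matched":
        k0 = np.array([math.sin(inc), 0.0, math.cos(inc)])
        return k0, 0.0
    if boundary != "fresnel":
        raise ValueError(f"unknown boundary model {boundary!r}")
    n = medium.n_medium
    si = math.sin(inc)
    ci = math.cos(inc)
    st = si / n
    ct = math.sqrt(1.0 - st * st)
    rp = (n * ci - ct) / (n * ci + ct)
    # horizontal launch polarization lies in the plane of incidence (p-pol)
    return np.array([st, 0.0, ct]), rp * rp


def run_transport(
    medium: Medium,
    geometry: SlabGeometry,
    n_photons: int,
    seed: int,
    *,
    detector: DetectorConfig | None = None,
    tables: MieTableSet | None = None,
    launch_stokes: Sequence[float] = HORIZONTAL,
    n_batches: int = 10,
    event_cap: int = 1000,
    absorption: str = "binary",
    boundary: str = "matched",
    engine: str = "numba",
    max_rejection: int = 10000,
) -> TransportResult:
    """Run the full slab simulation and superpose detected Stokes vectors.

    Photons are split into ``n_batches`` independent batches (for Monte
    Carlo error bars); each batch runs with a sub-seed spawned from
    ``seed``, so results are reproducible for a fixed configuration.
    """
    if n_photons < 1:
        raise ValueError("need at least one photon")
    if medium.mu_t <= 0:
        raise ValueError("medium with mu_a + mu_s = 0 cannot transport photons")
    if absorption not in ("binary", "weight"):
        raise ValueError(f"unknown absorption rule {absorption!r}")
    detector = detector or DetectorConfig()
    tables = tables or MieTableSet.for_medium(medium)

    k0, entry_refl = _entry_conditions(medium, geometry, boundary)
    e0, f0 = meridian_frame(k0)
    s0 = np.asarray(launch_stokes, dtype=float)
    if s0[0] <= 0:
        raise ValueError("launch Stokes I must be positive")

    cdf = medium.distribution.cdf
    if not np.array_equal(medium.distribution.radii_nm, tables.radii_nm):
        raise ValueError("table radii do not match the medium's distribution")

    runner = _engine.run_batch_numba if engine == "numba" else _engine.run_batch_python

    ss = np.random.SeedSequence(seed)
    batch_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n_batches)]
    counts = [n_photons // n_batches] * n_batches
    for i in range(n_photons % n_batches):
        counts[i] += 1

    batch_stokes = np.zeros((n_batches, 4))
    tallies = np.zeros(_engine.N_TALLY, dtype=np.int64)
    bins_s = np.zeros((_engine.N_EVENT_BINS, 4))
    bins_n = np.zeros(_engine.N_EVENT_BINS, dtype=np.int64)
    wsum = 0.0
    dop_dev = 0.0
    for b in range(n_batches):
        if counts[b] == 0:
            continue
        det = np.zeros(6)
        runner(
            batch_seeds[b], counts[b], medium.mu_a, medium.mu_s,
            geometry.thickness_mm,
            k0[0], k0[1], k0[2], e0[0], e0[1], e0[2], f0[0], f0[1], f0[2],
            s0[0], s0[1], s0[2], s0[3],
            cdf, tables.reS1, tables.imS1, tables.reS2, tables.imS2,
            tables.envelope,
            detector.collect_radius_mm, detector.cos_accept,
            event_cap, max_rejection,
            absorption == "binary",
            boundary == "fresnel", medium.n_medium, entry_refl,
            det, tallies, bins_s, bins_n,
        )
        batch_stokes[b] = det[:4]
        wsum += det[4]
        dop_dev = max(dop_dev, det[5])

    tally_dict = dict(zip(_TALLY_NAMES, (int(t) for t in tallies)))
    if tally_dict["rejection_failed"] > 0:
        raise RejectionFailure(
            f"{tally_dict['rejection_failed']} photons exhausted "
            f"{max_rejection} proposals: rejection envelope is broken"
        )
    return TransportResult(
        stokes=batch_stokes.sum(axis=0), batch_stokes=batch_stokes,
        tallies=tally_dict, detected_weight=wsum, dop_dev_max=dop_dev,
        event_bin_stokes=bins_s, event_bin_counts=bins_n,
        n_photons=n_photons, seed=seed, n_batches=n_batches,
    )
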