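"""YAML run-configuration loading for the command-line interface.

A config file collects everything one simulation cell needs::

    medium:
      mus_prime: 1.5            # or: il_concentration: 0.02
      mu_a: 0.0
      weighting: number          # number | cross_section
      distribution: sizes.tsv    # optional (radius_nm, weight) table
      monodisperse_nm: 200       # optional: overrides distribution
    geometry:
      thickness_mm: 10.0
      incidence_deg: 45.0
    detector:
      collect_radius_mm: 2.0
      accept_half_angle_deg: 90.0
    run:
      n_photons: 100000
      seed: 1
      n_batches: 10
      event_cap: 1000
      absorption: binary         # binary | weight
      boundary: matched          # matched | fresnel
"""

from __future__ import annotations

import yaml

from .medium import Medium, SizeDistribution, il_optical_properties
from .transport import DetectorConfig, SlabGeometry

__all__ = ["load_config", "medium_from_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out = {
        "medium": medium_from_config(cfg.get("medium", {})),
        "geometry": SlabGeometry(**cfg.get("geometry", {"thickness_mm": 10.0})),
        "detector": DetectorConfig(**cfg.get("detector", {})),
        "run": dict(cfg.get("run", {})),
    }
    return out


def medium_from_config(mcfg: dict) -> Medium:
    """Build a Medium from an explicit triple, a mu_s' target, or an IL dilution."""
    distribution = None
    if "monodisperse_nm" in mcfg:
        distribution = SizeDistribution.monodisperse(float(mcfg["monodisperse_nm"]))
    elif "distribution" in mcfg:
        distribution = SizeDistribution.from_file(mcfg["distribution"])

    mu_a = float(mcfg.get("mu_a", 0.0))
    if "mus_prime" in mcfg:
        return Medium.from_mus_prime(
            float(mcfg["mus_prime"]), distribution=distribution, mu_a=mu_a,
            weighting=mcfg.get("weighting", "number"),
        )
    if "il_concentration" in mcfg:
        return il_optical_properties(
            float(mcfg["il_concentration"]),
            wavelength_nm=float(mcfg.get("wavelength_nm", 632.8)),
            mu_a=mu_a, distribution=distribution,
        )
    if {"mu_s", "g"} <= mcfg.keys():
        return Medium.from_mu_s(
            float(mcfg["mu_s"]), float(mcfg["g"]), mu_a=mu_a,
            **({"distribution": distribution} if distribution else {}),
        )
    raise ValueError(
        "medium config needs one of: mus_prime, il_concentration, (mu_s, g)"
    )
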