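"""Synthetic experimental-curve fixtures for NMSE exercises.

The organ-scale validation data of the cited motion-segment experiments are
not redistributable, so tests and demonstrations use deterministic synthetic
stand-ins: a smooth parametric response family per test type (monotone
power-law-plus-linear ramps, saturating-exponential creep/relaxation), an
optional seeded noise perturbation of the mean, and a symmetric confidence
band.  All randomness in the package lives here, behind an explicit seed; the
simulation path is seed-free and deterministic.
"""

from __future__ import annotations

import numpy as np

from .metrics import Curve

__all__ = ["generate_fixture_curve", "FIXTURE_KINDS"]

FIXTURE_KINDS = (
    "slow_ramp",
    "creep",
    "stress_relaxation",
    "axial_compression",
    "torsion",
    "bending",
    "flexion",
)


def generate_fixture_curve(
    kind: str,
    n_points: int = 50,
    amplitude: float = 1.0,
    band_fraction: float = 0.15,
    noise: float = 0.0,
    seed: int = 0,
) -> Curve:
    """Deterministic synthetic 'experimental' curve of the given test type.

    ``band_fraction`` sets the half-width of the synthetic 95% CI relative to
    the response amplitude; ``noise`` perturbs the mean (seeded, for testing
    NMSE sensitivity).  With ``noise=0`` the mean equals the parametric family
    exactly.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    x = np.linspace(0.0, 1.0, n_points)
    if kind in ("slow_ramp", "axial_compression"):
        mean = amplitude * (0.35 * x**1.8 + 0.65 * x)
    elif kind in ("torsion", "bending", "flexion"):
        mean = amplitude * (0.25 * x**2.2 + 0.75 * x)
    elif kind == "creep":
        mean = amplitude * (1.0 - np.exp(-4.0 * x))
    else:  # stress_relaxation: decay toward a plateau
        mean = amplitude * (0.4 + 0.6 * np.exp(-5.0 * x))
    if noise > 0:
        rng = np.random.default_rng(seed)
        mean = mean + noise * amplitude * rng.standard_normal(n_points)
    band = band_fraction * amplitude * (0.25 + 0.75 * x)
    return Curve(
        x=x,
        y_model=mean.copy(),
        y_expmean=mean,
        y_ci=mean + band,
        meta={"kind": kind, "seed": seed, "noise": noise, "synthetic": True},
    )
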