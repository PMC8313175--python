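"""Packaged default material table and environment.

The per-region constants come from tissue-level experiments on disc
constituents (confined compression for matrix and permeability, proteoglycan
assays for fixed charge density, uniaxial tension for fibers, optical
microscopy for fiber angles).  The annulus varies radially; AFtrans and
NPtrans are single-element-wide transitional layers.

Reference water fractions are not part of the published table; the defaults
below (NP/NPtrans 0.80, annulus 0.70, CEP 0.60) are typical reported disc
tissue water contents and are configurable per region.
"""

from __future__ import annotations

from .materials import Environment, MaterialParams

__all__ = ["default_material_table", "default_environment", "VB_NEO_HOOKEAN"]

#: Young's modulus / Poisson ratio of the (optional) compliant vertebral-body
#: platens; by default platens are rigid and this law is unused.
VB_NEO_HOOKEAN = {"E": 10000.0, "nu": 0.3}

_TABLE = {
    #            E_m    nu    beta_m  k0      M     c0F  E_f   lam0   theta beta_f phi0_s
    "OAF":     (0.018, 0.24, 3.4,  0.0047,  5.75,  44.0, 15.6, 1.028, 31.0, 4.0, 0.30),
    "AFtrans": (0.023, 0.20, 2.8,  0.0036,  4.60,  50.0, 10.3, 1.025, 38.5, 4.0, 0.30),
    "IAF":     (0.026, 0.16, 2.1,  0.0025,  3.50,  55.0,  6.9, 1.023, 41.5, 4.0, 0.30),
    "NPtrans": (0.045, 0.20, 1.5,  0.0016,  2.71, 217.0,  3.0, 1.020, 44.5, 4.0, 0.20),
    "NP":      (0.065, 0.24, 0.95, 0.00056, 3.79, 379.0, None, None,  None, None, 0.20),
    "CEP":     (0.305, 0.18, 0.29, 0.00056, 3.79, 248.0, None, None,  None, None, 0.40),
}


def default_material_table() -> dict[str, MaterialParams]:
    """Region label -> MaterialParams for the packaged default disc."""
    table = {}
    for label, row in _TABLE.items():
        E_m, nu, beta_m, k0, M, c0F, E_f, lam0, theta, beta_f, phi0_s = row
        table[label] = MaterialParams(
            region_label=label,
            E_m=E_m,
            nu=nu,
            beta_m=beta_m,
            k0=k0,
            M=M,
            c0F=c0F,
            E_f=E_f,
            lambda0=lam0,
            theta=theta,
            beta_f=beta_f,
            phi0_s=phi0_s,
        )
    return table


def default_environment() -> Environment:
    """300 mOsm/L bath at body temperature, ideal Donnan (Phi = 1)."""
    return Environment()
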