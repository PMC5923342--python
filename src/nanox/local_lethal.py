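"""Effective lethal function (ELF) and the local-event core coefficient.

Local lethal events are inactivations of nanometric targets that alone kill
the cell.  Instead of a per-target inactivation probability ``f``, the model
works with the effective lethal function ``F = -N ln(1 - f)`` (``N`` targets),
represented by an error function of the restricted specific energy ``z``:

    F(z) = (h/2) * (1 + erf((z - z0) / sigma))

``z0`` is the restricted-specific-energy threshold above which damage can be
lethal, ``sigma`` the width of the rise, and ``h`` the saturation height
(which absorbs the total number of targets, so ``N`` never needs a value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .quality import GeometrySpec, RadiationQuality

__all__ = ["ELFParams", "elf_value", "inactivation_probability", "mean_elf", "alpha_core"]


@dataclass(frozen=True)
class ELFParams:
    """Error-function ELF parameters: threshold z0 (Gy), width sigma (Gy),
    saturation height h (dimensionless)."""

    z0: float
    sigma: float
    h: float

    def __post_init__(self) -> None:
        if not self.z0 > 0:
            raise ValueError(f"z0 must be > 0, got {self.z0}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.h < 0:
            raise ValueError(f"h must be >= 0, got {self.h}")


def elf_value(p: ELFParams, z):
    """F(z) = (h/2)(1 + erf((z - z0)/sigma)); monotone, range (0, h)."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("restricted specific energy z must be >= 0")
    out = 0.5 * p.h * (1.0 + erf((z - p.z0) / p.sigma))
    return float(out) if out.ndim == 0 else out


def inactivation_probability(F, n_targets: int):
    """Per-target inactivation probability f = 1 - exp(-F/N)."""
    if n_targets < 1:
        raise ValueError("number of local targets must be >= 1")
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("F must be >= 0")
    out = -np.expm1(-F / n_targets)
    return float(out) if out.ndim == 0 else out


def mean_elf(p: ELFParams, q: RadiationQuality) -> float:
    """<F(z)> over the nanotarget histogram of one impact (core tossing)."""
    return float(np.sum(q.z_prob * elf_value(p, q.z_values)))


def alpha_core(p: ELFParams, q: RadiationQuality, geom: GeometrySpec) -> float:
    """Core coefficient alpha_c (Gy^-1) for one radiation quality.

    alpha_c = <F(z)>_core / Zc_mean, so that the per-impact core exponent
    alpha_c * (Vc/Vs) * Zc_mean equals (Vc/Vs) * <F>_core.
    """
    f_mean = mean_elf(p, q)
    if q.Zc_mean <= 0.0:
        if f_mean > 1e-12 * max(p.h, 1.0):
            raise ValueError(
                "inconsistent table: Zc_mean = 0 but the ELF expectation is nonzero"
            )
        return 0.0
    return f_mean / q.Zc_mean
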