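"""Global (chemical) events: chemical specific energy, LQ survival, Cnorm.

Global events represent accumulated oxidative damage at the cell scale.
Survival with respect to them is linear-quadratic in the *chemical specific
energy* Z-tilde — the restricted specific energy rescaled per impact by the
relative chemical effectiveness, i.e. the OH-radical yield ratio G/Gr
evaluated at time TRCE:

    S_G = Cnorm * exp(-alphaG * Zt - betaG * Zt^2),   alphaG = 0

with betaG = betar / eta^2 derived from the reference radiation's quadratic
coefficient and the restricted-to-total specific-energy ratio eta.  Cnorm
normalizes the model so that its mean survival for the reference radiation
reproduces the experimental LQ response at the calibration dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .quality import GeometrySpec, RadiationQuality, yield_ratio_at

__all__ = [
    "GlobalParams",
    "ReferenceRadiation",
    "CalibrationError",
    "beta_g",
    "chemical_specific_energy",
    "survival_global",
    "reference_survival_samples",
    "calibrate_cnorm",
]

#: coefficient of variation of the reference-radiation restricted specific
#: energy at 2 Gy; scales as D^-1/2 (Gaussian-like photon impact statistics)
REF_CV_AT_2GY = 0.05


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GlobalParams:
    """Global-event parameters: alphaG (fixed 0), betaG (Gy^-2), Cnorm, TRCE (s)."""

    betaG: float
    alphaG: float = 0.0
    Cnorm: float | None = None
    TRCE: float = 1e-11

    def __post_init__(self) -> None:
        if self.betaG < 0:
            raise ValueError(f"betaG must be >= 0, got {self.betaG}")
        if self.Cnorm is not None and not (0.0 < self.Cnorm <= 1.5):
            raise ValueError(f"Cnorm must be in (0, 1.5], got {self.Cnorm}")
        if not (1e-12 <= self.TRCE <= 1e-7):
            raise ValueError(f"TRCE must be in [1e-12, 1e-7] s, got {self.TRCE}")


@dataclass(frozen=True)
class ReferenceRadiation:
    """LQ response to the reference (photon) radiation."""

    alphar: float
    betar: float
    SF2: float | None = None

    def __post_init__(self) -> None:
        if not self.alphar > 0:
            raise ValueError(f"alphar must be > 0, got {self.alphar}")
        if self.betar < 0:
            raise ValueError(f"betar must be >= 0, got {self.betar}")
        if self.SF2 is not None:
            model = math.exp(-2.0 * self.alphar - 4.0 * self.betar)
            if abs(model - self.SF2) > 1e-3:
                raise ValueError(
                    f"SF2={self.SF2} inconsistent with (alphar, betar): "
                    f"exp(-2a-4b)={model:.5f}"
                )

    @classmethod
    def from_sf2(cls, sf2: float, betar: float) -> "ReferenceRadiation":
        """Derive alphar from the surviving fraction at 2 Gy:
        -ln SF2 = 2*alphar + 4*betar."""
        if not (0.0 < sf2 < 1.0):
            raise ValueError(f"SF2 must be in (0, 1), got {sf2}")
        alphar = (-math.log(sf2) - 4.0 * betar) / 2.0
        if alphar <= 0:
            raise ValueError("derived alphar is non-positive; check SF2/betar")
        return cls(alphar=alphar, betar=betar, SF2=sf2)


def beta_g(betar: float, eta: float) -> float:
    """betaG = betar / eta^2 (betaG > betar since eta < 1)."""
    if not (0.0 < eta <= 1.0):
        raise ValueError(f"eta must be in (0, 1], got {eta}")
    if betar < 0:
        raise ValueError(f"betar must be >= 0, got {betar}")
    return betar / eta**2


def chemical_specific_energy(
    impacts: Sequence[tuple[float, float]],
    q: RadiationQuality,
    t: float,
    geom: GeometrySpec,
) -> float:
    """Z-tilde for a configuration of impacts given as (Zc, Zp) pairs:

    Zt = sum_k [ (G_c/Gr)(T) * (Vc/Vs) * Zc_k + (G_p/Gr)(T) * (Vp/Vs) * Zp_k ]
    """
    if geom.Vp < 0 or geom.Vc > geom.Vs:
        raise ValueError("inconsistent region volumes")
    if not impacts:
        return 0.0
    rc = yield_ratio_at(q, t, "core")
    rp = yield_ratio_at(q, t, "penumbra")
    fc, fp = geom.Vc / geom.Vs, geom.Vp / geom.Vs
    return float(sum(rc * fc * zc + rp * fp * zp for zc, zp in impacts))


def survival_global(z_tilde: float, g: GlobalParams) -> float:
    """Cnorm * exp(-alphaG*Zt - betaG*Zt^2). Requires a calibrated Cnorm."""
    if z_tilde < 0:
        raise ValueError("chemical specific energy must be >= 0")
    if g.Cnorm is None:
        raise CalibrationError("Cnorm has not been calibrated")
    return g.Cnorm * math.exp(-g.alphaG * z_tilde - g.betaG * z_tilde**2)


# ---------------------------------------------------------------------------
# Reference radiation and Cnorm calibration
# ---------------------------------------------------------------------------


def reference_survival_samples(
    cell, dose: float, n_mc: int, rng: np.random.Generator, cnorm: float = 1.0
) -> np.ndarray:
    """Per-configuration survival samples for the reference radiation.

    The photon field has no track core; the total restricted specific
    energy in the sensitive volume is Gaussian-like with mean eta*D and a
    coefficient of variation REF_CV_AT_2GY * sqrt(2/D).  Local survival is
    exp(-alpha_p * Z), global survival the LQ term in Z (yield ratio 1).
    """
    if dose == 0.0:
        return np.ones(n_mc)
    cv = REF_CV_AT_2GY * math.sqrt(2.0 / dose)
    mean = cell.eta * dose
    z = np.clip(rng.normal(mean, cv * mean, size=n_mc), 0.0, None)
    g = cell.global_params
    return cnorm * np.exp(-cell.alpha_p * z - g.alphaG * z - g.betaG * z**2)


def calibrate_cnorm(
    cell,
    ref_quality: RadiationQuality | None = None,
    d_cal: float = 2.0,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Cnorm such that the mean model survival for the reference radiation
    at ``d_cal`` equals exp(-alphar*D - betar*D^2).

    Cnorm enters the survival of every configuration linearly, so the
    calibration is a single division — exact (to Monte Carlo accuracy of the
    very estimator later used by the engine) and reproducible by seed.
    """
    if ref_quality is not None and ref_quality.Zc_mean != 0.0:
        raise ValueError("reference quality must have zero core contribution")
    if not d_cal > 0:
        raise ValueError(f"calibration dose must be > 0, got {d_cal}")
    rng = np.random.default_rng(seed)
    s_uncal = float(np.mean(reference_survival_samples(cell, d_cal, n_mc, rng)))
    if not (s_uncal > 0 and math.isfinite(s_uncal)):
        raise CalibrationError(f"uncalibrated mean survival is {s_uncal}")
    ref = cell.ref
    target = math.exp(-ref.alphar * d_cal - ref.betar * d_cal**2)
    cnorm = target / s_uncal
    if not (0.0 < cnorm <= 1.5):
        raise CalibrationError(
            f"calibrated Cnorm={cnorm:.4f} outside (0, 1.5]; "
            f"uncalibrated S({d_cal} Gy)={s_uncal:.4f}, target={target:.4f}"
        )
    return cnorm
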