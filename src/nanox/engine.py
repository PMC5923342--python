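"""Monte Carlo survival engine: impact statistics, curves, LQ outcomes.

Mean survival at dose D averages the per-configuration survival over the
Poisson-distributed number of radiation impacts K and over the per-impact
restricted specific energies:

    S(D) = sum_K P(K, D) * < S_local * S_global >

The local factor multiplies, per impact, a deterministic core term — the
track-type average exponent (Vc/Vs) <F(z)> — and a stochastic penumbra term
alpha_p * (Vp/Vs) * Zp_k.  The global factor is the LQ term in the chemical
specific energy accumulated over all impacts.  Because per-impact energies
are independent Gamma variables (compound-Poisson counts of fixed 40 eV
transfers), the sum over K impacts is again Gamma, which lets the engine
draw one variate per configuration instead of K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from . import global_events as ge
from .global_events import GlobalParams, ReferenceRadiation
from .local_lethal import ELFParams, mean_elf, alpha_core
from .quality import C_GY, GeometrySpec, IonSpec, RadiationQuality, yield_ratio_at

__all__ = [
    "CellLineParams",
    "SurvivalCurve",
    "LQCoefficients",
    "mean_impact_number",
    "sample_impacts",
    "survival_one_configuration",
    "simulate_survival",
    "alpha_closed_form",
    "lq_fit",
    "dose_at_survival",
    "calibrate",
]


@dataclass(frozen=True)
class CellLineParams:
    """All parameters of one modeled cell line."""

    name: str
    geom: GeometrySpec
    elf: ELFParams
    ref: ReferenceRadiation
    global_params: GlobalParams
    eta: float = 0.8
    penumbra_alpha_rescale: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.eta <= 1.0):
            raise ValueError(f"eta must be in (0, 1], got {self.eta}")
        expected = ge.beta_g(self.ref.betar, self.eta)
        if expected > 0 and abs(self.global_params.betaG - expected) / expected > 0.005:
            raise ValueError(
                f"betaG={self.global_params.betaG:.6g} inconsistent with "
                f"betar/eta^2={expected:.6g} (> 0.5%)"
            )

    @property
    def alpha_p(self) -> float:
        """Penumbra coefficient acting on restricted specific energy.

        Verbatim model choice: alpha_p = alphar.  With the rescale switch
        on, alpha_p = alphar / eta so that the linear response to the
        reference radiation (mean restricted specific energy eta*D) is
        exactly alphar * D at every dose.
        """
        if self.penumbra_alpha_rescale:
            return self.ref.alphar / self.eta
        return self.ref.alphar

    @property
    def is_calibrated(self) -> bool:
        return self.global_params.Cnorm is not None


@dataclass
class SurvivalCurve:
    doses: np.ndarray
    mean_survival: np.ndarray
    mc_stderr: np.ndarray
    n_mc: int
    seed: int

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.mean_survival = np.asarray(self.mean_survival, dtype=float)
        self.mc_stderr = np.asarray(self.mc_stderr, dtype=float)


@dataclass(frozen=True)
class LQCoefficients:
    alpha: float
    beta: float
    alpha_se: float | None = None
    beta_se: float | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("LQ coefficients must be >= 0")


# ---------------------------------------------------------------------------
# Impact statistics
# ---------------------------------------------------------------------------


def mean_impact_number(dose: float, ion: IonSpec, geom: GeometrySpec) -> float:
    """<K> = D * pi * RVs^2 / (C_GY * LET)."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if ion.is_reference:
        raise ValueError("the reference radiation uses its own impact model")
    return dose * math.pi * geom.RVs**2 / (C_GY * ion.let)


def _gamma_shapes(q: RadiationQuality, geom: GeometrySpec) -> tuple[float, float]:
    """Per-impact Gamma shape parameters for (Zc, Zp): the expected number
    of fixed-energy transfer points in each region."""
    kc = q.Zc_mean * geom.Vc / (C_GY * q.e0_kev)
    kp = q.Zp_mean * geom.Vp / (C_GY * q.e0_kev)
    return kc, kp


def sample_impacts(
    q: RadiationQuality, geom: GeometrySpec, k: int, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Draw k independent per-impact (Zc, Zp) pairs."""
    if q.deterministic:
        return [(q.Zc_mean, q.Zp_mean)] * k
    kc, kp = _gamma_shapes(q, geom)
    zc = rng.gamma(kc, q.Zc_mean / kc, size=k) if kc > 0 else np.zeros(k)
    zp = rng.gamma(kp, q.Zp_mean / kp, size=k) if kp > 0 else np.zeros(k)
    return list(zip(zc.tolist(), zp.tolist()))


# ---------------------------------------------------------------------------
# Survival of one configuration and Monte Carlo curves
# ---------------------------------------------------------------------------


def survival_one_configuration(
    impacts: Sequence[tuple[float, float]],
    cell: CellLineParams,
    q: RadiationQuality,
) -> float:
    """Survival for one configuration of impacts given as (Zc, Zp) pairs.

    The local core exponent uses the track-type average (Vc/Vs) <F(z)> per
    impact; the penumbra exponent and the global chemical term use the
    per-impact energies.
    """
    if not cell.is_calibrated:
        raise ge.CalibrationError(
            "model is uncalibrated: run calibrate() to set Cnorm first"
        )
    g = cell.global_params
    if not impacts:
        return g.Cnorm
    geom = cell.geom
    f_core = mean_elf(cell.elf, q)
    k = len(impacts)
    local_exp = k * (geom.Vc / geom.Vs) * f_core + cell.alpha_p * (
        geom.Vp / geom.Vs
    ) * sum(zp for _, zp in impacts)
    z_tilde = ge.chemical_specific_energy(impacts, q, g.TRCE, geom)
    return math.exp(-local_exp) * ge.survival_global(z_tilde, g)


def simulate_survival(
    cell: CellLineParams,
    q: RadiationQuality,
    doses: Sequence[float],
    n_mc: int = 10_000,
    seed: int = 0,
) -> SurvivalCurve:
    """Monte Carlo mean survival versus dose.

    For each dose, K ~ Poisson(<K>) and the per-impact energy sums are drawn
    from the closed-form Gamma convolution.  Impact-free configurations
    count as survival 1 (an unhit cell is unirradiated), so S(0) = 1
    exactly.  The reference radiation uses its Gaussian-like total-energy
    model instead of Poisson impact counting.
    """
    if n_mc < 100:
        raise ValueError("n_mc must be >= 100")
    if not cell.is_calibrated:
        raise ge.CalibrationError(
            "model is uncalibrated: run calibrate() to set Cnorm first"
        )
    rng = np.random.default_rng(seed)
    g = cell.global_params
    geom = cell.geom
    means = np.empty(len(doses))
    errs = np.empty(len(doses))

    if q.is_reference:
        for i, d in enumerate(doses):
            s = ge.reference_survival_samples(cell, d, n_mc, rng, cnorm=g.Cnorm)
            means[i] = s.mean()
            errs[i] = s.std(ddof=1) / math.sqrt(n_mc) if d > 0 else 0.0
        return SurvivalCurve(np.asarray(doses, float), means, errs, n_mc, seed)

    f_core = mean_elf(cell.elf, q)
    kc, kp = _gamma_shapes(q, geom)
    rc = yield_ratio_at(q, g.TRCE, "core")
    rp = yield_ratio_at(q, g.TRCE, "penumbra")
    fc, fp = geom.Vc / geom.Vs, geom.Vp / geom.Vs

    for i, d in enumerate(doses):
        if d == 0.0:
            means[i], errs[i] = 1.0, 0.0
            continue
        k = rng.poisson(mean_impact_number(d, q.ion, geom), size=n_mc)
        if q.deterministic:
            zc_sum = k * q.Zc_mean
            zp_sum = k * q.Zp_mean
        else:
            zc_sum = rng.gamma(k * kc, q.Zc_mean / kc) if kc > 0 else np.zeros(n_mc)
            zp_sum = rng.gamma(k * kp, q.Zp_mean / kp) if kp > 0 else np.zeros(n_mc)
        local_exp = k * fc * f_core + cell.alpha_p * fp * zp_sum
        z_tilde = rc * fc * zc_sum + rp * fp * zp_sum
        s = g.Cnorm * np.exp(-local_exp - g.alphaG * z_tilde - g.betaG * z_tilde**2)
        s[k == 0] = 1.0
        means[i] = s.mean()
        errs[i] = s.std(ddof=1) / math.sqrt(n_mc)
    return SurvivalCurve(np.asarray(doses, float), means, errs, n_mc, seed)


# ---------------------------------------------------------------------------
# Low-fluence alpha, LQ fitting, Dx%
# ---------------------------------------------------------------------------


def alpha_closed_form(cell: CellLineParams, q: RadiationQuality) -> float:
    """Low-fluence linear coefficient alpha (Gy^-1).

    alpha = pi * RVs^2 * (1 - <S_L1>) / (C_GY * LET), with <S_L1> the mean
    single-impact local survival; the penumbra expectation is evaluated in
    closed form via the Gamma moment-generating function.  Saturates at the
    geometric bound pi*RVs^2/(C_GY*LET) as <S_L1> -> 0.  For the reference
    radiation the local linear response alpha_p * eta is returned.
    """
    geom = cell.geom
    if q.is_reference:
        return cell.alpha_p * cell.eta
    f_core = mean_elf(cell.elf, q)
    core_term = math.exp(-(geom.Vc / geom.Vs) * f_core)
    a = cell.alpha_p * geom.Vp / geom.Vs
    if q.Zp_mean <= 0:
        pen_term = 1.0
    elif q.deterministic:
        pen_term = math.exp(-a * q.Zp_mean)
    else:
        _, kp = _gamma_shapes(q, geom)
        pen_term = (1.0 + a * q.Zp_mean / kp) ** (-kp)
    s_l1 = core_term * pen_term
    return math.pi * geom.RVs**2 * (1.0 - s_l1) / (C_GY * q.ion.let)


def lq_fit(curve: SurvivalCurve, dmax: float) -> LQCoefficients:
    """Weighted least-squares fit of -ln S on (D, D^2), coefficients
    clipped at zero (non-negative least squares)."""
    mask = (curve.doses > 0) & (curve.doses <= dmax)
    if mask.sum() < 4:
        raise ValueError(f"need >= 4 dose points in (0, {dmax}] Gy, got {mask.sum()}")
    d = curve.doses[mask]
    s = curve.mean_survival[mask]
    se = curve.mc_stderr[mask]
    if np.any(s <= 0):
        raise ValueError("survival must be > 0 for the log-linear fit")
    y = -np.log(s)
    if np.max(np.abs(y)) < 1e-12:
        raise ValueError("degenerate fit: survival is 1 at all doses")
    var = np.where(se > 0, (se / s) ** 2, np.nan)
    if np.all(np.isnan(var)):
        w = np.ones_like(y)
    else:
        w = 1.0 / np.where(np.isnan(var), np.nanmin(var), var)
    x = np.column_stack([d, d**2])
    sw = np.sqrt(w)
    coef, _ = nnls(x * sw[:, None], y * sw)
    xtwx = x.T @ (w[:, None] * x)
    try:
        cov = np.linalg.inv(xtwx)
        if np.all(np.isnan(var)) or np.all(se == 0):
            resid = y - x @ coef
            cov = cov * float(resid @ (w * resid)) / max(len(y) - 2, 1)
        a_se, b_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        a_se = b_se = None
    return LQCoefficients(float(coef[0]), float(coef[1]), a_se, b_se)


def dose_at_survival(lq: LQCoefficients, level: float) -> float:
    """Dose (Gy) at which the LQ survival reaches ``level``."""
    if not (0.0 < level < 1.0):
        raise ValueError(f"survival level must be in (0, 1), got {level}")
    if lq.alpha + lq.beta <= 0:
        raise ValueError("alpha + beta must be > 0")
    ln = -math.log(level)
    # stable form of the positive quadratic root (no cancellation as beta -> 0)
    return 2.0 * ln / (lq.alpha + math.sqrt(lq.alpha**2 + 4.0 * lq.beta * ln))


# ---------------------------------------------------------------------------
# Calibration front-end
# ---------------------------------------------------------------------------


def calibrate(
    cell: CellLineParams,
    d_cal: float = 2.0,
    n_mc: int = 100_000,
    seed: int = 0,
) -> CellLineParams:
    """Return a copy of ``cell`` with Cnorm calibrated against the
    reference radiation at ``d_cal`` (default the 2 Gy SF2 anchor)."""
    cnorm = ge.calibrate_cnorm(cell, d_cal=d_cal, n_mc=n_mc, seed=seed)
    return replace(cell, global_params=replace(cell.global_params, Cnorm=cnorm))
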