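"""Radiation-quality tables: the physical/chemical inputs of the NanOx model.

One "radiation quality" is an ion species at one energy (or the reference
photon radiation) characterized by everything the survival engine needs per
radiation impact:

* the distribution of restricted specific energy ``z`` (Gy) scored in a
  nanometric target tossed uniformly inside the track-core volume,
* the mean restricted specific energies deposited per impact in the core
  (``Zc_mean``) and penumbra (``Zp_mean``) regions of the sensitive volume,
* tabulated hydroxyl-radical yield ratios ``G/Gr`` versus time for the core
  and penumbra, and
* the restricted-to-total specific-energy ratio ``eta``.

The tables normally produced by dedicated track-structure / radiolysis
Monte Carlo codes are emulated here by a lightweight amorphous-track
surrogate: a flat radial dose core of 10 nm radius and a 1/r^2 penumbra
truncated at an energy-dependent radius, discretized into Poisson-sampled
40 eV energy-transfer points whose line density is normalized so that the
restricted energy per unit path equals ``eta * LET``.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "C_GY",
    "E0_KEV",
    "IonSpec",
    "GeometrySpec",
    "RadiationQuality",
    "QualityTableError",
    "surrogate_quality",
    "reference_quality",
    "yield_ratio_at",
    "read_quality_table",
    "write_quality_table",
]

# ---------------------------------------------------------------------------
# Physical constants and surrogate conventions
# ---------------------------------------------------------------------------

#: dose conversion factor: D [Gy] = C_GY * LET [keV/um] * fluence [um^-2]
C_GY = 0.1602

#: energy carried by one discrete energy-transfer point (keV); 40 eV
E0_KEV = 0.040

#: flat-core radius of the radial dose profile (um); 10 nm
RC_UM = 0.010

#: rmax(E) = clip(RMAX_COEF * E^RMAX_POW, RMAX_MIN, RMAX_CAP) um, E in MeV/u.
#: The cap keeps the penumbra inside the smallest sensitive volume studied
#: (radius 4.9 um) so that the full restricted energy eta*LET*L is scored.
RMAX_COEF = 0.062
RMAX_POW = 1.7
RMAX_CAP_UM = 4.5
RMAX_MIN_UM = 0.1

#: histogram support: an explicit zero bin plus 256 log-spaced bins 1..1e7 Gy
_N_LOG_BINS = 256
_Z_LO, _Z_HI = 1.0, 1.0e7

#: yield-ratio surrogate time grid (s)
_T_GRID = np.logspace(-12.0, -7.0, 26)

SCHEMA_VERSION = "1"

_REFERENCE_PARTICLES = frozenset({"photon", "photons", "reference"})


class QualityTableError(ValueError):
    """Schema or invariant violation in a radiation-quality table."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IonSpec:
    """One radiation type: particle label, energy (MeV/u) and LET (keV/um)."""

    particle: str
    energy: float
    let: float

    def __post_init__(self) -> None:
        if not self.energy > 0:
            raise ValueError(f"energy must be > 0, got {self.energy}")
        if not self.let > 0:
            raise ValueError(f"LET must be > 0, got {self.let}")

    @property
    def is_reference(self) -> bool:
        return self.particle.lower() in _REFERENCE_PARTICLES


@dataclass(frozen=True)
class GeometrySpec:
    """Sensitive-volume and track-core geometry.

    The sensitive volume is a cylinder of radius ``RVs`` (um) and length
    ``LVs`` (um) along the beam axis.  The track core is a square
    parallelepiped of side ``core_side`` (um, default 0.1) centred on the
    ion path; nanometric targets are cylinders of radius ``RVt`` and length
    ``LVt`` (nm, both fixed at 10) with axis parallel to the beam.
    """

    RVs: float
    LVs: float
    core_side: float = 0.1
    RVt_nm: float = 10.0
    LVt_nm: float = 10.0

    def __post_init__(self) -> None:
        for name in ("RVs", "LVs", "core_side", "RVt_nm", "LVt_nm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.Vc > self.Vs:
            raise ValueError("core volume exceeds the sensitive volume")

    @property
    def Vs(self) -> float:
        """Sensitive volume (um^3)."""
        return math.pi * self.RVs**2 * self.LVs

    @property
    def Vc(self) -> float:
        """Core intersection volume (um^3)."""
        return self.core_side**2 * self.LVs

    @property
    def Vp(self) -> float:
        """Penumbra volume (um^3)."""
        return self.Vs - self.Vc

    @property
    def Vt(self) -> float:
        """Nanometric target volume (um^3)."""
        r = self.RVt_nm * 1e-3
        return math.pi * r**2 * (self.LVt_nm * 1e-3)


@dataclass
class RadiationQuality:
    """Per-impact physical and chemical observables for one radiation quality.

    ``z_bin_low``/``z_bin_high``/``z_prob`` give the single-impact histogram
    of restricted specific energy in one nanometric target tossed in the
    core.  ``Zc_mean`` / ``Zp_mean`` are per-impact means over the core
    intersection and penumbra volumes of the geometry the table was
    generated for (recorded in ``gen_RVs`` / ``gen_LVs``).
    """

    ion: IonSpec
    z_bin_low: np.ndarray
    z_bin_high: np.ndarray
    z_prob: np.ndarray
    Zc_mean: float
    Zp_mean: float
    yield_T: np.ndarray
    yield_core: np.ndarray
    yield_pen: np.ndarray
    eta: float = 0.8
    e0_kev: float = E0_KEV
    seed: int = 0
    gen_RVs: float = 7.0
    gen_LVs: float = 1.0
    deterministic: bool = False
    warnings_: tuple = ()

    def __post_init__(self) -> None:
        self.z_bin_low = np.asarray(self.z_bin_low, dtype=float)
        self.z_bin_high = np.asarray(self.z_bin_high, dtype=float)
        self.z_prob = np.asarray(self.z_prob, dtype=float)
        self.yield_T = np.asarray(self.yield_T, dtype=float)
        self.yield_core = np.asarray(self.yield_core, dtype=float)
        self.yield_pen = np.asarray(self.yield_pen, dtype=float)
        self.validate()

    def validate(self) -> None:
        if np.any(self.z_prob < 0):
            raise QualityTableError("z_hist: negative probability")
        if abs(self.z_prob.sum() - 1.0) > 1e-9:
            raise QualityTableError(
                f"z_hist: probabilities sum to {self.z_prob.sum():.12g}, not 1"
            )
        if np.any(self.z_bin_low < 0) or np.any(self.z_bin_high < self.z_bin_low):
            raise QualityTableError("z_hist: invalid bin edges")
        if self.Zc_mean < 0 or self.Zp_mean < 0:
            raise QualityTableError("moments: negative mean specific energy")
        if not (0.0 < self.eta <= 1.0):
            raise QualityTableError(f"eta must be in (0, 1], got {self.eta}")
        if np.any(self.yield_core <= 0) or np.any(self.yield_pen <= 0):
            raise QualityTableError("yields: ratios must be > 0")
        if len(self.yield_T) > 1 and np.any(np.diff(self.yield_T) <= 0):
            raise QualityTableError("yields: time grid not strictly increasing")

    @property
    def is_reference(self) -> bool:
        return self.ion.is_reference

    @property
    def z_values(self) -> np.ndarray:
        """Representative z per bin (geometric mean of edges; 0 for the zero bin)."""
        lo, hi = self.z_bin_low, self.z_bin_high
        out = np.zeros_like(lo)
        pos = lo > 0
        out[pos] = np.sqrt(lo[pos] * hi[pos])
        deg = (lo == hi)
        out[deg] = lo[deg]
        # zero-low bins with positive high edge: arithmetic midpoint
        zl = (lo == 0) & (hi > 0)
        out[zl] = 0.0
        return out


# ---------------------------------------------------------------------------
# Yield-ratio surrogate
# ---------------------------------------------------------------------------


def _g_infinity(let: float) -> float:
    """Asymptotic OH-yield ratio G/Gr; decreases with LET (denser tracks
    recombine more)."""
    return 0.3 + 0.7 / (1.0 + let / 100.0)


def _tau_recomb(let: float) -> float:
    """Recombination time constant (s); faster for denser tracks."""
    return 3.0e-9 / (1.0 + let / 50.0)


def _yield_curve(let: float, t: np.ndarray) -> np.ndarray:
    g = _g_infinity(let)
    tau = _tau_recomb(let)
    return g + (1.0 - g) * np.exp(-t / tau)


# ---------------------------------------------------------------------------
# Surrogate track generator
# ---------------------------------------------------------------------------


def _rmax_um(energy_mev_u: float) -> float:
    return float(np.clip(RMAX_COEF * energy_mev_u**RMAX_POW, RMAX_MIN_UM, RMAX_CAP_UM))


def _sample_radii(n: int, rmax: float, rng: np.random.Generator) -> np.ndarray:
    """Sample radial distances from the amorphous radial energy profile:
    flat core (r < RC_UM), 1/r^2 penumbra truncated at rmax."""
    if rmax <= RC_UM:
        return RC_UM * np.sqrt(rng.random(n))
    big_l = math.log(rmax / RC_UM)
    f_flat = 1.0 / (1.0 + 2.0 * big_l)
    u = rng.random(n)
    in_flat = rng.random(n) < f_flat
    r = np.empty(n)
    r[in_flat] = RC_UM * np.sqrt(u[in_flat])
    r[~in_flat] = RC_UM * np.exp(big_l * u[~in_flat])
    return r


def _hist_edges() -> tuple[np.ndarray, np.ndarray]:
    edges = np.concatenate([[0.0], np.logspace(math.log10(_Z_LO), math.log10(_Z_HI), _N_LOG_BINS + 1)])
    return edges[:-1], edges[1:]


def surrogate_quality(
    ion: IonSpec,
    geom: GeometrySpec,
    n_tracks: int = 256,
    n_targets_per_track: int = 128,
    seed: int = 0,
    eta: float = 0.8,
    rmax_um: float | None = None,
) -> RadiationQuality:
    """Generate a radiation-quality table with the amorphous-track surrogate.

    Each of ``n_tracks`` tracks crosses the sensitive volume parallel to its
    axis.  The number of 40 eV transfer points per track is Poisson with
    mean ``eta * LET * LVs / E0``, so the expected restricted energy per
    impact is conserved exactly: ``E[Zc*Vc + Zp*Vp] = eta * C_GY * LET * LVs``.
    Nanometric targets are tossed uniformly in the core parallelepiped and
    score the transfer points they enclose (periodic wrap along the beam
    axis avoids end effects).

    Parameters
    ----------
    rmax_um:
        Override of the penumbra truncation radius (testing hook; e.g. a
        value below ``core_side/2`` confines all energy to the core).
    """
    if n_tracks < 1 or n_targets_per_track < 1:
        raise ValueError("n_tracks and n_targets_per_track must be >= 1")
    if not (0.0 < eta <= 1.0):
        raise ValueError(f"eta must be in (0, 1], got {eta}")
    rng = np.random.default_rng(seed)
    rmax = _rmax_um(ion.energy) if rmax_um is None else float(rmax_um)
    if rmax <= 0:
        raise ValueError("rmax must be > 0")

    half = geom.core_side / 2.0
    rvt = geom.RVt_nm * 1e-3
    lvt_half = geom.LVt_nm * 1e-3 / 2.0
    lam = eta * ion.let * geom.LVs / E0_KEV  # mean transfer points per track

    e_core_kev = 0.0
    e_total_kev = 0.0
    z_samples: list[np.ndarray] = []

    # candidate radius for target capture: farthest prism corner + target radius
    r_cand = half * math.sqrt(2.0) + rvt

    for _ in range(n_tracks):
        n_pts = rng.poisson(lam)
        e_total_kev += n_pts * E0_KEV
        if n_pts == 0:
            z_samples.append(np.zeros(n_targets_per_track))
            continue
        r = _sample_radii(n_pts, rmax, rng)
        phi = rng.random(n_pts) * 2.0 * math.pi
        x = r * np.cos(phi)
        y = r * np.sin(phi)
        in_core = (np.abs(x) <= half) & (np.abs(y) <= half)
        e_core_kev += in_core.sum() * E0_KEV

        # nanotarget tossing confined to the core prism
        near = r <= r_cand
        xs, ys = x[near], y[near]
        zs = rng.random(near.sum()) * geom.LVs
        order = np.argsort(zs)
        xs, ys, zs = xs[order], ys[order], zs[order]

        tx = rng.uniform(-half, half, n_targets_per_track)
        ty = rng.uniform(-half, half, n_targets_per_track)
        tz = rng.random(n_targets_per_track) * geom.LVs
        counts = np.zeros(n_targets_per_track)
        if len(zs):
            for j in range(n_targets_per_track):
                # axial window with periodic wrap
                zj = tz[j]
                lo, hi = zj - lvt_half, zj + lvt_half
                i0, i1 = np.searchsorted(zs, (lo, hi))
                sel_x, sel_y = xs[i0:i1], ys[i0:i1]
                if lo < 0.0:
                    i0w = np.searchsorted(zs, lo + geom.LVs)
                    sel_x = np.concatenate([sel_x, xs[i0w:]])
                    sel_y = np.concatenate([sel_y, ys[i0w:]])
                if hi > geom.LVs:
                    i1w = np.searchsorted(zs, hi - geom.LVs)
                    sel_x = np.concatenate([sel_x, xs[:i1w]])
                    sel_y = np.concatenate([sel_y, ys[:i1w]])
                if len(sel_x):
                    d2 = (sel_x - tx[j]) ** 2 + (sel_y - ty[j]) ** 2
                    counts[j] = np.count_nonzero(d2 <= rvt**2)
        z_samples.append(counts * E0_KEV * C_GY / geom.Vt)

    z_all = np.concatenate(z_samples)
    warns: list[str] = []
    if z_all.size < 100:
        msg = f"z_hist built from only {z_all.size} target samples (< 100)"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)

    lo_edges, hi_edges = _hist_edges()
    edges = np.concatenate([lo_edges, [hi_edges[-1]]])
    counts, _ = np.histogram(np.clip(z_all, 0.0, _Z_HI * (1 - 1e-12)), bins=edges)
    prob = counts / counts.sum()

    zc_mean = C_GY * (e_core_kev / n_tracks) / geom.Vc
    zp_mean = C_GY * ((e_total_kev - e_core_kev) / n_tracks) / geom.Vp

    return RadiationQuality(
        ion=ion,
        z_bin_low=lo_edges,
        z_bin_high=hi_edges,
        z_prob=prob,
        Zc_mean=zc_mean,
        Zp_mean=zp_mean,
        yield_T=_T_GRID.copy(),
        yield_core=_yield_curve(ion.let, _T_GRID),
        yield_pen=_yield_curve(0.1 * ion.let, _T_GRID),
        eta=eta,
        seed=seed,
        gen_RVs=geom.RVs,
        gen_LVs=geom.LVs,
        warnings_=tuple(warns),
    )


def reference_quality(eta: float = 0.8, geom: GeometrySpec | None = None) -> RadiationQuality:
    """Quality table for the reference photon radiation (Co-60-like).

    Photon impacts have no track core: the core contribution is zero and
    the OH-yield ratio is identically one at all times.
    """
    geom = geom or GeometrySpec(RVs=7.0, LVs=1.0)
    lo_edges, hi_edges = _hist_edges()
    prob = np.zeros(len(lo_edges))
    prob[0] = 1.0
    return RadiationQuality(
        ion=IonSpec("photon", 1.25, 0.3),
        z_bin_low=lo_edges,
        z_bin_high=hi_edges,
        z_prob=prob,
        Zc_mean=0.0,
        Zp_mean=0.0,
        yield_T=_T_GRID.copy(),
        yield_core=np.ones_like(_T_GRID),
        yield_pen=np.ones_like(_T_GRID),
        eta=eta,
        gen_RVs=geom.RVs,
        gen_LVs=geom.LVs,
    )


def adapt_quality(q: RadiationQuality, geom: GeometrySpec) -> RadiationQuality:
    """Rescale a table's penumbra moment to a different sensitive volume.

    The penumbra energy per impact is geometry-independent (the truncated
    penumbra is fully contained), so ``Zp_mean`` scales as the inverse of
    the penumbra volume; ``Zc_mean`` and the nanotarget histogram are
    unchanged.  Changing ``LVs`` rescales deposited energy and volumes
    proportionally, leaving both specific energies invariant.
    """
    if q.is_reference:
        return q
    vp_gen = (math.pi * q.gen_RVs**2 - geom.core_side**2) * q.gen_LVs
    scale = (vp_gen / q.gen_LVs) / (geom.Vp / geom.LVs)
    if abs(scale - 1.0) < 1e-12:
        return q
    return replace(q, Zp_mean=q.Zp_mean * scale, gen_RVs=geom.RVs, gen_LVs=geom.LVs)


# ---------------------------------------------------------------------------
# Yield-ratio lookup
# ---------------------------------------------------------------------------


def yield_ratio_at(q: RadiationQuality, t: float, region: str = "core") -> float:
    """OH-yield ratio G/Gr at time ``t`` (s), log-time linear interpolation.

    The reference radiation returns exactly 1 at any time.  No
    extrapolation: ``t`` outside the tabulated grid raises ValueError.
    """
    if q.is_reference:
        return 1.0
    if region not in ("core", "penumbra"):
        raise ValueError(f"region must be 'core' or 'penumbra', got {region!r}")
    grid = q.yield_T
    if not (grid[0] <= t <= grid[-1]):
        raise ValueError(
            f"T={t:g} s outside tabulated grid [{grid[0]:g}, {grid[-1]:g}] s"
        )
    vals = q.yield_core if region == "core" else q.yield_pen
    return float(np.interp(math.log(t), np.log(grid), vals))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_META_KEYS = ("particle", "energy_MeV_u", "LET_keV_um", "eta", "seed", "schema_version")
_COLUMNS = [
    "section",
    "bin_low_Gy",
    "bin_high_Gy",
    "probability",
    "Zc_mean_Gy",
    "Zp_mean_Gy",
    "T_s",
    "ratio_core",
    "ratio_pen",
]


def write_quality_table(q: RadiationQuality, path) -> None:
    """Write a radiation-quality table as commented-header CSV."""
    meta = {
        "particle": q.ion.particle,
        "energy_MeV_u": repr(q.ion.energy),
        "LET_keV_um": repr(q.ion.let),
        "eta": repr(q.eta),
        "seed": q.seed,
        "schema_version": SCHEMA_VERSION,
        "e0_keV": repr(q.e0_kev),
        "gen_RVs_um": repr(q.gen_RVs),
        "gen_LVs_um": repr(q.gen_LVs),
        "deterministic": int(q.deterministic),
    }
    for i, w in enumerate(q.warnings_):
        meta[f"warning_{i}"] = w

    rows = []
    for lo, hi, p in zip(q.z_bin_low, q.z_bin_high, q.z_prob):
        rows.append({"section": "z_hist", "bin_low_Gy": lo, "bin_high_Gy": hi, "probability": p})
    rows.append({"section": "moments", "Zc_mean_Gy": q.Zc_mean, "Zp_mean_Gy": q.Zp_mean})
    for t, rc, rp in zip(q.yield_T, q.yield_core, q.yield_pen):
        rows.append({"section": "yields", "T_s": t, "ratio_core": rc, "ratio_pen": rp})
    frame = pd.DataFrame(rows, columns=_COLUMNS)

    buf = io.StringIO()
    for k, v in meta.items():
        buf.write(f"# {k}={v}\n")
    frame.to_csv(buf, index=False, float_format="%.17g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_quality_table(path) -> RadiationQuality:
    """Read a radiation-quality table written by :func:`write_quality_table`."""
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
            else:
                body_lines.append(line)
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise QualityTableError(f"missing metadata keys: {missing}")
    if meta["schema_version"] != SCHEMA_VERSION:
        raise QualityTableError(
            f"unsupported schema_version {meta['schema_version']!r}"
        )
    frame = pd.read_csv(io.StringIO("".join(body_lines)), float_precision="round_trip")
    for col in _COLUMNS:
        if col not in frame.columns:
            raise QualityTableError(f"missing column {col!r}")

    zh = frame[frame["section"] == "z_hist"]
    mo = frame[frame["section"] == "moments"]
    yl = frame[frame["section"] == "yields"]
    if zh.empty or mo.empty or yl.empty:
        raise QualityTableError("table must contain z_hist, moments and yields sections")

    warns = tuple(v for k, v in sorted(meta.items()) if k.startswith("warning_"))
    try:
        return RadiationQuality(
            ion=IonSpec(meta["particle"], float(meta["energy_MeV_u"]), float(meta["LET_keV_um"])),
            z_bin_low=zh["bin_low_Gy"].to_numpy(),
            z_bin_high=zh["bin_high_Gy"].to_numpy(),
            z_prob=zh["probability"].to_numpy(),
            Zc_mean=float(mo["Zc_mean_Gy"].iloc[0]),
            Zp_mean=float(mo["Zp_mean_Gy"].iloc[0]),
            yield_T=yl["T_s"].to_numpy(),
            yield_core=yl["ratio_core"].to_numpy(),
            yield_pen=yl["ratio_pen"].to_numpy(),
            eta=float(meta["eta"]),
            e0_kev=float(meta.get("e0_keV", E0_KEV)),
            seed=int(meta["seed"]),
            gen_RVs=float(meta.get("gen_RVs_um", 7.0)),
            gen_LVs=float(meta.get("gen_LVs_um", 1.0)),
            deterministic=bool(int(meta.get("deterministic", 0))),
            warnings_=warns,
        )
    except ValueError as exc:
        raise QualityTableError(str(exc)) from exc
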