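"""Cell-line configuration files, packaged fixtures, and run manifests.

Cell configs are plain ``key = value`` text files.  Recognized keys:

    name, RVs_um, LVs_um, z0_Gy, sigma_Gy, h, betar_Gy2,
    alphar_Gy1 (optional; else derived from SF2), SF2 (optional),
    betaG_Gy2 (optional; cross-checked against betar/eta^2),
    eta, TRCE_s, penumbra_alpha_rescale (optional bool)

Packaged fixtures reproduce the standard parameter sets of the three
modeled cell lines (HSG human salivary-gland tumor, V79 Chinese-hamster
lung fibroblast, CHO-K1 Chinese-hamster ovary) plus the machine-readable
sensitivity-study tables (geometry variations, alpha datasets, ELF fit
outputs, betar variations).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import pandas as pd

from . import global_events as ge
from .engine import CellLineParams
from .local_lethal import ELFParams
from .quality import GeometrySpec, IonSpec

__all__ = [
    "load_cell_config",
    "fixture_path",
    "list_fixtures",
    "load_fixture_cell",
    "let_from_energy",
    "RunManifest",
]

CELL_FIXTURES = ("hsg", "v79", "cho_k1")
TABLE_FIXTURES = (
    "geometry_variations.csv",
    "alpha_datasets.csv",
    "elf_fit_outputs.csv",
    "betar_variations.csv",
)

# ---------------------------------------------------------------------------
# Surrogate LET(E) mapping for fixture ions
# ---------------------------------------------------------------------------

#: carbon stopping surrogate LET = LET_COEF * E^-LET_POW (keV/um, E in MeV/u);
#: other ions scale by the squared charge ratio.  Chosen so that the
#: clinician-oriented minimal datasets' carbon energies fall in the
#: intermediate (55-75) and high (150-200 keV/um) LET windows.
LET_COEF = 1155.0
LET_POW = 0.82

_CHARGE = {
    "proton": 1,
    "protons": 1,
    "helium": 2,
    "carbon": 6,
    "oxygen": 8,
    "neon": 10,
    "argon": 18,
}


def let_from_energy(particle: str, energy_mev_u: float) -> float:
    """Surrogate LET (keV/um) for an ion at a given energy per nucleon."""
    key = particle.lower()
    if key in ("photon", "photons", "reference"):
        return 0.3
    if key not in _CHARGE:
        raise ValueError(f"unknown particle {particle!r}")
    z2 = _CHARGE[key] ** 2
    return LET_COEF * (z2 / 36.0) * energy_mev_u ** (-LET_POW)


def ion_from_energy(particle: str, energy_mev_u: float) -> IonSpec:
    return IonSpec(particle, energy_mev_u, let_from_energy(particle, energy_mev_u))


# ---------------------------------------------------------------------------
# Cell config parsing
# ---------------------------------------------------------------------------

_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def _parse_kv(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed line {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        out[key] = val
    return out


def load_cell_config(path) -> CellLineParams:
    """Load and validate a cell-line config file."""
    kv = _parse_kv(path)
    required = ("RVs_um", "LVs_um", "z0_Gy", "sigma_Gy", "h", "betar_Gy2", "eta")
    missing = [k for k in required if k not in kv]
    if missing:
        raise ValueError(f"{path}: missing keys {missing}")

    eta = float(kv["eta"])
    betar = float(kv["betar_Gy2"])
    geom = GeometrySpec(RVs=float(kv["RVs_um"]), LVs=float(kv["LVs_um"]))
    elf = ELFParams(z0=float(kv["z0_Gy"]), sigma=float(kv["sigma_Gy"]), h=float(kv["h"]))

    if "alphar_Gy1" in kv:
        ref = ge.ReferenceRadiation(
            alphar=float(kv["alphar_Gy1"]),
            betar=betar,
            SF2=float(kv["SF2"]) if "SF2" in kv else None,
        )
    elif "SF2" in kv:
        ref = ge.ReferenceRadiation.from_sf2(float(kv["SF2"]), betar)
    else:
        raise ValueError(f"{path}: need alphar_Gy1 or SF2 to fix the reference response")

    betag = ge.beta_g(betar, eta)
    if "betaG_Gy2" in kv:
        explicit = float(kv["betaG_Gy2"])
        if betag > 0 and abs(explicit - betag) / betag > 0.005:
            raise ValueError(
                f"{path}: betaG_Gy2={explicit} inconsistent with "
                f"betar/eta^2={betag:.6g} (> 0.5%)"
            )
    gp = ge.GlobalParams(betaG=betag, TRCE=float(kv.get("TRCE_s", 1e-11)))
    rescale = _BOOL[kv.get("penumbra_alpha_rescale", "false").lower()]
    return CellLineParams(
        name=kv.get("name", Path(path).stem),
        geom=geom,
        elf=elf,
        ref=ref,
        global_params=gp,
        eta=eta,
        penumbra_alpha_rescale=rescale,
    )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture (cell name like 'hsg' or a table file)."""
    fname = f"{name}.cfg" if name in CELL_FIXTURES else name
    path = resources.files("nanox") / "fixtures" / fname
    with resources.as_file(path) as concrete:
        if not concrete.exists():
            raise FileNotFoundError(f"no packaged fixture {name!r}")
        return concrete


def list_fixtures() -> list[str]:
    return [f"{c}.cfg" for c in CELL_FIXTURES] + list(TABLE_FIXTURES)


def load_fixture_cell(name: str) -> CellLineParams:
    return load_cell_config(fixture_path(name))


def load_fixture_table(name: str) -> pd.DataFrame:
    return pd.read_csv(fixture_path(name), comment="#")


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    seed: int | None
    config_hash: str
    schema_version: str
    outputs: list[str] = field(default_factory=list)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @staticmethod
    def hash_file(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")
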