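import numpy as np
import pytest
from hypothesis import settings

import nanox

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_quality(
    z_points,
    z_probs,
    zc_mean,
    zp_mean,
    let=100.0,
    particle="carbon",
    energy=10.0,
    deterministic=True,
    ratio_core=(1.0, 1.0),
    ratio_pen=(1.0, 1.0),
    eta=0.8,
):
    """Hand-built quality table with degenerate histogram bins at z_points."""
    z_points = np.asarray(z_points, dtype=float)
    return nanox.RadiationQuality(
        ion=nanox.IonSpec(particle, energy, let),
        z_bin_low=z_points,
        z_bin_high=z_points,
        z_prob=np.asarray(z_probs, dtype=float),
        Zc_mean=zc_mean,
        Zp_mean=zp_mean,
        yield_T=np.array([1e-12, 1e-7]),
        yield_core=np.asarray(ratio_core, dtype=float),
        yield_pen=np.asarray(ratio_pen, dtype=float),
        eta=eta,
        deterministic=deterministic,
    )


@pytest.fixture(scope="session")
def hsg_cell():
    return nanox.load_fixture_cell("hsg")


@pytest.fixture(scope="session")
def hsg_calibrated(hsg_cell):
    return nanox.calibrate(hsg_cell, seed=11)


@pytest.fixture(scope="session")
def v79_cell():
    return nanox.load_fixture_cell("v79")


@pytest.fixture(scope="session")
def cho_cell():
    return nanox.load_fixture_cell("cho_k1")


@pytest.fixture(scope="session")
def carbon_quality(hsg_cell):
    """Mid-LET carbon surrogate table (39.1 MeV/u)."""
    ion = nanox.IonSpec("carbon", 39.1, nanox.let_from_energy("carbon", 39.1))
    return nanox.surrogate_quality(
        ion, hsg_cell.geom, n_tracks=192, n_targets_per_track=96, seed=7
    )


@pytest.fixture(scope="session")
def quality_grid(hsg_cell):
    """Small LET grid of carbon surrogate tables keyed by LET."""
    energies = [2.3, 8.5, 21.4, 39.1, 82.6]
    out = {}
    for i, e in enumerate(energies):
        ion = nanox.IonSpec("carbon", e, nanox.let_from_energy("carbon", e))
        out[ion.let] = nanox.surrogate_quality(
            ion, hsg_cell.geom, n_tracks=160, n_targets_per_track=96, seed=100 + i
        )
    return out


@pytest.fixture(scope="session")
def reference_q(hsg_cell):
    return nanox.reference_quality(eta=hsg_cell.eta, geom=hsg_cell.geom)
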