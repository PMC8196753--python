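"""Shared fixtures: models, thermodynamic states, and cached trajectories."""

import numpy as np
import pytest

import physcluster as pc
from physcluster.chem_model import RadialPotential


@pytest.fixture(scope="session")
def thermo300():
    return pc.ThermoState(300.0)


@pytest.fixture(scope="session")
def criterion():
    return pc.ClusterCriterion()


@pytest.fixture(scope="session")
def water_model():
    """Default surrogate: Cl- plus rigid 3-site waters, full coupling."""
    return pc.PotentialModel(
        ion=pc.ion("Cl"), ligand=pc.RigidLigand.rigid_water_3site()
    )


@pytest.fixture(scope="session")
def ideal_water_model():
    """Ligand-ligand coupling switched off (ideal-ligand limit)."""
    return pc.PotentialModel(
        ion=pc.ion("Cl"),
        ligand=pc.RigidLigand.rigid_water_3site(),
        ligand_coupling=0.0,
    )


def make_morse_toy(repulsion: float = 2.0, screening: float = 1.0):
    """Point-ligand toy surface: a shallow Morse ion-ligand well plus a
    bounded exponential ligand-ligand repulsion (no hard core), conditions
    under which the deletion-direction thermal average converges quickly."""
    D, a, r0 = 1.2, 1.2, 3.0
    well = RadialPotential(
        u=lambda r: D * (1 - np.exp(-a * (r - r0))) ** 2 - D,
        du=lambda r: 2 * D * a * (1 - np.exp(-a * (r - r0))) * np.exp(-a * (r - r0)),
    )
    kwargs = {}
    if repulsion > 0:
        kwargs["ligand_ligand_pair"] = RadialPotential(
            u=lambda r: repulsion * np.exp(-r / screening),
            du=lambda r: -repulsion / screening * np.exp(-r / screening),
        )
    return pc.PotentialModel(
        ion=pc.ion("toy"),
        ligand=pc.RigidLigand.point_ligand(charge=0.0, sigma=1.0, epsilon=0.0, mass=18.0),
        ion_ligand_pair=well,
        min_site_distance=1e-6,
        **kwargs,
    )


@pytest.fixture(scope="session")
def morse_toy_model():
    return make_morse_toy()


@pytest.fixture(scope="session")
def morse_toy_ideal():
    return make_morse_toy(repulsion=0.0)


@pytest.fixture(scope="session")
def w3_trajectory(water_model):
    """Seeded W3Cl canonical stream at the default cadence (100 frames)."""
    cfg = pc.SamplerConfig(seed=7)
    return pc.run_sampler(3, water_model, cfg)


@pytest.fixture(scope="session")
def w2_trajectory(water_model):
    cfg = pc.SamplerConfig(seed=5)
    return pc.run_sampler(2, water_model, cfg)
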