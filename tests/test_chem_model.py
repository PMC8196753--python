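"""Surrogate potential: pair sums, subsystem energies, rigid-motion invariance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import physcluster as pc
from physcluster.chem_model import (
    COULOMB,
    CoincidentSitesError,
    batch_energy,
    random_quaternions,
)


def pair_loop_energy(model, config):
    """Independent oracle: naive double loop over every intersite pair."""
    lig = model.ligand
    sites = config.all_sites(lig)
    q = list(lig.site_charges)
    lj = list(lig.site_lj)

    def pair(d, qq, lj_a, lj_b):
        sig = 0.5 * (lj_a[0] + lj_b[0])
        eps = np.sqrt(lj_a[1] * lj_b[1])
        e = COULOMB * qq / d
        if eps > 0:
            e += 4 * eps * ((sig / d) ** 12 - (sig / d) ** 6)
        return e

    ion_lj = (model.ion.lj_sigma, model.ion.lj_epsilon)
    e = 0.0
    for k in range(config.n):
        for s in range(lig.n_sites):
            d = np.linalg.norm(sites[k, s] - config.ion_position)
            e += pair(d, model.ion.charge * q[s], ion_lj, lj[s])
    for j in range(config.n):
        for k in range(j + 1, config.n):
            for a in range(lig.n_sites):
                for b in range(lig.n_sites):
                    d = np.linalg.norm(sites[j, a] - sites[k, b])
                    e += model.ligand_coupling * pair(d, q[a] * q[b], lj[a], lj[b])
    return e


def test_bare_ion_energy_is_zero(water_model):
    empty = pc.ClusterConfiguration(np.zeros(3), np.zeros((0, 3)), np.zeros((0, 4)))
    assert pc.total_energy(empty, water_model) == 0.0


def test_point_ligand_pair_sum_matches_hand_written_oracle():
    """A printed n=2 point-ligand configuration against an explicit per-pair sum."""
    lig = pc.RigidLigand.point_ligand(charge=0.3, sigma=3.0, epsilon=0.15, mass=18.0)
    model = pc.PotentialModel(ion=pc.ion("toy"), ligand=lig)
    config = pc.ClusterConfiguration(
        ion_position=[0.1, -0.2, 0.3],
        translations=[[3.2, 0.5, -0.4], [-1.0, 2.9, 1.1]],
        quaternions=[[0, 0, 0, 1], [0, 0, 0, 1]],
    )

    def pair(ra, rb, qq, sig, eps):
        d = np.linalg.norm(np.array(ra) - np.array(rb))
        return COULOMB * qq / d + 4 * eps * ((sig / d) ** 12 - (sig / d) ** 6)

    sig_il = 0.5 * (3.5 + 3.0)
    eps_il = np.sqrt(0.10 * 0.15)
    expected = (
        pair([0.1, -0.2, 0.3], [3.2, 0.5, -0.4], -1.0 * 0.3, sig_il, eps_il)
        + pair([0.1, -0.2, 0.3], [-1.0, 2.9, 1.1], -1.0 * 0.3, sig_il, eps_il)
        + pair([3.2, 0.5, -0.4], [-1.0, 2.9, 1.1], 0.09, 3.0, 0.15)
    )
    assert pc.total_energy(config, model) == pytest.approx(expected, abs=1e-10)


@pytest.mark.parametrize("coupling", [0.0, 0.37, 1.0])
def test_water_energy_matches_double_loop_oracle(coupling):
    model = pc.PotentialModel(
        ion=pc.ion("Cl"),
        ligand=pc.RigidLigand.rigid_water_3site(),
        ligand_coupling=coupling,
    )
    config = pc.random_configuration(3, pc.ClusterCriterion(), seed=11)
    assert pc.total_energy(config, model) == pytest.approx(
        pair_loop_energy(model, config), rel=1e-12
    )


def test_subsystem_energy_identity_and_empty(water_model):
    config = pc.random_configuration(3, pc.ClusterCriterion(), seed=2)
    assert pc.subsystem_energy(config, range(3), water_model) == pytest.approx(
        pc.total_energy(config, water_model), rel=1e-14
    )
    assert pc.subsystem_energy(config, [], water_model) == 0.0
    # single kept ligand equals the ion-ligand pair energy alone
    assert pc.subsystem_energy(config, [1], water_model) == pytest.approx(
        water_model.ion_ligand_energy(config, 1), rel=1e-14
    )
    with pytest.raises(IndexError):
        pc.subsystem_energy(config, [5], water_model)


def test_rigid_motion_invariance(water_model):
    """Total energy is invariant under global translations and rotations."""
    rng = np.random.default_rng(0)
    config = pc.random_configuration(3, pc.ClusterCriterion(), seed=4)
    e0 = pc.total_energy(config, water_model)
    for _ in range(100):
        shift = rng.uniform(-20, 20, 3)
        rot = Rotation.from_quat(random_quaternions(rng, 1)[0])
        moved = pc.ClusterConfiguration(
            rot.apply(config.ion_position) + shift,
            rot.apply(config.translations) + shift,
            (rot * Rotation.from_quat(config.quaternions)).as_quat(),
        )
        assert pc.total_energy(moved, water_model) == pytest.approx(e0, abs=1e-9)


def test_ideal_ligand_mode_is_exactly_additive(ideal_water_model):
    config = pc.random_configuration(4, pc.ClusterCriterion(), seed=8)
    total = pc.total_energy(config, ideal_water_model)
    parts = sum(
        pc.subsystem_energy(config, [k], ideal_water_model) for k in range(4)
    )
    assert total == parts  # exact: no ligand-ligand terms at all


def test_coincident_sites_raise_with_pair_identification():
    lig = pc.RigidLigand.point_ligand()
    model = pc.PotentialModel(ion=pc.ion("toy"), ligand=lig)
    config = pc.ClusterConfiguration(
        np.zeros(3), [[0.05, 0.0, 0.0]], [[0, 0, 0, 1]]
    )
    with pytest.raises(CoincidentSitesError, match="ion"):
        pc.total_energy(config, model)


def test_random_configuration_determinism_and_criterion():
    crit = pc.ClusterCriterion(r_ion_ligand=4.5)
    a = pc.random_configuration(3, crit, seed=1)
    b = pc.random_configuration(3, crit, seed=1)
    np.testing.assert_array_equal(a.translations, b.translations)
    np.testing.assert_array_equal(a.quaternions, b.quaternions)
    c5 = pc.random_configuration(5, crit, seed=9)
    assert np.all(np.linalg.norm(c5.translations, axis=1) <= 4.5)
    c0 = pc.random_configuration(0, crit, seed=0)
    assert c0.n == 0 and np.allclose(c0.ion_position, 0)


def test_unit_quaternion_invariant_enforced():
    with pytest.raises(ValueError, match="unit quaternion"):
        pc.ClusterConfiguration(np.zeros(3), [[3, 0, 0]], [[0, 0, 0, 1.01]])


def test_batch_energy_matches_scalar_path(water_model):
    rng = np.random.default_rng(3)
    configs = [
        pc.random_configuration(2, pc.ClusterCriterion(), rng=rng) for _ in range(6)
    ]
    trans = np.stack([c.translations for c in configs])
    quats = np.stack([c.quaternions for c in configs])
    batched = batch_energy(water_model, trans, quats)
    scalar = [pc.total_energy(c, water_model) for c in configs]
    np.testing.assert_allclose(batched, scalar, rtol=1e-12)
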