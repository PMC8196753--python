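"""Harmonic machinery: optimisation, Hessians, normal modes, RRHO constants."""

import math

import numpy as np
import pytest
from scipy.optimize import golden
from scipy.spatial.transform import Rotation

import physcluster as pc
from physcluster import rrho
from physcluster.chem_model import RadialPotential, random_quaternions
from physcluster.constants import wavenumber_from_eigenvalue
from physcluster.oracle import ion_ligand_radial_potential, k1_quadrature

from conftest import make_morse_toy


def _harmonic_model(k, r0=2.5):
    return pc.PotentialModel(
        ion=pc.ion("toy"),
        ligand=pc.RigidLigand.point_ligand(charge=0.0, sigma=1.0, epsilon=0.0, mass=18.0),
        ion_ligand_pair=RadialPotential(
            u=lambda r: 0.5 * k * (r - r0) ** 2, du=lambda r: k * (r - r0)
        ),
    )


def _short_run(model, n, seed=3):
    cfg = pc.SamplerConfig(seed=seed, n_sweeps=600, equilibration_sweeps=200,
                           sample_interval=10)
    return pc.run_sampler(n, model, cfg)


# ----------------------------------------------------------------- optimiser


def test_point_ligand_optimum_matches_golden_section(morse_toy_model):
    """The optimiser lands on the 1-D pair-potential minimum located
    independently by golden-section search."""
    traj = _short_run(morse_toy_model, 1)
    best = rrho.multi_start_optimize(traj, morse_toy_model, n_starts=8)
    r_opt = np.linalg.norm(best.config.translations[0] - best.config.ion_position)
    u = lambda r: float(ion_ligand_radial_potential(morse_toy_model, np.array([r]))[0])
    r_star = golden(u, brack=(2.0, 3.0, 4.4))
    assert r_opt == pytest.approx(r_star, abs=1e-5)
    assert best.energy == pytest.approx(u(r_star), abs=1e-10)
    assert best.gradient_norm < 1e-6


def test_optimizer_fixed_point(morse_toy_model):
    """An already-optimal structure is returned unchanged."""
    traj = _short_run(morse_toy_model, 1)
    best = rrho.multi_start_optimize(traj, morse_toy_model, n_starts=8)

    class _T:  # minimal trajectory stub holding the optimal frame
        frames = [best.config]

    again = rrho.multi_start_optimize(_T(), morse_toy_model, n_starts=1)
    assert again.gradient_norm < 1e-6
    assert again.energy == pytest.approx(best.energy, abs=1e-12)
    np.testing.assert_allclose(
        again.config.translations, best.config.translations, atol=1e-8
    )


def test_w5_optimization_finds_split_shell():
    """Optimising crowded W5F clusters pushes a water into a distinct outer
    shell in at least one converged structure (the split-shell / 4+1 motif),
    classified directly on the optimiser's own output distances."""
    model = pc.PotentialModel(ion=pc.ion("F"), ligand=pc.RigidLigand.rigid_water_3site())
    t1 = _short_run(model, 1, seed=2)
    r_inner = np.linalg.norm(
        rrho.multi_start_optimize(t1, model, n_starts=4).config.translations[0]
    )
    cfg = pc.SamplerConfig(seed=23, n_sweeps=900, equilibration_sweeps=300,
                           sample_interval=10)
    traj = pc.run_sampler(5, model, cfg)
    split = 0
    for i in np.linspace(0, len(traj.frames) - 1, 8).astype(int):
        s = rrho._optimize_single(traj.frames[i], model, 1e-6, int(i))
        if s is None:
            continue
        d = np.linalg.norm(s.config.translations - s.config.ion_position, axis=1)
        split += int((d > r_inner + 0.8).sum() >= 1)
    assert split >= 1


# ------------------------------------------------------------------- hessian


def test_hessian_exact_for_quadratic():
    k = 7.3
    f = lambda x: 0.5 * k * float(x @ x)
    H = rrho.numerical_hessian(f, np.array([0.3, -0.2, 0.9]), step=1e-3)
    np.testing.assert_allclose(H, k * np.eye(3), rtol=1e-6, atol=1e-6)


def test_hessian_translation_sum_rule(water_model):
    """Force-constant sum rule: per-coordinate rows summed over the
    translational blocks of every body vanish (translation invariance)."""
    traj = _short_run(water_model, 2, seed=5)
    best = rrho.multi_start_optimize(traj, water_model, n_starts=4)
    dof = best.dof
    x0 = dof.pack(best.config)
    H = rrho.numerical_hessian(dof.energy_fn(water_model), x0, step=1e-4)
    # columns of global translation: ion + each ligand COM along axis i
    for i in range(3):
        v = np.zeros(len(x0))
        v[i] = 1.0
        for kk in range(2):
            v[3 + kk * 6 + i] = 1.0
        assert np.abs(H @ v).max() < 1e-4


def test_morse_curvature_closed_form():
    d_e, a, r0 = 5.0, 1.3, 2.0
    f = lambda x: d_e * (1 - math.exp(-a * (float(x[0]) - r0))) ** 2
    H = rrho.numerical_hessian(f, np.array([r0]), step=1e-4)
    assert H[0, 0] == pytest.approx(2 * d_e * a**2, rel=1e-5)


# -------------------------------------------------------------- normal modes


def test_diatomic_frequency_closed_form():
    m1, m2, k = 4.0, 12.0, 50.0
    mu = m1 * m2 / (m1 + m2)
    H = np.array([[k, -k], [-k, k]])
    modes = rrho.normal_modes(H, np.array([m1, m2]), n_zero=1)
    assert len(modes.frequencies) == 1
    assert modes.frequencies[0] == pytest.approx(
        wavenumber_from_eigenvalue(k / mu), rel=1e-6
    )


def test_free_atom_has_no_retained_modes():
    modes = rrho.normal_modes(np.zeros((3, 3)), np.array([12.0] * 3), n_zero=3)
    assert len(modes.frequencies) == 0


def test_retained_mode_count_nonlinear_cluster(water_model):
    """Rigid-body dof minus 6 global zero modes for a nonlinear W2X cluster."""
    traj = _short_run(water_model, 2, seed=5)
    best = rrho.multi_start_optimize(traj, water_model, n_starts=4)
    modes = rrho.cluster_normal_modes(best, water_model)
    assert modes.n_zero_modes == 6
    assert len(modes.frequencies) == 3 + 2 * 6 - 6
    assert not modes.has_imaginary
    assert np.all(np.diff(modes.eigenvalues) >= 0)


# ------------------------------------------------------- partition functions


def test_qvib_quantum_classical_ratio_closed_form():
    from physcluster.constants import C_CM_S, KB_J, PLANCK_J_S

    nu, T = 850.0, 300.0
    u = PLANCK_J_S * nu * C_CM_S / (KB_J * T)
    expected = u * math.exp(-u / 2) / (1 - math.exp(-u))
    ratio = rrho.quantum_qvib_factor(nu, T) / rrho.classical_qvib_factor(nu, T)
    assert ratio == pytest.approx(expected, rel=1e-12)


def test_qvib_quantum_approaches_classical_at_high_t():
    """beta h nu = 0.01 => quantum/classical ratio within 1e-3 of 1."""
    from physcluster.constants import C_CM_S, KB_J, PLANCK_J_S

    T = 300.0
    nu = 0.01 * KB_J * T / (PLANCK_J_S * C_CM_S)
    ratio = rrho.quantum_qvib_factor(nu, T) / rrho.classical_qvib_factor(nu, T)
    assert abs(ratio - 1.0) < 1e-3


def test_classical_rrho_k1_converges_to_quadrature(thermo300):
    """Classical-statistics RRHO K_1 approaches the configurational-integral
    oracle as the well stiffens, with decreasing relative error across three
    stiffness decades (and within 1% by k = 100)."""
    errors = []
    crit = pc.ClusterCriterion()
    for k in (1.0, 10.0, 100.0):
        model = _harmonic_model(k)
        traj = _short_run(model, 1, seed=3)
        best = rrho.multi_start_optimize(traj, model, n_starts=6)
        ch = rrho.harmonic_chain([best], model, thermo300, statistics="classical")
        q = k1_quadrature(model, thermo300, crit)
        errors.append(abs(ch.k_n[1] / q.k_n - 1.0))
    assert errors[0] > errors[1] > errors[2]
    assert errors[2] < 0.01


def test_harmonic_chain_k0_is_one(thermo300, morse_toy_model):
    traj = _short_run(morse_toy_model, 1)
    best = rrho.multi_start_optimize(traj, morse_toy_model, n_starts=6)
    ch = rrho.harmonic_chain([best], morse_toy_model, thermo300)
    assert ch.k_n[0] == 1.0
    assert ch.n_max == 1


def test_rrho_k_invariant_under_rigid_rotation(thermo300, morse_toy_model):
    """K_n does not depend on the overall position/orientation of the input."""
    traj = _short_run(morse_toy_model, 1)
    best = rrho.multi_start_optimize(traj, morse_toy_model, n_starts=6)
    ch0 = rrho.harmonic_chain([best], morse_toy_model, thermo300, statistics="classical")
    rot = Rotation.from_quat(random_quaternions(np.random.default_rng(1), 1)[0])
    shift = np.array([5.0, -3.0, 2.0])
    moved_cfg = pc.ClusterConfiguration(
        rot.apply(best.config.ion_position) + shift,
        rot.apply(best.config.translations) + shift,
        (rot * Rotation.from_quat(best.config.quaternions)).as_quat(),
    )
    moved = rrho.OptimizedStructure(
        config=moved_cfg, energy=best.energy, gradient_norm=best.gradient_norm,
        start_index=best.start_index,
        dof=rrho.ClusterDOF.from_config(moved_cfg, morse_toy_model.ligand)[0],
    )
    ch1 = rrho.harmonic_chain([moved], morse_toy_model, thermo300, statistics="classical")
    assert ch1.k_n[1] == pytest.approx(ch0.k_n[1], rel=1e-6)


def test_water_cluster_chain_runs_quantum_and_classical(thermo300, water_model):
    traj = _short_run(water_model, 1, seed=41)
    best = rrho.multi_start_optimize(traj, water_model, n_starts=6)
    ch_q = rrho.harmonic_chain([best], water_model, thermo300, statistics="quantum")
    ch_c = rrho.harmonic_chain([best], water_model, thermo300, statistics="classical")
    # quantum binding is weaker than classical at these frequencies (ZPE)
    assert ch_q.k_n[1] < ch_c.k_n[1]
    assert ch_q.k_n[1] > 0
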