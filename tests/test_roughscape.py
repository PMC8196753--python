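"""Decoupling energies, the exponential step average, and the step-wise chain."""

import math

import numpy as np
import pytest

import physcluster as pc
from physcluster import roughscape as rough
from physcluster.oracle import k1_anchor_from_quadrature, kn_mc_integration

from conftest import make_morse_toy


def _frame(model, n, seed):
    return pc.random_configuration(n, pc.ClusterCriterion(), seed=seed, ligand=model.ligand)


def test_n1_decoupling_vanishes_identically(water_model):
    """For W1X the four decoupling terms cancel exactly on every frame."""
    for seed in range(5):
        frame = _frame(water_model, 1, seed)
        (d,) = rough.decompose_frame(frame, water_model)
        assert d.delta_u == 0.0
        assert d.u_rest == 0.0 and d.u_ion == 0.0


def test_ideal_ligand_decoupling_vanishes(ideal_water_model):
    frame = _frame(ideal_water_model, 3, 3)
    for d in rough.decompose_frame(frame, ideal_water_model):
        assert d.delta_u == 0.0


def test_decoupling_equals_pair_sum_oracle(water_model):
    """With a pairwise-additive surface, dU for ligand k is exactly the
    coupling-scaled sum of its interactions with the other ligands."""
    frame = _frame(water_model, 3, 12)
    decs = rough.decompose_frame(frame, water_model)
    assert len(decs) == 3
    for d in decs:
        k = d.distinguished_ligand
        expected = sum(
            water_model.ligand_coupling * water_model.ligand_pair_energy(frame, k, j)
            for j in range(3)
            if j != k
        )
        assert d.delta_u == pytest.approx(expected, abs=1e-10)


def test_decompose_rejects_bare_ion(water_model):
    empty = pc.ClusterConfiguration(np.zeros(3), np.zeros((0, 3)), np.zeros((0, 4)))
    with pytest.raises(ValueError):
        rough.decompose_frame(empty, water_model)


def _fake_decs(du_values):
    return [
        rough.EnergyDecomposition(
            frame_index=i, distinguished_ligand=0, u_full=du, u_rest=0.0,
            u_single=0.0, u_ion=0.0,
        )
        for i, du in enumerate(du_values)
    ]


def test_step_average_trivial_and_two_point(thermo300):
    sf = rough.step_average(_fake_decs(np.zeros(40)), thermo300, n=2)
    assert sf.mean_exp == 1.0 and sf.cumulant_estimate == pytest.approx(1.0)
    a = 0.9
    sf2 = rough.step_average(_fake_decs([a, -a] * 20), thermo300, n=2)
    assert sf2.mean_exp == pytest.approx(math.cosh(thermo300.beta * a), rel=1e-12)


def test_step_average_lognormal_closed_form(thermo300):
    """i.i.d. normal dU: <e^{beta dU}> -> exp(beta mu + beta^2 sigma^2/2)."""
    rng = np.random.default_rng(2024)
    mu0, sig0 = 0.3, 0.45
    du = rng.normal(mu0, sig0, size=10_000)
    sf = rough.step_average(_fake_decs(du), thermo300, n_blocks=20, n=2)
    beta = thermo300.beta
    exact = math.exp(beta * mu0 + beta**2 * sig0**2 / 2)
    assert abs(sf.mean_exp - exact) < 3 * sf.std_error
    # the Gaussian-model estimate agrees with the direct average here
    assert abs(sf.cumulant_estimate - exact) / exact < 0.05


def test_step_average_jensen_bound(thermo300, w2_trajectory, water_model):
    decs = rough.decompose_trajectory(w2_trajectory, water_model)
    sf = rough.step_average(decs, thermo300, n=2)
    assert sf.mean_exp >= math.exp(thermo300.beta * sf.sample_mean)
    assert sf.n_samples == 2 * len(w2_trajectory)


def test_step_average_rejects_nonfinite(thermo300):
    decs = _fake_decs([0.1, np.inf, 0.2, 0.3])
    with pytest.raises(ValueError, match="non-finite"):
        rough.step_average(decs, thermo300, n=2)


def test_chain_ideal_limit_exact(thermo300):
    """All step factors 1 => K_n = K_1^n/n! exactly (e.g. K_3 = K_1^3/6)."""
    k1 = 10.0
    anchor = rough.K1Anchor(k1, provenance="oracle")
    factors = [
        rough.StepFactor(n=n, mean_exp=1.0, std_error=0.0, n_samples=100,
                         n_blocks=10, sample_mean=0.0, sample_variance=0.0,
                         cumulant_estimate=1.0)
        for n in (2, 3)
    ]
    ch = rough.chain(anchor, factors, thermo300)
    assert ch.k_n[0] == 1.0
    assert ch.k_n[2] == pytest.approx(k1**2 / 2, rel=1e-14)
    assert ch.k_n[3] == pytest.approx(k1**3 / 6, rel=1e-14)


def test_chain_n1_returns_anchor_and_k0(thermo300):
    anchor = rough.K1Anchor(3.5, provenance="experiment")
    ch = rough.chain(anchor, [], thermo300)
    assert ch.k_n.tolist() == [1.0, 3.5]


def test_chain_requires_contiguous_steps(thermo300):
    anchor = rough.K1Anchor(1.0, provenance="oracle")
    sf3 = rough.StepFactor(n=3, mean_exp=1.0, std_error=0.0, n_samples=10,
                           n_blocks=2, sample_mean=0.0, sample_variance=0.0,
                           cumulant_estimate=1.0)
    with pytest.raises(ValueError, match="contiguous"):
        rough.chain(anchor, [sf3], thermo300)


def test_evaluation_counts():
    assert rough.evaluation_count(1, 1) == 4
    assert rough.evaluation_count(2, 10) == 60
    assert rough.evaluation_count(5, 100) == 1200


@pytest.fixture(scope="module")
def toy_chain_vs_oracle(thermo300):
    """Chain and MC oracle for the mild anharmonic toy (n = 2)."""
    model = make_morse_toy()
    crit = pc.ClusterCriterion()
    anchor = k1_anchor_from_quadrature(model, thermo300, crit)
    cfg = pc.SamplerConfig(seed=9, n_sweeps=9000, equilibration_sweeps=3000,
                           sample_interval=6)
    traj = pc.run_sampler(2, model, cfg)
    decs = rough.decompose_trajectory(traj, model)
    sf = rough.step_average(decs, thermo300, n=2)
    ch = rough.chain(anchor, [sf], thermo300)
    res = kn_mc_integration(model, thermo300, crit, 2, n_samples=400_000, seed=21)
    return anchor, sf, ch, res


def test_toy_chain_matches_oracle(toy_chain_vs_oracle, thermo300):
    """Oracle equivalence of the step-wise estimator on an anharmonic toy."""
    _, _, ch, res = toy_chain_vs_oracle
    rt = thermo300.rt
    fe_chain = -rt * math.log(ch.k_n[2])
    fe_oracle = -rt * math.log(res.k_n)
    sigma = rt * math.hypot(ch.log_std_error[2], res.std_error / res.k_n)
    assert abs(fe_chain - fe_oracle) < 3 * sigma


def test_rejected_equation_reading_fails_oracle(toy_chain_vs_oracle, thermo300):
    """Regression: placing the exponential average in the numerator (the
    rejected reading of the step-wise relation) disagrees with the oracle
    far beyond the statistical uncertainty."""
    anchor, sf, ch, res = toy_chain_vs_oracle
    rt = thermo300.rt
    k2_wrong = anchor.value**2 * sf.mean_exp / 2.0
    fe_wrong = -rt * math.log(k2_wrong)
    fe_oracle = -rt * math.log(res.k_n)
    sigma = rt * math.hypot(ch.log_std_error[2], res.std_error / res.k_n)
    assert abs(fe_wrong - fe_oracle) > 10 * sigma


def test_crowding_reduces_k_below_ideal(thermo300):
    """Purely repulsive ligand-ligand coupling: every dU >= 0, the step
    factor exceeds 1 beyond 3 SE, hence K_n < K_1^n/n! strictly."""
    model = make_morse_toy(repulsion=2.0)
    anchor = k1_anchor_from_quadrature(model, thermo300, pc.ClusterCriterion())
    factors = []
    for n in (2, 3):
        cfg = pc.SamplerConfig(seed=30 + n, n_sweeps=4000,
                               equilibration_sweeps=1000, sample_interval=6)
        traj = pc.run_sampler(n, model, cfg)
        decs = rough.decompose_trajectory(traj, model)
        sf = rough.step_average(decs, thermo300, n=n)
        assert min(d.delta_u for d in decs) >= 0.0
        assert sf.mean_exp > 1.0 + 3 * sf.std_error
        factors.append(sf)
    ch = rough.chain(anchor, factors, thermo300)
    for n in (2, 3):
        assert ch.k_n[n] < anchor.value**n / math.factorial(n)


def test_random_distinguish_mode(w2_trajectory, water_model, thermo300):
    decs = rough.decompose_trajectory(w2_trajectory, water_model, mode="random", seed=1)
    assert len(decs) == len(w2_trajectory)
    sf = rough.step_average(decs, thermo300, n=2)
    assert sf.mean_exp > 0
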