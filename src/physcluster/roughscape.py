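"""Step-wise rough-landscape estimator for cluster equilibrium constants.

The cluster formation constant K_n (volume units A^{3n}) is built step-wise
from K_1 through the recursion

    K_n = K_1 * K_{n-1} / ( n * < e^{beta dU_n} >_n ),

where dU_n = U(W_nX) - U(W_{n-1}X) - U(WX) + U(X) is the per-ligand
decoupling energy evaluated on frozen geometries from the canonical
simulation stream of the W_nX cluster, and the bracket is the thermal
average over that stream (and, by default, over every choice of
distinguished ligand).  dU_n measures the crowding of the n-th ligand:
it vanishes identically for n = 1 and whenever ligand-ligand interactions
are switched off, in which case the recursion collapses to the ideal
result K_n = K_1^n / n!.

The placement of the exponential average in the denominator follows from
writing the step-wise ratio as a single clustered-configuration integral in
numerator and denominator: the denominator lacks exactly the Boltzmann
factor e^{-beta dU_n}, i.e. equals the numerator times <e^{+beta dU_n}>_n.
That reading (i) reduces to K_n = K_1^n/n! at dU = 0 and (ii) makes
unfavourable crowding reduce K_n; it is locked in by oracle tests.

Everything here is classical-limit bookkeeping: zero-point motion enters
only through a user-supplied K_1 anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .chem_model import ClusterConfiguration, PotentialModel, ThermoState

__all__ = [
    "EnergyDecomposition",
    "StepFactor",
    "K1Anchor",
    "EquilibriumChain",
    "decompose_frame",
    "decompose_trajectory",
    "step_average",
    "chain",
    "evaluation_count",
]


@dataclass(frozen=True)
class EnergyDecomposition:
    """The four decoupling terms for one frame and one distinguished ligand."""

    frame_index: int
    distinguished_ligand: int
    u_full: float  # U(W_nX)
    u_rest: float  # U(W_{n-1}X), distinguished ligand removed
    u_single: float  # U(WX), distinguished ligand alone with the ion
    u_ion: float  # U(X), bare ion

    @property
    def delta_u(self) -> float:
        return self.u_full - self.u_rest - self.u_single + self.u_ion


@dataclass(frozen=True)
class StepFactor:
    """<e^{beta dU_n}>_n with block-averaged uncertainty."""

    n: int
    mean_exp: float
    std_error: float
    n_samples: int
    n_blocks: int
    sample_mean: float  # mean of dU_n, kcal/mol
    sample_variance: float  # variance of dU_n, (kcal/mol)^2
    cumulant_estimate: float  # exp(beta*mu + beta^2*sigma^2/2), Gaussian model


@dataclass(frozen=True)
class K1Anchor:
    """K_1 in volume units (A^3) with mandatory provenance metadata."""

    value: float
    provenance: str  # experiment | oracle | rrho
    log_std_error: float = 0.0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("K_1 must be positive")
        if self.provenance not in ("experiment", "oracle", "rrho"):
            raise ValueError(f"unknown K_1 provenance {self.provenance!r}")


@dataclass
class EquilibriumChain:
    """K_n^(0) values for n = 0..N with log-space uncertainties.

    ``k_n[i]`` is K_i in volume units (A^{3i}); ``free_energy(thermo)``
    returns -RT ln(K_n rho0^n) at the thermo state's standard concentration.
    """

    k_n: np.ndarray  # K_0..K_N, volume units
    log_std_error: np.ndarray  # std error of ln K_n
    method: str  # roughscape | harmonic | oracle | analytic_ideal
    k1_anchor: Optional[K1Anchor] = None
    criterion_mode: str = "ion_cutoff"

    def __post_init__(self) -> None:
        self.k_n = np.asarray(self.k_n, dtype=float)
        self.log_std_error = np.asarray(self.log_std_error, dtype=float)
        if self.k_n[0] != 1.0:
            raise ValueError("K_0 must equal 1")
        if np.any(self.k_n <= 0):
            raise ValueError("all K_n must be positive")

    @property
    def n_max(self) -> int:
        return len(self.k_n) - 1

    def free_energy(self, thermo: ThermoState) -> np.ndarray:
        """-RT ln(K_n rho0^n) in kcal/mol for n = 0..N."""
        rho0 = thermo.standard_concentration
        ns = np.arange(self.n_max + 1)
        return -thermo.rt * (np.log(self.k_n) + ns * math.log(rho0))

    def free_energy_error(self, thermo: ThermoState) -> np.ndarray:
        return thermo.rt * self.log_std_error


# --------------------------------------------------------------------------


def decompose_frame(
    frame: ClusterConfiguration,
    model: PotentialModel,
    frame_index: int = 0,
    ligands: Optional[Iterable[int]] = None,
) -> list[EnergyDecomposition]:
    """Decoupling energies for one sampled frame.

    The geometry is frozen: the W_{n-1}X and WX energies are sub-cluster
    energies of the same coordinates.  With ``ligands=None`` every ligand is
    distinguished in turn (the default estimator); pass a subset for the
    single-random-ligand variant.
    """
    n = frame.n
    if n < 1:
        raise ValueError("decompose_frame requires n >= 1")
    which = range(n) if ligands is None else list(ligands)
    u_full = model.energy(frame)
    u_ion = 0.0  # bare rigid species carry zero energy on this surface
    out = []
    for k in which:
        rest = [j for j in range(n) if j != k]
        u_rest = model.energy(frame, keep=rest)
        u_single = model.energy(frame, keep=[k])
        out.append(
            EnergyDecomposition(
                frame_index=frame_index,
                distinguished_ligand=k,
                u_full=u_full,
                u_rest=u_rest,
                u_single=u_single,
                u_ion=u_ion,
            )
        )
    return out


def decompose_trajectory(
    trajectory, model: PotentialModel, mode: str = "all", seed: int = 0
) -> list[EnergyDecomposition]:
    """Decompose every frame of a trajectory.

    ``mode='all'`` distinguishes each ligand in turn; ``mode='random'``
    picks one ligand per frame (seeded), for variance studies.
    """
    rng = np.random.default_rng(seed)
    out: list[EnergyDecomposition] = []
    for i, frame in enumerate(trajectory.frames):
        if mode == "all":
            out.extend(decompose_frame(frame, model, frame_index=i))
        elif mode == "random":
            k = int(rng.integers(frame.n))
            out.extend(decompose_frame(frame, model, frame_index=i, ligands=[k]))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def step_average(
    decompositions: Sequence[EnergyDecomposition],
    thermo: ThermoState,
    n_blocks: int = 10,
    n: Optional[int] = None,
) -> StepFactor:
    """Thermal average <e^{beta dU_n}>_n over frames and distinguished ligands.

    The standard error comes from non-overlapping block means over frames
    (samples from the same frame share a block, respecting correlation);
    the cumulant estimate is the Gaussian-model value exp(beta mu +
    beta^2 sigma^2 / 2) from the sample mean and variance of dU_n.
    """
    if not decompositions:
        raise ValueError("no decompositions supplied")
    n_step = (
        int(max(d.distinguished_ligand for d in decompositions)) + 1
        if n is None
        else n
    )
    du = np.array([d.delta_u for d in decompositions])
    frames = np.array([d.frame_index for d in decompositions])
    beta = thermo.beta
    w = np.exp(beta * du)
    if not np.all(np.isfinite(w)):
        bad = frames[~np.isfinite(w)]
        raise ValueError(f"non-finite e^(beta dU) at frames {sorted(set(bad))[:5]}")
    mean_exp = float(w.mean())

    # block averaging over distinct frames
    uniq = np.unique(frames)
    if len(uniq) < 2 * max(2, n_blocks // 5):
        n_blocks = max(2, len(uniq) // 2)
    if len(uniq) < 2:
        raise ValueError("need at least 2 frames for block averaging")
    edges = np.array_split(uniq, n_blocks)
    block_means = np.array(
        [w[np.isin(frames, e)].mean() for e in edges if len(e) > 0]
    )
    nb = len(block_means)
    se = float(block_means.std(ddof=1) / math.sqrt(nb)) if nb > 1 else math.inf

    mu = float(du.mean())
    var = float(du.var(ddof=1)) if len(du) > 1 else 0.0
    cumulant = math.exp(beta * mu + beta**2 * var / 2.0)
    return StepFactor(
        n=n_step,
        mean_exp=mean_exp,
        std_error=se,
        n_samples=len(du),
        n_blocks=nb,
        sample_mean=mu,
        sample_variance=var,
        cumulant_estimate=cumulant,
    )


def chain(
    k1_anchor: K1Anchor,
    step_factors: Sequence[StepFactor],
    thermo: ThermoState,
    criterion_mode: str = "ion_cutoff",
) -> EquilibriumChain:
    """Apply the step-wise recursion K_n = K_1 K_{n-1} / (n <e^{beta dU_n}>_n).

    ``step_factors`` must be contiguous from n = 2 (an empty sequence gives
    the trivial chain K_0 = 1, K_1 = anchor).  Uncertainties propagate in
    log space: Var ln K_n = n^2 Var ln K_1 + sum_m (se_m / mean_m)^2.
    """
    ks = [1.0, k1_anchor.value]
    var_log = [0.0, k1_anchor.log_std_error**2]
    expected = 2
    for sf in step_factors:
        if sf.n != expected:
            raise ValueError(
                f"step factors must be contiguous from n=2; got n={sf.n}, expected {expected}"
            )
        ks.append(k1_anchor.value * ks[-1] / (sf.n * sf.mean_exp))
        var_log.append(
            (sf.n**2) * k1_anchor.log_std_error**2
            + sum(
                (s.std_error / s.mean_exp) ** 2 for s in step_factors if s.n <= sf.n
            )
        )
        expected += 1
    n_max = len(ks) - 1
    if n_max == 1:
        var_log = [0.0, k1_anchor.log_std_error**2]
    return EquilibriumChain(
        k_n=np.array(ks),
        log_std_error=np.sqrt(np.array(var_log)),
        method="roughscape",
        k1_anchor=k1_anchor,
        criterion_mode=criterion_mode,
    )


def evaluation_count(n: int, n_frames: int) -> int:
    """Number of distinct subsystem single-point energy evaluations for the
    full decoupling bookkeeping with every ligand distinguished in turn and
    no caching across frames: n_frames * (1 full + n rest + n single + 1 ion)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return n_frames * (2 * n + 2)
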