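"""Canonical Monte Carlo sampling of clustered W_nX configurations.

The equilibrium-constant estimators only need configurations drawn from the
canonical distribution restricted to *clustered* configurations, so the
dynamical trajectories of the original workflow are replaced here by
Metropolis Monte Carlo with single-ligand rigid-body moves.  The clustering
constraint is enforced as outright rejection of criterion-breaking moves
(an infinite square well in the cluster indicator), which makes the sampled
ensemble exactly the clustered-configuration integral.

Two proximity definitions are provided:

* ``ion_cutoff`` -- every ligand reference site within ``r_ion_ligand`` of
  the ion (compact clusters, the definition under which the step-wise
  bookkeeping is internally consistent);
* ``stillinger`` -- the proximity graph with ion-O and O-O edges is
  connected, admitting ramified (branched) clusters.

The sampling cadence mirrors the source protocol: discard the first third
of the run as equilibration, then store a frame at a fixed sweep interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .chem_model import (
    ClusterConfiguration,
    PotentialModel,
    ThermoState,
    random_configuration,
    random_quaternions,
)

__all__ = [
    "ClusterCriterion",
    "SamplerConfig",
    "Trajectory",
    "metropolis_step",
    "run_sampler",
    "metropolis_accept",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterCriterion:
    """Operational definition of a formed W_nX cluster."""

    mode: str = "ion_cutoff"  # ion_cutoff | stillinger
    r_ion_ligand: float = 4.5
    r_ligand_ligand: float = 3.5

    def __post_init__(self) -> None:
        if self.mode not in ("ion_cutoff", "stillinger"):
            raise ValueError(f"unknown criterion mode {self.mode!r}")
        if self.r_ion_ligand <= 0 or self.r_ligand_ligand <= 0:
            raise ValueError("criterion radii must be positive")

    def is_clustered(self, config: ClusterConfiguration) -> bool:
        if config.n == 0:
            return True
        d_ion = np.linalg.norm(config.translations - config.ion_position, axis=1)
        if self.mode == "ion_cutoff":
            return bool(np.all(d_ion <= self.r_ion_ligand))
        return self._connected(config, d_ion)

    def _connected(self, config: ClusterConfiguration, d_ion: np.ndarray) -> bool:
        # BFS over the proximity graph {ion} U {ligand reference sites}
        n = config.n
        t = config.translations
        adj_ion = d_ion <= self.r_ion_ligand
        d_ll = np.linalg.norm(t[:, None, :] - t[None, :, :], axis=2)
        adj_ll = d_ll <= self.r_ligand_ligand
        seen = adj_ion.copy()
        frontier = list(np.nonzero(seen)[0])
        while frontier:
            k = frontier.pop()
            for j in np.nonzero(adj_ll[k])[0]:
                if not seen[j]:
                    seen[j] = True
                    frontier.append(j)
        return bool(seen.all())

    def is_ramified(self, config: ClusterConfiguration) -> bool:
        """Clustered but with some ligand beyond the ion-ligand radius --
        i.e. held in the cluster only through ligand-ligand connectivity."""
        if not self.is_clustered(config):
            return False
        d_ion = np.linalg.norm(config.translations - config.ion_position, axis=1)
        return bool(np.any(d_ion > self.r_ion_ligand))


@dataclass
class SamplerConfig:
    """Move amplitudes, cadence and seed for one Monte Carlo run.

    Defaults mirror the analysis protocol of the reference workflow: of
    ``n_sweeps`` total, the first third is discarded as equilibration and the
    remainder is sampled every ``sample_interval`` sweeps (1500/500/10 gives
    100 stored frames, the analogue of sampling every 0.1 ps of the last
    10 ps of a 15 ps trajectory).
    """

    thermo: ThermoState = field(default_factory=ThermoState)
    criterion: ClusterCriterion = field(default_factory=ClusterCriterion)
    n_sweeps: int = 1500
    equilibration_sweeps: int = 500
    sample_interval: int = 10
    max_translation: float = 0.35
    max_rotation: float = 0.6
    seed: int = 0
    tune: bool = True
    target_acceptance: float = 0.4

    def __post_init__(self) -> None:
        if self.equilibration_sweeps >= self.n_sweeps:
            raise ValueError("equilibration_sweeps must be < n_sweeps")
        if self.sample_interval < 1:
            raise ValueError("sample_interval must be >= 1")


@dataclass
class Trajectory:
    """Ordered, seeded stream of clustered configurations with energies."""

    frames: list
    energies: np.ndarray
    n: int
    acceptance_rate: float
    seed: int
    sampler_config: SamplerConfig

    def __len__(self) -> int:
        return len(self.frames)


def metropolis_accept(delta_e: float, beta: float, rng: np.random.Generator) -> bool:
    """The Metropolis rule: accept with probability min(1, e^{-beta dE})."""
    if delta_e <= 0.0:
        return True
    if not np.isfinite(delta_e):
        return False
    return rng.random() < np.exp(-beta * delta_e)


def _ligand_energy(model: PotentialModel, config: ClusterConfiguration, k: int) -> float:
    """Energy terms involving ligand k (its share of the total)."""
    e = model.ion_ligand_energy(config, k)
    if model.ligand_coupling != 0.0:
        for j in range(config.n):
            if j != k:
                e += model.ligand_coupling * model.ligand_pair_energy(config, j, k)
    return e


def metropolis_step(
    config: ClusterConfiguration,
    model: PotentialModel,
    sampler_config: SamplerConfig,
    rng: np.random.Generator,
    ligand_index: Optional[int] = None,
) -> tuple[ClusterConfiguration, bool, float]:
    """One single-ligand rigid-body trial move.

    Translation uniform in a cube of half-width ``max_translation``; rotation
    about a random axis by an angle uniform in +-``max_rotation``.  Moves that
    break the cluster criterion (or the hard-core guard) are rejected
    outright.  Returns (new config, accepted, energy change).
    """
    n = config.n
    k = int(rng.integers(n)) if ligand_index is None else ligand_index
    cfg = sampler_config
    e_old = _ligand_energy(model, config, k)

    trial = config.copy()
    trial.translations[k] = trial.translations[k] + rng.uniform(
        -cfg.max_translation, cfg.max_translation, size=3
    )
    if model.ligand.n_sites > 1:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(-cfg.max_rotation, cfg.max_rotation)
        dq = Rotation.from_rotvec(angle * axis)
        q_new = (dq * Rotation.from_quat(trial.quaternions[k])).as_quat()
        trial.quaternions[k] = q_new / np.linalg.norm(q_new)

    if not cfg.criterion.is_clustered(trial):
        return config, False, 0.0
    e_new = _ligand_energy(model, trial, k)
    delta = e_new - e_old
    if metropolis_accept(delta, cfg.thermo.beta, rng):
        return trial, True, delta
    return config, False, 0.0


def run_sampler(
    n: int,
    model: PotentialModel,
    sampler_config: SamplerConfig,
    initial: Optional[ClusterConfiguration] = None,
) -> Trajectory:
    """Generate the canonical simulation stream for a W_nX cluster.

    One sweep attempts n single-ligand moves.  Move amplitudes are tuned
    toward the target acceptance during equilibration only and frozen
    afterwards, preserving detailed balance over the production phase.
    Identical seeds give bit-identical trajectories.
    """
    if n < 1:
        raise ValueError("run_sampler requires n >= 1")
    cfg = replace(sampler_config)  # local copy: amplitudes may be tuned
    rng = np.random.default_rng(cfg.seed)
    config = initial if initial is not None else random_configuration(
        n, cfg.criterion, ligand=model.ligand, rng=rng
    )
    if not cfg.criterion.is_clustered(config):
        raise ValueError("initial configuration violates the cluster criterion")

    frames: list[ClusterConfiguration] = []
    energies: list[float] = []
    accepted = attempted = 0
    tune_acc = tune_att = 0
    tune_block = 50  # sweeps between amplitude adjustments

    for sweep in range(cfg.n_sweeps):
        for _ in range(n):
            config, acc, _ = metropolis_step(config, model, cfg, rng)
            attempted += 1
            accepted += acc
            tune_att += 1
            tune_acc += acc
        in_equil = sweep < cfg.equilibration_sweeps
        if cfg.tune and in_equil and (sweep + 1) % tune_block == 0 and tune_att:
            rate = tune_acc / tune_att
            scale = 1.15 if rate > cfg.target_acceptance else 0.85
            cfg.max_translation = float(
                np.clip(cfg.max_translation * scale, 0.01, cfg.criterion.r_ion_ligand)
            )
            cfg.max_rotation = float(np.clip(cfg.max_rotation * scale, 0.01, np.pi))
            tune_acc = tune_att = 0
        if not in_equil and (sweep - cfg.equilibration_sweeps) % cfg.sample_interval == 0:
            frames.append(config.copy())
            energies.append(model.energy(config))

    rate = accepted / attempted if attempted else 0.0
    if not 0.05 <= rate <= 0.95:
        logger.warning(
            "acceptance rate %.3f outside [0.05, 0.95]; consider retuning move amplitudes",
            rate,
        )
    return Trajectory(
        frames=frames,
        energies=np.asarray(energies),
        n=n,
        acceptance_rate=rate,
        seed=cfg.seed,
        sampler_config=cfg,
    )
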