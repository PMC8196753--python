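"""Formats, run configuration, and the end-to-end pipeline.

Trajectories travel as extended XYZ (atom symbols + Cartesian Angstrom,
comment line carrying ``key=value`` pairs including the frame index and
energy); energies and decoupling samples as CSV; chain and oracle summaries
as JSON; run configuration as TOML.  Every artifact embeds the seeds and a
hash of the echoed configuration so a run is exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import oracle as oracle_mod
from . import roughscape as rough
from . import rrho as rrho_mod
from .chem_model import (
    ClusterConfiguration,
    IonSpecies,
    PotentialModel,
    RigidLigand,
    ThermoState,
    ion,
)
from .sampler import ClusterCriterion, SamplerConfig, Trajectory, run_sampler

__all__ = [
    "RunConfig",
    "write_trajectory",
    "read_trajectory",
    "write_decompositions",
    "read_decompositions",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# extended XYZ


def write_trajectory(
    trajectory: Trajectory,
    path,
    model: PotentialModel,
) -> None:
    """Write frames as extended XYZ: ion first, then ligand site blocks."""
    path = Path(path)
    lines = []
    lig = model.ligand
    for i, (frame, energy) in enumerate(zip(trajectory.frames, trajectory.energies)):
        symbols, coords, _ = frame.to_atoms(lig, model.ion)
        lines.append(str(len(symbols)))
        lines.append(f"frame={i} energy={energy:.10f} n={frame.n}")
        for s, xyz in zip(symbols, coords):
            lines.append(f"{s} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}")
    path.write_text("\n".join(lines) + "\n")


def _pose_from_sites(sites: np.ndarray, ligand: RigidLigand):
    """Recover (translation, quaternion) from world-frame site coordinates."""
    t = sites[0]
    if ligand.n_sites == 1:
        return t, np.array([0.0, 0.0, 0.0, 1.0])
    body = ligand.body_positions[1:]  # offsets from the reference site
    world = sites[1:] - t
    rot, _ = Rotation.align_vectors(world, body)
    q = rot.as_quat()
    return t, q / np.linalg.norm(q)


def read_trajectory(
    path,
    ligand: Optional[RigidLigand] = None,
) -> tuple[Trajectory, IonSpecies]:
    """Read an extended-XYZ trajectory written by :func:`write_trajectory`.

    The ion is the first atom of each frame; ligand grouping is rebuilt from
    the atom ordering.  The ligand model is inferred from the symbol pattern
    (O,H,H blocks -> rigid 3-site water; uniform single symbols -> point
    ligand) unless supplied explicitly.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    frames: list[ClusterConfiguration] = []
    energies: list[float] = []
    i = 0
    n_atoms_ref = None
    frame_no = 0
    while i < len(raw):
        if not raw[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(raw[i].split()[0])
        except ValueError:
            raise ValueError(f"malformed atom count at line {i + 1}")
        comment = raw[i + 1] if i + 1 < len(raw) else ""
        kv = {}
        for tok in comment.split():
            if "=" in tok:
                k, _, v = tok.partition("=")
                kv[k] = v
        if "energy" not in kv:
            raise ValueError(f"frame {frame_no}: missing energy key in comment line")
        if n_atoms_ref is None:
            n_atoms_ref = n_atoms
        elif n_atoms != n_atoms_ref:
            raise ValueError(
                f"inconsistent atom count at frame {frame_no}: {n_atoms} != {n_atoms_ref}"
            )
        block = raw[i + 2 : i + 2 + n_atoms]
        if len(block) < n_atoms:
            raise ValueError(f"truncated frame {frame_no}")
        symbols = []
        coords = np.empty((n_atoms, 3))
        for a, line in enumerate(block):
            parts = line.split()
            symbols.append(parts[0])
            coords[a] = [float(p) for p in parts[1:4]]
        if frame_no == 0:
            ion_species, ligand = _infer_species(symbols, ligand)
            s = ligand.n_sites
            n_lig = (n_atoms - 1) // s
            if 1 + n_lig * s != n_atoms:
                raise ValueError(
                    f"atom count {n_atoms} incompatible with {s}-site ligand blocks"
                )
        trans, quats = [], []
        for k in range(n_lig):
            sites = coords[1 + k * s : 1 + (k + 1) * s]
            t, q = _pose_from_sites(sites, ligand)
            trans.append(t)
            quats.append(q)
        frames.append(
            ClusterConfiguration(
                coords[0],
                np.array(trans).reshape(-1, 3),
                np.array(quats).reshape(-1, 4),
            )
        )
        energies.append(float(kv["energy"]))
        i += 2 + n_atoms
        frame_no += 1
    if not frames:
        raise ValueError(f"no frames found in {path}")
    traj = Trajectory(
        frames=frames,
        energies=np.asarray(energies),
        n=frames[0].n,
        acceptance_rate=math.nan,
        seed=-1,
        sampler_config=None,
    )
    return traj, ion_species


def _infer_species(symbols: Sequence[str], ligand: Optional[RigidLigand]):
    from .chem_model import ION_TABLE

    ion_label = symbols[0]
    ion_species = ION_TABLE.get(ion_label)
    if ion_species is None:
        raise ValueError(f"unknown element label {ion_label!r} for the ion")
    rest = list(symbols[1:])
    if ligand is not None:
        return ion_species, ligand
    if rest and len(rest) % 3 == 0 and all(
        rest[i : i + 3] == ["O", "H", "H"] for i in range(0, len(rest), 3)
    ):
        return ion_species, RigidLigand.rigid_water_3site()
    if rest and len(set(rest)) == 1:
        return ion_species, RigidLigand.point_ligand(symbol=rest[0])
    raise ValueError(f"cannot infer ligand model from symbols {rest[:6]}...")


# --------------------------------------------------------------------------
# decoupling-sample CSV (also the adapter for externally computed energies)


def write_decompositions(decompositions, path) -> None:
    """CSV layout: frame, ligand, u_full, u_rest, u_single, u_ion, delta_u."""
    df = pd.DataFrame(
        [
            {
                "frame": d.frame_index,
                "ligand": d.distinguished_ligand,
                "u_full": d.u_full,
                "u_rest": d.u_rest,
                "u_single": d.u_single,
                "u_ion": d.u_ion,
                "delta_u": d.delta_u,
            }
            for d in decompositions
        ]
    )
    df.to_csv(path, index=False)


def read_decompositions(path) -> list:
    """Read the CSV layout above; lets the step-wise estimator run on
    externally supplied (e.g. quantum-chemistry) subsystem energies."""
    df = pd.read_csv(path)
    required = {"frame", "ligand", "u_full", "u_rest", "u_single", "u_ion"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"decomposition CSV missing columns: {sorted(missing)}")
    return [
        rough.EnergyDecomposition(
            frame_index=int(r.frame),
            distinguished_ligand=int(r.ligand),
            u_full=float(r.u_full),
            u_rest=float(r.u_rest),
            u_single=float(r.u_single),
            u_ion=float(r.u_ion),
        )
        for r in df.itertuples()
    ]


# --------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run bit-for-bit."""

    ion_label: str = "Cl"
    ligand_mode: str = "rigid_water_3site"  # or point_ligand
    ligand_coupling: float = 1.0
    temperature: float = 300.0
    standard_state: str = "1atm"
    criterion_mode: str = "ion_cutoff"
    r_ion_ligand: float = 4.5
    r_ligand_ligand: float = 3.5
    n_max: int = 3
    n_sweeps: int = 1500
    equilibration_sweeps: int = 500
    sample_interval: int = 10
    seed: int = 0
    n_blocks: int = 10
    distinguish: str = "all"  # all | random
    k1_source: str = "oracle"  # oracle | value
    k1_value: Optional[float] = None
    run_rrho: bool = True
    rrho_statistics: str = "classical"
    n_starts: int = 20
    run_oracle: bool = True
    oracle_samples: int = 200_000
    output_dir: str = "physcluster_run"

    def thermo(self) -> ThermoState:
        return ThermoState(self.temperature, self.standard_state)

    def criterion(self) -> ClusterCriterion:
        return ClusterCriterion(
            self.criterion_mode, self.r_ion_ligand, self.r_ligand_ligand
        )

    def model(self) -> PotentialModel:
        lig = (
            RigidLigand.rigid_water_3site()
            if self.ligand_mode == "rigid_water_3site"
            else RigidLigand.point_ligand()
        )
        return PotentialModel(
            ion=ion(self.ion_label), ligand=lig, ligand_coupling=self.ligand_coupling
        )

    def sampler_config(self, seed: int) -> SamplerConfig:
        return SamplerConfig(
            thermo=self.thermo(),
            criterion=self.criterion(),
            n_sweeps=self.n_sweeps,
            equilibration_sweeps=self.equilibration_sweeps,
            sample_interval=self.sample_interval,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        flat = {}
        for key, val in data.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def to_toml(self, path) -> None:
        lines = []
        for key, val in self.to_dict().items():
            if val is None:
                continue
            if isinstance(val, str):
                lines.append(f'{key} = "{val}"')
            elif isinstance(val, bool):
                lines.append(f"{key} = {str(val).lower()}")
            else:
                lines.append(f"{key} = {val}")
        Path(path).write_text("\n".join(lines) + "\n")


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] >> 1)


# --------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig, output_dir=None) -> pd.DataFrame:
    """Sample -> decouple -> chains -> oracle, for n = 1..n_max.

    Returns the results table (one row per n and method, carrying
    -RT ln K_n at the configured standard state, its uncertainty, the K_1
    anchor provenance, criterion, and seed) and writes CSV/JSON artifacts
    plus the echoed configuration to ``output_dir``.
    """
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    thermo = config.thermo()
    criterion = config.criterion()
    model = config.model()
    cfg_hash = config.hash()
    t0 = time.time()

    stage = "sample"
    try:
        trajectories = {}
        for n in range(1, config.n_max + 1):
            scfg = config.sampler_config(seed=_child_seed(config.seed, 1, n))
            traj = run_sampler(n, model, scfg)
            trajectories[n] = traj
            write_trajectory(traj, outdir / f"frames_n{n}.xyz", model)
            logger.info(
                "stage=sample n=%d frames=%d acceptance=%.3f seed=%d",
                n, len(traj), traj.acceptance_rate, scfg.seed,
            )

        stage = "roughscape"
        if config.k1_source == "value":
            if config.k1_value is None:
                raise ValueError("k1_source='value' requires k1_value")
            anchor = rough.K1Anchor(config.k1_value, provenance="experiment")
        else:
            anchor = oracle_mod.k1_anchor_from_quadrature(model, thermo, criterion)
        factors = []
        for n in range(2, config.n_max + 1):
            dec = rough.decompose_trajectory(
                trajectories[n], model, mode=config.distinguish,
                seed=_child_seed(config.seed, 2, n),
            )
            write_decompositions(dec, outdir / f"delta_u_n{n}.csv")
            factors.append(
                rough.step_average(dec, thermo, n_blocks=config.n_blocks, n=n)
            )
        rough_chain = rough.chain(
            anchor, factors, thermo, criterion_mode=criterion.mode
        )

        rows = _chain_rows(rough_chain, thermo, criterion, config, "roughscape")

        if config.run_rrho:
            stage = "rrho"
            structures = [
                rrho_mod.multi_start_optimize(
                    trajectories[n], model, n_starts=min(config.n_starts, len(trajectories[n]))
                )
                for n in range(1, config.n_max + 1)
            ]
            harm = rrho_mod.harmonic_chain(
                structures, model, thermo, statistics=config.rrho_statistics
            )
            rows += _chain_rows(harm, thermo, criterion, config, harm.method)

        if config.run_oracle:
            stage = "oracle"
            for n in range(1, min(3, config.n_max) + 1):
                res = oracle_mod.kn_mc_integration(
                    model, thermo, criterion, n,
                    n_samples=config.oracle_samples,
                    seed=_child_seed(config.seed, 3, n),
                )
                if res.low_precision:
                    logger.warning("oracle n=%d flagged low precision", n)
                rho0 = thermo.standard_concentration
                rows.append(
                    {
                        "n": n,
                        "method": "oracle_mc",
                        "minus_rt_ln_k": -thermo.rt
                        * (math.log(res.k_n) + n * math.log(rho0)),
                        "uncertainty": thermo.rt * res.std_error / res.k_n,
                        "k1_provenance": "oracle",
                        "criterion": criterion.mode,
                        "seed": res.seed,
                        "config_hash": cfg_hash,
                    }
                )
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (artifacts under {outdir})"
        ) from err

    table = pd.DataFrame(rows)
    table.to_csv(outdir / "results.csv", index=False)
    (outdir / "results.json").write_text(table.to_json(orient="records", indent=2))
    config.to_toml(outdir / "config_echo.toml")
    (outdir / "config_echo.json").write_text(
        json.dumps({"hash": cfg_hash, **config.to_dict()}, indent=2)
    )
    logger.info("pipeline done in %.1fs -> %s", time.time() - t0, outdir)
    return table


def _chain_rows(chain_obj, thermo, criterion, config, method):
    fe = chain_obj.free_energy(thermo)
    fe_err = chain_obj.free_energy_error(thermo)
    prov = chain_obj.k1_anchor.provenance if chain_obj.k1_anchor else ""
    return [
        {
            "n": n,
            "method": method,
            "minus_rt_ln_k": float(fe[n]),
            "uncertainty": float(fe_err[n]),
            "k1_provenance": prov,
            "criterion": criterion.mode,
            "seed": config.seed,
            "config_hash": config.hash(),
        }
        for n in range(1, chain_obj.n_max + 1)
    ]
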