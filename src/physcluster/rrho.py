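"""Rigid-rotor harmonic-oscillator free energies and equilibrium constants.

The harmonic baseline for K_n: sampled frames seed multi-start local
minimisation on the surrogate surface; the lowest minimum supplies the well
depth, a numerical Hessian in rigid-body generalised coordinates supplies
the normal modes, and standard RRHO partition functions assemble

    K_n = q_trans/V * q_rot * q_vib * e^{-beta E_min}
          / ( n! * (q_trans,X/V) * (q_trans,W/V * q_rot,W)^n ).

Coordinates and measures
------------------------
Each rigid ligand contributes 3 centre-of-mass translations plus (for
multi-site ligands) a 3-component rotation vector about its centre of mass;
the mass metric is block diagonal (ion mass, ligand mass, world-frame
inertia tensor), so the generalised eigenproblem H v = lambda M v yields
the harmonic frequencies directly.  Global translations and rotations are
projected out before diagonalisation (6 zero modes for nonlinear clusters,
5 for linear, 3 for a bare atom).

Statistics: ``quantum`` vibrations use q_vib = prod e^{-u/2}/(1-e^{-u})
with u = beta h nu (zero-point energy included); ``classical`` vibrations
use q_vib = prod 1/u.  Rotations use the classical rotor formula in both
cases.  In the classical limit the construction converges to the
configurational-integral oracle as the well stiffens.

The ligand-permutation factor n! is applied explicitly; the rotor symmetry
number defaults to sigma = 1 for the asymmetric optimised clusters (and for
free water, whose symmetry numbers cancel between the cluster and free-W
partition functions).  Both are overridable.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import linalg, optimize
from scipy.spatial.transform import Rotation

from .chem_model import (
    ClusterConfiguration,
    IonSpecies,
    PotentialModel,
    RigidLigand,
    ThermoState,
)
from .constants import (
    C_CM_S,
    KB_J,
    PLANCK_J_S,
    AMU_KG,
    thermal_wavelength_cubed_inv,
    wavenumber_from_eigenvalue,
)
from .roughscape import EquilibriumChain

__all__ = [
    "OptimizedStructure",
    "NormalModeSet",
    "HarmonicThermo",
    "ClusterDOF",
    "multi_start_optimize",
    "numerical_hessian",
    "normal_modes",
    "cluster_normal_modes",
    "harmonic_thermo",
    "harmonic_chain",
    "classical_qvib_factor",
    "quantum_qvib_factor",
]

logger = logging.getLogger(__name__)

LOW_FREQ_WARN_CM = 10.0


# --------------------------------------------------------------------------
# rigid-body generalised coordinates


def _left_jacobian(phi: np.ndarray) -> np.ndarray:
    """Left Jacobian of SO(3) for the rotation-vector parametrisation."""
    theta = np.linalg.norm(phi)
    K = np.array(
        [[0, -phi[2], phi[1]], [phi[2], 0, -phi[0]], [-phi[1], phi[0], 0]]
    )
    if theta < 1e-8:
        return np.eye(3) + 0.5 * K + K @ K / 6.0
    a = (1 - math.cos(theta)) / theta**2
    b = (theta - math.sin(theta)) / theta**3
    return np.eye(3) + a * K + b * (K @ K)


@dataclass
class ClusterDOF:
    """Mapping between a flat coordinate vector and a cluster configuration.

    Layout: ion xyz, then per ligand [com xyz, rotation vector (multi-site
    only)].  Rotation vectors are increments on stored reference
    orientations; ``recenter`` absorbs them back into the reference so the
    analytic gradient stays exact near the working point.
    """

    ligand: RigidLigand
    n: int
    ref_quats: np.ndarray  # (n, 4)

    @property
    def has_orientation(self) -> bool:
        return self.ligand.n_sites > 1

    @property
    def per_ligand(self) -> int:
        return 6 if self.has_orientation else 3

    @property
    def n_dof(self) -> int:
        return 3 + self.n * self.per_ligand

    @classmethod
    def from_config(cls, config: ClusterConfiguration, ligand: RigidLigand):
        dof = cls(ligand=ligand, n=config.n, ref_quats=config.quaternions.copy())
        return dof, dof.pack(config)

    def pack(self, config: ClusterConfiguration) -> np.ndarray:
        x = np.empty(self.n_dof)
        x[:3] = config.ion_position
        c_b = self.ligand.com_body
        for k in range(self.n):
            o = 3 + k * self.per_ligand
            rot = Rotation.from_quat(self.ref_quats[k])
            x[o : o + 3] = config.translations[k] + rot.apply(c_b)
            if self.has_orientation:
                x[o + 3 : o + 6] = 0.0
        return x

    def unpack(self, x: np.ndarray) -> ClusterConfiguration:
        c_b = self.ligand.com_body
        trans = np.empty((self.n, 3))
        quats = np.empty((self.n, 4))
        for k in range(self.n):
            o = 3 + k * self.per_ligand
            com = x[o : o + 3]
            if self.has_orientation:
                rot = Rotation.from_rotvec(x[o + 3 : o + 6]) * Rotation.from_quat(
                    self.ref_quats[k]
                )
            else:
                rot = Rotation.from_quat(self.ref_quats[k])
            q = rot.as_quat()
            quats[k] = q / np.linalg.norm(q)
            trans[k] = com - rot.apply(c_b)
        return ClusterConfiguration(x[:3].copy(), trans, quats)

    def recenter(self, x: np.ndarray) -> np.ndarray:
        config = self.unpack(x)
        self.ref_quats = config.quaternions.copy()
        return self.pack(config)

    def energy_fn(self, model: PotentialModel) -> Callable[[np.ndarray], float]:
        def f(x: np.ndarray) -> float:
            e = model.energy(self.unpack(x), raise_on_overlap=False)
            return e if np.isfinite(e) else 1e12

        return f

    def gradient_fn(self, model: PotentialModel) -> Callable[[np.ndarray], np.ndarray]:
        def g(x: np.ndarray) -> np.ndarray:
            config = self.unpack(x)
            g_ion, g_sites = model.site_gradients(config)
            out = np.empty(self.n_dof)
            out[:3] = g_ion
            sites = config.all_sites(self.ligand)
            for k in range(self.n):
                o = 3 + k * self.per_ligand
                out[o : o + 3] = g_sites[k].sum(axis=0)
                if self.has_orientation:
                    com = x[o : o + 3]
                    a = sites[k] - com
                    torque = np.cross(a, g_sites[k]).sum(axis=0)
                    out[o + 3 : o + 6] = _left_jacobian(x[o + 3 : o + 6]).T @ torque
            return out

        return g

    def mass_matrix(self, x: np.ndarray, ion_mass: float) -> np.ndarray:
        """Block-diagonal metric: ion mass, ligand masses, world-frame inertia."""
        M = np.zeros((self.n_dof, self.n_dof))
        M[:3, :3] = ion_mass * np.eye(3)
        config = self.unpack(x)
        for k in range(self.n):
            o = 3 + k * self.per_ligand
            M[o : o + 3, o : o + 3] = self.ligand.mass * np.eye(3)
            if self.has_orientation:
                R = Rotation.from_quat(config.quaternions[k]).as_matrix()
                M[o + 3 : o + 6, o + 3 : o + 6] = R @ self.ligand.inertia_body @ R.T
        return M

    def rigid_zero_basis(self, x: np.ndarray) -> np.ndarray:
        """Columns spanning global translations and rotations (about origin)."""
        config = self.unpack(x)
        cols = []
        for i in range(3):
            v = np.zeros(self.n_dof)
            v[i] = 1.0
            for k in range(self.n):
                v[3 + k * self.per_ligand + i] = 1.0
            cols.append(v)
        for i in range(3):
            w = np.zeros(3)
            w[i] = 1.0
            v = np.zeros(self.n_dof)
            v[:3] = np.cross(w, config.ion_position)
            for k in range(self.n):
                o = 3 + k * self.per_ligand
                v[o : o + 3] = np.cross(w, x[o : o + 3])
                if self.has_orientation:
                    v[o + 3 : o + 6] = w
            cols.append(v)
        return np.array(cols).T


# --------------------------------------------------------------------------
# optimisation


@dataclass
class OptimizedStructure:
    """A converged local minimum on the surrogate surface."""

    config: ClusterConfiguration
    energy: float
    gradient_norm: float  # max |dE/dx|, kcal/mol per A (or rad)
    start_index: int
    dof: ClusterDOF

    @property
    def n(self) -> int:
        return self.config.n

    def atoms(self, model: PotentialModel):
        return self.config.to_atoms(model.ligand, model.ion)


def _optimize_single(
    config: ClusterConfiguration,
    model: PotentialModel,
    gtol: float,
    start_index: int,
    max_cycles: int = 8,
) -> Optional[OptimizedStructure]:
    dof, x = ClusterDOF.from_config(config, model.ligand)
    f = dof.energy_fn(model)
    g = dof.gradient_fn(model)
    for _ in range(max_cycles):
        res = optimize.minimize(
            f,
            x,
            jac=g,
            method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": 1e-16, "gtol": 1e-9},
        )
        x = dof.recenter(res.x)
        gnorm = float(np.abs(g(x)).max())
        if gnorm < gtol:
            return OptimizedStructure(
                config=dof.unpack(x),
                energy=float(f(x)),
                gradient_norm=gnorm,
                start_index=start_index,
                dof=dof,
            )
    return None


def multi_start_optimize(
    trajectory,
    model: PotentialModel,
    n_starts: int = 20,
    gtol: float = 1e-6,
) -> OptimizedStructure:
    """Local minimisation from uniformly spaced sampled frames.

    Returns the lowest-energy converged structure; ties below 1e-8 kcal/mol
    go to the earliest start index.  Raises if no start converges.
    """
    frames = trajectory.frames
    if len(frames) < n_starts:
        raise ValueError(f"trajectory has {len(frames)} frames < n_starts={n_starts}")
    idx = np.unique(np.linspace(0, len(frames) - 1, n_starts).astype(int))
    results, failures = [], []
    for i in idx:
        out = _optimize_single(frames[i], model, gtol, start_index=int(i))
        if out is None:
            failures.append(int(i))
        else:
            results.append(out)
    if not results:
        raise RuntimeError(f"no optimisation start converged (starts: {failures})")
    best = min(results, key=lambda s: (round(s.energy / 1e-8), s.start_index))
    return best


# --------------------------------------------------------------------------
# Hessian and normal modes


def numerical_hessian(
    f: Callable[[np.ndarray], float], x0: np.ndarray, step: float = 1e-3
) -> np.ndarray:
    """Central finite-difference Hessian, symmetrised as (H + H^T)/2.

    Warns if the raw asymmetry exceeds 1e-4 (a sign the step is poorly
    chosen for the surface's curvature scale).
    """
    x0 = np.asarray(x0, dtype=float)
    d = len(x0)
    H = np.empty((d, d))
    f0 = f(x0)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * step**2)
    asym = np.abs(H - H.T).max()
    if asym > 1e-4:
        warnings.warn(f"Hessian asymmetry {asym:.2e} before symmetrisation")
    return 0.5 * (H + H.T)


@dataclass
class NormalModeSet:
    """Retained harmonic modes after zero-mode removal."""

    frequencies: np.ndarray  # cm^-1, ascending, magnitudes
    eigenvalues: np.ndarray  # kcal/mol/(amu A^2), ascending
    n_zero_modes: int
    imaginary_flags: np.ndarray  # bool per retained mode

    @property
    def has_imaginary(self) -> bool:
        return bool(self.imaginary_flags.any())


def normal_modes(
    hessian: np.ndarray,
    masses,
    n_zero: Optional[int] = None,
    zero_basis: Optional[np.ndarray] = None,
    imag_tol: float = 1e-6,
) -> NormalModeSet:
    """Mass-weighted normal modes of a (generalised-coordinate) Hessian.

    ``masses`` is either a per-coordinate vector (diagonal metric) or a full
    mass matrix.  If ``zero_basis`` is given, rigid-body directions are
    projected out first and ``n_zero`` defaults to its rank; otherwise the
    ``n_zero`` smallest-|eigenvalue| modes are removed (or counted
    automatically against a tolerance when ``n_zero`` is None).
    """
    H = np.asarray(hessian, dtype=float)
    masses = np.asarray(masses, dtype=float)
    M = np.diag(masses) if masses.ndim == 1 else masses
    L = linalg.cholesky(M, lower=True)
    Linv = linalg.solve_triangular(L, np.eye(len(M)), lower=True)
    Ht = Linv @ H @ Linv.T
    rank = 0
    if zero_basis is not None and zero_basis.size:
        Y = L.T @ zero_basis
        u, s, _ = np.linalg.svd(Y, full_matrices=False)
        rank = int((s > s[0] * 1e-10).sum())
        Q = u[:, :rank]
        P = np.eye(len(M)) - Q @ Q.T
        Ht = P @ Ht @ P
        if n_zero is None:
            n_zero = rank
    lam = np.linalg.eigvalsh(0.5 * (Ht + Ht.T))
    order = np.argsort(np.abs(lam))
    if n_zero is None:
        scale = max(np.abs(lam).max(), 1.0)
        n_zero = int((np.abs(lam) < imag_tol * scale).sum())
    kept = np.sort(lam[order[n_zero:]])
    freqs = np.array([wavenumber_from_eigenvalue(l) for l in kept])
    flags = kept < -imag_tol
    low = freqs[(~flags) & (freqs < LOW_FREQ_WARN_CM)]
    if low.size:
        logger.warning(
            "%d retained mode(s) below %.0f cm^-1: classical and quantum q_vib diverge there",
            low.size,
            LOW_FREQ_WARN_CM,
        )
    return NormalModeSet(
        frequencies=freqs,
        eigenvalues=kept,
        n_zero_modes=int(n_zero),
        imaginary_flags=flags,
    )


def cluster_normal_modes(
    structure: OptimizedStructure,
    model: PotentialModel,
    step: float = 1e-3,
) -> NormalModeSet:
    """Normal modes of an optimised cluster in rigid-body coordinates."""
    dof = structure.dof
    x0 = dof.pack(structure.config)
    H = numerical_hessian(dof.energy_fn(model), x0, step=step)
    M = dof.mass_matrix(x0, model.ion.mass)
    B = dof.rigid_zero_basis(x0)
    return normal_modes(H, M, zero_basis=B)


# --------------------------------------------------------------------------
# partition functions


def _freq_s1(nu_cm: float) -> float:
    return nu_cm * C_CM_S


def quantum_qvib_factor(nu_cm: float, temperature: float) -> float:
    """Per-mode quantum HO factor e^{-u/2}/(1 - e^{-u}), u = beta h nu."""
    u = PLANCK_J_S * _freq_s1(nu_cm) / (KB_J * temperature)
    return math.exp(-u / 2.0) / (1.0 - math.exp(-u))

def classical_qvib_factor(nu_cm: float, temperature: float) -> float:
    """Per-mode classical HO factor 1/u, u = beta h nu."""
    u = PLANCK_J_S * _freq_s1(nu_cm) / (KB_J * temperature)
    return 1.0 / u


def _principal_moments(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    com = masses @ coords / masses.sum()
    d = coords - com
    r2 = np.einsum("si,si->s", d, d)
    inertia = np.einsum("s,ij->ij", masses * r2, np.eye(3)) - np.einsum(
        "s,si,sj->ij", masses, d, d
    )
    return np.sort(np.linalg.eigvalsh(inertia))  # amu A^2, ascending


def rotational_partition(
    coords: np.ndarray, masses: np.ndarray, temperature: float, sigma: int = 1
) -> float:
    """Classical rotor q_rot from atomic coordinates; 1 for a single atom."""
    if len(masses) == 1:
        return 1.0
    I = _principal_moments(coords, masses) * AMU_KG * 1e-20  # kg m^2
    kT = KB_J * temperature
    h2 = PLANCK_J_S**2
    if I[0] < 1e-6 * I[2]:  # linear
        return 8 * math.pi**2 * I[2] * kT / (sigma * h2)
    return (
        math.sqrt(math.pi)
        / sigma
        * (8 * math.pi**2 * kT / h2) ** 1.5
        * math.sqrt(I[0] * I[1] * I[2])
    )


@dataclass
class HarmonicThermo:
    """RRHO factors for one optimised W_nX cluster."""

    n: int
    q_trans_per_volume: float  # A^-3
    q_rot: float
    q_vib: float
    zero_point_energy: float  # kcal/mol (0 for classical statistics)
    well_depth: float  # E_min, kcal/mol (negative when bound)
    permutation_factor: float  # n!
    rotor_symmetry_number: int
    modes: NormalModeSet
    statistics: str


def harmonic_thermo(
    structure: OptimizedStructure,
    model: PotentialModel,
    thermo: ThermoState,
    statistics: str = "quantum",
    sigma: int = 1,
    step: float = 1e-3,
) -> HarmonicThermo:
    """Assemble the RRHO partition factors for one optimised structure."""
    if statistics not in ("quantum", "classical"):
        raise ValueError("statistics must be 'quantum' or 'classical'")
    modes = cluster_normal_modes(structure, model, step=step)
    if modes.has_imaginary:
        raise ValueError(
            f"imaginary modes present for n={structure.n} structure "
            f"(start {structure.start_index}); not a true minimum"
        )
    _, coords, masses = structure.config.to_atoms(model.ligand, model.ion)
    T = thermo.temperature
    q_t = thermal_wavelength_cubed_inv(masses.sum(), T)
    q_r = rotational_partition(coords, masses, T, sigma=sigma)
    if statistics == "quantum":
        q_v = float(np.prod([quantum_qvib_factor(f, T) for f in modes.frequencies]))
        zpe = 0.5 * sum(
            PLANCK_J_S * _freq_s1(f) / (KB_J * T) for f in modes.frequencies
        ) * thermo.rt
    else:
        q_v = float(np.prod([classical_qvib_factor(f, T) for f in modes.frequencies]))
        zpe = 0.0
    return HarmonicThermo(
        n=structure.n,
        q_trans_per_volume=q_t,
        q_rot=q_r,
        q_vib=q_v,
        zero_point_energy=zpe,
        well_depth=structure.energy,
        permutation_factor=float(math.factorial(structure.n)),
        rotor_symmetry_number=sigma,
        modes=modes,
        statistics=statistics,
    )


def ligand_free_partition(
    ligand: RigidLigand, temperature: float, sigma: int = 1
) -> tuple[float, float]:
    """(q_trans/V, q_rot) of a free rigid ligand (q_vib = 1: rigid)."""
    q_t = thermal_wavelength_cubed_inv(ligand.mass, temperature)
    if ligand.n_sites == 1:
        return q_t, 1.0
    coords = ligand.body_positions
    masses = np.asarray(ligand.site_masses, dtype=float)
    return q_t, rotational_partition(coords, masses, temperature, sigma=sigma)


def harmonic_chain(
    structures: Sequence[OptimizedStructure],
    model: PotentialModel,
    thermo: ThermoState,
    statistics: str = "quantum",
    sigma: int = 1,
    ligand_sigma: int = 1,
) -> EquilibriumChain:
    """RRHO equilibrium constants K_n (volume units) for the given structures.

    ``structures`` holds optimised clusters for n = 1..N (contiguous).
    K_0 = 1 by construction.  Raises if any structure has imaginary modes.
    """
    structures = sorted(structures, key=lambda s: s.n)
    if [s.n for s in structures] != list(range(1, len(structures) + 1)):
        raise ValueError("structures must cover n = 1..N contiguously")
    T = thermo.temperature
    beta = thermo.beta
    qt_ion = thermal_wavelength_cubed_inv(model.ion.mass, T)
    qt_w, qr_w = ligand_free_partition(model.ligand, T, sigma=ligand_sigma)
    ks = [1.0]
    for s in structures:
        ht = harmonic_thermo(s, model, thermo, statistics=statistics, sigma=sigma)
        log_k = (
            math.log(ht.q_trans_per_volume)
            + math.log(ht.q_rot)
            + math.log(ht.q_vib)
            - beta * ht.well_depth
            - math.log(ht.permutation_factor)
            - math.log(qt_ion)
            - s.n * (math.log(qt_w) + math.log(qr_w))
        )
        ks.append(math.exp(log_k))
    return EquilibriumChain(
        k_n=np.array(ks),
        log_std_error=np.zeros(len(ks)),
        method=f"harmonic_{statistics}",
    )
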