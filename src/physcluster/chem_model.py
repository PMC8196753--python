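"""Species, cluster geometry, and the surrogate potential energy surface.

The package studies associative equilibria  n W + X <-> W_nX  for an anion X
solvated by rigid ligands W.  This module defines the thermodynamic state,
the species (ion + rigid ligand), the cluster configuration (ion position
plus one rigid-body pose per ligand), and a classical surrogate potential --
fixed point charges plus Lennard-Jones sites -- standing in for the cluster
electronic energy U(W_nX).

Conventions
-----------
* Units: Angstrom, kcal/mol, amu, Kelvin, elementary charge.
* A ligand pose is (translation, unit quaternion); the translation is the
  position of the ligand *reference site* (the O atom for water), which is
  pinned at the body-frame origin.  Proximity criteria are evaluated on
  reference sites.
* Quaternions use the scipy scalar-last convention (x, y, z, w).
* ``ligand_coupling`` scales every ligand-ligand interaction; 0 gives the
  ideal-ligand limit in which the cluster energy is a sum of independent
  ion-ligand terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import KB, COULOMB, standard_concentration

__all__ = [
    "ThermoState",
    "IonSpecies",
    "RigidLigand",
    "ClusterConfiguration",
    "PotentialModel",
    "RadialPotential",
    "CoincidentSitesError",
    "ion",
    "total_energy",
    "subsystem_energy",
    "random_configuration",
    "batch_energy",
    "random_quaternions",
]


class CoincidentSitesError(ValueError):
    """Two interaction sites closer than the hard-core guard distance."""


# --------------------------------------------------------------------------
# thermodynamic state


@dataclass(frozen=True)
class ThermoState:
    """Temperature and standard-state convention.

    ``beta`` is 1/(k_B T) in mol/kcal; ``standard_concentration`` is the
    number density (1/A^3) of the chosen standard state, used to make the
    volume-unit equilibrium constants K_n (A^{3n}) dimensionless.
    """

    temperature: float = 300.0
    standard_state: str = "1atm"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)

    @property
    def rt(self) -> float:
        """RT in kcal/mol."""
        return KB * self.temperature

    @property
    def standard_concentration(self) -> float:
        return standard_concentration(self.temperature, self.standard_state)


# --------------------------------------------------------------------------
# species


@dataclass(frozen=True)
class IonSpecies:
    label: str
    mass: float
    lj_sigma: float
    lj_epsilon: float
    charge: float = -1.0

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.lj_sigma <= 0 or self.lj_epsilon < 0:
            raise ValueError("invalid ion parameters")


#: Surrogate halide parameters.  Charges are -1 e; the LJ radii grow down the
#: group so the first-shell distance and well depth follow the familiar
#: F > Cl > Br > I binding-strength order.  Qualitative stand-ins only.
ION_TABLE: dict[str, IonSpecies] = {
    "F": IonSpecies("F", 18.998, 3.10, 0.20),
    "Cl": IonSpecies("Cl", 35.453, 4.40, 0.10),
    "Br": IonSpecies("Br", 79.904, 4.65, 0.07),
    "I": IonSpecies("I", 126.904, 5.10, 0.04),
    "toy": IonSpecies("toy", 40.0, 3.50, 0.10),
}


def ion(label: str, **overrides) -> IonSpecies:
    """Look up an ion species by label, optionally overriding fields."""
    try:
        base = ION_TABLE[label]
    except KeyError:
        raise KeyError(f"unknown ion label {label!r}; known: {sorted(ION_TABLE)}")
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class RigidLigand:
    """A rigid multi-site ligand; geometry is identical in every configuration.

    ``site_positions_body_frame[0]`` is the reference site and sits at the
    body-frame origin.
    """

    site_positions_body_frame: tuple  # of (x, y, z)
    site_charges: tuple
    site_lj: tuple  # of (sigma, epsilon)
    site_masses: tuple
    site_symbols: tuple
    mode: str  # rigid_water_3site | point_ligand

    def __post_init__(self) -> None:
        pos = np.asarray(self.site_positions_body_frame, dtype=float)
        if np.linalg.norm(pos[0]) > 1e-12:
            raise ValueError("reference site must be at the body-frame origin")
        if self.mode == "rigid_water_3site":
            if self.n_sites != 3:
                raise ValueError("rigid_water_3site has exactly 3 sites")
            if abs(sum(self.site_charges)) > 1e-12:
                raise ValueError("water site charges must sum to zero")
        elif self.mode == "point_ligand":
            if self.n_sites != 1:
                raise ValueError("point_ligand has exactly 1 site")
        else:
            raise ValueError(f"unknown ligand mode {self.mode!r}")

    @property
    def n_sites(self) -> int:
        return len(self.site_positions_body_frame)

    @property
    def body_positions(self) -> np.ndarray:
        return np.asarray(self.site_positions_body_frame, dtype=float)

    @property
    def mass(self) -> float:
        return float(sum(self.site_masses))

    @property
    def com_body(self) -> np.ndarray:
        m = np.asarray(self.site_masses, dtype=float)
        return m @ self.body_positions / m.sum()

    @property
    def inertia_body(self) -> np.ndarray:
        """Inertia tensor (amu A^2) about the centre of mass, body frame."""
        m = np.asarray(self.site_masses, dtype=float)
        d = self.body_positions - self.com_body
        r2 = np.einsum("si,si->s", d, d)
        return np.einsum("s,ij->ij", m * r2, np.eye(3)) - np.einsum(
            "s,si,sj->ij", m, d, d
        )

    @staticmethod
    def rigid_water_3site(
        r_oh: float = 0.9572,
        theta_deg: float = 104.52,
        q_h: float = 0.417,
        sigma_o: float = 3.1506,
        epsilon_o: float = 0.1521,
    ) -> "RigidLigand":
        """TIP3P-like rigid water: O at the origin, H sites in the xz-plane,
        LJ on O only, charges q_O = -2 q_H."""
        half = math.radians(theta_deg / 2.0)
        h1 = (r_oh * math.sin(half), 0.0, r_oh * math.cos(half))
        h2 = (-r_oh * math.sin(half), 0.0, r_oh * math.cos(half))
        return RigidLigand(
            site_positions_body_frame=((0.0, 0.0, 0.0), h1, h2),
            site_charges=(-2.0 * q_h, q_h, q_h),
            site_lj=((sigma_o, epsilon_o), (0.0, 0.0), (0.0, 0.0)),
            site_masses=(15.999, 1.008, 1.008),
            site_symbols=("O", "H", "H"),
            mode="rigid_water_3site",
        )

    @staticmethod
    def point_ligand(
        charge: float = 0.25,
        sigma: float = 3.0,
        epsilon: float = 0.10,
        mass: float = 18.0,
        symbol: str = "L",
    ) -> "RigidLigand":
        """A single-site (structureless) ligand; no orientational degrees of freedom."""
        return RigidLigand(
            site_positions_body_frame=((0.0, 0.0, 0.0),),
            site_charges=(charge,),
            site_lj=((sigma, epsilon),),
            site_masses=(mass,),
            site_symbols=(symbol,),
            mode="point_ligand",
        )


# --------------------------------------------------------------------------
# configurations


IDENTITY_QUAT = np.array([0.0, 0.0, 0.0, 1.0])


@dataclass
class ClusterConfiguration:
    """Geometry of one W_nX cluster: ion position plus n rigid-body poses."""

    ion_position: np.ndarray
    translations: np.ndarray  # (n, 3), reference-site positions
    quaternions: np.ndarray  # (n, 4), scalar-last

    def __post_init__(self) -> None:
        self.ion_position = np.asarray(self.ion_position, dtype=float).reshape(3)
        self.translations = np.asarray(self.translations, dtype=float).reshape(-1, 3)
        self.quaternions = np.asarray(self.quaternions, dtype=float).reshape(-1, 4)
        if len(self.quaternions) != len(self.translations):
            raise ValueError("one quaternion required per ligand")
        norms = np.linalg.norm(self.quaternions, axis=1)
        if self.n and np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("orientations must be unit quaternions")

    @property
    def n(self) -> int:
        return len(self.translations)

    def copy(self) -> "ClusterConfiguration":
        return ClusterConfiguration(
            self.ion_position.copy(),
            self.translations.copy(),
            self.quaternions.copy(),
        )

    def ligand_sites(self, ligand: RigidLigand, k: int) -> np.ndarray:
        """World-frame site coordinates (s, 3) of ligand ``k``."""
        rot = Rotation.from_quat(self.quaternions[k])
        return self.translations[k] + rot.apply(ligand.body_positions)

    def all_sites(self, ligand: RigidLigand) -> np.ndarray:
        """World-frame site coordinates (n, s, 3) of all ligands."""
        if self.n == 0:
            return np.zeros((0, ligand.n_sites, 3))
        mats = Rotation.from_quat(self.quaternions).as_matrix()  # (n, 3, 3)
        body = ligand.body_positions
        return self.translations[:, None, :] + np.einsum(
            "nij,sj->nsi", mats, body
        )

    def to_atoms(self, ligand: RigidLigand, ion_species: IonSpecies):
        """Expand to Cartesian atoms: (symbols, coords (1 + n*s, 3), masses)."""
        coords = [self.ion_position[None, :]]
        symbols = [ion_species.label]
        masses = [ion_species.mass]
        if self.n:
            sites = self.all_sites(ligand)
            coords.append(sites.reshape(-1, 3))
            symbols += list(ligand.site_symbols) * self.n
            masses += list(ligand.site_masses) * self.n
        return symbols, np.concatenate(coords, axis=0), np.array(masses)


def random_quaternions(rng: np.random.Generator, size: int) -> np.ndarray:
    """Quaternions uniform on S^3 (Haar measure on SO(3))."""
    q = rng.normal(size=(size, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


# --------------------------------------------------------------------------
# potential model


@dataclass(frozen=True)
class RadialPotential:
    """A radial pair potential u(r) with an optional analytic derivative.

    Used to override the Coulomb+LJ form between the ion and the ligand
    reference site (or between reference sites), e.g. for toy wells in
    validation studies.  ``u`` must accept numpy arrays.
    """

    u: Callable[[np.ndarray], np.ndarray]
    du: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __call__(self, r: np.ndarray) -> np.ndarray:
        return self.u(np.asarray(r, dtype=float))

    def deriv(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if self.du is not None:
            return self.du(r)
        h = 1e-6
        return (self.u(r + h) - self.u(r - h)) / (2 * h)


def _lorentz_berthelot(lj_a, lj_b):
    sig = 0.5 * (lj_a[0] + lj_b[0])
    eps = math.sqrt(lj_a[1] * lj_b[1])
    return sig, eps


@dataclass(frozen=True)
class PotentialModel:
    """Classical surrogate for the cluster energy U(W_nX).

    Pairwise Coulomb (dielectric 1) + Lennard-Jones over all intersite
    pairs; Lorentz-Berthelot combining for cross LJ parameters; no cutoffs
    or periodicity (finite clusters, all pairs summed exactly).  Isolated
    rigid species have zero energy, so U(X) = U(W) = 0 and cluster energies
    are binding energies directly.
    """

    ion: IonSpecies
    ligand: RigidLigand
    ligand_coupling: float = 1.0
    combining: str = "lorentz_berthelot"
    ion_ligand_pair: Optional[RadialPotential] = None
    ligand_ligand_pair: Optional[RadialPotential] = None
    min_site_distance: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.ligand_coupling <= 1.0:
            raise ValueError("ligand_coupling must lie in [0, 1]")
        if self.combining != "lorentz_berthelot":
            raise ValueError("only lorentz_berthelot combining is implemented")

    # cached parameter tables -------------------------------------------------
    @property
    def _ion_site_params(self):
        """Per-site (qq, sigma, epsilon) for ion-site pairs."""
        lig = self.ligand
        qq = np.array([self.ion.charge * q for q in lig.site_charges])
        se = [
            _lorentz_berthelot((self.ion.lj_sigma, self.ion.lj_epsilon), lj)
            for lj in lig.site_lj
        ]
        return qq, np.array([s for s, _ in se]), np.array([e for _, e in se])

    @property
    def _site_site_params(self):
        """Per-(s,s') (qq, sigma, epsilon) for sites on two different ligands."""
        lig = self.ligand
        q = np.asarray(lig.site_charges, dtype=float)
        qq = np.outer(q, q)
        s_ = lig.n_sites
        sig = np.zeros((s_, s_))
        eps = np.zeros((s_, s_))
        for a in range(s_):
            for b in range(s_):
                sig[a, b], eps[a, b] = _lorentz_berthelot(lig.site_lj[a], lig.site_lj[b])
        return qq, sig, eps

    # pair energies -----------------------------------------------------------
    def _coul_lj(self, d, qq, sig, eps):
        """Coulomb + LJ on distance array d; +inf below the hard-core guard."""
        d = np.asarray(d, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            e = COULOMB * qq / d
            x6 = (sig / np.maximum(d, 1e-300)) ** 6
            e = e + np.where(eps > 0, 4.0 * eps * (x6 * x6 - x6), 0.0)
        return np.where(d < self.min_site_distance, np.inf, e)

    def ion_ligand_energy(self, config: ClusterConfiguration, k: int) -> float:
        """Interaction energy between the ion and ligand k (all sites)."""
        sites = config.ligand_sites(self.ligand, k)
        if self.ion_ligand_pair is not None:
            r = np.linalg.norm(sites[0] - config.ion_position)
            if r < self.min_site_distance:
                return np.inf
            return float(self.ion_ligand_pair(r))
        qq, sig, eps = self._ion_site_params
        d = np.linalg.norm(sites - config.ion_position, axis=1)
        return float(np.sum(self._coul_lj(d, qq, sig, eps)))

    def ligand_pair_energy(self, config: ClusterConfiguration, j: int, k: int) -> float:
        """Unscaled interaction energy between ligands j and k."""
        if self.ligand_ligand_pair is not None:
            r = np.linalg.norm(config.translations[j] - config.translations[k])
            if r < self.min_site_distance:
                return np.inf
            return float(self.ligand_ligand_pair(r))
        a = config.ligand_sites(self.ligand, j)
        b = config.ligand_sites(self.ligand, k)
        qq, sig, eps = self._site_site_params
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
        return float(np.sum(self._coul_lj(d, qq, sig, eps)))

    # total / subsystem energies ----------------------------------------------
    def energy(self, config: ClusterConfiguration, keep: Optional[Iterable[int]] = None,
               raise_on_overlap: bool = True) -> float:
        idx = list(range(config.n)) if keep is None else sorted(set(keep))
        for k in idx:
            if not 0 <= k < config.n:
                raise IndexError(f"ligand index {k} out of range for n={config.n}")
        e = 0.0
        for k in idx:
            e += self.ion_ligand_energy(config, k)
        if self.ligand_coupling != 0.0:
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    e += self.ligand_coupling * self.ligand_pair_energy(
                        config, idx[a], idx[b]
                    )
        if not np.isfinite(e) and raise_on_overlap:
            pair = self._find_overlap(config, idx)
            raise CoincidentSitesError(
                f"sites closer than {self.min_site_distance} A: {pair}"
            )
        return float(e)

    def _find_overlap(self, config, idx):
        sites = config.all_sites(self.ligand)
        for k in idx:
            d = np.linalg.norm(sites[k] - config.ion_position, axis=1)
            if d.min() < self.min_site_distance:
                return ("ion", f"ligand {k} site {int(d.argmin())}")
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                d = np.linalg.norm(
                    sites[idx[a]][:, None, :] - sites[idx[b]][None, :, :], axis=2
                )
                if d.min() < self.min_site_distance:
                    return (f"ligand {idx[a]}", f"ligand {idx[b]}")
        return ("unknown", "unknown")

    # analytic site gradients ---------------------------------------------------
    def site_gradients(self, config: ClusterConfiguration):
        """dE/dr for the ion and every ligand site: (g_ion (3,), g_sites (n,s,3))."""
        lig = self.ligand
        sites = config.all_sites(lig)
        g_ion = np.zeros(3)
        g_sites = np.zeros_like(sites)

        def pair_grad(d, qq, sig, eps):
            # dE/dd for Coulomb + LJ
            with np.errstate(divide="ignore"):
                x6 = np.where(eps > 0, (sig / d) ** 6, 0.0)
                return -COULOMB * qq / d**2 + np.where(
                    eps > 0, 4.0 * eps * (-12.0 * x6 * x6 + 6.0 * x6) / d, 0.0
                )

        # ion-ligand
        for k in range(config.n):
            if self.ion_ligand_pair is not None:
                vec = sites[k, 0] - config.ion_position
                r = np.linalg.norm(vec)
                du = float(self.ion_ligand_pair.deriv(r))
                g = du * vec / r
                g_sites[k, 0] += g
                g_ion -= g
            else:
                qq, sig, eps = self._ion_site_params
                vec = sites[k] - config.ion_position
                d = np.linalg.norm(vec, axis=1)
                du = pair_grad(d, qq, sig, eps)
                g = (du / d)[:, None] * vec
                g_sites[k] += g
                g_ion -= g.sum(axis=0)
        # ligand-ligand
        if self.ligand_coupling != 0.0:
            lam = self.ligand_coupling
            for j in range(config.n):
                for k in range(j + 1, config.n):
                    if self.ligand_ligand_pair is not None:
                        vec = sites[k, 0] - sites[j, 0]
                        r = np.linalg.norm(vec)
                        du = lam * float(self.ligand_ligand_pair.deriv(r))
                        g = du * vec / r
                        g_sites[k, 0] += g
                        g_sites[j, 0] -= g
                    else:
                        qq, sig, eps = self._site_site_params
                        vec = sites[k][None, :, :] - sites[j][:, None, :]
                        d = np.linalg.norm(vec, axis=2)
                        du = lam * pair_grad(d, qq, sig, eps)
                        g = (du / d)[:, :, None] * vec
                        g_sites[k] += g.sum(axis=0)
                        g_sites[j] -= g.sum(axis=1)
        return g_ion, g_sites


def total_energy(config: ClusterConfiguration, model: PotentialModel) -> float:
    """Cluster energy U(W_nX): ion-ligand pair sums plus coupling-scaled
    ligand-ligand pair sums.  Raises :class:`CoincidentSitesError` if any two
    sites fall inside the hard-core guard."""
    return model.energy(config)


def subsystem_energy(
    config: ClusterConfiguration, keep_ligands: Iterable[int], model: PotentialModel
) -> float:
    """Energy of the sub-cluster containing the ion and only ``keep_ligands``
    (0-based indices), all coordinates frozen at the parent configuration."""
    return model.energy(config, keep=keep_ligands)


# --------------------------------------------------------------------------
# random configurations


def random_configuration(
    n: int,
    criterion,
    seed: Optional[int] = None,
    *,
    ligand: Optional[RigidLigand] = None,
    rng: Optional[np.random.Generator] = None,
    min_separation: float = 1.8,
    max_tries: int = 2000,
) -> ClusterConfiguration:
    """A clustered starting configuration: ion at the origin, ligands placed
    at random within the criterion's ion-ligand radius, random orientations,
    rejecting placements that bring any two sites closer than
    ``min_separation``.  Deterministic for a fixed seed."""
    if n < 0:
        raise ValueError("n must be non-negative")
    ligand = ligand or RigidLigand.rigid_water_3site()
    rng = rng or np.random.default_rng(seed)
    if n == 0:
        return ClusterConfiguration(np.zeros(3), np.zeros((0, 3)), np.zeros((0, 4)))
    r_hi = criterion.r_ion_ligand
    r_lo = min(2.0, 0.5 * r_hi)
    placed_sites: list[np.ndarray] = []
    trans, quats = [], []
    for _ in range(n):
        for attempt in range(max_tries):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = (r_lo**3 + (r_hi**3 - r_lo**3) * rng.random()) ** (1.0 / 3.0)
            t = r * u
            q = random_quaternions(rng, 1)[0]
            sites = t + Rotation.from_quat(q).apply(ligand.body_positions)
            ok = np.linalg.norm(sites, axis=1).min() >= r_lo * 0.8
            for other in placed_sites:
                if not ok:
                    break
                d = np.linalg.norm(sites[:, None, :] - other[None, :, :], axis=2)
                ok = d.min() >= min_separation
            if ok:
                placed_sites.append(sites)
                trans.append(t)
                quats.append(q)
                break
        else:
            raise RuntimeError(
                f"could not place ligand without overlap after {max_tries} tries"
            )
    config = ClusterConfiguration(np.zeros(3), np.array(trans), np.array(quats))
    if not criterion.is_clustered(config):
        raise RuntimeError("random placement violated the cluster criterion")
    return config


# --------------------------------------------------------------------------
# batched energies (vectorized over many configurations; used by the oracles)


def batch_energy(
    model: PotentialModel,
    translations: np.ndarray,  # (B, n, 3)
    quaternions: np.ndarray,  # (B, n, 4)
    ion_position: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Cluster energies for a batch of configurations; +inf where the
    hard-core guard is violated (excluded region of the PES domain)."""
    B, n, _ = translations.shape
    lig = model.ligand
    s = lig.n_sites
    ion_pos = np.zeros(3) if ion_position is None else np.asarray(ion_position)
    # site coordinates (B, n, s, 3)
    body = lig.body_positions
    if s == 1:
        sites = translations[:, :, None, :].copy()
    else:
        mats = Rotation.from_quat(quaternions.reshape(B * n, 4)).as_matrix()
        sites = translations[:, :, None, :] + np.einsum(
            "bij,sj->bsi", mats, body
        ).reshape(B, n, s, 3)
    e = np.zeros(B)
    # ion-ligand terms
    if model.ion_ligand_pair is not None:
        d = np.linalg.norm(sites[:, :, 0, :] - ion_pos, axis=2)
        e += np.where(
            d < model.min_site_distance, np.inf, model.ion_ligand_pair(d)
        ).sum(axis=1)
    else:
        qq, sig, eps = model._ion_site_params
        d = np.linalg.norm(sites - ion_pos, axis=3)  # (B, n, s)
        e += model._coul_lj(d, qq, sig, eps).sum(axis=(1, 2))
    # ligand-ligand terms
    if model.ligand_coupling != 0.0 and n > 1:
        lam = model.ligand_coupling
        for j in range(n):
            for k in range(j + 1, n):
                if model.ligand_ligand_pair is not None:
                    d = np.linalg.norm(
                        sites[:, j, 0, :] - sites[:, k, 0, :], axis=1
                    )
                    e += lam * np.where(
                        d < model.min_site_distance,
                        np.inf,
                        model.ligand_ligand_pair(d),
                    )
                else:
                    qq, sig, eps = model._site_site_params
                    d = np.linalg.norm(
                        sites[:, j, :, None, :] - sites[:, k, None, :, :], axis=3
                    )  # (B, s, s)
                    e += lam * model._coul_lj(d, qq, sig, eps).sum(axis=(1, 2))
    return e
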