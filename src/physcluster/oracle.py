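"""Independent brute-force references for cluster equilibrium constants.

All estimators in this package are validated against direct evaluations of
the clustered-configuration integrals

    K_n = (1/n!) INT_clustered prod_i d^3r_i <dOmega_i>  e^{-beta U},

with the orientation measure normalised to 1 (so a free rigid ligand
contributes no factor and K_n carries volume units A^{3n}).  Three routes
are provided:

* ``analytic_ideal_chain`` -- the closed form K_n = K_1^n/n! of the
  ideal-ligand (no ligand-ligand coupling) limit;
* ``k1_quadrature`` -- deterministic radial (and orientation-grid)
  quadrature for n = 1;
* ``kn_mc_integration`` -- seeded Monte Carlo integration for n <= 3.

The Monte Carlo oracle supports two proposal densities: plain uniform
sampling of reference-site positions in the cutoff ball (simple, but
hopeless once beta times the well depth is large), and the default
``boltzmann1`` proposal, which draws each ligand's radius from the
orientation-averaged single-ligand Boltzmann density (piecewise-constant
histogram, so importance weights are exact) and orientations uniformly.
Both are unbiased; they differ only in variance.  In the ideal-ligand limit
with point ligands the boltzmann1 weights are constant and the estimator is
exact to machine precision.

Oracles target the ion_cutoff criterion, whose domain is a product of
balls.  The stillinger domain is not a product space; it is handled by
rejection counting against an enclosing ball (``domain_radius``), reported
with its own error bar, and documented as experimental.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate
from scipy.spatial.transform import Rotation

from .chem_model import PotentialModel, ThermoState, batch_energy, random_quaternions
from .roughscape import K1Anchor
from .sampler import ClusterCriterion

__all__ = [
    "OracleResult",
    "analytic_ideal_chain",
    "k1_quadrature",
    "kn_mc_integration",
    "k1_anchor_from_quadrature",
    "ion_ligand_radial_potential",
    "orientation_averaged_boltzmann",
]


@dataclass(frozen=True)
class OracleResult:
    """One oracle value of K_n (volume units A^{3n})."""

    k_n: float
    n: int
    method: str  # analytic_ideal | quadrature | mc_integration
    std_error: float = 0.0  # mc only
    error_estimate: float = 0.0  # quadrature grid-halving estimate
    n_evaluations: int = 0
    seed: Optional[int] = None
    low_precision: bool = False


# --------------------------------------------------------------------------


def analytic_ideal_chain(k1: float, n_max: int) -> list[OracleResult]:
    """K_n = K_1^n / n! for n = 0..n_max (exact in the ideal-ligand limit)."""
    if k1 <= 0:
        raise ValueError("k1 must be positive")
    return [
        OracleResult(k_n=k1**n / math.factorial(n), n=n, method="analytic_ideal")
        for n in range(n_max + 1)
    ]


# --------------------------------------------------------------------------


def ion_ligand_radial_potential(model: PotentialModel, r: np.ndarray) -> np.ndarray:
    """u(r) between the ion and a *point* ligand at distance r."""
    if model.ligand.n_sites != 1:
        raise ValueError("radial potential defined for point ligands only")
    if model.ion_ligand_pair is not None:
        return np.asarray(model.ion_ligand_pair(r), dtype=float)
    qq, sig, eps = model._ion_site_params
    return np.asarray(model._coul_lj(r, qq[0], sig[0], eps[0]), dtype=float)


def _orientation_grid(n_orient: int):
    """Product grid over SO(3): uniform alpha, gamma; Gauss-Legendre in cos(beta).
    Returns (quaternions (M,4), weights (M,) summing to 1)."""
    alpha = (np.arange(n_orient) + 0.5) * 2 * np.pi / n_orient
    gamma = (np.arange(n_orient) + 0.5) * 2 * np.pi / n_orient
    x, wx = np.polynomial.legendre.leggauss(n_orient)
    beta = np.arccos(x)
    a, b, g = np.meshgrid(alpha, beta, gamma, indexing="ij")
    w = np.broadcast_to(wx[None, :, None], a.shape).ravel()
    eul = np.stack([a.ravel(), b.ravel(), g.ravel()], axis=1)
    quats = Rotation.from_euler("ZYZ", eul).as_quat()
    return quats, w / w.sum()


def orientation_averaged_boltzmann(
    model: PotentialModel,
    thermo: ThermoState,
    r_grid: np.ndarray,
    n_orient: int = 16,
) -> np.ndarray:
    """<e^{-beta u(r, Omega)}>_Omega on a radial grid.

    For point ligands this is simply e^{-beta u(r)}.  Orientations excluded
    by the hard-core guard contribute zero weight.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    beta = thermo.beta
    if model.ligand.n_sites == 1:
        u = ion_ligand_radial_potential(model, r_grid)
        with np.errstate(over="ignore"):
            return np.exp(-beta * u)
    quats, w = _orientation_grid(n_orient)
    M = len(quats)
    out = np.empty_like(r_grid)
    for i, r in enumerate(r_grid):
        trans = np.zeros((M, 1, 3))
        trans[:, 0, 2] = r
        e = batch_energy(model, trans, quats[:, None, :])
        with np.errstate(over="ignore"):
            bz = np.where(np.isfinite(e), np.exp(-beta * e), 0.0)
        out[i] = float(bz @ w)
    return out


def k1_quadrature(
    model: PotentialModel,
    thermo: ThermoState,
    criterion: ClusterCriterion,
    n_radial: int = 512,
    n_orient: int = 24,
) -> OracleResult:
    """K_1 = 4 pi INT_0^Rc <e^{-beta u}>_Omega r^2 dr by quadrature.

    Point ligands use adaptive radial quadrature; rigid multi-site ligands
    use a Simpson radial grid times an SO(3) product grid, with the error
    estimated by halving both grids.
    """
    rc = criterion.r_ion_ligand
    beta = thermo.beta
    r_lo = model.min_site_distance
    if model.ligand.n_sites == 1:
        def integrand(r):
            u = ion_ligand_radial_potential(model, np.asarray([r]))[0]
            return math.exp(-beta * u) * r * r if np.isfinite(u) else 0.0

        val, err = integrate.quad(
            integrand, r_lo, rc, epsabs=0.0, epsrel=1e-10, limit=500
        )
        return OracleResult(
            k_n=4 * math.pi * val,
            n=1,
            method="quadrature",
            error_estimate=4 * math.pi * err,
            n_evaluations=0,
        )

    def grid_value(nr: int, no: int) -> float:
        r = np.linspace(r_lo, rc, nr | 1)  # odd count for Simpson
        bz = orientation_averaged_boltzmann(model, thermo, r, n_orient=no)
        return 4 * math.pi * float(integrate.simpson(bz * r * r, x=r))

    full = grid_value(n_radial, n_orient)
    half = grid_value(n_radial // 2, max(4, n_orient // 2))
    return OracleResult(
        k_n=full,
        n=1,
        method="quadrature",
        error_estimate=abs(full - half),
        n_evaluations=(n_radial | 1) * n_orient**3,
    )


def k1_anchor_from_quadrature(
    model: PotentialModel, thermo: ThermoState, criterion: ClusterCriterion, **kw
) -> K1Anchor:
    """Quadrature K_1 packaged as a chain anchor (the self-contained default)."""
    res = k1_quadrature(model, thermo, criterion, **kw)
    rel = res.error_estimate / res.k_n if res.k_n > 0 else 0.0
    return K1Anchor(value=res.k_n, provenance="oracle", log_std_error=rel)


# --------------------------------------------------------------------------


def _is_clustered_batch(criterion, trans: np.ndarray, ion_at_origin=True) -> np.ndarray:
    """Vectorised criterion indicator for (B, n, 3) reference-site positions."""
    d_ion = np.linalg.norm(trans, axis=2)  # (B, n)
    if criterion.mode == "ion_cutoff":
        return np.all(d_ion <= criterion.r_ion_ligand, axis=1)
    B, n, _ = trans.shape
    d_ll = np.linalg.norm(trans[:, :, None, :] - trans[:, None, :, :], axis=3)
    adj_ion = d_ion <= criterion.r_ion_ligand
    adj_ll = d_ll <= criterion.r_ligand_ligand
    out = np.empty(B, dtype=bool)
    for b in range(B):  # n <= 3 here, so this loop is cheap
        seen = adj_ion[b].copy()
        frontier = list(np.nonzero(seen)[0])
        while frontier:
            k = frontier.pop()
            for j in np.nonzero(adj_ll[b, k])[0]:
                if not seen[j]:
                    seen[j] = True
                    frontier.append(j)
        out[b] = seen.all()
    return out


def kn_mc_integration(
    model: PotentialModel,
    thermo: ThermoState,
    criterion: ClusterCriterion,
    n: int,
    n_samples: int = 200_000,
    seed: int = 0,
    proposal: str = "boltzmann1",
    domain_radius: Optional[float] = None,
    n_batches: int = 50,
    n_proposal_bins: int = 1024,
    n_orient_table: int = 12,
    chunk: int = 50_000,
) -> OracleResult:
    """Monte Carlo estimate of K_n for n <= 3 (seeded, reproducible).

    Reference-site positions are drawn in a ball of ``domain_radius``
    (default: the criterion's ion-ligand radius) and orientations uniformly;
    the clustered-configuration indicator and the Boltzmann factor weight
    each sample.  ``proposal='boltzmann1'`` importance-samples each radius
    from the orientation-averaged single-ligand Boltzmann density.  The
    standard error comes from batch means; a relative error above 20% flags
    the result as low precision.
    """
    if n < 1 or n > 3:
        raise ValueError("MC oracle supports 1 <= n <= 3")
    rng = np.random.default_rng(seed)
    beta = thermo.beta
    r_dom = domain_radius if domain_radius is not None else criterion.r_ion_ligand
    if criterion.mode == "ion_cutoff" and r_dom < criterion.r_ion_ligand:
        raise ValueError("domain must enclose the criterion ball")
    r_lo = model.min_site_distance
    need_indicator = criterion.mode != "ion_cutoff" or r_dom > criterion.r_ion_ligand

    if proposal == "boltzmann1":
        edges = np.linspace(r_lo, r_dom, n_proposal_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dr = edges[1] - edges[0]
        qbar = orientation_averaged_boltzmann(
            model, thermo, centers, n_orient=n_orient_table
        )
        mass = np.maximum(qbar, 1e-280) * centers**2 * dr
        pmf = mass / mass.sum()
        log_p_r = np.log(pmf / dr)  # radial density per bin
    elif proposal != "uniform":
        raise ValueError(f"unknown proposal {proposal!r}")

    vol_dom = 4.0 / 3.0 * math.pi * r_dom**3
    sums = []
    remaining = n_samples
    has_orient = model.ligand.n_sites > 1
    while remaining > 0:
        B = min(chunk, remaining)
        remaining -= B
        if proposal == "uniform":
            r = r_dom * rng.random((B, n)) ** (1.0 / 3.0)
            log_w = np.full(B, n * math.log(vol_dom))
        else:
            bins = rng.choice(n_proposal_bins, size=B * n, p=pmf).reshape(B, n)
            r = edges[bins] + dr * rng.random((B, n))
            # position density = p_r(r) / (4 pi r^2)
            log_w = -(
                log_p_r[bins] - np.log(4 * math.pi * r**2)
            ).sum(axis=1)
        u = rng.normal(size=(B, n, 3))
        u /= np.linalg.norm(u, axis=2, keepdims=True)
        trans = r[:, :, None] * u
        if has_orient:
            quats = random_quaternions(rng, B * n).reshape(B, n, 4)
        else:
            quats = np.zeros((B, n, 4))
            quats[:, :, 3] = 1.0
        e = batch_energy(model, trans, quats)
        with np.errstate(over="ignore", invalid="ignore"):
            w = np.where(np.isfinite(e), np.exp(-beta * e + log_w), 0.0)
        if need_indicator:
            w = np.where(_is_clustered_batch(criterion, trans), w, 0.0)
        sums.append(w)
    w_all = np.concatenate(sums)
    k_est = float(w_all.mean()) / math.factorial(n)
    batches = np.array_split(w_all, n_batches)
    bm = np.array([b.mean() for b in batches]) / math.factorial(n)
    se = float(bm.std(ddof=1) / math.sqrt(len(bm)))
    rel = se / k_est if k_est > 0 else math.inf
    return OracleResult(
        k_n=k_est,
        n=n,
        method="mc_integration",
        std_error=se,
        n_evaluations=n_samples,
        seed=seed,
        low_precision=bool(rel > 0.2),
    )
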