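"""Structural observables: neighborship-ordered radial densities, cumulative
site counts, and distributions of the decoupling energy.

The neighborship-ordered density rho^(j)(r) is the radial distribution of
the j-th nearest site of a chosen type (H sites, O sites, or all ligand
sites) from the ion.  Each rank is normalised so that
4 pi SUM_bins rho^(j)(r) r^2 dr = 1 -- exact by construction because the
normalisation uses the same discrete bin sums as the profile itself.  The
cumulative curve n(r) is the average number of selected sites within r of
the ion; with full support inside the grid it reaches the number of
selected sites per frame.  Internally everything is in Angstrom; a
figure-style export in nm / nm^-3 is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .chem_model import RigidLigand, ThermoState
from .roughscape import EnergyDecomposition

__all__ = [
    "NeighborshipProfile",
    "DeltaUHistogram",
    "neighborship_densities",
    "stochastic_order_check",
    "delta_u_histogram",
]

_SELECTORS = ("H_sites", "O_sites", "ligand_sites")


@dataclass
class NeighborshipProfile:
    """rho^(j)(r) per neighborship rank j plus the cumulative count curve."""

    r_grid: np.ndarray  # bin centres, uniform width (A)
    bin_width: float
    densities: np.ndarray  # (j_max, n_bins), units A^-3, each rank normalised
    cumulative: np.ndarray  # (n_bins,), average selected sites within r
    n_frames: int
    selector: str
    sites_per_frame: int

    def rank_normalization(self) -> np.ndarray:
        """4 pi SUM rho^(j) r^2 dr for each rank (1 for full support)."""
        shell = 4 * math.pi * self.r_grid**2 * self.bin_width
        return self.densities @ shell

    def total_density(self) -> np.ndarray:
        """Sum over ranks: the total selected-site density (A^-3)."""
        return self.densities.sum(axis=0)

    def rank_cdf(self) -> np.ndarray:
        """(j_max, n_bins) cumulative distribution of each rank's distance."""
        shell = 4 * math.pi * self.r_grid**2 * self.bin_width
        return np.cumsum(self.densities * shell, axis=1)

    def to_paper_units(self):
        """(r in nm, densities in nm^-3) for figure-style plots."""
        return self.r_grid / 10.0, self.densities * 1000.0


def neighborship_densities(
    trajectory,
    ligand: RigidLigand,
    selector: str = "H_sites",
    j_max: Optional[int] = None,
    bin_width: float = 0.02,
    r_max: Optional[float] = None,
) -> NeighborshipProfile:
    """Neighborship-ordered radial densities from a sampled trajectory.

    Per frame, the selected site-ion distances are sorted ascending and the
    j-th smallest accumulates into rho^(j).  The grid must cover every
    observed distance (error otherwise, reporting the maximum).
    """
    if selector not in _SELECTORS:
        raise ValueError(f"selector must be one of {_SELECTORS}")
    frames = trajectory.frames
    if not frames:
        raise ValueError("empty trajectory")
    if selector == "H_sites":
        site_idx = [
            i for i, s in enumerate(ligand.site_symbols) if s == "H"
        ] or list(range(ligand.n_sites))
    elif selector == "O_sites":
        site_idx = [0]
    else:
        site_idx = list(range(ligand.n_sites))
    n = frames[0].n
    per_frame = n * len(site_idx)
    j_max = per_frame if j_max is None else j_max
    if j_max > per_frame:
        raise ValueError(f"j_max={j_max} exceeds {per_frame} selected sites per frame")

    dists = np.empty((len(frames), per_frame))
    for fi, frame in enumerate(frames):
        sites = frame.all_sites(ligand)[:, site_idx, :].reshape(-1, 3)
        dists[fi] = np.sort(np.linalg.norm(sites - frame.ion_position, axis=1))
    d_max = float(dists.max())
    if r_max is None:
        r_max = (math.floor(d_max / bin_width) + 1) * bin_width
    if d_max >= r_max:
        raise ValueError(
            f"bin grid [0, {r_max}) does not cover observed distances (max {d_max:.3f} A)"
        )
    n_bins = int(round(r_max / bin_width))
    centers = (np.arange(n_bins) + 0.5) * bin_width
    shell = 4 * math.pi * centers**2 * bin_width

    densities = np.empty((j_max, n_bins))
    for j in range(j_max):
        counts, _ = np.histogram(dists[:, j], bins=n_bins, range=(0.0, r_max))
        densities[j] = counts / (len(frames) * shell)
    # cumulative over *all* selected sites (not just the first j_max ranks)
    counts_all, _ = np.histogram(dists.ravel(), bins=n_bins, range=(0.0, r_max))
    cumulative = np.cumsum(counts_all) / len(frames)
    return NeighborshipProfile(
        r_grid=centers,
        bin_width=bin_width,
        densities=densities,
        cumulative=cumulative,
        n_frames=len(frames),
        selector=selector,
        sites_per_frame=per_frame,
    )


@dataclass
class OrderCheckReport:
    violations: list  # (rank j, r, cdf_j, cdf_j+1)
    n_pairs_checked: int

    @property
    def ok(self) -> bool:
        return not self.violations


def stochastic_order_check(
    profile: NeighborshipProfile, tol: float = 1e-9
) -> OrderCheckReport:
    """Verify first-order stochastic dominance of rank j over rank j+1.

    Sorting distances per frame implies CDF_j(r) >= CDF_{j+1}(r) at every r;
    violations indicate a corrupted or mislabeled profile.
    """
    cdf = profile.rank_cdf()
    violations = []
    for j in range(len(cdf) - 1):
        bad = np.nonzero(cdf[j] < cdf[j + 1] - tol)[0]
        for b in bad:
            violations.append((j + 1, float(profile.r_grid[b]), float(cdf[j, b]), float(cdf[j + 1, b])))
    return OrderCheckReport(violations=violations, n_pairs_checked=len(cdf) - 1)


# --------------------------------------------------------------------------


@dataclass
class DeltaUHistogram:
    """Histogram of beta*dU with Gaussian-model overlay and modality count."""

    bin_edges: np.ndarray  # dimensionless beta*dU
    counts: np.ndarray
    sample_mean: float  # of beta*dU
    sample_variance: float
    n_samples: int
    n_modes: int

    def gaussian_overlay(self, x: Optional[np.ndarray] = None) -> np.ndarray:
        """Normal density with the sample mean and variance (integrates to 1)."""
        if x is None:
            x = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        var = max(self.sample_variance, 1e-300)
        return np.exp(-((x - self.sample_mean) ** 2) / (2 * var)) / math.sqrt(
            2 * math.pi * var
        )


def delta_u_histogram(
    decompositions: Sequence[EnergyDecomposition],
    thermo: ThermoState,
    bin_width: float = 0.25,
) -> DeltaUHistogram:
    """Distribution of beta*dU_n over frames and distinguished ligands.

    The modality diagnostic counts local maxima exceeding the neighbouring
    minima by more than 3*sqrt(count) (a Poisson noise floor); it is
    descriptive only.
    """
    if len(decompositions) < 2:
        raise ValueError("need at least 2 samples")
    x = thermo.beta * np.array([d.delta_u for d in decompositions])
    lo = math.floor(x.min() / bin_width) * bin_width
    hi = math.ceil(x.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    if x.var() == 0.0 and n_bins > 1:
        n_bins = 1
        hi = lo + bin_width
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    n_modes = _count_modes(counts)
    return DeltaUHistogram(
        bin_edges=edges,
        counts=counts,
        sample_mean=float(x.mean()),
        sample_variance=float(x.var(ddof=1)) if len(x) > 1 else 0.0,
        n_samples=len(x),
        n_modes=n_modes,
    )


def _count_modes(counts: np.ndarray) -> int:
    """Local maxima exceeding flanking minima by > 3 sqrt(count)."""
    if len(counts) < 3:
        return 1 if counts.sum() else 0
    modes = 0
    for i in range(len(counts)):
        c = counts[i]
        if c == 0:
            continue
        left = counts[:i]
        right = counts[i + 1 :]
        if len(left) and left[-1] > c:
            continue
        if len(right) and right[0] > c:
            continue
        lmin = left.min() if len(left) else 0
        rmin = right.min() if len(right) else 0
        if c - max(lmin, rmin) > 3 * math.sqrt(max(c, 1)):
            modes += 1
    return max(modes, 1 if counts.sum() else 0)
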