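"""Umbrella sampling for lipid flip-flop and a WHAM free-energy solver.

The reaction coordinate is the signed z-offset of one lipid's phosphate
bead from the instantaneous bilayer midplane (the centre of mass of all
lipid beads along z), which makes the potential of mean force invariant
to membrane drift.  The production protocol uses 61 windows spaced
0.15 r0 apart with a harmonic force constant of 200 kBT/r0^2, starting
at the bilayer centre; starting structures are generated sequentially by
pulling with a softer 10 kBT/r0^2 spring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .analysis import _membrane_midplane, _minimum_image
from .forcefield import ForceField, default_forcefield
from .integrate import Simulation
from .state import SystemState


@dataclass
class UmbrellaWindow:
    """One biased simulation window along the flip-flop coordinate."""

    index: int
    z_star: float                 # bias centre relative to midplane, r0
    k_umb: float = 200.0          # production force constant, kBT/r0^2
    samples: np.ndarray = field(default_factory=lambda: np.empty(0))

    def histogram(self, edges: np.ndarray) -> np.ndarray:
        h, _ = np.histogram(self.samples, bins=edges)
        return h.astype(float)


def make_windows(n: int = 61, spacing: float = 0.15,
                 k: float = 200.0) -> list[UmbrellaWindow]:
    """Windows 0..n-1 at z* = i * spacing, from the bilayer centre outward."""
    if n < 2:
        raise ValueError("need at least 2 windows")
    return [UmbrellaWindow(index=i, z_star=i * spacing, k_umb=k)
            for i in range(n)]


class UmbrellaBias:
    """Harmonic bias on the phosphate z-offset from the bilayer midplane.

    The restoring force acts on the phosphate bead, with the reaction
    force distributed uniformly over all lipid beads (the gradient of the
    midplane reference), so total momentum stays conserved.
    """

    def __init__(self, k: float, z_star: float, phosphate_index: int,
                 lipid_indices: np.ndarray):
        self.k = float(k)
        self.z_star = float(z_star)
        self.phosphate_index = int(phosphate_index)
        self.lipid_indices = np.asarray(lipid_indices, dtype=np.int64)
        self.last_offset: float = np.nan

    def offset(self, positions: np.ndarray, box: np.ndarray) -> float:
        Lz = box[2]
        z_mid = _membrane_midplane(positions[self.lipid_indices, 2], Lz)
        return float(_minimum_image(
            positions[self.phosphate_index, 2] - z_mid, Lz))

    def apply(self, positions: np.ndarray, box: np.ndarray,
              forces: np.ndarray) -> float:
        off = self.offset(positions, box)
        d = off - self.z_star
        forces[self.phosphate_index, 2] -= self.k * d
        forces[self.lipid_indices, 2] += self.k * d / len(self.lipid_indices)
        self.last_offset = off
        return off


def _bias_for(state: SystemState, window: UmbrellaWindow,
              k: float | None = None, lipid_id: int = 0) -> UmbrellaBias:
    topo = state.topology
    lipids = [(t, s) for t, s in topo.molecule_slices() if t.chains]
    if not lipids:
        raise ValueError("no lipids to bias")
    tmpl, sl = lipids[lipid_id]
    lipid_idx = np.concatenate([np.arange(s.start, s.stop) for _, s in lipids])
    return UmbrellaBias(
        k=window.k_umb if k is None else k,
        z_star=window.z_star,
        phosphate_index=sl.start + tmpl.phosphate_index,
        lipid_indices=lipid_idx,
    )


def pull_to_window(
    state: SystemState,
    window: UmbrellaWindow,
    ff: ForceField | None = None,
    k_pull: float = 10.0,
    steps: int = 10_000,
    seed: int = 0,
    dt: float = 0.02,
    lipid_id: int = 0,
) -> SystemState:
    """Drag the tagged lipid to the window centre with a soft spring.

    Runs ``steps`` biased steps at force constant ``k_pull`` and verifies
    the final offset sits within 3 sigma (sigma = sqrt(kBT/k_pull)) of
    the window centre; otherwise signals a retry.
    """
    if ff is None:
        ff = default_forcefield()
    bias = _bias_for(state, window, k=k_pull, lipid_id=lipid_id)
    sim = Simulation(state, ff, dt=dt, seed=seed, bias=bias)
    sim.run(steps)
    final = bias.offset(state.positions, state.box)
    sigma = np.sqrt(ff.temperature / k_pull)
    if abs(final - window.z_star) > 3.0 * sigma:
        warnings.warn(
            f"window {window.index}: offset {final:.2f} not within 3 sigma of "
            f"{window.z_star:.2f}; consider a longer pull")
    return state


def run_window(
    state: SystemState,
    window: UmbrellaWindow,
    ff: ForceField | None = None,
    equil: int = 50_000,
    prod: int = 50_000,
    sample_stride: int = 10,
    seed: int = 0,
    dt: float = 0.02,
    lipid_id: int = 0,
) -> UmbrellaWindow:
    """Biased NVT run; z-offset samples accumulate during production only."""
    if ff is None:
        ff = default_forcefield()
    bias = _bias_for(state, window, lipid_id=lipid_id)
    sim = Simulation(state, ff, dt=dt, seed=seed, bias=bias)
    sim.run(equil)
    samples = []
    sim.run(prod, callback=lambda s: samples.append(bias.last_offset),
            callback_stride=sample_stride)
    window.samples = np.asarray(samples)
    return window


@dataclass
class PMFResult:
    """WHAM-reconstructed potential of mean force (minimum at zero)."""

    grid: np.ndarray            # bin centres, r0
    pmf: np.ndarray             # kBT
    iterations: int
    residual: float
    window_free_energies: np.ndarray
    overlaps: np.ndarray        # adjacent-window histogram overlaps


def wham(
    windows: list[UmbrellaWindow],
    bin_width: float = 0.05,
    tol: float = 1.0e-6,
    max_iter: int = 100_000,
    temperature: float = 1.0,
) -> PMFResult:
    """Self-consistent WHAM over binned biased histograms.

    Iterates the coupled equations for the unbiased distribution P(b) and
    the window free energies f_w until the largest change in any f_w is
    below ``tol``; the returned profile is shifted so its minimum is 0.
    """
    wins = sorted([w for w in windows if len(w.samples)], key=lambda w: w.z_star)
    if not wins:
        raise ValueError("no sampled windows")
    lo = min(w.samples.min() for w in wins)
    hi = max(w.samples.max() for w in wins)
    nbin = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + np.arange(nbin + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.array([w.histogram(edges) for w in wins])   # (W, B)
    overlaps = np.array([
        np.minimum(counts[i] > 0, counts[i + 1] > 0).sum()
        for i in range(len(wins) - 1)
    ])
    for i, ov in enumerate(overlaps):
        if ov == 0:
            raise ValueError(
                f"no histogram overlap between windows at z* = "
                f"{wins[i].z_star:.2f} and {wins[i + 1].z_star:.2f}")

    beta = 1.0 / temperature
    N_w = counts.sum(axis=1)                                 # (W,)
    bias = 0.5 * np.array([w.k_umb for w in wins])[:, None] * (
        centers[None, :] - np.array([w.z_star for w in wins])[:, None]) ** 2
    boltz = np.exp(-beta * bias)                             # (W, B)
    numer = counts.sum(axis=0)                               # (B,)

    f = np.zeros(len(wins))
    it = 0
    resid = np.inf
    for it in range(1, max_iter + 1):
        denom = (N_w * np.exp(beta * f)) @ boltz             # (B,)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(denom > 0, numer / denom, 0.0)
        z = boltz @ P                                        # (W,)
        f_new = -np.log(np.where(z > 0, z, 1.0)) / beta
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < tol:
            break
    P = P / max(P.sum(), 1e-300)
    mask = P > 0
    pmf = np.full_like(P, np.nan)
    pmf[mask] = -np.log(P[mask]) / beta
    pmf -= np.nanmin(pmf)
    return PMFResult(grid=centers, pmf=pmf, iterations=it, residual=resid,
                     window_free_energies=f, overlaps=overlaps)


def pmf_barrier(result: PMFResult) -> tuple[float, float]:
    """Flip-flop barrier: PMF at the bilayer centre minus the global minimum.

    Returns ``(barrier_kBT, z_min)``, warning when the minimum sits at the
    domain edge (insufficient window coverage).
    """
    ok = np.isfinite(result.pmf)
    grid, pmf = result.grid[ok], result.pmf[ok]
    i_min = int(np.argmin(pmf))
    if i_min in (0, len(pmf) - 1):
        warnings.warn("PMF minimum at domain edge: coverage may be insufficient")
    i_center = int(np.argmin(np.abs(grid)))
    return float(pmf[i_center] - pmf[i_min]), float(grid[i_min])
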