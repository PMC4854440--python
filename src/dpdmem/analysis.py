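"""Membrane and fluid observables.

Covers the full validation battery for the coarse-grained model: surface
tension from the pressure-tensor anisotropy, density profiles, membrane
thickness / area per lipid / tail order, area compressibility and bending
rigidity, the Flory-Huggins chi calibration from demixed binary slabs,
the equation-of-state compressibility constant alpha, Gaussian fits of
bond/angle distributions, and water-percolation rupture detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .forcefield import ForceField
from .integrate import PressureTensor, pressure_tensor
from .state import SystemState
from .trajectory import Frame, Trajectory
from .units import DEFAULT_UNITS, Units


class DemixingError(RuntimeError):
    """Raised when a profile shows no phase separation (chi undefined)."""


# ---------------------------------------------------------------------------
# surface tension
# ---------------------------------------------------------------------------

def surface_tension_from_tensors(
    tensors: list[PressureTensor], Lz: float | np.ndarray
) -> float:
    """gamma_s = < Lz * [P_z - (P_x + P_y)/2] > in kBT/r0^2."""
    Lz = np.broadcast_to(np.asarray(Lz, dtype=float), (len(tensors),))
    vals = [L * (p.Pzz - p.tangential) for p, L in zip(tensors, Lz)]
    return float(np.mean(vals))


def surface_tension(traj: Trajectory, ff: ForceField) -> float:
    """Average surface tension of a bilayer-spanning trajectory.

    Recomputes the conservative+bonded virial per frame; the kinetic part
    uses stored velocities when present and the isotropic thermal value
    (which cancels in the normal-tangential difference) otherwise.
    """
    if len(traj) < 2:
        warnings.warn("fewer than 2 frames: single-frame tension estimate")
    tensors, Lzs = [], []
    for fr in traj:
        vel = fr.velocities
        if vel is None:
            vel = np.zeros_like(fr.positions)
        st = SystemState(fr.positions.copy(), vel, traj.topology, fr.box.copy())
        tensors.append(pressure_tensor(st, ff))
        Lzs.append(fr.box[2])
    return surface_tension_from_tensors(tensors, np.asarray(Lzs))


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Per-type number densities binned along one box axis."""

    axis: int
    bin_centers: np.ndarray
    bin_width: float
    densities: dict[str, np.ndarray]
    n_frames: int
    box: np.ndarray = field(default=None)

    def total(self) -> np.ndarray:
        return np.sum(list(self.densities.values()), axis=0)

    def fraction(self, label: str) -> np.ndarray:
        """Local number fraction of one bead type (phi profile)."""
        tot = self.total()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.densities[label] / tot, np.nan)


def density_profile(
    traj: Trajectory,
    axis: int = 2,
    n_bins: int = 40,
    labels: list[str] | None = None,
) -> DensityProfile:
    """Time-averaged per-bead-type number density along ``axis``."""
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    topo = traj.topology
    if labels is None:
        labels = [lb for lb in topo.type_labels
                  if np.any(topo.type_index == topo.type_labels.index(lb))]
    if not labels:
        raise ValueError("empty bead-type selection")
    L = traj.frames[0].box[axis]
    edges = np.linspace(0.0, L, n_bins + 1)
    width = edges[1] - edges[0]
    counts = {lb: np.zeros(n_bins) for lb in labels}
    for fr in traj:
        x = fr.positions[:, axis]
        for lb in labels:
            mask = topo.type_index == topo.type_labels.index(lb)
            h, _ = np.histogram(np.mod(x[mask], L), bins=edges)
            counts[lb] += h
    cross = np.prod(np.delete(traj.frames[0].box, axis))
    vol_bin = cross * width
    dens = {lb: c / (len(traj) * vol_bin) for lb, c in counts.items()}
    return DensityProfile(
        axis=axis,
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        bin_width=width,
        densities=dens,
        n_frames=len(traj),
        box=traj.frames[0].box.copy(),
    )


# ---------------------------------------------------------------------------
# membrane structure
# ---------------------------------------------------------------------------

@dataclass
class MembraneStructure:
    """Bilayer thickness and area per lipid, reduced and physical."""

    l_mem: float           # r0
    a0: float              # r0^2
    l_mem_nm: float
    a0_nm2: float
    n_lipids: int


def _lipid_slices(topo):
    return [(t, s) for t, s in topo.molecule_slices() if t.chains]


def _minimum_image(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


def membrane_structure(
    traj: Trajectory, units: Units = DEFAULT_UNITS
) -> MembraneStructure:
    """Thickness (choline-to-choline) and projected area per lipid.

    The membrane thickness is the distance along z between the mean
    choline (Q0) positions of the two leaflets; lipids are assigned to
    leaflets by whether the head sits above or below the tail midpoint.
    """
    topo = traj.topology
    lipids = _lipid_slices(topo)
    if not lipids:
        raise ValueError("no lipids in topology")
    n_lip = len(lipids)
    l_vals, a_vals = [], []
    for fr in traj:
        Lz = fr.box[2]
        z = fr.positions[:, 2]
        all_lipid_idx = np.concatenate([np.arange(s.start, s.stop) for _, s in lipids])
        z_mid = _membrane_midplane(z[all_lipid_idx], Lz)
        up, lo = [], []
        for tmpl, s in lipids:
            zc = z[s.start + tmpl.head_index]
            tails = [s.start + i for c in tmpl.chains for i in c]
            z_tail = z_mid + np.mean(_minimum_image(z[tails] - z_mid, Lz))
            zc_rel = _minimum_image(zc - z_mid, Lz)
            zt_rel = z_tail - z_mid
            (up if zc_rel > zt_rel else lo).append(zc_rel)
        if not up or not lo:
            raise ValueError("leaflet assignment ambiguous (ruptured bilayer?)")
        l_vals.append(abs(np.mean(up) - np.mean(lo)))
        a_vals.append(fr.box[0] * fr.box[1] / (n_lip / 2))
    l_mem = float(np.mean(l_vals))
    a0 = float(np.mean(a_vals))
    return MembraneStructure(
        l_mem=l_mem,
        a0=a0,
        l_mem_nm=units.to_physical(l_mem, "length"),
        a0_nm2=units.to_physical(a0, "area"),
        n_lipids=n_lip,
    )


def _membrane_midplane(z_lipid: np.ndarray, Lz: float) -> float:
    """Circular-mean z of the lipid beads (robust to box-edge straddling)."""
    ang = z_lipid * (2.0 * np.pi / Lz)
    mean_ang = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return float(np.mod(mean_ang * Lz / (2.0 * np.pi), Lz))


def chain_order(traj: Trajectory, method: str = "end_to_end") -> float:
    """Tail orientation order S_chain = 0.5 <3 cos^2(theta) - 1>.

    theta is the angle between each hydrocarbon chain's vector and the
    bilayer normal (z).  ``method='end_to_end'`` uses the first-to-last
    tail-bead vector; ``'per_bond'`` averages over successive tail bonds.
    """
    topo = traj.topology
    lipids = _lipid_slices(topo)
    if not lipids:
        raise ValueError("no lipids in topology")
    acc, n = 0.0, 0
    for fr in traj:
        box = fr.box
        pos = fr.positions
        for tmpl, s in lipids:
            for chain in tmpl.chains:
                idx = [s.start + i for i in chain]
                if method == "per_bond":
                    pairs = list(zip(idx[:-1], idx[1:]))
                else:
                    pairs = [(idx[0], idx[-1])]
                for i, j in pairs:
                    d = pos[j] - pos[i]
                    d -= box * np.round(d / box)
                    r2 = float(d @ d)
                    if r2 <= 0:
                        continue
                    cos2 = d[2] * d[2] / r2
                    acc += 0.5 * (3.0 * cos2 - 1.0)
                    n += 1
    return acc / n


# ---------------------------------------------------------------------------
# elasticity
# ---------------------------------------------------------------------------

@dataclass
class ElasticFit:
    """Linear tension-area fit Sigma = K_A (a_prj - a0) / a0."""

    K_A: float             # kBT/r0^2
    a0: float              # r0^2
    residuals: np.ndarray
    used: np.ndarray       # mask of points inside the near-tensionless window


def fit_area_compressibility(
    a_prj: np.ndarray, sigma: np.ndarray, window: float = 3.0
) -> ElasticFit:
    """Fit the area compressibility from tension-versus-area samples.

    Only points with |Sigma| <= ``window`` (kBT/r0^2), i.e. close to the
    tensionless state, enter the fit.
    """
    a_prj = np.asarray(a_prj, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    used = np.abs(sigma) <= window
    if used.sum() < 3:
        used = np.ones_like(used, dtype=bool)
        warnings.warn("fewer than 3 points in the near-tensionless window; "
                      "using all samples")
    if np.all(sigma[used] > 0) or np.all(sigma[used] < 0):
        warnings.warn("no sign change in Sigma: a0 is an extrapolation")
    m, b = np.polyfit(a_prj[used], sigma[used], 1)
    K_A = -b
    a0 = -b / m
    resid = sigma[used] - (m * a_prj[used] + b)
    return ElasticFit(K_A=float(K_A), a0=float(a0), residuals=resid, used=used)


def bending_rigidity(
    K_A: float, l_mem: float, units: Units = DEFAULT_UNITS
) -> tuple[float, float]:
    """kappa = K_A l_mem^2 / 48, returned in kBT and joules."""
    if K_A <= 0 or l_mem <= 0:
        raise ValueError("K_A and l_mem must be positive")
    kappa = K_A * l_mem**2 / 48.0
    return kappa, units.to_physical(kappa, "energy")


# ---------------------------------------------------------------------------
# Flory-Huggins chi calibration
# ---------------------------------------------------------------------------

def chi_from_phi(phi: float) -> float:
    """chi = ln[(1-phi)/phi] / (1-2 phi); equals 2 in the phi->1/2 limit."""
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie in (0, 1)")
    u = 1.0 - 2.0 * phi
    if abs(u) < 1.0e-8:
        return 2.0
    return float(2.0 * np.arctanh(u) / u)


def phi_from_chi(chi: float) -> float:
    """Minority volume fraction solving chi = ln[(1-phi)/phi]/(1-2 phi)."""
    if chi <= 2.0:
        raise ValueError("demixed solution requires chi > 2")
    return float(optimize.brentq(
        lambda p: chi_from_phi(p) - chi, 1.0e-12, 0.5 - 1.0e-9, xtol=1e-14))


def chi_from_profile(
    profile: DensityProfile,
    labels: tuple[str, str] = ("A", "B"),
    d_excl: float = 2.0,
) -> tuple[float, float]:
    """Flory-Huggins chi from a demixed two-phase density profile.

    The minority fraction phi is averaged over the homogeneous slab
    interiors: bins farther than ``d_excl`` (r0) from every interface,
    interfaces being the phi = 0.5 crossings of the A-fraction profile
    (periodic along the profile axis).  Returns ``(chi, phi)``.
    """
    la, lb = labels
    phi_a = profile.fraction(la)
    z = profile.bin_centers
    L = float(profile.box[profile.axis]) if profile.box is not None else float(
        z[-1] + profile.bin_width / 2)
    n = len(z)
    dev = phi_a - 0.5
    crossings = []
    for i in range(n):
        j = (i + 1) % n
        if dev[i] == 0.0 or dev[i] * dev[j] < 0:
            # linear interpolation of the crossing position
            zi, zj = z[i], z[(i + 1) % n]
            if j == 0:
                zj = z[0] + L
            t = dev[i] / (dev[i] - dev[j]) if dev[i] != dev[j] else 0.0
            crossings.append(np.mod(zi + t * (zj - zi), L))
    if not crossings:
        raise DemixingError("no interface found: system is not demixed")
    crossings = np.asarray(crossings)
    # distance of each bin to the nearest interface (periodic)
    dist = np.min(
        np.abs(_minimum_image(z[:, None] - crossings[None, :], L)), axis=1)
    interior = dist > d_excl
    if interior.sum() < 2:
        raise DemixingError("no homogeneous slab interior at this exclusion width")
    minority = np.minimum(phi_a[interior], 1.0 - phi_a[interior])
    phi = float(np.mean(minority))
    if phi <= 0.0:
        phi = 0.5 / (profile.n_frames * max(profile.total().max(), 1.0)
                     * profile.bin_width)  # resolution floor
    if phi >= 0.5 - 1e-6:
        raise DemixingError(f"phi = {phi:.3f}: no demixing, chi undefined")
    return chi_from_phi(phi), phi


def fit_lambda(
    deltas: np.ndarray, chis: np.ndarray
) -> tuple[float, float]:
    """Zero-intercept least-squares slope of chi = lambda * da.

    Non-demixed points (NaN chi) are excluded with a warning.  Returns
    ``(lambda, standard_error)``.
    """
    deltas = np.asarray(deltas, dtype=float)
    chis = np.asarray(chis, dtype=float)
    ok = np.isfinite(chis)
    if not np.all(ok):
        warnings.warn(f"excluding {np.count_nonzero(~ok)} non-demixed point(s)")
    d, c = deltas[ok], chis[ok]
    if len(d) < 2:
        raise ValueError("need at least 2 demixed points")
    lam = float(np.sum(d * c) / np.sum(d * d))
    resid = c - lam * d
    dof = max(len(d) - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(d * d)))
    return lam, se


# ---------------------------------------------------------------------------
# equation of state
# ---------------------------------------------------------------------------

@dataclass
class AlphaFit:
    """DPD equation-of-state fit P = rho T + alpha a rho^2."""

    alpha: float
    samples: list[tuple[float, float, float]]  # (a, rho, P)
    temperature: float = 1.0

    def k_inverse(self, a: float, rho: float = 3.0) -> float:
        """Dimensionless compressibility k^-1 = 1 + 2 alpha a rho / kBT."""
        return 1.0 + 2.0 * self.alpha * a * rho / self.temperature

    def k_inverse_per_molecule(self, a: float, rho: float = 3.0,
                               Nm: int = 4) -> float:
        return self.k_inverse(a, rho) / Nm


def fit_compressibility_alpha(
    samples: list[tuple[float, float, float]], temperature: float = 1.0
) -> AlphaFit:
    """Fit alpha from bulk NVT pressure measurements.

    ``samples`` holds ``(a, rho, P)`` triples; the excess pressure
    ``P - rho T`` is regressed on ``a rho^2`` through the origin.
    """
    if len(samples) < 1:
        raise ValueError("need at least one (a, rho, P) sample")
    arr = np.asarray(samples, dtype=float)
    a, rho, P = arr.T
    x = a * rho**2
    y = P - rho * temperature
    if np.sum(x * x) == 0:
        raise ValueError("singular design: all a rho^2 vanish")
    alpha = float(np.sum(x * y) / np.sum(x * x))
    return AlphaFit(alpha=alpha, samples=[tuple(s) for s in samples],
                    temperature=temperature)


# ---------------------------------------------------------------------------
# Gaussian distribution fits (bonded-parameter inversion)
# ---------------------------------------------------------------------------

@dataclass
class GaussianFit:
    """Fit of P(x) = A / (w sqrt(pi/2)) exp(-2 (x - xc)^2 / w^2)."""

    center: float
    width: float
    area: float
    force_constant: float  # K = 4 kBT / w^2


def fit_gaussian(
    samples: np.ndarray | None = None,
    n_bins: int = 60,
    histogram: tuple[np.ndarray, np.ndarray] | None = None,
    temperature: float = 1.0,
) -> GaussianFit:
    """Gaussian fit of a bond-length or angle distribution.

    Provide raw ``samples`` (binned internally) or a precomputed
    ``histogram = (bin_centers, counts)``.  The fitted width maps onto a
    harmonic force constant K = 4 kBT / w^2 by Boltzmann inversion.
    """
    if histogram is not None:
        centers, counts = (np.asarray(v, dtype=float) for v in histogram)
        dx = centers[1] - centers[0]
    else:
        samples = np.asarray(samples, dtype=float)
        counts, edges = np.histogram(samples, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = counts.astype(float)
        dx = edges[1] - edges[0]

    def model(x, A, xc, w):
        return A / (np.abs(w) * np.sqrt(np.pi / 2.0)) * np.exp(
            -2.0 * (x - xc) ** 2 / w**2)

    total = counts.sum() * dx
    xc0 = float(np.sum(centers * counts) / counts.sum())
    var0 = float(np.sum((centers - xc0) ** 2 * counts) / counts.sum())
    p0 = [total, xc0, 2.0 * np.sqrt(max(var0, 1e-12))]
    try:
        popt, _ = optimize.curve_fit(model, centers, counts, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"Gaussian fit did not converge: {exc}") from exc
    A, xc, w = popt
    w = abs(float(w))
    return GaussianFit(center=float(xc), width=w, area=float(A),
                       force_constant=4.0 * temperature / w**2)


# ---------------------------------------------------------------------------
# rupture detection
# ---------------------------------------------------------------------------

def detect_rupture(
    traj: Trajectory,
    mid_margin: float = 2.0,
    link_cut: float = 1.0,
) -> str:
    """Classify a bilayer trajectory as ``intact``, ``pore`` or ``ruptured``.

    A frame has a pore when a connected chain of water beads (neighbour
    distance < ``link_cut``) links the region above the midplane
    (z > z_mid + ``mid_margin``) to the region below it.  A pore in more
    than half the frames counts as rupture.  Systems without a membrane
    are flagged ``ruptured`` (degenerate).
    """
    topo = traj.topology
    lipids = _lipid_slices(topo)
    if not lipids:
        return "ruptured"
    w_mask = np.array([topo.type_labels[t] == "W" for t in topo.type_index])
    lipid_idx = np.concatenate([np.arange(s.start, s.stop) for _, s in lipids])
    n_pore = 0
    for fr in traj:
        box = fr.box
        Lz = box[2]
        z_mid = _membrane_midplane(fr.positions[lipid_idx, 2], Lz)
        zw = _minimum_image(fr.positions[w_mask, 2] - z_mid, Lz)
        near = np.abs(zw) <= mid_margin + link_cut + 1.0
        pts = fr.positions[w_mask][near]
        if len(pts) == 0:
            continue
        tree = cKDTree(np.mod(pts, box), boxsize=box)
        pairs = tree.query_pairs(link_cut, output_type="ndarray")
        n = len(pts)
        adj = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        _, comp = connected_components(adj, directed=False)
        zr = zw[near]
        for c in np.unique(comp):
            sel = comp == c
            if zr[sel].max() > mid_margin and zr[sel].min() < -mid_margin:
                n_pore += 1
                break
    if n_pore == 0:
        return "intact"
    if n_pore > len(traj.frames) / 2:
        return "ruptured"
    return "pore"
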