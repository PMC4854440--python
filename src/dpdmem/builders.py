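"""Initial-configuration builders for every experiment type.

All builders produce a :class:`~dpdmem.state.SystemState` with bead
density rho = 3/r0^3 (within one bead of rho*V), Maxwell-Boltzmann
velocities at the requested temperature with the centre-of-mass drift
removed, and wrapped coordinates.  Soft DPD potentials tolerate initial
overlaps, so placement only needs to be topologically sensible.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .forcefield import BEAD_LABELS
from .state import SystemState
from .topology import MoleculeTemplate, Topology, assemble, lipid_template

RHO = 3.0  # reference bead density in 1/r0^3


def _mb_velocities(n: int, temperature: float, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(0.0, np.sqrt(temperature), size=(n, 3))
    v -= v.mean(axis=0)
    return v


def _single_bead_template(label: str) -> MoleculeTemplate:
    return MoleculeTemplate(name=label, bead_types=(label,))


def n_beads_for_box(box: Sequence[float], density: float = RHO) -> int:
    """Bead count rho*V rounded to the nearest integer."""
    return int(round(density * float(np.prod(np.asarray(box, dtype=float)))))


def build_bulk(
    box: Sequence[float],
    composition: Mapping[str, int] | None = None,
    seed: int = 0,
    temperature: float = 1.0,
    type_labels: Sequence[str] | None = None,
    density: float = RHO,
) -> SystemState:
    """Homogeneous bulk fluid with uniformly random positions.

    ``composition`` maps bead labels to counts; ``None`` means pure water
    at ``rho*V`` beads.  The total count must match ``rho*V`` within one
    bead.
    """
    box = np.asarray(box, dtype=np.float64)
    if np.any(box < 3.0):
        raise ValueError("box must be at least 3x3x3 r0")
    target = n_beads_for_box(box, density)
    if composition is None:
        composition = {"W": target}
    total = sum(composition.values())
    if abs(total - target) > 1:
        raise ValueError(
            f"composition holds {total} beads but rho*V = {target}")
    if type_labels is None:
        type_labels = tuple(composition)
    topo = assemble(
        [(_single_bead_template(lb), n) for lb, n in composition.items()],
        type_labels,
    )
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, 1.0, size=(total, 3)) * box
    vel = _mb_velocities(total, temperature, rng)
    state = SystemState(pos, vel, topo, box)
    state.wrap()
    return state


def build_binary_slab(
    nA: int,
    nB: int,
    box: Sequence[float],
    seed: int = 0,
    temperature: float = 1.0,
    labels: tuple[str, str] = ("A", "B"),
    density: float = RHO,
) -> SystemState:
    """Pre-separated A/B starting configuration for demixing runs.

    A-type beads are placed uniformly in the upper half of the box
    (z > Lz/2), B-type beads in the lower half, mirroring the two-slab
    start of the chi-calibration experiment.
    """
    box = np.asarray(box, dtype=np.float64)
    target = n_beads_for_box(box, density)
    if abs(nA + nB - target) > 1:
        raise ValueError(f"nA + nB = {nA + nB} but rho*V = {target}")
    topo = assemble(
        [(_single_bead_template(labels[0]), nA),
         (_single_bead_template(labels[1]), nB)],
        labels,
    )
    rng = np.random.default_rng(seed)
    pos = np.empty((nA + nB, 3))
    half = box[2] / 2.0
    pos[:nA] = rng.uniform(0.0, 1.0, size=(nA, 3)) * [box[0], box[1], half]
    pos[:nA, 2] += half  # A occupies the upper half
    pos[nA:] = rng.uniform(0.0, 1.0, size=(nB, 3)) * [box[0], box[1], half]
    vel = _mb_velocities(nA + nB, temperature, rng)
    state = SystemState(pos, vel, topo, box)
    state.wrap()
    return state


def _leaflet_offsets(tmpl: MoleculeTemplate) -> np.ndarray:
    """Per-bead (dx, dy, dz) for an extended upper-leaflet lipid.

    The first glycerol bead sits at the local origin with the head group
    stacked above it and both tails descending toward the midplane; the
    second glycerol/tail column is displaced laterally by the backbone
    bond length.  Bond lengths are the template's L0 values.
    """
    off = np.zeros((tmpl.n_beads, 3))
    lut = tmpl.bond_lookup()

    def L0(i: int, j: int) -> float:
        return lut[(min(i, j), max(i, j))][0]

    chain1, chain2 = tmpl.chains
    in_chain = set(chain1) | set(chain2)
    # glycerol beads: the bond partners of each chain's first bead
    g1 = next(k for (a, b), _ in lut.items()
              for k in (a, b) if (a == chain1[0] or b == chain1[0]) and k not in in_chain)
    g2 = next(k for (a, b), _ in lut.items()
              for k in (a, b) if (a == chain2[0] or b == chain2[0]) and k not in in_chain)
    head, phos = tmpl.head_index, tmpl.phosphate_index
    off[g1] = (0.0, 0.0, 0.0)
    off[phos] = (0.0, 0.0, L0(phos, g1))
    off[head] = (0.0, 0.0, L0(phos, g1) + L0(head, phos))
    off[g2] = (L0(g1, g2), 0.0, 0.0)
    for root, chain in ((g1, chain1), (g2, chain2)):
        z = 0.0
        for k, bead in enumerate(chain):
            prev = chain[k - 1] if k else root
            z -= L0(prev, bead)
            off[bead] = (off[root][0], 0.0, z)
    return off


def build_bilayer(
    species: str = "DMPC",
    n_lipids: int = 1152,
    a_prj: float = 1.30,
    Lz: float = 24.0,
    seed: int = 0,
    temperature: float = 1.0,
    density: float = RHO,
    jitter: float = 0.1,
) -> SystemState:
    """Planar bilayer spanning the x-y plane at the box midplane.

    ``Lx = Ly = sqrt(n_lipids * a_prj / 2)`` fixes the projected area per
    lipid; lipids sit on two opposing square leaflet lattices with heads
    outward and tails inward, and water fills the remaining volume (kept
    out of the hydrophobic slab, |z - z_mid| < 3 r0, at build time).
    """
    if n_lipids % 2:
        raise ValueError("n_lipids must be even (two leaflets)")
    tmpl = lipid_template(species)
    if not tmpl.chains:
        raise ValueError("species must be a lipid")
    L = np.sqrt(n_lipids * a_prj / 2.0)
    box = np.array([L, L, Lz])
    n_per_leaflet = n_lipids // 2
    n_side = int(np.ceil(np.sqrt(n_per_leaflet)))
    spacing = L / n_side
    off_up = _leaflet_offsets(tmpl)
    z_mid = Lz / 2.0
    chain_len = max(len(c) for c in tmpl.chains)
    z_gly = 0.59 * chain_len + 0.3  # glycerol height above midplane

    rng = np.random.default_rng(seed)
    pos_lipids = np.empty((n_lipids * tmpl.n_beads, 3))
    k = 0
    for leaflet, sign in ((0, 1.0), (1, -1.0)):
        for m in range(n_per_leaflet):
            ix, iy = divmod(m, n_side)
            x0 = (ix + 0.5) * spacing + rng.normal(0.0, jitter)
            y0 = (iy + 0.5) * spacing + rng.normal(0.0, jitter)
            off = off_up.copy()
            off[:, 2] *= sign
            base = np.array([x0, y0, z_mid + sign * z_gly])
            block = base + off + rng.normal(0.0, 0.02, size=off.shape)
            pos_lipids[k:k + tmpl.n_beads] = block
            k += tmpl.n_beads

    n_total = n_beads_for_box(box, density)
    n_water = n_total - n_lipids * tmpl.n_beads
    if n_water < 0:
        raise ValueError("lipids alone exceed rho*V; increase the box")
    slab_half = 3.0
    pos_w = np.empty((n_water, 3))
    pos_w[:, 0] = rng.uniform(0.0, L, n_water)
    pos_w[:, 1] = rng.uniform(0.0, L, n_water)
    free = Lz - 2.0 * slab_half
    zw = rng.uniform(0.0, free, n_water)
    pos_w[:, 2] = np.where(zw < z_mid - slab_half, zw, zw + 2.0 * slab_half)

    topo = assemble(
        [(tmpl, n_lipids), (lipid_template("WATER"), n_water)], BEAD_LABELS)
    pos = np.vstack([pos_lipids, pos_w])
    vel = _mb_velocities(topo.n_beads, temperature, rng)
    state = SystemState(pos, vel, topo, box)
    state.wrap()
    return state


def build_vesicle_start(
    species: str = "DMPC",
    n_lipids: int = 1152,
    a_prj: float = 1.30,
    pad: float = 12.0,
    box_side: float | None = None,
    seed: int = 0,
    temperature: float = 1.0,
    density: float = RHO,
) -> SystemState:
    """Free-standing square bilayer patch in an enlarged water box.

    The patch (side ``sqrt(n_lipids * a_prj / 2)``) is centred in a cubic
    box of side ``patch + pad`` (override with ``box_side``) so it never
    touches its periodic images; vesicles then form by self-assembly.
    """
    tmpl = lipid_template(species)
    Lp = np.sqrt(n_lipids * a_prj / 2.0)
    side = float(box_side) if box_side is not None else Lp + pad
    if side <= Lp * np.sqrt(2.0):
        raise ValueError(
            f"box side {side:.1f} must exceed the patch diagonal {Lp * np.sqrt(2):.1f}")
    box = np.array([side, side, side])
    z_mid = side / 2.0
    n_per_leaflet = n_lipids // 2
    n_side = int(np.ceil(np.sqrt(n_per_leaflet)))
    spacing = Lp / n_side
    off_up = _leaflet_offsets(tmpl)
    chain_len = max(len(c) for c in tmpl.chains)
    z_gly = 0.59 * chain_len + 0.3
    x0c = (side - Lp) / 2.0

    rng = np.random.default_rng(seed)
    pos_lipids = np.empty((n_lipids * tmpl.n_beads, 3))
    k = 0
    for leaflet, sign in ((0, 1.0), (1, -1.0)):
        for m in range(n_per_leaflet):
            ix, iy = divmod(m, n_side)
            x0 = x0c + (ix + 0.5) * spacing + rng.normal(0.0, 0.1)
            y0 = x0c + (iy + 0.5) * spacing + rng.normal(0.0, 0.1)
            off = off_up.copy()
            off[:, 2] *= sign
            base = np.array([x0, y0, z_mid + sign * z_gly])
            pos_lipids[k:k + tmpl.n_beads] = base + off + rng.normal(0.0, 0.02, size=off.shape)
            k += tmpl.n_beads

    n_total = n_beads_for_box(box, density)
    n_water = n_total - n_lipids * tmpl.n_beads
    # rejection-sample water outside the patch slab
    pos_w = np.empty((n_water, 3))
    filled = 0
    margin = 1.0
    while filled < n_water:
        cand = rng.uniform(0.0, side, size=(2 * (n_water - filled) + 16, 3))
        in_slab = (
            (np.abs(cand[:, 2] - z_mid) < z_gly + margin)
            & (cand[:, 0] > x0c - margin) & (cand[:, 0] < x0c + Lp + margin)
            & (cand[:, 1] > x0c - margin) & (cand[:, 1] < x0c + Lp + margin)
        )
        keep = cand[~in_slab][: n_water - filled]
        pos_w[filled:filled + len(keep)] = keep
        filled += len(keep)

    topo = assemble(
        [(tmpl, n_lipids), (lipid_template("WATER"), n_water)], BEAD_LABELS)
    pos = np.vstack([pos_lipids, pos_w])
    vel = _mb_velocities(topo.n_beads, temperature, rng)
    state = SystemState(pos, vel, topo, box)
    state.wrap()
    return state
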