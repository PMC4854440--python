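"""Molecule templates and global topology assembly.

Lipids follow the h-shape architecture: a choline bead (Q0) bonded to a
phosphate bead (Qa), which connects to a glycerol backbone of two Na
beads, each carrying a hydrocarbon tail of C beads.  DMPC has three C
beads per tail; DPPC and DOPC have four, with DOPC bending the terminal
tail angle to 120 degrees to mimic the unsaturated chain.  Bonds are
harmonic, E2 = K2 (r - L0)^2 / 2, and angles cosine-harmonic,
E3 = K3 [1 - cos(theta - theta0)].  Bonded beads additionally interact
through the nonbonded DPD repulsion, which is why L0 sits below the
fitted equilibrium bond length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .forcefield import _load_default_config

SPECIES = ("WATER", "DMPC", "DPPC", "DOPC")


@dataclass(frozen=True)
class MoleculeTemplate:
    """Per-species bead sequence and bonded-interaction lists.

    Bead indices are zero-based within the molecule.  ``bonds`` entries are
    ``(i, j, L0, K2)`` with L0 in r0 and K2 in kBT/r0^2; ``angles`` entries
    are ``(i, j, k, theta0_deg, K3)`` with the middle bead at the vertex.
    ``chains`` lists the hydrocarbon-tail bead indices, ordered from the
    glycerol-attached bead to the terminal bead.
    """

    name: str
    bead_types: tuple[str, ...]
    bonds: tuple[tuple[int, int, float, float], ...] = ()
    angles: tuple[tuple[int, int, int, float, float], ...] = ()
    chains: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.bead_types)
        seen = set()
        for i, j, L0, K2 in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"bond ({i},{j}) out of range for {n} beads")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        for i, j, k, _, _ in self.angles:
            if len({i, j, k}) != 3 or not all(0 <= x < n for x in (i, j, k)):
                raise ValueError(f"angle ({i},{j},{k}) invalid for {n} beads")

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)

    @property
    def head_index(self) -> int:
        """Index of the choline (Q0) bead, or 0 for single-bead species."""
        return self.bead_types.index("Q0") if "Q0" in self.bead_types else 0

    @property
    def phosphate_index(self) -> int:
        """Index of the phosphate (Qa) bead targeted by umbrella biases."""
        return self.bead_types.index("Qa") if "Qa" in self.bead_types else 0

    def bond_lookup(self) -> dict[tuple[int, int], tuple[float, float]]:
        return {(min(i, j), max(i, j)): (L0, K2) for i, j, L0, K2 in self.bonds}

    def to_dict(self) -> dict:
        return {
            "beads": list(self.bead_types),
            "bonds": [[i, j, L0, K2] for i, j, L0, K2 in self.bonds],
            "angles": [[i, j, k, t0, K3] for i, j, k, t0, K3 in self.angles],
            "chains": [list(c) for c in self.chains],
        }

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "MoleculeTemplate":
        return cls(
            name=name,
            bead_types=tuple(d["beads"]),
            bonds=tuple((int(i), int(j), float(L0), float(K2)) for i, j, L0, K2 in d.get("bonds", ())),
            angles=tuple(
                (int(i), int(j), int(k), float(t0), float(K3))
                for i, j, k, t0, K3 in d.get("angles", ())
            ),
            chains=tuple(tuple(int(i) for i in c) for c in d.get("chains", ())),
        )


_TEMPLATE_CACHE: dict[str, MoleculeTemplate] = {}


def lipid_template(name: str) -> MoleculeTemplate:
    """Packaged template for one of WATER, DMPC, DPPC, DOPC."""
    name = name.upper()
    if name not in SPECIES:
        raise ValueError(f"unknown species {name!r}; choose from {SPECIES}")
    if not _TEMPLATE_CACHE:
        cfg = _load_default_config()
        for sp, d in cfg["templates"].items():
            _TEMPLATE_CACHE[sp] = MoleculeTemplate.from_dict(sp, d)
    return _TEMPLATE_CACHE[name]


def water_template() -> MoleculeTemplate:
    return lipid_template("WATER")


@dataclass
class Topology:
    """Global bonded topology for a whole system.

    Arrays concatenate every molecule's bonds/angles with global bead
    indices.  ``molecules`` records ``(template, count)`` in build order so
    analyses can recover per-lipid bead indices.
    """

    n_beads: int
    type_labels: tuple[str, ...]            # label per type index
    type_index: np.ndarray                  # (N,) int32
    molecule_id: np.ndarray                 # (N,) int32
    bond_index: np.ndarray                  # (nb, 2) int32
    bond_params: np.ndarray                 # (nb, 2) float64: L0, K2
    angle_index: np.ndarray                 # (na, 3) int32
    angle_params: np.ndarray                # (na, 2) float64: theta0_rad, K3
    molecules: tuple[tuple[MoleculeTemplate, int], ...] = ()

    def molecule_slices(self, species: str | None = None) -> list[tuple[MoleculeTemplate, slice]]:
        """Per-molecule global bead slices, optionally filtered by species."""
        out = []
        offset = 0
        for tmpl, count in self.molecules:
            for _ in range(count):
                if species is None or tmpl.name == species.upper():
                    out.append((tmpl, slice(offset, offset + tmpl.n_beads)))
                offset += tmpl.n_beads
        return out

    def bead_labels(self) -> np.ndarray:
        """Per-bead string labels (for trajectory output)."""
        return np.asarray(self.type_labels, dtype=object)[self.type_index]


def assemble(
    molecules: Sequence[tuple[MoleculeTemplate, int]],
    type_labels: Sequence[str],
) -> Topology:
    """Concatenate molecule templates into a global :class:`Topology`.

    ``type_labels`` fixes the mapping from bead label to type index (it
    must cover every label used by the templates; order should match the
    force-field matrix the system will be simulated with).
    """
    type_labels = tuple(type_labels)
    label_to_idx = {lb: i for i, lb in enumerate(type_labels)}
    tidx, mol_id = [], []
    b_idx, b_par, a_idx, a_par = [], [], [], []
    offset = 0
    mol_counter = 0
    for tmpl, count in molecules:
        t_local = [label_to_idx[lb] for lb in tmpl.bead_types]
        for _ in range(count):
            tidx.extend(t_local)
            mol_id.extend([mol_counter] * tmpl.n_beads)
            for i, j, L0, K2 in tmpl.bonds:
                b_idx.append((offset + i, offset + j))
                b_par.append((L0, K2))
            for i, j, k, t0, K3 in tmpl.angles:
                a_idx.append((offset + i, offset + j, offset + k))
                a_par.append((np.deg2rad(t0), K3))
            offset += tmpl.n_beads
            mol_counter += 1
    return Topology(
        n_beads=offset,
        type_labels=type_labels,
        type_index=np.asarray(tidx, dtype=np.int32),
        molecule_id=np.asarray(mol_id, dtype=np.int32),
        bond_index=np.asarray(b_idx, dtype=np.int32).reshape(-1, 2),
        bond_params=np.asarray(b_par, dtype=np.float64).reshape(-1, 2),
        angle_index=np.asarray(a_idx, dtype=np.int32).reshape(-1, 3),
        angle_params=np.asarray(a_par, dtype=np.float64).reshape(-1, 2),
        molecules=tuple((tmpl, count) for tmpl, count in molecules),
    )
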