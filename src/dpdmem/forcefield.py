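"""Nonbonded DPD force field: bead taxonomy, repulsion and friction tables.

Beads are classified as charged (Q), polar (P/W), nonpolar (N), or apolar
(C), subdivided by hydrogen-bonding capacity (donor *d*, acceptor *a*,
none *0*).  Five bead types are parameterized here: water W, the choline
bead Q0, the phosphate bead Qa, the glycerol bead Na, and the hydrocarbon
bead C.  Like-bead repulsion is 100 kBT/r0 (chosen so that a density-3
water fluid with four molecules per bead reproduces the dimensionless
water compressibility k^-1 of about 16); unlike-bead repulsions encode
Flory-Huggins chi-parameters via the linear relation chi = lambda * da.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

from .units import Units

BEAD_LABELS = ("W", "Q0", "Qa", "Na", "C")


@dataclass(frozen=True)
class BeadType:
    """One coarse-grained bead species (~4 heavy atoms)."""

    label: str
    charge_class: str  # charged | polar | nonpolar | apolar
    hbond_class: str   # donor | acceptor | none


@dataclass(frozen=True)
class FrictionTiers:
    """Piecewise-constant map from repulsion strength to friction gamma_ij.

    Low, intermediate and high repulsions get gamma of 4.5, 9 and 20
    respectively; the tier boundaries (``low_max``, ``mid_max``) are a
    package convention and can be overridden in the config.
    """

    low: float = 4.5
    mid: float = 9.0
    high: float = 20.0
    low_max: float = 102.0
    mid_max: float = 110.0

    def __call__(self, a: float) -> float:
        if a <= 0:
            raise ValueError(f"repulsion must be positive, got {a}")
        if a <= self.low_max:
            return self.low
        if a <= self.mid_max:
            return self.mid
        return self.high


DEFAULT_TIERS = FrictionTiers()


def friction_for(a: float, tiers: FrictionTiers = DEFAULT_TIERS) -> float:
    """Friction coefficient gamma_ij for a given repulsion a_ij (kBT/r0)."""
    return tiers(a)


@dataclass
class ForceField:
    """Symmetric nonbonded parameter tables over a set of bead labels.

    ``repulsion`` holds a_ij in kBT/r0 and ``friction`` gamma_ij in reduced
    friction units; both are symmetric with positive entries.  The thermal
    energy follows the reduced temperature ``temperature``.
    """

    labels: tuple[str, ...]
    repulsion: np.ndarray
    friction: np.ndarray
    temperature: float = 1.0
    bead_types: dict[str, BeadType] = field(default_factory=dict)
    tiers: FrictionTiers = field(default_factory=FrictionTiers)
    units: Units = field(default_factory=Units)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        n = len(self.labels)
        self.repulsion = np.asarray(self.repulsion, dtype=np.float64)
        self.friction = np.asarray(self.friction, dtype=np.float64)
        for name, mat in (("repulsion", self.repulsion), ("friction", self.friction)):
            if mat.shape != (n, n):
                raise ValueError(f"{name} matrix must be {n}x{n}")
            if not np.allclose(mat, mat.T):
                raise ValueError(f"{name} matrix must be symmetric")
            if np.any(mat <= 0):
                raise ValueError(f"{name} entries must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    # -- lookups ----------------------------------------------------------
    def index(self, label: str) -> int:
        return self.labels.index(label)

    def a(self, label_i: str, label_j: str) -> float:
        """Repulsion a_ij between two bead labels."""
        return float(self.repulsion[self.index(label_i), self.index(label_j)])

    def gamma(self, label_i: str, label_j: str) -> float:
        """Friction gamma_ij between two bead labels."""
        return float(self.friction[self.index(label_i), self.index(label_j)])

    def subset(self, labels: Iterable[str]) -> "ForceField":
        """Force field restricted (and reordered) to the given labels."""
        idx = [self.index(lb) for lb in labels]
        return ForceField(
            labels=tuple(self.labels[i] for i in idx),
            repulsion=self.repulsion[np.ix_(idx, idx)],
            friction=self.friction[np.ix_(idx, idx)],
            temperature=self.temperature,
            bead_types={lb: self.bead_types[lb] for lb in labels if lb in self.bead_types},
            tiers=self.tiers,
            units=self.units,
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "temperature": float(self.temperature),
            "repulsion": {
                "labels": list(self.labels),
                "matrix": self.repulsion.tolist(),
            },
            "friction_tiers": {
                "low": self.tiers.low,
                "mid": self.tiers.mid,
                "high": self.tiers.high,
                "low_max": self.tiers.low_max,
                "mid_max": self.tiers.mid_max,
            },
            "units": {
                "r0_nm": self.units.r0_nm,
                "tau_ps": self.units.tau_ps,
                "Nm": self.units.Nm,
            },
            "bead_types": {
                lb: {"charge_class": bt.charge_class, "hbond_class": bt.hbond_class}
                for lb, bt in self.bead_types.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ForceField":
        tiers_d = d.get("friction_tiers", {})
        tiers = FrictionTiers(**tiers_d) if tiers_d else FrictionTiers()
        labels = tuple(d["repulsion"]["labels"])
        rep = np.asarray(d["repulsion"]["matrix"], dtype=np.float64)
        fric_entry = d.get("friction")
        if fric_entry is not None:
            fric = np.asarray(fric_entry, dtype=np.float64)
        else:
            fric = np.vectorize(tiers)(rep)
        units_d = d.get("units", {})
        units = Units(**units_d) if units_d else Units()
        bead_types = {
            lb: BeadType(lb, spec["charge_class"], spec["hbond_class"])
            for lb, spec in d.get("bead_types", {}).items()
        }
        return cls(
            labels=labels,
            repulsion=rep,
            friction=fric,
            temperature=float(d.get("temperature", 1.0)),
            bead_types=bead_types,
            tiers=tiers,
            units=units,
        )


def _load_default_config() -> dict:
    ref = importlib.resources.files("dpdmem.data").joinpath("forcefield.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def default_forcefield() -> ForceField:
    """The packaged five-type force field (W, Q0, Qa, Na, C).

    Friction entries are derived from the repulsion table through
    :func:`friction_for` applied elementwise.
    """
    return ForceField.from_dict(_load_default_config())


def binary_forcefield(
    a_ii: float,
    a_ij: float,
    temperature: float = 1.0,
    tiers: FrictionTiers = DEFAULT_TIERS,
) -> ForceField:
    """Two-species (A/B) force field for binary demixing experiments.

    Like-bead repulsion ``a_ii`` applies to both species; ``a_ij`` is the
    mismatch repulsion between them.  The excess repulsion
    ``da = a_ij - a_ii`` sets the Flory-Huggins chi via chi = lambda*da.
    """
    rep = np.array([[a_ii, a_ij], [a_ij, a_ii]], dtype=np.float64)
    fric = np.vectorize(tiers)(rep)
    return ForceField(
        labels=("A", "B"),
        repulsion=rep,
        friction=fric,
        temperature=temperature,
        tiers=tiers,
    )
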