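"""System state container: coordinates, velocities, box, topology."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .topology import Topology


class SimulationError(RuntimeError):
    """Raised when integration fails (non-finite coordinates, box collapse)."""


@dataclass
class SystemState:
    """Full microstate of a DPD system in reduced units.

    Positions in r0, velocities in r0/tau, orthorhombic periodic box
    ``box = (Lx, Ly, Lz)`` in r0, time in tau.  Coordinates are kept
    wrapped into ``[0, L)`` on each axis.
    """

    positions: np.ndarray
    velocities: np.ndarray
    topology: Topology
    box: np.ndarray
    time: float = 0.0
    step: int = 0
    rng_state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        n = self.topology.n_beads
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError(f"positions/velocities must be ({n}, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")

    @property
    def n_beads(self) -> int:
        return self.topology.n_beads

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def density(self) -> float:
        return self.n_beads / self.volume

    def wrap(self) -> None:
        """Wrap all coordinates into [0, L) per axis (in place)."""
        self.positions -= self.box * np.floor(self.positions / self.box)

    def kinetic_temperature(self) -> float:
        """Instantaneous kinetic temperature, sum(m v^2) / (3 N)."""
        return float(np.sum(self.velocities**2) / (3.0 * self.n_beads))

    def total_momentum(self) -> np.ndarray:
        return self.velocities.sum(axis=0)

    def copy(self) -> "SystemState":
        return replace(
            self,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            box=self.box.copy(),
            rng_state=dict(self.rng_state),
        )
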