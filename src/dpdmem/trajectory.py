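"""Lightweight trajectory containers shared by the analysis operations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .state import SystemState
from .topology import Topology


@dataclass
class Frame:
    """One snapshot: wrapped positions, box, time; velocities optional."""

    positions: np.ndarray
    box: np.ndarray
    time: float = 0.0
    velocities: np.ndarray | None = None

    @classmethod
    def from_state(cls, state: SystemState, with_velocities: bool = False) -> "Frame":
        return cls(
            positions=state.positions.copy(),
            box=state.box.copy(),
            time=state.time,
            velocities=state.velocities.copy() if with_velocities else None,
        )


@dataclass
class Trajectory:
    """A sequence of frames over a fixed topology."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def append_state(self, state: SystemState, with_velocities: bool = False) -> None:
        self.frames.append(Frame.from_state(state, with_velocities))

    def sampler(self, with_velocities: bool = False):
        """Callback for :meth:`dpdmem.integrate.Simulation.run`."""

        def _cb(sim):
            self.append_state(sim.state, with_velocities)

        return _cb
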