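"""Time integration and ensemble control.

The equations of motion are integrated with the Groot-Warren modified
velocity-Verlet scheme: positions advance ballistically, the dissipative
force is evaluated at a predicted velocity ``v + lambda*dt*f`` (default
lambda = 0.5), and velocities are corrected with the mean of old and new
forces.  The pairwise random/dissipative forces form a momentum-conserving
thermostat, so NVT needs no extra machinery.

Constant normal pressure at zero surface tension (the N gamma_s P_perp T
ensemble used for bilayers) is realized by a semi-isotropic Langevin
piston: one strain coordinate for the bilayer normal (z) and one shared
by the tangential axes (x = y), both relaxing toward the same target
pressure, which drives the tension gamma_s to zero on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .forcefield import ForceField
from .state import SimulationError, SystemState


@dataclass
class PressureTensor:
    """Diagonal pressure components in kBT/r0^3 (kinetic + virial)."""

    Pxx: float
    Pyy: float
    Pzz: float

    @property
    def mean(self) -> float:
        return (self.Pxx + self.Pyy + self.Pzz) / 3.0

    @property
    def tangential(self) -> float:
        return 0.5 * (self.Pxx + self.Pyy)


@dataclass
class LangevinPiston:
    """Semi-isotropic Langevin-piston barostat.

    Each strain coordinate epsilon obeys
    ``W d(eps_dot)/dt = (P - P0) V - W gamma_p eps_dot + noise`` with
    piston inertia ``mass`` and damping ``gamma`` chosen for overdamped
    box relaxation within ~10^4 steps at typical system sizes; both are
    configurable.  Box lengths scale as ``L *= exp(eps_dot * dt)`` with
    affine scaling of particle coordinates.
    """

    P_target: float = 89.0
    mass: float = 2.0e6
    gamma: float = 0.5
    temperature: float = 1.0
    with_noise: bool = True
    mode: str = "normal_pressure_zero_tension"  # or "isotropic"
    eps_dot_xy: float = 0.0
    eps_dot_z: float = 0.0

    def update(self, state: SystemState, ptens: PressureTensor, dt: float,
               rng: np.random.Generator) -> None:
        V = state.volume
        noise_amp = (
            np.sqrt(2.0 * self.gamma * self.temperature / self.mass / dt)
            if self.with_noise
            else 0.0
        )
        if self.mode == "isotropic":
            drive = (ptens.mean - self.P_target) * V / self.mass
            self.eps_dot_xy += dt * (
                drive - self.gamma * self.eps_dot_xy + noise_amp * rng.standard_normal()
            )
            self.eps_dot_z = self.eps_dot_xy
        else:
            drive_t = (ptens.tangential - self.P_target) * V / self.mass
            drive_n = (ptens.Pzz - self.P_target) * V / self.mass
            self.eps_dot_xy += dt * (
                drive_t - self.gamma * self.eps_dot_xy + noise_amp * rng.standard_normal()
            )
            self.eps_dot_z += dt * (
                drive_n - self.gamma * self.eps_dot_z + noise_amp * rng.standard_normal()
            )
        s_xy = np.exp(self.eps_dot_xy * dt)
        s_z = np.exp(self.eps_dot_z * dt)
        state.box[0] *= s_xy
        state.box[1] *= s_xy
        state.box[2] *= s_z
        state.positions[:, 0] *= s_xy
        state.positions[:, 1] *= s_xy
        state.positions[:, 2] *= s_z
        if np.any(state.box < 2.0):
            raise SimulationError(
                f"box collapsed below two cutoffs: {state.box.tolist()}"
            )


class Simulation:
    """Driver binding a :class:`SystemState` to a force field.

    Parameters
    ----------
    state
        System to advance (mutated in place).
    ff
        Force field; its labels must cover the topology's type labels.
    dt
        Time step in tau (default 0.02).
    seed
        Seed for the pairwise random forces and the piston noise.
    lambda_vv
        Velocity-prediction parameter of the modified velocity Verlet.
    barostat
        Optional :class:`LangevinPiston`; ``None`` means NVT.
    bias
        Optional external bias with an ``apply(positions, box, forces)``
        method (used by umbrella sampling).
    """

    def __init__(
        self,
        state: SystemState,
        ff: ForceField,
        dt: float = 0.02,
        seed: int = 0,
        lambda_vv: float = 0.5,
        barostat: LangevinPiston | None = None,
        bias=None,
        use_cell_list: bool = True,
    ):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.state = state
        self.ff = ff
        self.dt = dt
        self.seed = int(seed)
        self.lambda_vv = lambda_vv
        self.barostat = barostat
        self.bias = bias
        self.use_cell_list = use_cell_list
        self.skin = 0.4  # Verlet-list skin in r0
        self._pairs = None
        self._ref_pos = None
        self._eval_counter = 0
        self._piston_rng = np.random.default_rng(
            np.random.SeedSequence([self.seed & 0x7FFFFFFF, 0x9157]))

        topo = state.topology
        idx = [ff.index(lb) for lb in topo.type_labels]
        sel = np.ix_(idx, idx)
        self.aij = np.ascontiguousarray(ff.repulsion[sel])
        self.gij = np.ascontiguousarray(ff.friction[sel])
        self.sij = np.sqrt(2.0 * self.gij * ff.temperature)
        self.forces, self.virial = self._eval_forces(state.velocities)

    # -- force evaluation --------------------------------------------------
    def _current_pairs(self):
        """Verlet list reused until any bead has moved more than skin/2."""
        pos, box = self.state.positions, self.state.box
        if self._pairs is not None:
            d = pos - self._ref_pos
            d -= box * np.rint(d / box)
            if np.max(np.einsum("ij,ij->i", d, d)) < (0.5 * self.skin) ** 2:
                return self._pairs
        self._pairs = _kernels.build_pair_list(pos, box, 1.0 + self.skin)
        self._ref_pos = pos.copy()
        return self._pairs

    def _eval_forces(self, velocities: np.ndarray):
        topo = self.state.topology
        stream = _kernels.rng_stream(self.seed, self._eval_counter)
        self._eval_counter += 1
        pairs = self._current_pairs() if self.use_cell_list else None
        forces, virial = _kernels.compute_forces(
            self.state.positions, velocities, self.state.box,
            topo.type_index, self.aij, self.gij, self.sij,
            self.dt, stream, self.use_cell_list, pairs,
        )
        _kernels.add_bonded(
            self.state.positions, self.state.box,
            topo.bond_index, topo.bond_params,
            topo.angle_index, topo.angle_params,
            forces, virial,
        )
        if self.bias is not None:
            self.bias.apply(self.state.positions, self.state.box, forces)
        return forces, virial

    # -- observables -------------------------------------------------------
    def pressure_tensor(self) -> PressureTensor:
        """Instantaneous diagonal pressure from the last force evaluation."""
        v = self.state.velocities
        kin = np.sum(v * v, axis=0)
        V = self.state.volume
        return PressureTensor(*((kin + self.virial) / V))

    # -- stepping ----------------------------------------------------------
    def step(self) -> None:
        """Advance one modified velocity-Verlet step (plus barostat)."""
        st = self.state
        dt = self.dt
        f = self.forces
        st.positions += dt * st.velocities + (0.5 * dt * dt) * f
        st.wrap()
        v_pred = st.velocities + (self.lambda_vv * dt) * f
        f_new, virial = self._eval_forces(v_pred)
        st.velocities += (0.5 * dt) * (f + f_new)
        self.forces, self.virial = f_new, virial
        st.step += 1
        st.time += dt
        if self.barostat is not None:
            self.barostat.update(st, self.pressure_tensor(), dt, self._piston_rng)

    def run(self, n_steps: int, callback=None, callback_stride: int = 1,
            check_every: int = 200) -> None:
        """Advance ``n_steps``, invoking ``callback(sim)`` at the stride."""
        for k in range(n_steps):
            self.step()
            if callback is not None and self.state.step % callback_stride == 0:
                callback(self)
            if (k + 1) % check_every == 0 and not np.all(
                np.isfinite(self.state.positions)
            ):
                raise SimulationError(
                    f"non-finite coordinates at step {self.state.step}"
                )
        if not np.all(np.isfinite(self.state.positions)):
            raise SimulationError(f"non-finite coordinates at step {self.state.step}")


# -- functional wrappers matching the one-step operations --------------------

def step_nvt(state: SystemState, ff: ForceField, dt: float = 0.02,
             seed: int = 0) -> SystemState:
    """One NVT step (constructs a throwaway :class:`Simulation`)."""
    sim = Simulation(state, ff, dt=dt, seed=seed)
    sim.step()
    return sim.state


def step_npt(state: SystemState, ff: ForceField, dt: float = 0.02,
             P_target: float = 89.0, seed: int = 0,
             mode: str = "normal_pressure_zero_tension",
             piston: LangevinPiston | None = None) -> SystemState:
    """One constant-normal-pressure / zero-tension step."""
    if piston is None:
        piston = LangevinPiston(P_target=P_target, temperature=ff.temperature,
                                mode=mode)
    sim = Simulation(state, ff, dt=dt, seed=seed, barostat=piston)
    sim.step()
    return sim.state


def pressure_tensor(state: SystemState, ff: ForceField) -> PressureTensor:
    """Diagonal pressure of a state: kinetic plus conservative+bonded virial."""
    topo = state.topology
    idx = [ff.index(lb) for lb in topo.type_labels]
    sel = np.ix_(idx, idx)
    aij = np.ascontiguousarray(ff.repulsion[sel])
    zeros = np.zeros_like(aij)
    forces, virial = _kernels.compute_forces(
        state.positions, state.velocities, state.box,
        topo.type_index, aij, zeros, zeros,
        1.0, np.uint64(0), True,
    )
    _kernels.add_bonded(
        state.positions, state.box, topo.bond_index, topo.bond_params,
        topo.angle_index, topo.angle_params, forces, virial,
    )
    v = state.velocities
    kin = np.sum(v * v, axis=0)
    return PressureTensor(*((kin + virial) / state.volume))
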