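"""Force evaluation, integrator, thermostat and pressure machinery."""

import numpy as np
import pytest

from dpdmem import (ForceField, SimulationError, Simulation, SystemState,
                    assemble, builders, lipid_template, pressure_tensor)
from dpdmem import _kernels
from dpdmem.topology import MoleculeTemplate


def _two_bead_state(r, box=8.0):
    tmpl = MoleculeTemplate(name="W", bead_types=("W",))
    topo = assemble([(tmpl, 2)], ("W",))
    pos = np.array([[1.0, 1.0, 1.0], [1.0 + r, 1.0, 1.0]])
    vel = np.zeros((2, 3))
    return SystemState(pos, vel, topo, np.full(3, box))


def _conservative_force(state, a):
    ff_a = np.array([[float(a)]])
    zeros = np.zeros((1, 1))
    f, _ = _kernels.compute_forces(
        state.positions, state.velocities, state.box,
        state.topology.type_index, ff_a, zeros, zeros,
        0.02, np.uint64(0), True)
    return f


class TestPairForces:
    def test_soft_repulsion_magnitude(self):
        # F_C = a (1 - r) r_hat
        f = _conservative_force(_two_bead_state(0.5), a=100.0)
        assert np.linalg.norm(f[0]) == pytest.approx(50.0)
        np.testing.assert_allclose(f[0], -f[1])

    def test_water_carbon_repulsion(self, ff_default):
        f = _conservative_force(_two_bead_state(0.5), a=ff_default.a("W", "C"))
        assert np.linalg.norm(f[0]) == pytest.approx(65.0)

    def test_cutoff(self):
        f = _conservative_force(_two_bead_state(1.2), a=100.0)
        np.testing.assert_array_equal(f, 0.0)

    def test_random_force_antisymmetric_per_pair(self, ff_water):
        state = builders.build_bulk((5, 5, 5), seed=4)
        sim = Simulation(state, ff_water, seed=4)
        # random + dissipative + conservative forces all pairwise
        np.testing.assert_allclose(sim.forces.sum(axis=0), 0.0, atol=1e-10)


class TestBondedForces:
    def test_bond_at_rest_length_and_displaced(self):
        tmpl = MoleculeTemplate(name="DIMER", bead_types=("W", "W"),
                                bonds=((0, 1, 0.5, 512.0),))
        topo = assemble([(tmpl, 1)], ("W",))
        for dr, fmag in ((0.0, 0.0), (0.1, 51.2)):
            pos = np.array([[1.0, 1, 1], [1.5 + dr, 1, 1]])
            f = np.zeros((2, 3))
            vir = np.zeros(3)
            _kernels.add_bonded(pos, np.full(3, 8.0), topo.bond_index,
                                topo.bond_params, topo.angle_index,
                                topo.angle_params, f, vir)
            assert np.linalg.norm(f[0]) == pytest.approx(fmag, abs=1e-12)

    def test_angle_at_equilibrium_is_forceless(self):
        tmpl = MoleculeTemplate(
            name="TRI", bead_types=("W", "W", "W"),
            bonds=((0, 1, 1.0, 1.0), (1, 2, 1.0, 1.0)),
            angles=((0, 1, 2, 120.0, 6.0),))
        topo = assemble([(tmpl, 1)], ("W",))
        th = np.deg2rad(120.0)
        pos = np.array([[2.0, 2.0, 2.0], [3.0, 2.0, 2.0],
                        [3.0 + np.cos(np.pi - th), 2.0 + np.sin(np.pi - th), 2.0]])
        f = np.zeros((3, 3))
        vir = np.zeros(3)
        topo.bond_params[:, 1] = 0.0  # isolate the angle term
        _kernels.add_bonded(pos, np.full(3, 10.0), topo.bond_index,
                            topo.bond_params, topo.angle_index,
                            topo.angle_params, f, vir)
        np.testing.assert_allclose(f, 0.0, atol=1e-10)

    @pytest.mark.parametrize("species", ["DMPC", "DPPC", "DOPC"])
    def test_forces_are_exact_gradients(self, species):
        """Numerical gradient of E2+E3 matches analytic bonded forces."""
        tmpl = lipid_template(species)
        topo = assemble([(tmpl, 2)], ("W", "Q0", "Qa", "Na", "C"))
        rng = np.random.default_rng(7)
        box = np.full(3, 12.0)
        pos = np.cumsum(rng.normal(0, 0.4, (topo.n_beads, 3)), axis=0) + 6.0
        f = np.zeros_like(pos)
        vir = np.zeros(3)
        _kernels.add_bonded(pos, box, topo.bond_index, topo.bond_params,
                            topo.angle_index, topo.angle_params, f, vir)
        h = 1e-6
        num = np.zeros_like(f)
        for i in range(topo.n_beads):
            for ax in range(3):
                for s, sign in ((h, 1.0), (-h, -1.0)):
                    p = pos.copy()
                    p[i, ax] += s
                    e = _kernels.bonded_energy(
                        p, box, topo.bond_index, topo.bond_params,
                        topo.angle_index, topo.angle_params)
                    num[i, ax] -= sign * e / (2 * h)
        scale = np.max(np.abs(f))
        np.testing.assert_allclose(f, num, atol=2e-6 * scale)

    def test_bonded_forces_conserve_momentum_and_torque(self):
        tmpl = lipid_template("DMPC")
        topo = assemble([(tmpl, 1)], ("W", "Q0", "Qa", "Na", "C"))
        rng = np.random.default_rng(3)
        box = np.full(3, 50.0)  # effectively open boundaries
        pos = np.cumsum(rng.normal(0, 0.4, (topo.n_beads, 3)), axis=0) + 25.0
        f = np.zeros_like(pos)
        vir = np.zeros(3)
        _kernels.add_bonded(pos, box, topo.bond_index, topo.bond_params,
                            topo.angle_index, topo.angle_params, f, vir)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)
        torque = np.cross(pos - pos.mean(axis=0), f).sum(axis=0)
        np.testing.assert_allclose(torque, 0.0, atol=1e-9)


class TestCellList:
    @pytest.mark.parametrize("fixture", ["bulk64", "slab750", "bilayer32"])
    def test_pair_list_matches_all_pairs_bitwise(self, fixture, request,
                                                 ff_default):
        from dpdmem import binary_forcefield
        state = request.getfixturevalue(fixture)
        labels = set(state.topology.type_labels)
        ff = ff_default if labels <= set(ff_default.labels) \
            else binary_forcefield(100.0, 110.0)
        idx = [ff.index(lb) for lb in state.topology.type_labels]
        sel = np.ix_(idx, idx)
        aij = np.ascontiguousarray(ff.repulsion[sel])
        gij = np.ascontiguousarray(ff.friction[sel])
        sij = np.sqrt(2.0 * gij)
        stream = _kernels.rng_stream(99, 1)
        args = (state.positions, state.velocities, state.box,
                state.topology.type_index, aij, gij, sij, 0.02, stream)
        f_cell, v_cell = _kernels.compute_forces(*args, True)
        f_ref, v_ref = _kernels.compute_forces(*args, False)
        np.testing.assert_array_equal(f_cell, f_ref)
        np.testing.assert_array_equal(v_cell, v_ref)

    def test_pair_list_valid_during_reuse(self, ff_water):
        """Verlet-list reuse gives the same forces as a fresh rebuild."""
        state = builders.build_bulk((6, 6, 6), seed=21)
        sim = Simulation(state, ff_water, seed=21)
        sim.run(37)  # arbitrary, mid reuse-cycle
        stream = _kernels.rng_stream(5, 5)
        pairs = sim._current_pairs()
        args = (state.positions, state.velocities, state.box,
                state.topology.type_index, sim.aij, sim.gij, sim.sij,
                0.02, stream)
        f_reused, _ = _kernels.compute_forces(*args, True, pairs)
        f_fresh, _ = _kernels.compute_forces(*args, True, None)
        np.testing.assert_array_equal(f_reused, f_fresh)


class TestIntegrator:
    def test_ballistic_motion(self):
        state = _two_bead_state(3.0)  # outside cutoff: no forces
        state.velocities[:] = [[0.1, 0.0, -0.2], [0.0, 0.3, 0.0]]
        ff = ForceField(labels=("W",), repulsion=np.array([[100.0]]),
                        friction=np.array([[1e-12]]))
        x0 = state.positions.copy()
        v = state.velocities.copy()
        sim = Simulation(state, ff, dt=0.02, seed=0)
        sim.step()
        np.testing.assert_allclose(state.positions, x0 + 0.02 * v, atol=1e-12)

    def test_momentum_conserved(self, ff_water):
        state = builders.build_bulk((5, 5, 5), seed=8)
        sim = Simulation(state, ff_water, seed=8)
        sim.run(2000)
        np.testing.assert_allclose(state.total_momentum(), 0.0, atol=1e-9)

    def test_same_seed_reproduces_bitwise(self, ff_water):
        runs = []
        for _ in range(2):
            state = builders.build_bulk((5, 5, 5), seed=17)
            sim = Simulation(state, ff_water, seed=17)
            sim.run(100)
            runs.append((state.positions.copy(), state.velocities.copy()))
        np.testing.assert_array_equal(runs[0][0], runs[1][0])
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_nonfinite_coordinates_signalled(self, ff_water):
        state = builders.build_bulk((5, 5, 5), seed=8)
        sim = Simulation(state, ff_water, seed=8)
        state.positions[0, 0] = np.nan
        with pytest.raises(SimulationError, match="non-finite"):
            sim.run(300)


class TestPressure:
    def test_ideal_gas_pressure(self):
        # vanishing repulsion: P = rho T by the ideal-gas law
        state = builders.build_bulk((6, 6, 6), seed=5)
        ff = ForceField(labels=("W",), repulsion=np.array([[1e-9]]),
                        friction=np.array([[4.5]]))
        sim = Simulation(state, ff, seed=5)
        sim.run(500)
        ps = []
        sim.run(2000, callback=lambda s: ps.append(s.pressure_tensor().mean),
                callback_stride=10)
        assert np.mean(ps) == pytest.approx(3.0, rel=0.03)

    def test_static_sparse_lattice_has_zero_pressure(self, ff_water):
        # beads farther apart than the cutoff, at rest: no kinetic, no virial
        tmpl = MoleculeTemplate(name="W", bead_types=("W",))
        n_side = 4
        topo = assemble([(tmpl, n_side**3)], ("W",))
        g = (np.stack(np.meshgrid(*[np.arange(n_side)] * 3), -1)
             .reshape(-1, 3) * 1.5 + 0.5)
        state = SystemState(g, np.zeros_like(g), topo, np.full(3, 6.0))
        p = pressure_tensor(state, ff_water)
        assert p.Pxx == p.Pyy == p.Pzz == 0.0

    def test_isotropy_in_bulk(self, ff_water):
        state = builders.build_bulk((6, 6, 6), seed=9)
        sim = Simulation(state, ff_water, seed=9)
        sim.run(500)
        acc = []
        sim.run(3000, callback=lambda s: acc.append(
            [s.pressure_tensor().Pxx, s.pressure_tensor().Pyy,
             s.pressure_tensor().Pzz]), callback_stride=10)
        mean = np.mean(acc, axis=0)
        assert abs(mean[0] - mean[2]) < 1.0  # |Pxx - Pzz| -> 0


class TestBarostat:
    def test_bulk_density_held_at_target_pressure(self, ff_water):
        from dpdmem import LangevinPiston
        state = builders.build_bulk((6, 6, 6), seed=2)
        piston = LangevinPiston(P_target=89.0, mode="isotropic")
        sim = Simulation(state, ff_water, seed=2, barostat=piston)
        sim.run(4000)
        rhos = []
        sim.run(4000, callback=lambda s: rhos.append(s.state.density),
                callback_stride=20)
        assert np.mean(rhos) == pytest.approx(3.00, abs=0.02)

    def test_box_collapse_detected(self, ff_water):
        from dpdmem import LangevinPiston
        state = builders.build_bulk((5, 5, 5), seed=2)
        piston = LangevinPiston(P_target=89.0, mode="isotropic")
        piston.eps_dot_xy = -20.0  # violent compression
        piston.eps_dot_z = -20.0
        sim = Simulation(state, ff_water, seed=2, barostat=piston)
        with pytest.raises(SimulationError, match="collapsed"):
            sim.run(200)
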