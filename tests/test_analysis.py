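"""Observables: tension, profiles, structure, order, fits, chi, rupture."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpdmem import Trajectory, analysis, builders
from dpdmem.analysis import (DemixingError, bending_rigidity, chi_from_phi,
                             chi_from_profile, chain_order, density_profile,
                             detect_rupture, fit_area_compressibility,
                             fit_compressibility_alpha, fit_gaussian,
                             fit_lambda, membrane_structure, phi_from_chi,
                             surface_tension_from_tensors)
from dpdmem.fixtures import synthetic_demixed_profile
from dpdmem.integrate import PressureTensor
from dpdmem.units import KBT_298K_J


class TestSurfaceTension:
    def test_synthetic_tensor(self):
        # gamma_s = Lz (Pz - (Px+Py)/2) = 24 * (90 - 88) = 48
        t = PressureTensor(Pxx=88.0, Pyy=88.0, Pzz=90.0)
        assert surface_tension_from_tensors([t], 24.0) == pytest.approx(48.0)

    def test_isotropic_fluid_is_tensionless(self, ff_water):
        from dpdmem import Simulation
        state = builders.build_bulk((6, 6, 6), seed=31)
        sim = Simulation(state, ff_water, seed=31)
        sim.run(500)
        traj = Trajectory(state.topology)
        sim.run(1500, callback=traj.sampler(with_velocities=True),
                callback_stride=30)
        gamma = analysis.surface_tension(traj, ff_water)
        assert abs(gamma) < 3.0  # zero within sampling noise

    def test_single_frame_warns(self, ff_water):
        from dpdmem import Simulation
        state = builders.build_bulk((5, 5, 5), seed=3)
        traj = Trajectory(state.topology)
        traj.append_state(state, with_velocities=True)
        with pytest.warns(UserWarning, match="fewer than 2"):
            analysis.surface_tension(traj, ff_water)


class TestDensityProfile:
    def test_bulk_water_is_flat_and_conserving(self, ff_water):
        state = builders.build_bulk((6, 6, 12), seed=41)
        traj = Trajectory(state.topology)
        traj.append_state(state)
        prof = density_profile(traj, axis=2, n_bins=12)
        total = prof.total()
        # integral of density over volume recovers the bead count
        vol_bin = 36.0 * prof.bin_width
        assert total.sum() * vol_bin == pytest.approx(state.n_beads)
        assert np.all(np.abs(total - 3.0) < 0.8)

    def test_per_type_sums_to_total(self, slab750):
        traj = Trajectory(slab750.topology)
        traj.append_state(slab750)
        prof = density_profile(traj, n_bins=20)
        np.testing.assert_allclose(
            prof.densities["A"] + prof.densities["B"], prof.total())

    def test_demixed_slab_shape(self):
        prof = synthetic_demixed_profile(chi=4.0)
        frac = prof.fraction("A")
        # two interfaces, homogeneous plateaus near phi and 1-phi
        crossings = np.sum(np.abs(np.diff((frac > 0.5).astype(int))))
        assert crossings == 2

    def test_too_few_bins_rejected(self, slab750):
        traj = Trajectory(slab750.topology)
        traj.append_state(slab750)
        with pytest.raises(ValueError):
            density_profile(traj, n_bins=5)


class TestMembraneStructure:
    def test_synthetic_choline_sheets(self, bilayer32):
        state = bilayer32
        topo = state.topology
        z_mid = state.box[2] / 2.0
        # pin cholines to two planes 5 r0 apart
        for tmpl, s in topo.molecule_slices("DMPC"):
            head = s.start + tmpl.head_index
            tails = [s.start + i for c in tmpl.chains for i in c]
            up = state.positions[tails, 2].mean() < state.positions[head, 2]
            state.positions[head, 2] = z_mid + (2.5 if up else -2.5)
        traj = Trajectory(topo)
        traj.append_state(state)
        ms = membrane_structure(traj)
        assert ms.l_mem == pytest.approx(5.0, abs=1e-9)
        n_leaflet = ms.n_lipids / 2
        assert ms.a0 == pytest.approx(
            state.box[0] * state.box[1] / n_leaflet)
        assert ms.l_mem_nm == pytest.approx(3.55, abs=0.01)

    def test_no_lipids_rejected(self, ff_water):
        state = builders.build_bulk((5, 5, 5), seed=3)
        traj = Trajectory(state.topology)
        traj.append_state(state)
        with pytest.raises(ValueError, match="no lipids"):
            membrane_structure(traj)


class TestChainOrder:
    def _oriented_bilayer(self, bilayer32, direction):
        state = bilayer32.copy()
        topo = state.topology
        for tmpl, s in topo.molecule_slices("DMPC"):
            for chain in tmpl.chains:
                first = s.start + chain[0]
                for k, b in enumerate(chain[1:], start=1):
                    state.positions[s.start + b] = (
                        state.positions[first] + k * 0.5 * np.asarray(direction))
        traj = Trajectory(topo)
        traj.append_state(state)
        return traj

    def test_aligned_chains(self, bilayer32):
        traj = self._oriented_bilayer(bilayer32, (0, 0, 1.0))
        assert chain_order(traj) == pytest.approx(1.0)

    def test_in_plane_chains(self, bilayer32):
        traj = self._oriented_bilayer(bilayer32, (1.0, 0, 0))
        assert chain_order(traj) == pytest.approx(-0.5)

    def test_isotropic_orientations_average_to_zero(self, bilayer32):
        """Monte-Carlo oracle: S computed from the sampled directions."""
        state = bilayer32.copy()
        topo = state.topology
        rng = np.random.default_rng(99)
        cos2 = []
        for tmpl, s in topo.molecule_slices("DMPC"):
            for chain in tmpl.chains:
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cos2.append(u[2] ** 2)
                first = s.start + chain[0]
                for k, b in enumerate(chain[1:], start=1):
                    state.positions[s.start + b] = (
                        state.positions[first] + k * 0.3 * u)
        traj = Trajectory(topo)
        traj.append_state(state)
        oracle = float(np.mean(0.5 * (3 * np.asarray(cos2) - 1)))
        s_val = chain_order(traj)
        assert s_val == pytest.approx(oracle, abs=1e-9)
        assert abs(s_val) < 3.0 / np.sqrt(len(cos2))  # ~0 for isotropic

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_bounds(self, seed):
        """-1/2 <= S_chain <= 1 for arbitrary chain orientations."""
        rng = np.random.default_rng(seed)
        cos2 = rng.uniform(0, 1, 50)
        s = np.mean(0.5 * (3 * cos2 - 1))
        assert -0.5 - 1e-12 <= s <= 1.0 + 1e-12


class TestElasticity:
    def test_exact_line_round_trip(self):
        a = np.linspace(1.20, 1.40, 7)
        sigma = 23.0 * (a - 1.30) / 1.30
        fit = fit_area_compressibility(a, sigma)
        assert fit.K_A == pytest.approx(23.0, rel=1e-9)
        assert fit.a0 == pytest.approx(1.30, rel=1e-9)

    def test_tension_vanishes_at_a0(self):
        a = np.array([1.25, 1.30, 1.35])
        sigma = 23.0 * (a - 1.30) / 1.30
        fit = fit_area_compressibility(a, sigma)
        assert fit.K_A * (fit.a0 - fit.a0) / fit.a0 == 0.0

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(5)
        a = np.linspace(1.15, 1.45, 15)
        sigma = 23.0 * (a - 1.30) / 1.30 + rng.normal(0, 0.1, a.size)
        fit = fit_area_compressibility(a, sigma)
        assert fit.K_A == pytest.approx(23.0, rel=0.10)

    def test_extrapolation_warns(self):
        a = np.array([1.31, 1.33, 1.35])
        sigma = 23.0 * (a - 1.30) / 1.30
        with pytest.warns(UserWarning, match="sign change"):
            fit_area_compressibility(a, sigma)

    def test_bending_rigidity(self):
        kappa, kappa_J = bending_rigidity(48.0, 1.0)
        assert kappa == pytest.approx(1.0)
        # the reference DMPC numbers give ~12 kBT ~ 0.5e-19 J
        kappa, kappa_J = bending_rigidity(23.0, 3.56 / 0.71)
        assert kappa == pytest.approx(23.0 * (3.56 / 0.71) ** 2 / 48.0)
        assert kappa_J == pytest.approx(kappa * KBT_298K_J)
        with pytest.raises(ValueError):
            bending_rigidity(-1.0, 1.0)


class TestChi:
    def test_closed_form(self):
        assert chi_from_phi(0.2) == pytest.approx(np.log(4.0) / 0.6)
        assert chi_from_phi(0.2) == pytest.approx(2.3105, abs=1e-4)

    def test_half_filling_limit(self):
        assert chi_from_phi(0.5 - 1e-12) == pytest.approx(2.0)

    def test_round_trip_through_root_finder(self):
        assert chi_from_phi(phi_from_chi(3.0)) == pytest.approx(3.0, abs=1e-9)

    @given(st.floats(2.5, 6.0))
    @settings(max_examples=50, deadline=None)
    def test_identity_on_demixed_range(self, chi):
        assert chi_from_phi(phi_from_chi(chi)) == pytest.approx(chi, abs=1e-6)

    def test_chi_from_synthetic_profile(self):
        prof = synthetic_demixed_profile(chi=4.0, width=0.4)
        chi, phi = chi_from_profile(prof, d_excl=2.0)
        assert chi == pytest.approx(4.0, abs=0.1)
        assert 0.0 < phi < 0.5

    def test_mixed_profile_rejected(self):
        prof = synthetic_demixed_profile(chi=4.0)
        prof.densities["A"] = np.full_like(prof.densities["A"], 1.5)
        prof.densities["B"] = np.full_like(prof.densities["B"], 1.5)
        with pytest.raises(DemixingError):
            chi_from_profile(prof)


class TestLambdaFit:
    def test_exact_slope(self):
        d = np.array([10.0, 13.0, 16.0])
        lam, se = fit_lambda(d, 0.277 * d)
        assert lam == pytest.approx(0.277, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_non_demixed_points_excluded(self):
        d = np.array([4.0, 10.0, 13.0])
        chis = np.array([np.nan, 2.77, 3.60])
        with pytest.warns(UserWarning, match="non-demixed"):
            lam, _ = fit_lambda(d, chis)
        assert lam == pytest.approx(np.sum(d[1:] * chis[1:]) / np.sum(d[1:] ** 2))


class TestAlphaFit:
    def test_published_constant_reproduces_water_compressibility(self):
        fit = fit_compressibility_alpha([(100.0, 3.0, 3.0 + 0.101 * 100 * 9)])
        assert fit.alpha == pytest.approx(0.101)
        assert fit.k_inverse(100.0, 3.0) == pytest.approx(61.6)
        assert fit.k_inverse_per_molecule(100.0, 3.0, 4) == pytest.approx(15.4)

    def test_exact_scan_recovery(self):
        samples = [(a, 3.0, 3.0 + 0.101 * a * 9.0) for a in (25.0, 50.0, 100.0)]
        assert fit_compressibility_alpha(samples).alpha == pytest.approx(0.101)

    def test_ideal_gas_is_singular(self):
        with pytest.raises(ValueError, match="singular"):
            fit_compressibility_alpha([(0.0, 3.0, 3.0)])


class TestGaussianFit:
    def test_width_maps_to_force_constant(self):
        # w = sqrt(4/512) ~ 0.0884 corresponds to K2 = 512
        w = np.sqrt(4.0 / 512.0)
        x = np.linspace(0.4, 0.9, 200)
        counts = 1000.0 / (w * np.sqrt(np.pi / 2)) * np.exp(
            -2 * (x - 0.66) ** 2 / w**2)
        fit = fit_gaussian(histogram=(x, counts))
        assert fit.force_constant == pytest.approx(512.0, rel=1e-6)
        assert fit.center == pytest.approx(0.66, abs=1e-9)

    def test_center_recovery_from_samples(self):
        rng = np.random.default_rng(8)
        samples = rng.normal(174.0, 4.0, 40_000)
        fit = fit_gaussian(samples, n_bins=80)
        assert fit.center == pytest.approx(174.0, abs=0.5)
        assert fit.width == pytest.approx(8.0, rel=0.05)  # w = 2 sigma

    def test_area_matches_sample_normalization(self):
        rng = np.random.default_rng(9)
        samples = rng.normal(0.0, 1.0, 20_000)
        fit = fit_gaussian(samples, n_bins=60)
        dx = (samples.max() - samples.min()) / 60
        assert fit.area == pytest.approx(len(samples) * dx, rel=0.05)


class TestRupture:
    def test_built_bilayer_is_intact(self, bilayer32):
        traj = Trajectory(bilayer32.topology)
        traj.append_state(bilayer32)
        assert detect_rupture(traj) == "intact"

    def test_water_column_is_a_pore(self, bilayer32):
        state = bilayer32.copy()
        topo = state.topology
        w_idx = np.where(np.array(
            [topo.type_labels[t] for t in topo.type_index]) == "W")[0]
        z_mid = state.box[2] / 2.0
        column = w_idx[:14]
        state.positions[column, 0] = 2.0
        state.positions[column, 1] = 2.0
        state.positions[column, 2] = z_mid + np.linspace(-3.2, 3.2, len(column))
        traj = Trajectory(topo)
        traj.append_state(state)
        assert detect_rupture(traj) in ("pore", "ruptured")

    def test_bulk_water_is_degenerate(self, ff_water):
        state = builders.build_bulk((5, 5, 5), seed=4)
        traj = Trajectory(state.topology)
        traj.append_state(state)
        assert detect_rupture(traj) == "ruptured"
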