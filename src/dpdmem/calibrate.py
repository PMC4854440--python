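"""End-to-end calibration pipelines.

These drive full simulations and feed the analysis fitters:

* the binary-demixing experiment that maps excess repulsion da onto the
  Flory-Huggins chi and yields the slope lambda in chi = lambda * da;
* bulk NVT pressure scans for the equation-of-state constant alpha in
  P = rho T + alpha a rho^2;
* tensionless-bilayer equilibration for the structural observables.

Default problem sizes are laterally scaled-down versions of the
reference experiments (the slab keeps its 20 r0 height but a quarter of
the cross-section; bulk runs use ~1000-3000 beads) so a full calibration
completes in minutes on one core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import analysis, builders
from .forcefield import ForceField, binary_forcefield, default_forcefield
from .integrate import LangevinPiston, Simulation
from .trajectory import Trajectory


@dataclass
class ChiMeasurement:
    a_ii: float
    delta_a: float
    chi: float
    phi: float
    profile: analysis.DensityProfile


@dataclass
class LambdaCalibration:
    """Result of the chi-versus-da slope fit at one like-bead repulsion."""

    a_ii: float
    lam: float
    lam_se: float
    measurements: list[ChiMeasurement] = field(default_factory=list)


def measure_chi(
    a_ii: float,
    delta_a: float,
    box: tuple[float, float, float] = (5.0, 5.0, 20.0),
    n_equil: int = 30_000,
    n_prod: int = 70_000,
    sample_stride: int = 50,
    n_bins: int = 40,
    d_excl: float = 2.0,
    seed: int = 0,
    dt: float = 0.02,
) -> ChiMeasurement:
    """chi from one demixed A/B slab simulation at excess repulsion da.

    Builds a pre-separated slab at density 3, runs NVT, accumulates the
    A/B density profile over production, and converts the interior
    minority fraction to chi.
    """
    box = np.asarray(box, dtype=float)
    n_total = builders.n_beads_for_box(box)
    nA = n_total // 2
    state = builders.build_binary_slab(nA, n_total - nA, box, seed=seed)
    ff = binary_forcefield(a_ii, a_ii + delta_a)
    sim = Simulation(state, ff, dt=dt, seed=seed)
    sim.run(n_equil)
    traj = Trajectory(state.topology)
    sim.run(n_prod, callback=traj.sampler(), callback_stride=sample_stride)
    profile = analysis.density_profile(traj, axis=2, n_bins=n_bins,
                                       labels=["A", "B"])
    chi, phi = analysis.chi_from_profile(profile, labels=("A", "B"),
                                         d_excl=d_excl)
    return ChiMeasurement(a_ii=a_ii, delta_a=delta_a, chi=chi, phi=phi,
                          profile=profile)


def calibrate_lambda(
    a_ii: float = 100.0,
    deltas: tuple[float, ...] = (10.0, 13.0, 16.0),
    seed: int = 0,
    **kwargs,
) -> LambdaCalibration:
    """Slope lambda of chi = lambda * da from a set of demixing runs."""
    meas = []
    chis, ds = [], []
    for k, da in enumerate(deltas):
        m = measure_chi(a_ii, da, seed=seed + 101 * k, **kwargs)
        meas.append(m)
        ds.append(da)
        chis.append(m.chi)
    lam, se = analysis.fit_lambda(np.asarray(ds), np.asarray(chis))
    return LambdaCalibration(a_ii=a_ii, lam=lam, lam_se=se, measurements=meas)


def bulk_pressure(
    a: float = 100.0,
    box: tuple[float, float, float] = (10.0, 10.0, 10.0),
    n_equil: int = 10_000,
    n_prod: int = 10_000,
    sample_stride: int = 10,
    seed: int = 0,
    dt: float = 0.02,
    temperature: float = 1.0,
) -> tuple[float, float]:
    """Mean diagonal pressure of a one-component bulk DPD fluid (NVT).

    Returns ``(P, standard_error)`` in kBT/r0^3, averaged over the
    production phase.
    """
    state = builders.build_bulk(box, seed=seed, temperature=temperature)
    ff = ForceField(
        labels=("W",), repulsion=np.array([[a]]),
        friction=np.array([[4.5]]), temperature=temperature,
    )
    sim = Simulation(state, ff, dt=dt, seed=seed)
    sim.run(n_equil)
    vals = []
    sim.run(n_prod, callback=lambda s: vals.append(s.pressure_tensor().mean),
            callback_stride=sample_stride)
    vals = np.asarray(vals)
    # crude autocorrelation-blind error bar from blocked means
    nblock = max(len(vals) // 20, 1)
    blocks = np.array_split(vals, nblock)
    bm = np.array([b.mean() for b in blocks])
    return float(vals.mean()), float(bm.std(ddof=1) / np.sqrt(len(bm))
                                     if len(bm) > 1 else 0.0)


def eos_scan(
    a_values: tuple[float, ...] = (25.0, 50.0, 100.0),
    box: tuple[float, float, float] = (7.0, 7.0, 7.0),
    n_equil: int = 5_000,
    n_prod: int = 15_000,
    seed: int = 0,
    temperature: float = 1.0,
    **kwargs,
) -> analysis.AlphaFit:
    """Fit the equation-of-state constant alpha from bulk pressure runs."""
    rho = builders.RHO
    samples = []
    for k, a in enumerate(a_values):
        P, _ = bulk_pressure(a, box=box, n_equil=n_equil, n_prod=n_prod,
                             seed=seed + 17 * k, temperature=temperature,
                             **kwargs)
        samples.append((a, rho, P))
    return fitted_alpha(samples, temperature)


def fitted_alpha(samples, temperature: float = 1.0) -> analysis.AlphaFit:
    return analysis.fit_compressibility_alpha(samples, temperature)


@dataclass
class BilayerRun:
    """Equilibrated tensionless bilayer and its structural observables."""

    structure: analysis.MembraneStructure
    s_chain: float
    tension: float
    trajectory: Trajectory


def equilibrate_bilayer(
    species: str = "DMPC",
    n_lipids: int = 128,
    a_prj: float = 1.30,
    P_target: float = 89.0,
    n_equil: int = 60_000,
    n_prod: int = 40_000,
    sample_stride: int = 200,
    seed: int = 0,
    dt: float = 0.02,
    temperature: float = 1.0,
    ff: ForceField | None = None,
) -> BilayerRun:
    """Zero-tension bilayer run plus structure/order analysis.

    Runs the constant-normal-pressure / zero-surface-tension ensemble
    (semi-isotropic Langevin piston at P_perp) and averages the membrane
    observables over the production frames.
    """
    if ff is None:
        ff = default_forcefield()
        if temperature != ff.temperature:
            ff.temperature = temperature
    state = builders.build_bilayer(species, n_lipids, a_prj, seed=seed,
                                   temperature=temperature)
    piston = LangevinPiston(P_target=P_target, temperature=temperature)
    sim = Simulation(state, ff, dt=dt, seed=seed, barostat=piston)
    sim.run(n_equil)
    traj = Trajectory(state.topology)
    tensions = []

    def cb(s):
        traj.append_state(s.state)
        p = s.pressure_tensor()
        tensions.append(s.state.box[2] * (p.Pzz - p.tangential))

    sim.run(n_prod, callback=cb, callback_stride=sample_stride)
    structure = analysis.membrane_structure(traj)
    s_chain = analysis.chain_order(traj)
    return BilayerRun(
        structure=structure,
        s_chain=s_chain,
        tension=float(np.mean(tensions)),
        trajectory=traj,
    )
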