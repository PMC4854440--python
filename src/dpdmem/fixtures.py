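"""Deterministic miniature systems and synthetic datasets for testing.

Everything here is generated programmatically from a seed; the
``synthetic_*`` kinds draw from stated closed-form distributions so they
can serve as independent oracles for the analysis and WHAM machinery.
"""

from __future__ import annotations

import numpy as np

from . import builders
from .analysis import DensityProfile, phi_from_chi
from .umbrella import UmbrellaWindow

KINDS = ("bulk64", "slab750", "bilayer32", "synthetic_profile",
         "synthetic_pmf_samples")


def fixture_generator(kind: str, size: int | None = None, seed: int = 0):
    """Small deterministic inputs for the test suite.

    ``bulk64``: 64 water beads in a 3x3x3 box (sub-reference density, for
    force-kernel checks).  ``slab750``: 375+375 A/B slab in 5x5x10.
    ``bilayer32``: 32 DMPC + water at density 3 in a ~4.6x4.6x24 box.
    ``synthetic_profile``: analytic demixed two-slab profile at a known
    chi.  ``synthetic_pmf_samples``: umbrella windows with Gaussian
    samples drawn from a known quadratic free-energy surface.
    """
    if kind == "bulk64":
        n = size or 64
        box = (3.0, 3.0, 3.0)
        return builders.build_bulk(
            box, composition={"W": n}, seed=seed,
            density=n / float(np.prod(box)))
    if kind == "slab750":
        n = size or 750
        box = (5.0, 5.0, n / 75.0)
        return builders.build_binary_slab(n // 2, n - n // 2, box, seed=seed)
    if kind == "bilayer32":
        return builders.build_bilayer("DMPC", size or 32, a_prj=1.30, seed=seed)
    if kind == "synthetic_profile":
        return synthetic_demixed_profile(chi=4.0, n_bins=size or 100, seed=seed)
    if kind == "synthetic_pmf_samples":
        return synthetic_pmf_samples(n_per_window=size or 4000, seed=seed)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {KINDS}")


def synthetic_demixed_profile(
    chi: float = 4.0,
    Lz: float = 20.0,
    n_bins: int = 100,
    width: float = 0.7,
    rho: float = 3.0,
    seed: int = 0,
    noise: float = 0.0,
) -> DensityProfile:
    """Analytic two-slab A/B density profile at a prescribed chi.

    The A fraction follows tanh interfaces at z = Lz/4 and 3Lz/4 between
    the coexistence fractions phi (minority) and 1-phi, with phi solved
    from chi; optional multiplicative noise emulates binning scatter.
    """
    phi = phi_from_chi(chi)
    z = (np.arange(n_bins) + 0.5) * (Lz / n_bins)
    z1, z2 = Lz / 4.0, 3.0 * Lz / 4.0
    step = 0.5 * (np.tanh((z - z1) / width) - np.tanh((z - z2) / width))
    frac_a = phi + (1.0 - 2.0 * phi) * step
    if noise > 0:
        rng = np.random.default_rng(seed)
        frac_a = np.clip(frac_a * (1 + rng.normal(0, noise, n_bins)), 1e-6, 1 - 1e-6)
    return DensityProfile(
        axis=2,
        bin_centers=z,
        bin_width=Lz / n_bins,
        densities={"A": rho * frac_a, "B": rho * (1.0 - frac_a)},
        n_frames=1,
        box=np.array([5.0, 5.0, Lz]),
    )


def synthetic_pmf_samples(
    curvature: float = 1.5,
    n_windows: int = 10,
    spacing: float = 0.5,
    k_umb: float = 20.0,
    n_per_window: int = 4000,
    seed: int = 0,
) -> tuple[list[UmbrellaWindow], callable]:
    """Umbrella windows sampled exactly from a known quadratic PMF.

    The unbiased surface is U0(z) = curvature * z^2 / 2; under window
    bias k (z - z*)^2 / 2 the stationary distribution is Gaussian with
    mean k z* / (curvature + k) and variance 1/(curvature + k), which is
    sampled directly.  Returns ``(windows, U0)``.
    """
    rng = np.random.default_rng(seed)
    windows = []
    for i in range(n_windows):
        z_star = (i - (n_windows - 1) / 2.0) * spacing
        mean = k_umb * z_star / (curvature + k_umb)
        std = 1.0 / np.sqrt(curvature + k_umb)
        w = UmbrellaWindow(index=i, z_star=z_star, k_umb=k_umb)
        w.samples = rng.normal(mean, std, n_per_window)
        windows.append(w)
    return windows, lambda z: 0.5 * curvature * np.asarray(z) ** 2
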