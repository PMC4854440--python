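"""Tensionless DMPC bilayer structure.

Equilibrates a 128-lipid DMPC patch in the constant-normal-pressure /
zero-surface-tension ensemble and reports the membrane thickness, area
per lipid and tail order parameter.  A fluid-phase DMPC bilayer should
settle near a0 ~ 0.66 nm^2, l_mem ~ 3.6 nm, S_chain ~ 0.5 with the
surface tension fluctuating around zero.  (~4 minutes on one core;
increase the step counts for tighter averages.)
"""

from dpdmem import analysis, calibrate

run = calibrate.equilibrate_bilayer(
    "DMPC", n_lipids=128, a_prj=1.30, n_equil=30_000, n_prod=20_000,
    sample_stride=250, seed=1)
ms = run.structure
print(f"area per lipid     a0 = {ms.a0:.3f} r0^2 = {ms.a0_nm2:.3f} nm^2")
print(f"membrane thickness l  = {ms.l_mem:.2f} r0  = {ms.l_mem_nm:.2f} nm")
print(f"chain order        S  = {run.s_chain:.3f}")
print(f"surface tension       = {run.tension:+.2f} kBT/r0^2 (should be ~0)")
kappa, kappa_J = analysis.bending_rigidity(23.0, ms.l_mem)
print(f"bending rigidity (with K_A = 23 kBT/r0^2): "
      f"kappa = {kappa:.1f} kBT = {kappa_J:.2e} J")
print(f"membrane status: {analysis.detect_rupture(run.trajectory)}")
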