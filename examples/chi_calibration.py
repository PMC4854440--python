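"""Flory-Huggins chi calibration from binary demixing.

Simulates pre-separated A/B slabs at like-bead repulsion 100 for three
mismatch strengths, converts the equilibrated minority fraction phi to
chi = ln[(1-phi)/phi]/(1-2phi), and fits the slope lambda of
chi = lambda * da.  lambda links the repulsion table to experimental
solubilities: for the four-to-one mapping it should come out near 0.277.
(Short runs here; the acceptance script uses longer production.)
"""

from dpdmem import calibrate

cal = calibrate.calibrate_lambda(
    a_ii=100.0, deltas=(10.0, 13.0, 16.0), box=(5.0, 5.0, 20.0),
    n_equil=12_000, n_prod=18_000, sample_stride=25, seed=1)
for m in cal.measurements:
    print(f"da = {m.delta_a:4.1f}  phi = {m.phi:.4f}  chi = {m.chi:.3f}")
print(f"lambda = {cal.lam:.4f} +/- {cal.lam_se:.4f}   (reference ~0.277)")
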