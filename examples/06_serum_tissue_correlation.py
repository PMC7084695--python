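"""Serum–tissue correlation analysis with 95% confidence ellipses.

Generates a paired brain-tissue panel in which the serum–tissue relationship
flips sign after injury (as reported for glutamine: positive in shams,
negative in injured animals), then estimates per-group Pearson correlations
and the ellipse geometry used to draw them.
"""

from aapanel import (
    generate_cohort,
    generate_paired_tissue,
    planted_signal_config,
    serum_tissue_correlation,
)

ANALYTES = ("GLN", "GLY", "TAU")
config = planted_signal_config(
    analyte_names=ANALYTES, signal_set=(), n_uninjured=12, n_injured=12, seed=19
)
serum = generate_cohort(config)
# GLN flips sign between groups; GLY and TAU stay positively coupled
slopes = {"GLN": (0.9, -0.9), "GLY": (0.8, 0.8), "TAU": (0.7, 0.7)}
tissue = generate_paired_tissue(serum, slopes, noise_sd=6.0, seed=3)

for group in ("sham", "injured"):
    print(f"{group} group:")
    for s in serum_tissue_correlation(serum, tissue, group):
        print(
            f"  {s.analyte}: r = {s.r:+.2f} (p = {s.p_value:.3f}), "
            f"ellipse axes {s.axes[0]:.1f}/{s.axes[1]:.1f} at {s.angle:.0f} deg"
        )
print(
    "\nGLN's correlation changes sign between groups — the pattern that flags"
    "\nan injury-driven reversal of exchange between serum and brain tissue."
)
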