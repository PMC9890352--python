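"""Evaluate the published circadian posting curve and its headline constants.

Builds the reference unified model (flat daytime rate, quadratic nighttime
depletion) from the published coefficients and prints the quantities that
characterize it: where posting starts to fall, where the lull bottoms out,
how deep it is, and the flat height implied by normalization.
"""

from noctograph import eval_model, reference_model

m = reference_model()
vals = eval_model(m)

print(f"parabolic section: {m.S} h before to {m.E} h after bedtime "
      f"({m.n_parabolic_bins} of 96 bins)")
print(f"flat daytime height d = {m.d:.3g} per 15-min bin")
print(f"nadir at {m.nadir_x:.2f} h after bedtime, "
      f"{100 * m.depletion_fraction():.0f}% below the daytime rate")
print(f"curve sums to {vals.sum():.12f} over the 96 bins")

# Interpretation: a user posts at a steady rate while awake; posting starts
# declining 45 minutes before bedtime and is deepest about 4.6 h after it.
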