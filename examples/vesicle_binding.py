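"""Vesicle co-sedimentation: comparing membrane affinity of two enzyme forms.

Fits saturable binding curves to pellet/supernatant densitometry series and
asks how much anionic lipid the weaker binder needs to match the stronger
binder at the same bound fraction.
"""

import ptenkin as pk

molpct = [0.5, 1, 2, 3, 5, 7, 10]
strong = pk.gen_binding(c50=2.0, fmax=0.9, molpct_levels=molpct, noise=pk.default_noise(1), sample="unphos")
weak = pk.gen_binding(c50=8.0, fmax=0.9, molpct_levels=molpct, noise=pk.default_noise(2), sample="phos")

for series in (strong, weak):
    fit = pk.fit_binding_curve(series)
    print(f"{series.sample:7s} c50 = {fit.c50:.2f} mol%, plateau = {fit.fmax:.2f}")

target = 0.2
c_weak, c_strong = pk.equivalent_composition(weak, strong, target_fraction=target)
print(f"to sediment {target:.0%} of the protein: weak binder needs "
      f"{c_weak:.1f} mol% anionic lipid vs {c_strong:.1f} mol% for the strong binder")
# The ratio of the two compositions is a design-free measure of how much
# membrane affinity is lost on phosphorylation.
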