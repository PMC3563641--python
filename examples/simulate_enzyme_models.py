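"""Simulate the two rival enzyme models and compare their progress curves.

The simple mechanism (S + E <-> ES -> E + P) produces hyperbolic substrate
decay; the hysteretic (slow-transition) enzyme shows a lag phase followed by
a fast sigmoidal conversion, because the catalytically efficient conformation
accumulates slowly.
"""

import numpy as np

import modeldiscrim as md
from modeldiscrim.models import HYSTERETIC_ENZYME_PARAMS, SIMPLE_ENZYME_PARAMS

design_h = md.equispaced_design(26, 260.0, {"S": 2.0, "Ei": 0.1})
design_s = md.equispaced_design(26, 260.0, {"S": 2.0, "E": 0.1})

hyst = md.simulate(md.get_model("hysteretic_enzyme"), HYSTERETIC_ENZYME_PARAMS, design_h)
simp = md.simulate(md.get_model("simple_enzyme"), SIMPLE_ENZYME_PARAMS, design_s)

print("time   S(hysteretic)  P(hysteretic)  S(simple)  P(simple)")
for i in range(0, 26, 5):
    print(
        f"{hyst.times[i]:5.0f}  {hyst.row('S')[i]:12.4f}  {hyst.row('P')[i]:12.4f}"
        f"  {simp.row('S')[i]:9.4f}  {simp.row('P')[i]:9.4f}"
    )

# the lag phase: the fastest production interval comes after the first one
p = hyst.row("P")
gains = np.diff(np.concatenate([[0.0], p]))
print(f"\nhysteretic product gained in the first 10 time units: {gains[0]:.4f}")
print(f"fastest 10-unit gain ({gains.max():.4f}) occurs around t = "
      f"{hyst.times[int(np.argmax(gains))]:.0f}")
print("production accelerates after a lag -> sigmoidal kinetics:", np.argmax(gains) > 0)
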