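"""Evaluate the published response-function presets.

Prints each randomness preset r(d) at the trap rim, mid-field and far
field of the reference square arena (trap radius 5, half-diagonal ~35),
the admissibility statistic for the dazzle family r3, and the speed
presets s(d) at the same distances.  Values near or below 1 mean directed
(r) or slow (s) movement; the interplay of the two shapes the trap-count
pattern.
"""

import numpy as np

from trapwalk import eval_r, eval_s, r3_admissibility, r3_minimum
from trapwalk.response import r_presets, s_presets

distances = np.array([5.0, 15.0, 25.0, 35.0])

print(f"{'preset':20s}" + "".join(f"  r(d={d:g})" for d in distances))
for name, p in sorted(r_presets().items()):
    vals = eval_r(p, distances)
    print(f"{name:20s}" + "".join(f"  {v:7.3f}" for v in vals))
    if p.family == "r3":
        stat, ok = r3_admissibility(p)
        d_star, mn = r3_minimum(p)
        flag = "admissible" if ok else "NOT admissible (clamped at floor)"
        print(f"{'':20s}  |a-b|sqrt(J) = {stat:.2f} ({flag}); "
              f"min r = {mn:.4f} at d = {d_star:g}")

print()
print(f"{'preset':20s}" + "".join(f"  s(d={d:g})" for d in distances))
for name, p in sorted(s_presets().items()):
    vals = eval_s(p, distances)
    print(f"{name:20s}" + "".join(f"  {v:7.3f}" for v in vals))

print()
print("Reading: r < 1 ~ directed toward the trap, r >> 1 ~ random headings;")
print("mean step length is s*sqrt(2/pi), so s < 1 means slow movement.")
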