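"""V1 stage: complex-cell motion energy and end-stopped responses.

For an oblique bar drifting rightward, complex cells along the edges respond
mainly to the direction perpendicular to the bar (the aperture problem),
while the rightward channel is comparatively strongest near the bar's
end-points — the terminators, whose 2-D structure carries the true motion.
The end-stopped stage then suppresses cells whose same-direction surround is
heavily active (the edge cells), sharpening the terminator signal.
"""

import numpy as np

from v1mt import BarSpec, ModelParams, make_bar_stimulus, simulate
from v1mt.stimulus import DIRECTION_NAMES

p = ModelParams()
bar = BarSpec(orientation=45, direction="right", length=21, bar_width=1,
              n_frames=10)
stim = make_bar_stimulus(bar)
res = simulate(stim, p)

f = stim.n_frames - 1
ys, xs = np.nonzero(stim.mask(f))
mid = len(ys) // 2

print("complex-cell activity on the final frame (0 = silent, 1 = saturated):")
for d, label in ((7, "down-right (perpendicular)"), (0, "right (true direction)")):
    v = res.v_cx[f]
    print(f"  {label:28s} mid-bar {v[ys[mid], xs[mid], d]:.2f}   "
          f"ends {v[ys[0], xs[0], d]:.2f} / {v[ys[-1], xs[-1], d]:.2f}")

print("\nend-stopped activity (same cells):")
for d, label in ((7, "down-right (perpendicular)"), (0, "right (true direction)")):
    v = res.v_es[f]
    print(f"  {label:28s} mid-bar {v[ys[mid], xs[mid], d]:.2f}   "
          f"ends {v[ys[0], xs[0], d]:.2f} / {v[ys[-1], xs[-1], d]:.2f}")

print("\nIn the complex field the perpendicular channel saturates along the "
      "edge while the rightward channel is strongest near the ends.  The "
      "end-stopped stage eliminates the perpendicular edge signal entirely; "
      "the surviving activity is weak in absolute terms (a known limitation "
      "of this reconstruction, see docs/methods.md).")
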