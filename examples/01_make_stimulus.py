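"""Build a drifting-bar stimulus and look at what the model will see.

A bar is an oriented rectangle rasterised onto a binary luminance grid and
translated rigidly by one pixel per frame along its motion direction.  The
printout shows that the footprint is identical in every frame (pure
translation) and where the bar sits at the start and end of the sequence.
"""

import numpy as np

from v1mt import BarSpec, GridSpec, make_bar_stimulus

bar = BarSpec(orientation=45, direction="right", length=9, bar_width=1,
              n_frames=10)
stim = make_bar_stimulus(bar, GridSpec(64, 64))

print(f"stimulus: {stim.n_frames} frames of {stim.grid.height}x{stim.grid.width}")
print(f"bar: {bar.length} px long, {bar.bar_width} px wide, oriented "
      f"{bar.orientation} deg, drifting {bar.direction} at {bar.speed} px/frame")
for f in (0, stim.n_frames - 1):
    ys, xs = np.nonzero(stim.mask(f))
    print(f"frame {f}: {len(ys)} bar pixels, x-range {xs.min()}..{xs.max()}, "
          f"y-range {ys.min()}..{ys.max()}")
# the whole footprint moves one pixel rightward per frame:
y0, x0 = np.nonzero(stim.mask(0))
y1, x1 = np.nonzero(stim.mask(1))
assert sorted(zip(y1, x1)) == sorted(zip(y0, x0 + 1))
print("translation check passed: frame 1 footprint = frame 0 shifted by (1, 0)")
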