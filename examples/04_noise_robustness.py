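"""Noise robustness: classification error under activity-dependent noise.

Gaussian noise with variance proportional to each cell's activity (alpha = 1
matching Poisson-like variability) is injected at the outputs of all four
populations, and the direction classification is repeated several times per
noise scale.  This is a scaled-down sweep (3 noise levels x 3 repeats) so it
runs in about a minute; `v1mt sweep` runs the full 11-point, 10-repeat
version.
"""

from v1mt import BarSpec, ModelParams
from v1mt.evaluation import noise_sweep

p = ModelParams()
bar = BarSpec(orientation=45, direction="right", length=9, bar_width=1,
              n_frames=5)
df = noise_sweep(p, bar, alphas=[0.0, 0.4, 0.8], repeats=3, seed=7)

print(df[["alpha", "mean_error", "sem"]].to_string(index=False))
print("\nmean_error 0 means every repeat picked the true direction; "
      "1 means a wrong (typically aperture-biased) direction won every time.")
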