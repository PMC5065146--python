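"""Fitting the free gains with the genetic algorithm (miniature run).

The 11 connection gains/decays are evolved against a fitness that rewards
correct, exclusive integration winners and discontinuity-localised
segmentation on a training bar.  This miniature run (6 individuals, 3
generations, 24x24 grid) only demonstrates the machinery; `v1mt ga` runs a
desk-scale fit.
"""

from v1mt.ga import GAConfig, default_training_stimuli, evolve
from v1mt.params import GA_PARAM_NAMES, ModelParams
from v1mt.stimulus import BarSpec, GridSpec, make_bar_stimulus

stims = [make_bar_stimulus(
    BarSpec(orientation=45, direction="right", length=9, bar_width=1, n_frames=4),
    GridSpec(24, 24))]
cfg = GAConfig(population_size=6, generation_cap=3, seed=11)
res = evolve(cfg, ModelParams(), stims, progress=True)

print(f"\nconverged: {res.converged} "
      f"(a zero classification error E_GA terminates the run)")
best = (res.solutions or [res.best])[0]
print("best individual (fitness %.1f, E_GA %.2f):" % (best.fitness, best.error))
for name, v in zip(GA_PARAM_NAMES, best.params):
    print(f"  {name:10s} = {v:.3f}")
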