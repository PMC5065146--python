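"""Genetic-algorithm fitting of the network gains.

The 11 free constants (connection gains and the shared MT decay rate) are fit
by maximising a fitness F = F1 + F2 computed from a complete simulation of a
training stimulus:

* F1 rewards integration activity in the correct direction channel wherever
  complex cells respond, exclusive winners (low activity in the other
  channels), and silence in the background;
* F2 rewards segmentation activity at motion discontinuities (active complex
  cells whose neighbourhood is mostly inactive), and silence both along the
  coherent part of the stimulus and in the background.

A candidate counts as a *solution* when its direction-classification error
E_GA is exactly zero: at every pixel either the correct channel is the only
one above threshold T, or (in the background) everything including the
complex drive is below T.

Selection is elitist (the top 10% are copied), 50% of each generation comes
from single-point crossover between high-fitness parents, and 40% from
heuristic mutation: uniform perturbations whose *sign* is steered by three
diagnostics of the simulated behaviour (aperture problem unsolved -> increase
the end-stopped weights relative to the complex weights; wrong channels above
threshold -> increase inter-directional inhibition; background leakage ->
decrease lateral excitation and increase segmentation inhibition; segmentation
active in the coherent region -> increase surround suppression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import GA_PARAM_NAMES, ModelParams
from .simulate import simulate
from .stimulus import BarSpec, GridSpec, StimulusSequence, make_bar_stimulus
from .evaluation import evaluation_mask, overall_error, winner_map

__all__ = ["GAConfig", "GAIndividual", "fitness_F1", "fitness_F2", "ga_error",
           "evaluate_individual", "mutate_heuristic", "crossover", "evolve"]


# ---------------------------------------------------------------------------
# fitness and error
# ---------------------------------------------------------------------------

def fitness_F1(v_ig: np.ndarray, v_cx: np.ndarray, theta: int) -> float:
    """Integration-cell fitness for a stimulus moving in direction ``theta``."""
    ig_th = v_ig[..., theta]
    cx_th = v_cx[..., theta]
    others = v_ig.sum(axis=-1) - ig_th
    term_motion = ((1.0 - others) * ig_th * cx_th).sum()
    term_bg = ((1.0 - v_ig.sum(axis=-1)) * (1.0 - cx_th)).sum()
    return float(term_motion + term_bg)


def fitness_F2(v_sg: np.ndarray, v_cx: np.ndarray, v_ig: np.ndarray,
               theta: int) -> float:
    """Segmentation-cell fitness: discontinuities, coherence, background."""
    from .fields import box_sum
    sg_th = v_sg[..., theta]
    cx_th = v_cx[..., theta]
    ig_th = v_ig[..., theta]
    neigh_mean = (box_sum(cx_th, 1) - cx_th) / 8.0
    term_disc = (sg_th * cx_th * (1.0 - neigh_mean)).sum()
    term_coher = ((1.0 - sg_th) * cx_th).sum()
    term_bg = ((1.0 - sg_th) * (1.0 - ig_th)).sum()
    return float(term_disc + term_coher + term_bg)


def ga_error(v_ig: np.ndarray, v_cx: np.ndarray, theta: int,
             T: float = 0.15) -> float:
    """Summed per-pixel error between desired and simulated winners.

    Zero at a pixel when the wrong channels are all below ``T`` and either
    the correct channel is above ``T`` (moving region) or everything
    including the complex drive is below ``T`` (background); otherwise the
    pixel contributes ``(1 - v_ig_th) v_cx_th + v_ig_th (1 - v_cx_th) +
    sum_other v_ig_phi``.
    """
    ig_th = v_ig[..., theta]
    cx_th = v_cx[..., theta]
    wrong = np.delete(v_ig, theta, axis=-1)
    wrong_ok = (wrong < T).all(axis=-1)
    b1 = wrong_ok & (ig_th > T)
    b2 = wrong_ok & (ig_th <= T) & (cx_th < T)
    penalty = (1.0 - ig_th) * cx_th + ig_th * (1.0 - cx_th) + wrong.sum(axis=-1)
    penalty = np.where(b1 | b2, 0.0, penalty)
    return float(penalty.sum())


# ---------------------------------------------------------------------------
# GA machinery
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    population_size: int = 100
    frac_reproduction: float = 0.10
    frac_crossover: float = 0.50
    frac_mutation: float = 0.40
    error_threshold: float = 0.15     # T in the error branches
    active_threshold_cx: float = 0.01  # complex cell considered active
    inactive_threshold_ig: float = 0.15
    generation_cap: int = 200
    init_spread: float = 0.3          # uniform +-fraction around the seed
    mutation_scale: float = 0.2       # uniform perturbation, fraction of value
    crossover_mode: str = "single_point"   # or "uniform"
    seed: int = 0

    def __post_init__(self):
        total = self.frac_reproduction + self.frac_crossover + self.frac_mutation
        if abs(total - 1.0) > 1e-9:
            raise ValueError("reproduction/crossover/mutation fractions must sum to 1")


@dataclass
class GAIndividual:
    params: np.ndarray                 # vector over GA_PARAM_NAMES
    fitness: float = -np.inf
    error: float = np.inf
    diagnostics: dict = field(default_factory=dict)

    def as_model_params(self, base: ModelParams) -> ModelParams:
        return base.with_ga_vector(self.params)


def _diagnostics(res, stim: StimulusSequence, theta: int,
                 cfg: GAConfig) -> dict:
    """The three behavioural evaluations steering heuristic mutation."""
    f = stim.n_frames - 1
    ig = res.v_ig[f]
    sg = res.v_sg[f]
    mask = stim.mask(f)
    em = evaluation_mask(stim, f)
    w = winner_map(ig, em, active_floor=cfg.inactive_threshold_ig)
    aperture_unsolved = overall_error(w, theta) == 1
    wrong = np.delete(ig, theta, axis=-1)
    wrong_active = bool((wrong[mask] > cfg.inactive_threshold_ig).any())
    bg_leak = bool((ig[~em] > cfg.inactive_threshold_ig).any())
    # coherent region: bar pixels more than 3 px (Chebyshev) from either end
    ys, xs = np.nonzero(mask)
    coherent = np.zeros_like(mask)
    if len(ys) > 6:
        ends = np.array([[ys[0], xs[0]], [ys[-1], xs[-1]]])
        for y, x in zip(ys, xs):
            if (np.abs(ends - [y, x]).max(axis=1) > 3).all():
                coherent[y, x] = True
    sg_coherent = bool((sg[coherent] > 10 * res.params.rho_sg).any())
    return dict(aperture_unsolved=aperture_unsolved, wrong_active=wrong_active,
                bg_leak=bg_leak, sg_coherent=sg_coherent)


def evaluate_individual(ind: GAIndividual, base: ModelParams,
                        stimuli, cfg: GAConfig) -> GAIndividual:
    """Simulate every training stimulus and fill fitness/error/diagnostics."""
    p = ind.as_model_params(base)
    F = 0.0
    E = 0.0
    diags = dict(aperture_unsolved=False, wrong_active=False,
                 bg_leak=False, sg_coherent=False)
    for stim in stimuli:
        theta = stim.bar.direction_idx
        try:
            res = simulate(stim, p)
        except FloatingPointError:
            ind.fitness, ind.error = -np.inf, np.inf
            ind.diagnostics = dict(diags, aperture_unsolved=True)
            return ind
        f = stim.n_frames - 1
        F += fitness_F1(res.v_ig[f], res.v_cx[f], theta)
        F += fitness_F2(res.v_sg[f], res.v_cx[f], res.v_ig[f], theta)
        E += ga_error(res.v_ig[f], res.v_cx[f], theta, cfg.error_threshold)
        d = _diagnostics(res, stim, theta, cfg)
        for k in diags:
            diags[k] = diags[k] or d[k]
    ind.fitness = F
    ind.error = E
    ind.diagnostics = diags
    return ind


#: sign of the heuristic mutation per parameter, per diagnostic flag
_HEURISTIC_SIGNS = {
    "aperture_unsolved": {"G_ig_es": +1, "G_ig_cx": -1},
    "wrong_active": {"G_ig_ig1": +1},
    "bg_leak": {"G_ig_ig2": -1, "G_ig_sg": +1},
    "sg_coherent": {"G_sg_sg": +1},
}


def mutate_heuristic(ind: GAIndividual, cfg: GAConfig,
                     rng: np.random.Generator) -> GAIndividual:
    """Uniform perturbation whose sign follows the behavioural heuristics.

    Parameters named by an active diagnostic get a perturbation of the
    prescribed sign; all other parameters get an unbiased uniform
    perturbation.  Gains stay non-negative.
    """
    signs = {}
    for flag, rules in _HEURISTIC_SIGNS.items():
        if ind.diagnostics.get(flag):
            signs.update(rules)
    new = ind.params.copy()
    for i, name in enumerate(GA_PARAM_NAMES):
        step = cfg.mutation_scale * max(abs(new[i]), 1e-3)
        s = signs.get(name)
        if s is None:
            delta = rng.uniform(-step, step)
        else:
            delta = s * rng.uniform(0.0, step)
        new[i] = max(new[i] + delta, 0.0)
    return GAIndividual(params=new)


def crossover(a: GAIndividual, b: GAIndividual, cfg: GAConfig,
              rng: np.random.Generator) -> GAIndividual:
    if cfg.crossover_mode == "uniform":
        pick = rng.integers(0, 2, size=len(a.params)).astype(bool)
        child = np.where(pick, a.params, b.params)
    else:  # single-point swap over the ordered parameter vector
        cut = int(rng.integers(1, len(a.params)))
        child = np.concatenate([a.params[:cut], b.params[cut:]])
    return GAIndividual(params=child.copy())


def default_training_stimuli(grid: GridSpec | None = None,
                             n_frames: int = 8) -> list[StimulusSequence]:
    """The training condition: short 45-deg bar drifting right, desk scale."""
    grid = grid or GridSpec(32, 32)
    bar = BarSpec(orientation=45, direction="right", length=9, bar_width=1,
                  n_frames=n_frames)
    return [make_bar_stimulus(bar, grid)]


@dataclass
class GAResult:
    solutions: list          # individuals with error == 0
    best: GAIndividual       # best-fitness individual seen
    converged: bool
    log: pd.DataFrame        # generation, best_fitness, best_error, n_solutions


def evolve(cfg: GAConfig, base: ModelParams | None = None,
           stimuli=None, *, seed_vector=None,
           progress: bool = False) -> GAResult:
    """Run the GA until a zero-error solution appears or the cap is reached.

    The initial population is drawn uniformly within ``init_spread`` of the
    seed vector (the reference gains by default).  Two runs with the same
    config are identical.
    """
    base = base or ModelParams()
    stimuli = stimuli if stimuli is not None else default_training_stimuli()
    rng = np.random.default_rng(cfg.seed)
    seed_vec = np.asarray(seed_vector if seed_vector is not None
                          else base.ga_vector(), dtype=float)

    pop = []
    for i in range(cfg.population_size):
        if i == 0:
            vec = seed_vec.copy()          # keep the seed itself
        else:
            jitter = rng.uniform(1.0 - cfg.init_spread, 1.0 + cfg.init_spread,
                                 size=seed_vec.shape)
            vec = seed_vec * jitter
        pop.append(GAIndividual(params=vec))

    n_rep = max(1, int(round(cfg.frac_reproduction * cfg.population_size)))
    n_cross = int(round(cfg.frac_crossover * cfg.population_size))
    n_mut = cfg.population_size - n_rep - n_cross

    solutions: list[GAIndividual] = []
    rows = []
    best_ever: GAIndividual | None = None
    for gen in range(cfg.generation_cap):
        for ind in pop:
            if not np.isfinite(ind.fitness):
                evaluate_individual(ind, base, stimuli, cfg)
        pop.sort(key=lambda ind: -ind.fitness)
        if best_ever is None or pop[0].fitness > best_ever.fitness:
            best_ever = pop[0]
        sols = [ind for ind in pop if ind.error == 0.0]
        rows.append(dict(generation=gen, best_fitness=pop[0].fitness,
                         best_error=min(i.error for i in pop),
                         n_solutions=len(sols)))
        if progress:
            print(f"gen {gen:3d}  best F={pop[0].fitness:9.2f}  "
                  f"best E={rows[-1]['best_error']:9.3f}  sols={len(sols)}")
        if sols:
            solutions = sols
            break
        elite = pop[:n_rep]
        parents = pop[:max(2, cfg.population_size // 2)]
        children = []
        for _ in range(n_cross):
            i, j = rng.choice(len(parents), size=2, replace=False)
            children.append(crossover(parents[i], parents[j], cfg, rng))
        mutants = []
        for _ in range(n_mut):
            k = int(rng.integers(0, len(parents)))
            mutants.append(mutate_heuristic(parents[k], cfg, rng))
        pop = [GAIndividual(params=e.params.copy(), fitness=e.fitness,
                            error=e.error, diagnostics=dict(e.diagnostics))
               for e in elite] + children + mutants

    return GAResult(solutions=solutions, best=best_ever,
                    converged=bool(solutions), log=pd.DataFrame(rows))
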