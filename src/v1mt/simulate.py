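"""Frame-loop orchestration: stimulus -> V1 complex -> end-stopped -> MT.

For each stimulus frame, the motion-energy front end is evaluated on the
frame history, the resulting complex-cell field is held fixed, and the
recurrent end-stopped/MT dynamics are advanced for ``mt_frame_duration``
(12 ms by default, dt = 0.1 ms -> 120 Euler steps per frame).  Model time is
the accumulated dynamics time; the stimulus frame clock (20 ms per frame) is
kept separate.

Optional activity-dependent Gaussian noise can be injected at the outputs of
any of the four populations (see :class:`v1mt.dynamics.NoiseModel`).  Within
a frame the dynamics frequently reach a fixed point well before the end of
the 12 ms window; steps are skipped once the state stops changing (the
remaining trace is constant by construction), which does not alter results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import Network, NoiseModel
from .motion_energy import FilterBank, complex_response
from .params import ModelParams
from .stimulus import StimulusSequence

__all__ = ["SimResult", "Probe", "simulate"]

# steady-state detection: stop stepping within a frame after the state has
# changed by less than EXIT_TOL for EXIT_RUN consecutive steps
EXIT_TOL = 1e-10
EXIT_RUN = 10


@dataclass(frozen=True)
class Probe:
    """A single recorded cell: population, (y, x) location, direction index."""
    population: str   # "es" | "ig" | "sg"
    y: int
    x: int
    direction: int


@dataclass
class SimResult:
    """Per-frame final activity of all four populations plus optional
    per-step recordings.  Field arrays have shape (T, H, W, 8)."""
    stim: StimulusSequence
    params: ModelParams
    v_cx: np.ndarray
    v_es: np.ndarray
    v_ig: np.ndarray
    v_sg: np.ndarray
    alpha: float = 0.0
    seed: int | None = None
    # per-step recording of v_ig for one requested frame
    step_frame: int | None = None
    step_times: np.ndarray | None = None        # model time (ms) per step
    step_v_ig: np.ndarray | None = None         # (n_steps, H, W, 8)
    # probe traces: dict probe -> array over all steps of all frames
    probe_times: np.ndarray | None = None
    probes: dict = field(default_factory=dict)

    @property
    def final(self) -> dict[str, np.ndarray]:
        return {"cx": self.v_cx[-1], "es": self.v_es[-1],
                "ig": self.v_ig[-1], "sg": self.v_sg[-1]}

    def probe_table(self):
        """Probe traces as a tidy DataFrame (cell, t, activity)."""
        import pandas as pd

        rows = []
        for pr, vals in self.probes.items():
            cell = f"{pr.population}[{pr.y},{pr.x},d{pr.direction}]"
            for t, v in zip(self.probe_times, vals):
                rows.append(dict(cell=cell, t=t, activity=float(v)))
        return pd.DataFrame(rows)

    def summary(self):
        """Per-population, per-direction max and mean activity on the final
        frame, as a tidy DataFrame (one row per population x direction)."""
        import pandas as pd

        from .stimulus import DIRECTION_NAMES

        rows = []
        for pop, field in self.final.items():
            for d in range(field.shape[-1]):
                rows.append(dict(population=pop,
                                 direction=DIRECTION_NAMES[d],
                                 max=float(field[..., d].max()),
                                 mean=float(field[..., d].mean())))
        return pd.DataFrame(rows)


def simulate(
    stim: StimulusSequence,
    p: ModelParams,
    *,
    alpha: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    noise_populations=NoiseModel.POPULATIONS,
    noise_granularity: str = "frame",
    record_steps_frame: int | None = None,
    probe_cells: tuple[Probe, ...] = (),
    bank: FilterBank | None = None,
    network: Network | None = None,
) -> SimResult:
    """Run the full model on a stimulus sequence.

    Parameters of note
    ------------------
    alpha
        Noise scale of the activity-dependent Gaussian output noise
        (0 = deterministic).
    seed / rng
        Seed every source of randomness; the same seed yields bit-identical
        traces.
    record_steps_frame
        Frame index (negative allowed) whose within-frame integration
        dynamics are recorded every Euler step (for propagation timing).
    probe_cells
        Cells whose activity is recorded every step of every frame.
    """
    T, H, W = stim.frames.shape
    n_steps = int(round(p.mt_frame_duration / p.dt))
    if record_steps_frame is not None and record_steps_frame < 0:
        record_steps_frame += T

    v_cx_all = complex_response(stim.frames, p, bank)
    net = network if network is not None else Network(p, H, W)
    noise = None
    if alpha > 0:
        gen = rng if rng is not None else np.random.default_rng(seed)
        noise = NoiseModel(alpha, gen, populations=noise_populations,
                           granularity=noise_granularity)

    shape = (H, W, p.n_directions)
    out = {k: np.zeros((T,) + shape) for k in ("es", "ig", "sg")}
    step_times = step_v_ig = None
    probe_vals = {pr: [] for pr in probe_cells}
    probe_t = []

    for f in range(T):
        net.set_input(v_cx_all[f], noise)
        recording = record_steps_frame == f
        if recording:
            step_times = np.empty(n_steps)
            step_v_ig = np.empty((n_steps,) + shape)
        quiet = 0
        for k in range(n_steps):
            if quiet < EXIT_RUN:
                delta = net.step(noise)
                quiet = quiet + 1 if delta < EXIT_TOL else 0
            else:
                net.freeze_step()     # converged: state frozen for the rest
            if recording:
                step_times[k] = net.state.t
                step_v_ig[k] = net.state.v_ig
            if probe_cells:
                probe_t.append(net.state.t)
                for pr in probe_cells:
                    v = getattr(net.state, f"v_{pr.population}")
                    probe_vals[pr].append(v[pr.y, pr.x, pr.direction])
        out["es"][f] = net.state.v_es
        out["ig"][f] = net.state.v_ig
        out["sg"][f] = net.state.v_sg

    return SimResult(
        stim=stim, params=p, v_cx=v_cx_all,
        v_es=out["es"], v_ig=out["ig"], v_sg=out["sg"],
        alpha=alpha, seed=seed,
        step_frame=record_steps_frame, step_times=step_times,
        step_v_ig=step_v_ig,
        probe_times=np.asarray(probe_t) if probe_cells else None,
        probes={pr: np.asarray(v) for pr, v in probe_vals.items()},
    )
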