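"""Recurrent dynamics of the end-stopped and MT populations.

All four populations are rate fields in ``[0, 1]`` advanced by forward Euler
with step ``dt`` (0.1 ms).  Two clocks exist: the stimulus frame clock
(``frame_interval``, 20 ms) and the dynamics clock; for every stimulus frame
the V1 complex input is held fixed and the end-stopped + MT dynamics are
advanced for ``mt_frame_duration`` (12 ms).

The inter-directional and long-range inhibitory terms act with delays
(``T_es``, ``T_ig``): activity is allowed to develop before the competition
starts.  :class:`DelayBuffer` keeps the bounded history needed for the
``t - T`` lookups and returns zeros before any history exists.

End-stopped cells follow shunting dynamics,

    dv/dt = (1 - v) G1 v_cx  -  v (tau_es + G2 Gamma + G3 Omega(t-T) + G4 Lambda(t-T)),

which keeps ``v`` in [0, 1] for bounded inputs.  The MT updates are additive
with a piece-wise linear saturation; by default the saturation is applied to
the *state*, ``v <- h(v + dt * rhs)``, so that net-negative drive can lower
activity (applying h to the derivative itself would make activity
non-decreasing).  The literal derivative-clipping form is available via
``clip_mode='derivative'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import (annulus_kernel, chi_surround, eta_excitation, gamma_mu,
                     gamma_surround, interdir_inhibition, lambda_longrange_es,
                     lateral_excitation, longrange_inhibition, omega_interdir,
                     saturation_h)
from .params import ModelParams

__all__ = ["DelayBuffer", "Network", "NoiseModel"]


class DelayBuffer:
    """Fixed-delay ring buffer of activity fields.

    ``push_read(x)`` stores the field computed at the current step and returns
    the field stored ``delay_steps`` earlier (zeros while no such history
    exists yet).
    """

    def __init__(self, delay_steps: int, shape: tuple):
        if delay_steps < 1:
            raise ValueError("delay must be at least one step")
        self.delay = delay_steps
        self.ring = np.zeros((delay_steps,) + shape)
        self.idx = 0
        self.count = 0

    def push_read(self, x: np.ndarray) -> np.ndarray:
        if self.count >= self.delay:
            out = self.ring[self.idx].copy()
        else:
            out = np.zeros_like(x)
        self.ring[self.idx] = x
        self.idx = (self.idx + 1) % self.delay
        self.count += 1
        return out


class NoiseModel:
    """Activity-dependent Gaussian output noise, ``v + alpha * N(0, v)``.

    The variance of the perturbation equals the activity itself (``alpha = 1``
    mimicking Poisson spiking variability); noisy outputs are clipped to
    [0, 1] since activities are rates.  Noise is what downstream neurons
    *read*; the sender's own state is not overwritten.

    ``granularity`` controls how often fresh noise is drawn: ``"frame"`` draws
    one realisation per population per stimulus frame (the noise is frozen
    over the 12 ms of within-frame dynamics), ``"step"`` redraws each Euler
    step.
    """

    POPULATIONS = ("cx", "es", "ig", "sg")

    def __init__(self, alpha: float, rng: np.random.Generator | None = None,
                 populations=POPULATIONS, granularity: str = "frame"):
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        if granularity not in ("frame", "step"):
            raise ValueError("granularity must be 'frame' or 'step'")
        self.alpha = float(alpha)
        self.rng = rng if rng is not None else np.random.default_rng()
        self.populations = frozenset(populations)
        self.granularity = granularity
        self._z: dict[str, np.ndarray] = {}

    @property
    def active(self) -> bool:
        return self.alpha > 0.0

    def new_frame(self, shape: tuple) -> None:
        if not self.active:
            return
        for pop in self.POPULATIONS:
            if pop in self.populations:
                self._z[pop] = self.rng.standard_normal(shape)

    def read(self, pop: str, v: np.ndarray) -> np.ndarray:
        if not self.active or pop not in self.populations:
            return v
        if self.granularity == "step":
            z = self.rng.standard_normal(v.shape)
        else:
            z = self._z[pop]
        return np.clip(v + self.alpha * np.sqrt(v) * z, 0.0, 1.0)


def inject_noise(v: np.ndarray, alpha: float,
                 rng: np.random.Generator) -> np.ndarray:
    """One-shot activity-dependent noise injection (clipped to [0, 1])."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0:
        return v.copy()
    z = rng.standard_normal(v.shape)
    return np.clip(v + alpha * np.sqrt(np.maximum(v, 0.0)) * z, 0.0, 1.0)


@dataclass
class NetworkState:
    v_es: np.ndarray
    v_ig: np.ndarray
    v_sg: np.ndarray
    t: float = 0.0


class Network:
    """The coupled end-stopped + MT integration/segmentation network on a
    fixed grid.  Owns the state fields, the delay buffers and the precomputed
    connectivity kernels; :meth:`step` advances everything by one ``dt``."""

    def __init__(self, p: ModelParams, height: int, width: int):
        self.p = p
        shape = (height, width, p.n_directions)
        self.state = NetworkState(
            v_es=np.zeros(shape), v_ig=np.zeros(shape), v_sg=np.zeros(shape))
        n_es = max(1, round(p.T_es / p.dt))
        n_ig = max(1, round(p.T_ig / p.dt))
        self.buf_omega = DelayBuffer(n_es, shape)
        self.buf_lambda_es = DelayBuffer(n_es, shape)
        self.buf_gamma = DelayBuffer(n_ig, shape)
        self.buf_zeta = DelayBuffer(n_ig, shape)
        self.mu = gamma_mu(p)
        self.chi_kernel = annulus_kernel(
            p.surround_center_radius, p.surround_outer_radius, p.surround_sigma)
        if p.annulus_normalize:
            self.chi_kernel = self.chi_kernel / self.chi_kernel.sum()
        if p.sg_input_pooling:
            from .fields import gaussian_window
            self.sg_pool_kernel = gaussian_window(
                p.surround_center_radius, p.sg_center_sigma, "sum")
        else:
            self.sg_pool_kernel = None
        self.sg_drive = p.sg_baseline * p.tau_sg   # steady state = sg_baseline
        # per-frame input and its derived (input-only) fields
        self.v_cx = np.zeros(shape)
        self._gamma_es = np.zeros(shape)
        self._omega = np.zeros(shape)

    def set_input(self, v_cx: np.ndarray, noise: NoiseModel | None = None) -> None:
        """Install the complex-cell field for the current stimulus frame."""
        if v_cx.shape != self.state.v_ig.shape:
            raise ValueError(f"input shape {v_cx.shape} != state shape "
                             f"{self.state.v_ig.shape}")
        if not np.isfinite(v_cx).all():
            raise FloatingPointError("non-finite complex-cell input")
        self.v_cx = v_cx
        if noise is not None:
            noise.new_frame(v_cx.shape)
        self._refresh_input_terms(noise)

    def _refresh_input_terms(self, noise: NoiseModel | None) -> None:
        cx = noise.read("cx", self.v_cx) if noise is not None else self.v_cx
        self._cx_read = cx
        self._gamma_es = gamma_surround(cx, self.p, self.mu)
        self._omega = omega_interdir(cx, self.p.omega_mode)
        if self.sg_pool_kernel is not None:
            from scipy.signal import fftconvolve
            self._cx_sg = fftconvolve(cx, self.sg_pool_kernel[:, :, None],
                                      mode="same", axes=(0, 1))
        else:
            self._cx_sg = cx

    def step(self, noise: NoiseModel | None = None) -> float:
        """One Euler step of the coupled dynamics.  Returns the largest
        absolute state change (used for steady-state detection)."""
        p = self.p
        s = self.state
        if noise is not None and noise.active and noise.granularity == "step":
            self._refresh_input_terms(noise)
        cx = self._cx_read
        es = noise.read("es", s.v_es) if noise is not None else s.v_es
        ig = noise.read("ig", s.v_ig) if noise is not None else s.v_ig
        sg = noise.read("sg", s.v_sg) if noise is not None else s.v_sg

        # --- end-stopped cells (shunting form, delayed Omega/Lambda) -------
        lambda_now = lambda_longrange_es(es, p)
        if p.delay_mode == "onset":
            on = 1.0 if s.t >= p.T_es else 0.0
            omega_d, lambda_d = on * self._omega, on * lambda_now
            self.buf_omega.push_read(self._omega)
            self.buf_lambda_es.push_read(lambda_now)
        else:
            omega_d = self.buf_omega.push_read(self._omega)
            lambda_d = self.buf_lambda_es.push_read(lambda_now)
        rhs_es = ((1.0 - s.v_es) * (p.G_es_cx1 * cx)
                  - s.v_es * (p.tau_es + p.G_es_cx2 * self._gamma_es
                              + p.G_es_es1 * omega_d + p.G_es_es2 * lambda_d))
        new_es = np.clip(s.v_es + p.dt * rhs_es, 0.0, 1.0)

        # --- MT integration (delayed gamma/zeta) ---------------------------
        lam = lateral_excitation(ig, sg, p)
        gamma_now = interdir_inhibition(ig)
        zeta_now = longrange_inhibition(ig, p)
        if p.delay_mode == "onset":
            on = 1.0 if s.t >= p.T_ig else 0.0
            gamma_d, zeta_d = on * gamma_now, on * zeta_now
            self.buf_gamma.push_read(gamma_now)
            self.buf_zeta.push_read(zeta_now)
        else:
            gamma_d = self.buf_gamma.push_read(gamma_now)
            zeta_d = self.buf_zeta.push_read(zeta_now)
        self._pushed = (self._omega, lambda_now, gamma_now, zeta_now)
        rhs_ig = (p.G_ig_cx * cx + p.G_ig_es * es + p.G_ig_ig2 * lam
                  - p.G_ig_ig1 * gamma_d - p.G_ig_ig3 * zeta_d
                  - p.G_ig_sg * sg - p.tau_ig * s.v_ig)

        # --- MT segmentation ----------------------------------------------
        eta = eta_excitation(ig)
        chi_e, chi_i = chi_surround(sg, p, self.chi_kernel)
        rhs_sg = (p.G_sg_cx * self._cx_sg - p.G_sg_es * es
                  + p.G_sg_ig * eta[:, :, None]
                  + p.G_sg_sg * chi_e - p.G_sg_sg * chi_i
                  - p.tau_sg * s.v_sg + self.sg_drive)

        if p.clip_mode == "state":
            new_ig = saturation_h(s.v_ig + p.dt * rhs_ig)
            new_sg = saturation_h(s.v_sg + p.dt * rhs_sg)
        else:  # literal derivative clipping
            new_ig = s.v_ig + p.dt * saturation_h(rhs_ig)
            new_sg = s.v_sg + p.dt * saturation_h(rhs_sg)

        delta = max(np.abs(new_es - s.v_es).max(),
                    np.abs(new_ig - s.v_ig).max(),
                    np.abs(new_sg - s.v_sg).max())
        s.v_es, s.v_ig, s.v_sg = new_es, new_ig, new_sg
        s.t += p.dt
        if not np.isfinite(delta):
            raise FloatingPointError(f"non-finite network state at t={s.t:.1f} ms")
        return float(delta)

    def freeze_step(self) -> None:
        """Advance time at a fixed point: keep the state, but re-push the
        (constant) delayed quantities so ``t - T`` lookups stay aligned."""
        omega, lambda_now, gamma_now, zeta_now = self._pushed
        self.buf_omega.push_read(omega)
        self.buf_lambda_es.push_read(lambda_now)
        self.buf_gamma.push_read(gamma_now)
        self.buf_zeta.push_read(zeta_now)
        self.state.t += self.p.dt
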