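"""V1 complex cells: oriented spatiotemporal (motion) energy.

The front end is the classic opponent-energy construction: quadrature pairs of
oriented Gabor filters (sine and cosine phase) are combined with two temporal
multi-stage low-pass kernels of different latency, the four spatiotemporal
products are squared and summed into an energy for the preferred direction
(``r``) and for the opposite direction (``l``), and each opponent pair is
normalised to give direction-selective complex-cell activity in ``[0, 1]``.

Four filter orientations (0, 45, 90, 135 deg) yield eight direction channels:
channel ``o`` (= orientation index) is the ``r`` branch, channel ``o + 4`` the
``l`` branch.

The temporal kernels are DC-balanced (their continuous-time integral is zero),
so a static stimulus produces (near-)zero energy and hence silent cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .params import ModelParams

__all__ = ["temporal_kernel", "FilterBank", "OpponentEnergy",
           "opponent_energy", "normalize_complex", "complex_response"]

ORIENTATIONS_DEG = (0.0, 45.0, 90.0, 135.0)


def temporal_kernel(n: int, tau_g: float, t):
    """Biphasic multi-stage low-pass temporal filter.

    ``g_n(t) = (t/tau)^n exp(-t/tau) [1/n! - (t/tau)^2/(n+2)!]`` for ``t >= 0``.
    The kernel rises, peaks, crosses zero at ``t/tau = sqrt((n+2)!/n!)`` and
    decays through a negative lobe back to zero.  ``n`` selects the latency
    (the model uses n = 6 and n = 9).

    Raises for negative ``t`` (the kernel is causal).
    """
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("temporal kernel is causal: t must be >= 0")
    s = t / tau_g
    return s**n * np.exp(-s) * (1.0 / math.factorial(n)
                                - s**2 / math.factorial(n + 2))


def _gabor_pair(angle_deg: float, p: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Odd (sine) and even (cosine) phase Gabor kernels for one orientation.

    The carrier varies along the orientation axis; ``y`` increases downward so
    the upward image direction carries positive angle.
    """
    R = p.spatial_radius
    f = p.f_cyc_per_deg / p.pixels_per_degree          # cycles / pixel
    sx = p.sigma_x * p.pixels_per_degree               # pixels
    sy = p.sigma_y * p.pixels_per_degree
    ys, xs = np.mgrid[-R:R + 1, -R:R + 1].astype(np.float64)
    y_up = -ys
    a = np.deg2rad(angle_deg)
    x_t = xs * np.cos(a) + y_up * np.sin(a)
    y_t = -xs * np.sin(a) + y_up * np.cos(a)
    env = np.exp(-(x_t**2 / sx**2 + y_t**2 / sy**2))
    odd = np.sin(2 * np.pi * f * x_t) * env
    even = np.cos(2 * np.pi * f * x_t) * env
    # the odd kernel is zero-mean by symmetry; remove the small DC component of
    # the even kernel so that uniform stimuli produce no energy
    even = even - even.mean()
    return odd, even


@dataclass
class FilterBank:
    """Spatial quadrature pairs for 4 orientations + the two temporal kernels."""
    odd: list    # sine-phase kernel per orientation, (2R+1, 2R+1)
    even: list   # cosine-phase kernel per orientation
    g6: np.ndarray  # temporal kernels sampled on the frame clock
    g9: np.ndarray

    @classmethod
    def from_params(cls, p: ModelParams) -> "FilterBank":
        odd, even = [], []
        for ang in ORIENTATIONS_DEG:
            o, e = _gabor_pair(ang, p)
            odd.append(o)
            even.append(e)
        ts = np.arange(p.temporal_len, dtype=np.float64)
        g6 = temporal_kernel(6, p.tau_g_frames, ts)
        g9 = temporal_kernel(9, p.tau_g_frames, ts)
        return cls(odd=odd, even=even, g6=g6, g9=g9)


@dataclass
class OpponentEnergy:
    """Opponent motion energies per orientation: ``r`` toward the preferred
    direction (channel index = orientation index), ``l`` toward the opposite.
    Both are sums of squares, hence non-negative.  Shape (T, H, W, 4)."""
    r: np.ndarray
    l: np.ndarray


def _spatial_conv(frames: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True 2-D convolution of every frame with ``kernel`` (zero padding)."""
    return fftconvolve(frames, kernel[None, :, :], mode="same", axes=(1, 2))


def _temporal_conv(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Causal temporal convolution along axis 0: out[t] = sum_k g[k] x[t-k]."""
    T = x.shape[0]
    out = np.zeros_like(x)
    for k in range(min(len(g), T)):
        if g[k] == 0.0:
            continue
        out[k:] += g[k] * x[:T - k]
    return out


def opponent_energy(frames: np.ndarray, bank: FilterBank) -> OpponentEnergy:
    """Compute opponent motion energy for a (T, H, W) luminance sequence.

    Fewer than 2 frames cannot carry motion; a warning-level underestimate is
    produced for sequences shorter than the temporal support.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3:
        raise ValueError("frames must have shape (T, H, W)")
    if frames.shape[0] < 2:
        raise ValueError("motion energy needs at least 2 frames")
    T, H, W = frames.shape
    r = np.empty((T, H, W, 4))
    l = np.empty((T, H, W, 4))
    for o in range(4):
        S = _spatial_conv(frames, bank.odd[o])
        C = _spatial_conv(frames, bank.even[o])
        S6 = _temporal_conv(S, bank.g6)
        S9 = _temporal_conv(S, bank.g9)
        C6 = _temporal_conv(C, bank.g6)
        C9 = _temporal_conv(C, bank.g9)
        # quadrature combinations; which of the two opponent branches prefers
        # the +axis direction was fixed empirically on a drifting grating
        r[..., o] = (-S6 + C9) ** 2 + (S9 + C6) ** 2
        l[..., o] = (S6 + C9) ** 2 + (-S9 + C6) ** 2
    return OpponentEnergy(r=r, l=l)


def normalize_complex(e: OpponentEnergy, p: ModelParams) -> np.ndarray:
    """Opponent normalisation into 8 direction channels in ``[0, 1]``.

    ``v[th] = r / (sqrt(pool) + eps)`` and ``v[th+pi] = l / (...)``, where the
    pool is either the channel's own opponent pair (``norm_pool="pair"``) or
    the energy summed over all four orientations at that pixel (``"all"``,
    the default): divisive normalisation across the orientation population,
    which leaves the true-direction channel visible at terminators while the
    dominant perpendicular energy crushes it along clean edges.
    Locations whose total opponent energy falls below ``energy_floor`` times
    the field's maximum are silenced: normalisation is a ratio, and amplifying
    numerically negligible energies far from any stimulus into order-one
    "activity" would put motion where there is none.
    """
    r, l = e.r, e.l
    if p.opponent_subtraction:
        d = r - l
        a = np.maximum(d, 0.0)    # signal toward the preferred direction
        b = np.maximum(-d, 0.0)   # toward the opposite direction
    else:
        a, b = r, l
    if p.norm_pool == "all":
        # mean over the orientation population (per-orientation RMS): strongly
        # oriented responses saturate at 1 while the weaker unambiguous
        # terminator signal keeps a workable amplitude
        pool = (a**2 + b**2).mean(axis=-1, keepdims=True)
        den = np.broadcast_to(
            pool if p.norm_squared_denominator else np.sqrt(pool),
            r.shape).copy() + p.energy_epsilon
    elif p.norm_squared_denominator:
        den = a**2 + b**2 + p.energy_epsilon
    else:
        den = np.sqrt(a**2 + b**2) + p.energy_epsilon
    v = np.empty(r.shape[:-1] + (8,))
    v[..., :4] = a / den
    v[..., 4:] = b / den
    total = a + b
    floor = p.energy_floor * max(total.max(), 1e-300)
    gate = total >= floor
    v[..., :4] *= gate
    v[..., 4:] *= gate
    return np.clip(v, 0.0, 1.0)


def complex_response(frames: np.ndarray, p: ModelParams,
                     bank: FilterBank | None = None) -> np.ndarray:
    """Convenience: frames -> complex-cell activity field (T, H, W, 8)."""
    bank = bank or FilterBank.from_params(p)
    return normalize_complex(opponent_energy(frames, bank), p)
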