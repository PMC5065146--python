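"""Neighbourhood operators of the V1/MT network.

All activity fields have shape ``(H, W, 8)`` — rows (y), columns (x), and the
8 direction channels.  Out-of-grid neighbours contribute zero everywhere
(zero padding), matching a stimulus surrounded by blank background.

Operators
---------
- ``gamma_surround``      Gaussian same-direction surround inhibition onto
                          end-stopped cells, gated by local complex activity.
- ``omega_interdir``      inter-directional inhibition (sum over other
                          channels at the same pixel), complex sources.
- ``lambda_longrange_es`` long-range other-direction inhibition between
                          end-stopped cells (+-3 window).
- ``lateral_excitation``  MT integration lateral excitation: +-6 window,
                          only from neighbours exceeding the receiving cell
                          by ``rho_igig``, shunted off where the local
                          segmentation activity exceeds ``rho_sg``.
- ``interdir_inhibition`` same-pixel other-channel sum, integration sources.
- ``longrange_inhibition`` other-direction sum over the Chebyshev-distance-3
                          ring of integration cells.
- ``eta_excitation``      per-pixel total integration activity (all 8
                          channels), driving segmentation cells.
- ``chi_surround``        centre-surround antagonism between segmentation
                          cells: Gaussian-weighted annulus sums of same-
                          (inhibitory) and other-direction (excitatory)
                          suprathreshold activity, gated on the centre cell
                          being suprathreshold.

Each operator has a brute-force loop oracle in the test-suite; the
implementations here use separable box sums, FFT convolution and a numba
kernel, and must agree with the oracles to floating tolerance.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.ndimage import uniform_filter
from scipy.signal import fftconvolve

from .params import ModelParams

__all__ = [
    "box_sum", "gaussian_window", "annulus_kernel",
    "gamma_surround", "omega_interdir", "lambda_longrange_es",
    "lateral_excitation", "interdir_inhibition", "longrange_inhibition",
    "eta_excitation", "chi_surround", "saturation_h",
]


def saturation_h(x):
    """Piece-wise linear saturation: 0 below 0, identity on [0, 1), 1 above."""
    return np.clip(x, 0.0, 1.0)


def box_sum(field: np.ndarray, radius: int) -> np.ndarray:
    """Sum over the (2r+1)^2 spatial window (including self), zero padded."""
    if radius == 0:
        return field.copy()
    k = 2 * radius + 1
    size = (k, k) + (1,) * (field.ndim - 2)
    return uniform_filter(field, size=size, mode="constant", cval=0.0) * (k * k)


def gaussian_window(radius: int, sigma: float, normalize: str = "sum") -> np.ndarray:
    """Discretised Gaussian weights on a (2r+1)^2 window."""
    ys, xs = np.mgrid[-radius:radius + 1, -radius:radius + 1].astype(np.float64)
    w = np.exp(-(xs**2 + ys**2) / (2.0 * sigma**2))
    if normalize == "sum":
        w /= w.sum()
    elif normalize != "peak":
        raise ValueError("normalize must be 'sum' or 'peak'")
    return w


def annulus_kernel(center_radius: int, outer_radius: int, sigma: float) -> np.ndarray:
    """Gaussian-weighted surround annulus: weights on Euclidean distances
    ``center_radius < d <= outer_radius``, zero inside the RF centre."""
    R = outer_radius
    ys, xs = np.mgrid[-R:R + 1, -R:R + 1].astype(np.float64)
    d = np.hypot(xs, ys)
    w = np.exp(-d**2 / (2.0 * sigma**2))
    w[(d <= center_radius) | (d > outer_radius)] = 0.0
    return w


def _conv2_channels(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Spatial convolution of each direction channel with a symmetric kernel."""
    return fftconvolve(field, kernel[:, :, None], mode="same", axes=(0, 1))


# ---------------------------------------------------------------------------
# end-stopped cell operators
# ---------------------------------------------------------------------------

def gamma_mu(p: ModelParams) -> np.ndarray:
    """The inhibitory connectivity matrix of the ES surround: Gaussian weights
    over the +-gamma_radius window, optionally zeroed inside an inner core
    (an annular end-zone surround)."""
    R = p.gamma_radius
    ys, xs = np.mgrid[-R:R + 1, -R:R + 1].astype(np.float64)
    mu = np.exp(-(xs**2 + ys**2) / (2.0 * p.mu_sigma**2))
    if p.mu_inner_radius > 0:
        core = np.maximum(np.abs(xs), np.abs(ys)) <= p.mu_inner_radius
        mu[core] = 0.0
    if p.gamma_exclude_self:
        mu[R, R] = 0.0
    if p.mu_normalize == "sum":
        mu = mu / mu.sum()
    return mu


def gamma_surround(v_cx: np.ndarray, p: ModelParams,
                   mu: np.ndarray | None = None) -> np.ndarray:
    """Same-direction Gaussian surround inhibition onto end-stopped cells.

    The weighted sum runs over the full +-``gamma_radius`` window; it is
    applied only where the activation condition on the +-``gamma_act_radius``
    window holds (by default: any neighbour other than the cell itself has
    complex activity above ``rho_cx``), and is zero elsewhere.
    """
    if mu is None:
        mu = gamma_mu(p)
    src = v_cx
    if p.rho_gamma_source > 0.0:
        src = np.where(v_cx > p.rho_gamma_source, v_cx, 0.0)
    weighted = _conv2_channels(src, mu)
    active = (v_cx > p.rho_cx).astype(np.float64)
    if p.gamma_condition == "any":
        neigh = box_sum(active, p.gamma_act_radius) - active
        cond = neigh > 0.0
    else:  # mean of the surrounding window above rho_cx
        k = 2 * p.gamma_act_radius + 1
        neigh = (box_sum(v_cx, p.gamma_act_radius) - v_cx) / (k * k - 1)
        cond = neigh > p.rho_cx
    return np.where(cond, weighted, 0.0)


def omega_interdir(v_cx: np.ndarray, mode: str = "other") -> np.ndarray:
    """Inter-directional inhibition onto end-stopped cells, complex sources.

    ``mode="other"``: sum of complex activity over the 7 other direction
    channels.  ``mode="own"``: the cell's own channel (the equation as
    printed) — a drive-proportional suppression that normalises strongly
    driven channels.
    """
    if mode == "own":
        return v_cx.copy()
    return v_cx.sum(axis=-1, keepdims=True) - v_cx


def lambda_longrange_es(v_es: np.ndarray, p: ModelParams) -> np.ndarray:
    """Long-range inhibition between end-stopped cells over the +-3 window.

    ``lambda_es_mode="other"``: other-direction activity summed over the
    window.  ``"same"``: the summand as printed carries the cell's own
    channel for each of the 7 other directions — 7x the same-direction
    surround, a second end-stopping stage on the ES field itself.
    Source cells below ``rho_es`` are treated as silent.
    """
    u = np.where(v_es > p.rho_es, v_es, 0.0)
    box_own = box_sum(u, p.lambda_es_radius)
    if p.lambda_es_mode == "same":
        out = box_own - u if p.lambda_es_exclude_self else box_own
        return 7.0 * out
    box_all = box_sum(u.sum(axis=-1, keepdims=True), p.lambda_es_radius)
    return box_all - box_own


# ---------------------------------------------------------------------------
# MT integration operators
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lambda_ig_kernel(v, gate, cand, R, rho):  # pragma: no cover - numba
    H, W, D = v.shape
    out = np.zeros((H, W, D))
    for y in range(H):
        for x in range(W):
            if cand[y, x] == 0:
                continue
            y0 = max(0, y - R)
            y1 = min(H, y + R + 1)
            x0 = max(0, x - R)
            x1 = min(W, x + R + 1)
            for d in range(D):
                if gate[y, x, d] == 0:
                    continue
                thr = v[y, x, d] + rho
                s = 0.0
                for yy in range(y0, y1):
                    for xx in range(x0, x1):
                        vn = v[yy, xx, d]
                        if vn > thr:
                            s += vn
                if s > 0.0:
                    out[y, x, d] = s
    return out


def lateral_excitation(v_ig: np.ndarray, v_sg: np.ndarray, p: ModelParams) -> np.ndarray:
    """Lateral excitation between same-direction integration cells.

    A cell sums activity of the +-``excitation_radius`` neighbours whose
    activity exceeds its own by more than ``rho_igig`` (so a uniform field
    excites nobody and activity flows only downhill from stronger cells, e.g.
    away from terminators).  Where the cell's own segmentation partner is
    above ``rho_sg`` — at motion discontinuities — the excitation is shunted
    to zero.
    """
    gate = (v_sg <= p.rho_sg).astype(np.uint8)
    any_src = (v_ig > p.rho_igig).any(axis=-1).astype(np.float64)
    cand = (box_sum(any_src, p.excitation_radius) > 0.0).astype(np.uint8)
    return _lambda_ig_kernel(np.ascontiguousarray(v_ig), gate, cand,
                             p.excitation_radius, p.rho_igig)


def interdir_inhibition(v_ig: np.ndarray) -> np.ndarray:
    """Winner-take-all term: other-channel integration activity, same pixel."""
    return v_ig.sum(axis=-1, keepdims=True) - v_ig


def longrange_inhibition(v_ig: np.ndarray, p: ModelParams) -> np.ndarray:
    """Other-direction integration activity on the square ring of cells exactly
    ``ring_radius`` (Chebyshev) positions away."""
    r = p.ring_radius
    total = v_ig.sum(axis=-1, keepdims=True)
    ring_all = box_sum(total, r) - box_sum(total, r - 1)
    ring_own = box_sum(v_ig, r) - box_sum(v_ig, r - 1)
    return ring_all - ring_own


# ---------------------------------------------------------------------------
# MT segmentation operators
# ---------------------------------------------------------------------------

def eta_excitation(v_ig: np.ndarray) -> np.ndarray:
    """Direction-independent drive onto segmentation cells: per-pixel total
    integration activity.  Shape (H, W)."""
    return v_ig.sum(axis=-1)


def chi_surround(v_sg: np.ndarray, p: ModelParams,
                 kernel: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Centre-surround antagonism between segmentation cells.

    Returns ``(chi_e, chi_i)``.  ``chi_i`` is the Gaussian-weighted sum of
    *same-direction* suprathreshold segmentation activity over the surround
    annulus, applied where the centre cell itself is suprathreshold — coherent
    same-direction motion in the surround suppresses the cell.  ``chi_e`` is
    the analogous sum over *other-direction* surround activity (motion
    contrast excites); it is zeroed when ``chi_e_enabled`` is off.
    """
    if kernel is None:
        kernel = annulus_kernel(p.surround_center_radius,
                                p.surround_outer_radius, p.surround_sigma)
        if p.annulus_normalize:
            kernel = kernel / kernel.sum()
    thr = max(p.rho_sg, p.rho_chi)
    u = np.where(v_sg > thr, v_sg, 0.0)
    ann_own = _conv2_channels(u, kernel)
    center_on = v_sg > thr
    chi_i = np.where(center_on, ann_own, 0.0)
    if p.chi_e_enabled:
        ann_all = fftconvolve(u.sum(axis=-1), kernel, mode="same")
        chi_e = np.where(center_on, ann_all[:, :, None] - ann_own, 0.0)
    else:
        chi_e = np.zeros_like(v_sg)
    return chi_e, chi_i
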