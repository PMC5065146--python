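import math

import numpy as np
import pytest
from scipy.optimize import brentq

from v1mt.motion_energy import (FilterBank, complex_response, normalize_complex,
                                opponent_energy, temporal_kernel, OpponentEnergy)
from v1mt.params import ModelParams
from v1mt.stimulus import BarSpec, GridSpec, make_bar_stimulus


class TestTemporalKernel:
    def test_zero_at_origin(self):
        assert temporal_kernel(6, 0.7, 0.0) == 0.0

    def test_causality_enforced(self):
        with pytest.raises(ValueError):
            temporal_kernel(6, 1.0, -0.1)

    @pytest.mark.parametrize("n", [6, 9])
    def test_zero_crossing_at_analytic_location(self, n):
        """The kernel changes sign exactly where 1/n! = (t/tau)^2/(n+2)!,
        i.e. t/tau = sqrt((n+2)!/n!)."""
        analytic = math.sqrt(math.factorial(n + 2) / math.factorial(n))
        numeric = brentq(lambda t: temporal_kernel(n, 1.0, t), n / 2, 4 * n)
        assert numeric == pytest.approx(analytic, rel=1e-10)
        if n == 6:
            assert analytic == pytest.approx(math.sqrt(56))

    def test_biphasic_and_decaying_tail(self):
        t = np.linspace(0.01, 40, 2000)
        g = temporal_kernel(6, 1.0, t)
        assert g.max() > 0 and g.min() < 0
        # single sign change: positive lobe then negative lobe
        assert np.count_nonzero(np.diff(np.sign(g[np.abs(g) > 1e-12]))) == 1
        tail = temporal_kernel(6, 1.0, np.array([25.0, 30.0, 40.0]))
        assert np.all(np.abs(tail) < 1e-3)
        assert np.abs(tail[2]) < np.abs(tail[1]) < np.abs(tail[0])


def _naive_opponent(frames, bank):
    """Direct triple-loop evaluation of the spatiotemporal quadrature sums."""
    T, H, W = frames.shape
    R = bank.odd[0].shape[0] // 2
    r = np.zeros((T, H, W, 4))
    l = np.zeros((T, H, W, 4))
    for o in range(4):
        S = np.zeros((T, H, W))
        C = np.zeros((T, H, W))
        for t in range(T):
            for y in range(H):
                for x in range(W):
                    sacc = cacc = 0.0
                    for i in range(-R, R + 1):
                        for j in range(-R, R + 1):
                            yy, xx = y - i, x - j
                            if 0 <= yy < H and 0 <= xx < W:
                                sacc += bank.odd[o][i + R, j + R] * frames[t, yy, xx]
                                cacc += bank.even[o][i + R, j + R] * frames[t, yy, xx]
                    S[t, y, x], C[t, y, x] = sacc, cacc
        S6 = np.zeros_like(S); S9 = np.zeros_like(S)
        C6 = np.zeros_like(C); C9 = np.zeros_like(C)
        for t in range(T):
            for k in range(min(len(bank.g6), t + 1)):
                S6[t] += bank.g6[k] * S[t - k]
                S9[t] += bank.g9[k] * S[t - k]
                C6[t] += bank.g6[k] * C[t - k]
                C9[t] += bank.g9[k] * C[t - k]
        r[..., o] = (-S6 + C9) ** 2 + (S9 + C6) ** 2
        l[..., o] = (S6 + C9) ** 2 + (-S9 + C6) ** 2
    return r, l


class TestOpponentEnergy:
    def test_matches_bruteforce_oracle_on_random_stimulus(self, params, rng):
        """The FFT/convolution path equals a naive triple-loop evaluation of
        the oriented quadrature sums on a tiny random stimulus."""
        p = params.copy(spatial_radius=2)
        bank = FilterBank.from_params(p)
        frames = rng.random((5, 8, 8))
        e = opponent_energy(frames, bank)
        r_ref, l_ref = _naive_opponent(frames, bank)
        np.testing.assert_allclose(e.r, r_ref, atol=1e-10)
        np.testing.assert_allclose(e.l, l_ref, atol=1e-10)

    def test_nonnegative(self, params, rng):
        bank = FilterBank.from_params(params)
        e = opponent_energy(rng.random((6, 12, 12)), bank)
        assert (e.r >= 0).all() and (e.l >= 0).all()

    def test_time_reversal_swaps_opponent_channels(self, params):
        """Playing a drifting grating backwards exchanges preferred and
        opposite motion energy."""
        bank = FilterBank.from_params(params)
        f = params.f_cyc_per_deg / params.pixels_per_degree
        xs = np.arange(24)
        frames = np.stack([np.tile(0.5 + 0.5 * np.sin(2 * np.pi * f * (xs - t)),
                                   (24, 1)) for t in range(12)])
        e_fwd = opponent_energy(frames, bank)
        e_rev = opponent_energy(frames[::-1], bank)
        c = 12
        assert e_fwd.r[-1, c, c, 0] == pytest.approx(e_rev.l[-1, c, c, 0], rel=0.05)
        assert e_fwd.l[-1, c, c, 0] == pytest.approx(e_rev.r[-1, c, c, 0], rel=0.05)

    def test_constant_stimulus_is_balanced(self, params):
        """A spatially and temporally uniform stimulus carries no direction
        signal: r = l everywhere."""
        bank = FilterBank.from_params(params)
        frames = np.full((8, 12, 12), 0.5)
        e = opponent_energy(frames, bank)
        np.testing.assert_allclose(e.r, e.l, atol=1e-12)

    def test_static_bar_is_balanced_at_steady_state(self, params):
        bar = BarSpec(orientation=45, direction="right", speed=0, n_frames=14)
        stim = make_bar_stimulus(bar, GridSpec(32, 32))
        bank = FilterBank.from_params(params)
        e = opponent_energy(stim.frames, bank)
        np.testing.assert_allclose(e.r[-1], e.l[-1], rtol=1e-6, atol=1e-9)

    def test_requires_at_least_two_frames(self, params):
        bank = FilterBank.from_params(params)
        with pytest.raises(ValueError):
            opponent_energy(np.zeros((1, 8, 8)), bank)

    def test_drifting_grating_prefers_its_drift_direction(self, params):
        """A rightward-drifting grating yields r > l in the channel whose
        preferred direction is rightward."""
        bank = FilterBank.from_params(params)
        f = params.f_cyc_per_deg / params.pixels_per_degree
        xs = np.arange(24)
        frames = np.stack([np.tile(0.5 + 0.5 * np.sin(2 * np.pi * f * (xs - t)),
                                   (24, 1)) for t in range(10)])
        e = opponent_energy(frames, bank)
        c = 12
        assert e.r[-1, c, c, 0] > 2 * e.l[-1, c, c, 0]


class TestNormalization:
    def test_zero_energy_gives_silent_cells(self, params):
        e = OpponentEnergy(r=np.zeros((1, 4, 4, 4)), l=np.zeros((1, 4, 4, 4)))
        v = normalize_complex(e, params)
        assert (v == 0).all()

    def test_bounded_to_unit_interval(self, params, rng):
        e = OpponentEnergy(r=rng.random((2, 6, 6, 4)) * 10,
                           l=rng.random((2, 6, 6, 4)) * 10)
        v = normalize_complex(e, params)
        assert (v >= 0).all() and (v <= 1).all()

    def test_balanced_pair_splits_equally(self, params):
        """r = l > 0 gives equal activity in the two opposite channels."""
        p = params.copy(opponent_subtraction=False, norm_pool="pair",
                        energy_epsilon=1e-9, energy_floor=0.0)
        r = np.full((1, 4, 4, 4), 2.0)
        v = normalize_complex(OpponentEnergy(r=r, l=r.copy()), p)
        np.testing.assert_allclose(v[..., :4], v[..., 4:])
        np.testing.assert_allclose(v[..., 0], 1 / np.sqrt(2), rtol=1e-6)

    def test_eight_direction_channels_from_four_orientations(self, params):
        stim = make_bar_stimulus(BarSpec(n_frames=5), GridSpec(32, 32))
        v = complex_response(stim.frames, params)
        assert v.shape[-1] == 8

    def test_edges_respond_more_than_terminators(self, params):
        """On the oblique bar the perpendicular channel along the edge is much
        stronger than the rightward channel at the terminators."""
        bar = BarSpec(orientation=45, direction="right", length=21,
                      bar_width=1, n_frames=10)
        stim = make_bar_stimulus(bar)
        v = complex_response(stim.frames, params)[-1]
        ys, xs = np.nonzero(stim.mask(stim.n_frames - 1))
        mid = len(ys) // 2
        edge_perp = v[ys[mid], xs[mid], 7]          # down-right at mid-bar
        term_right = max(v[ys[0], xs[0], 0], v[ys[-1], xs[-1], 0])
        assert edge_perp > term_right
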