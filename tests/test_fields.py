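"""Brute-force oracle equivalence for every neighbourhood operator.

Each operator of the network (Gamma, Omega, Lambda, lambda, gamma, zeta, eta,
chi) is re-implemented here as a naive loop over neighbourhoods, and the fast
implementation must agree on random fields to floating tolerance.
"""

import numpy as np
import pytest

from v1mt.fields import (annulus_kernel, box_sum, chi_surround, eta_excitation,
                         gamma_mu, gamma_surround, interdir_inhibition,
                         lambda_longrange_es, lateral_excitation,
                         longrange_inhibition, omega_interdir, saturation_h)
from v1mt.params import ModelParams


@pytest.mark.parametrize("x,expected", [(-0.5, 0.0), (0.0, 0.0), (0.3, 0.3),
                                        (1.0, 1.0), (1.7, 1.0)])
def test_saturation_is_piecewise_linear(x, expected):
    assert saturation_h(np.array([x]))[0] == expected


def test_box_sum_zero_pads(rng):
    f = rng.random((5, 5))
    out = box_sum(f, 1)
    assert out[0, 0] == pytest.approx(f[:2, :2].sum())
    assert out[2, 2] == pytest.approx(f[1:4, 1:4].sum())


# ---------------------------------------------------------------------------
# naive references
# ---------------------------------------------------------------------------

def naive_gamma(v, p):
    H, W, D = v.shape
    mu = gamma_mu(p)
    R = p.gamma_radius
    a = p.gamma_act_radius
    out = np.zeros_like(v)
    for y in range(H):
        for x in range(W):
            for d in range(D):
                cond = False
                for i in range(-a, a + 1):
                    for j in range(-a, a + 1):
                        if i == 0 and j == 0:
                            continue
                        yy, xx = y + i, x + j
                        if 0 <= yy < H and 0 <= xx < W and v[yy, xx, d] > p.rho_cx:
                            cond = True
                if not cond:
                    continue
                s = 0.0
                for i in range(-R, R + 1):
                    for j in range(-R, R + 1):
                        yy, xx = y + i, x + j
                        if 0 <= yy < H and 0 <= xx < W:
                            src = v[yy, xx, d]
                            if src > p.rho_gamma_source:
                                s += mu[i + R, j + R] * src
                out[y, x, d] = s
    return out


def naive_lambda_es(v, p):
    H, W, D = v.shape
    r = p.lambda_es_radius
    out = np.zeros_like(v)
    for y in range(H):
        for x in range(W):
            for d in range(D):
                s = 0.0
                for phi in range(D):
                    if phi == d:
                        continue
                    for i in range(-r, r + 1):
                        for j in range(-r, r + 1):
                            yy, xx = y + i, x + j
                            if 0 <= yy < H and 0 <= xx < W:
                                src = v[yy, xx, phi]
                                if src > p.rho_es:
                                    s += src
                out[y, x, d] = s
    return out


def naive_lateral_excitation(v_ig, v_sg, p):
    H, W, D = v_ig.shape
    R = p.excitation_radius
    out = np.zeros_like(v_ig)
    for y in range(H):
        for x in range(W):
            for d in range(D):
                if v_sg[y, x, d] > p.rho_sg:
                    continue
                s = 0.0
                for i in range(-R, R + 1):
                    for j in range(-R, R + 1):
                        yy, xx = y + i, x + j
                        if 0 <= yy < H and 0 <= xx < W:
                            vn = v_ig[yy, xx, d]
                            if vn - v_ig[y, x, d] > p.rho_igig:
                                s += vn
                out[y, x, d] = s
    return out


def naive_zeta(v, p):
    H, W, D = v.shape
    r = p.ring_radius
    out = np.zeros_like(v)
    for y in range(H):
        for x in range(W):
            for d in range(D):
                s = 0.0
                for i in range(-r, r + 1):
                    for j in range(-r, r + 1):
                        if max(abs(i), abs(j)) != r:
                            continue
                        yy, xx = y + i, x + j
                        if 0 <= yy < H and 0 <= xx < W:
                            for phi in range(D):
                                if phi != d:
                                    s += v[yy, xx, phi]
                out[y, x, d] = s
    return out


def naive_chi(v_sg, p):
    H, W, D = v_sg.shape
    kern = annulus_kernel(p.surround_center_radius, p.surround_outer_radius,
                          p.surround_sigma)
    if p.annulus_normalize:
        kern = kern / kern.sum()
    R = p.surround_outer_radius
    thr = max(p.rho_sg, p.rho_chi)
    chi_e = np.zeros_like(v_sg)
    chi_i = np.zeros_like(v_sg)
    for y in range(H):
        for x in range(W):
            for d in range(D):
                if v_sg[y, x, d] <= thr:
                    continue
                si = se = 0.0
                for i in range(-R, R + 1):
                    for j in range(-R, R + 1):
                        yy, xx = y + i, x + j
                        if not (0 <= yy < H and 0 <= xx < W):
                            continue
                        w = kern[i + R, j + R]
                        if w == 0.0:
                            continue
                        for phi in range(D):
                            src = v_sg[yy, xx, phi]
                            if src > thr:
                                if phi == d:
                                    si += w * src
                                else:
                                    se += w * src
                chi_i[y, x, d] = si
                chi_e[y, x, d] = se
    return chi_e, chi_i


# ---------------------------------------------------------------------------
# equivalence tests
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    def test_gamma_surround(self, params, random_field):
        got = gamma_surround(random_field, params)
        want = naive_gamma(random_field, params)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_gamma_with_sparse_field_and_sum_norm(self, params, rng):
        p = params.copy(mu_normalize="sum", mu_inner_radius=0,
                        rho_gamma_source=0.0)
        v = np.where(rng.random((8, 8, 8)) > 0.7, rng.random((8, 8, 8)), 0.0)
        np.testing.assert_allclose(gamma_surround(v, p), naive_gamma(v, p),
                                   atol=1e-10)

    def test_omega_other_is_total_minus_own(self, random_field):
        got = omega_interdir(random_field, "other")
        want = random_field.sum(-1, keepdims=True) - random_field
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_omega_single_active_channel(self):
        v = np.zeros((4, 4, 8))
        v[2, 2, 3] = 0.6
        om = omega_interdir(v, "other")
        assert om[2, 2, 3] == 0.0
        assert all(om[2, 2, d] == 0.6 for d in range(8) if d != 3)

    def test_omega_uniform_channels_sum_to_seven(self):
        v = np.full((3, 3, 8), 0.25)
        np.testing.assert_allclose(omega_interdir(v, "other"), 7 * 0.25)

    def test_lambda_es(self, params, random_field):
        got = lambda_longrange_es(random_field, params)
        want = naive_lambda_es(random_field, params)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_lambda_es_single_source_support(self, params):
        """One active cell inhibits only other-direction cells within
        Chebyshev distance 3."""
        v = np.zeros((9, 9, 8))
        v[4, 4, 2] = 0.5
        lam = lambda_longrange_es(v, params)
        assert lam[4, 4, 2] == pytest.approx(0.0, abs=1e-12)
        assert lam[4, 4, 0] == pytest.approx(0.5)
        assert lam[7, 7, 0] == pytest.approx(0.5)   # distance 3: inside
        assert lam[8, 8, 0] == pytest.approx(0.0, abs=1e-12)  # distance 4: out

    def test_lateral_excitation(self, params, random_field, rng):
        v_sg = rng.random((8, 8, 8)) * 0.05
        got = lateral_excitation(random_field, v_sg, params)
        want = naive_lateral_excitation(random_field, v_sg, params)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_lateral_excitation_uniform_field_is_zero(self, params):
        v = np.full((10, 10, 8), 0.4)
        sg = np.zeros_like(v)
        assert (lateral_excitation(v, sg, params) == 0).all()

    def test_lateral_excitation_gated_by_segmentation(self, params):
        v = np.zeros((10, 10, 8))
        v[5, 5, 0] = 1.0
        sg = np.zeros_like(v)
        sg[5, 7, 0] = 5 * params.rho_sg     # discontinuity at the receiver
        lam = lateral_excitation(v, sg, params)
        assert lam[5, 7, 0] == 0.0
        assert lam[5, 6, 0] == 1.0

    def test_interdir_identity(self, random_field):
        got = interdir_inhibition(random_field)
        want = random_field.sum(-1, keepdims=True) - random_field
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_zeta(self, params, random_field):
        got = longrange_inhibition(random_field, params)
        want = naive_zeta(random_field, params)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_zeta_ring_excludes_interior(self, params):
        """Activity at Chebyshev distance 1 contributes nothing; at exactly
        ring distance it does."""
        v = np.zeros((9, 9, 8))
        v[4, 5, 1] = 1.0                      # distance 1 from (4, 4)
        assert longrange_inhibition(v, params)[4, 4, 0] == pytest.approx(0.0, abs=1e-12)
        v2 = np.zeros((9, 9, 8))
        v2[4, 7, 1] = 1.0                     # distance 3: on the ring
        assert longrange_inhibition(v2, params)[4, 4, 0] == pytest.approx(1.0)
        assert longrange_inhibition(v2, params)[4, 4, 1] == pytest.approx(0.0, abs=1e-12)

    def test_eta_is_channel_total(self, random_field):
        np.testing.assert_allclose(eta_excitation(random_field),
                                   random_field.sum(-1), atol=1e-12)

    def test_chi(self, params, rng):
        p = params.copy(surround_outer_radius=5)
        v = rng.random((12, 12, 8))
        got_e, got_i = chi_surround(v, p)
        want_e, want_i = naive_chi(v, p)
        np.testing.assert_allclose(got_i, want_i, atol=1e-10)
        assert (got_e == 0).all()            # chi_e disabled by default

    def test_chi_e_symmetric_form(self, rng, params):
        p = params.copy(surround_outer_radius=5, chi_e_enabled=True)
        v = rng.random((12, 12, 8))
        got_e, got_i = chi_surround(v, p)
        want_e, want_i = naive_chi(v, p)
        np.testing.assert_allclose(got_e, want_e, atol=1e-10)
        np.testing.assert_allclose(got_i, want_i, atol=1e-10)

    def test_chi_center_below_threshold_is_zero(self, params):
        v = np.full((12, 12, 8), 0.5)
        v[6, 6, 0] = 0.0
        _, chi_i = chi_surround(v, params)
        assert chi_i[6, 6, 0] == 0.0
        assert chi_i[6, 6, 1] > 0.0
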