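"""Numba kernel for the joint log posterior and gradient.

Loop-level translation of ``PredationModel._logpost_grad_numpy``; the
two implementations are asserted equal in the test suite.  Kept in a
separate module so the package degrades gracefully to the numpy path
when numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["nb_logpost_grad"]

# hyperprior vector layout (matches PredationModel._hp_vec):
# 0 prey_b0_loc, 1 prey_b0_scale, 2 prey_ll_loc, 3 prey_ll_scale,
# 4 mu_d0_loc, 5 mu_d0_scale, 6 mu_dl_loc, 7 mu_dl_scale,
# 8 mu_b1_loc, 9 mu_b1_scale, 10..14 sigma scales (d0, dl, g0, gl, b1)


@njit(cache=False, error_model="numpy")
def nb_logpost_grad(theta, P, C,
                    lab_pair, lab_t, lab_n, lab_k,
                    field_pair, field_n, field_k,
                    hp):
    dim = theta.shape[0]
    grad = np.zeros(dim)
    neg_inf = -np.inf
    for i in range(dim):
        v = theta[i]
        if not np.isfinite(v) or abs(v) > 300.0:
            return neg_inf, grad

    K = P * C
    o = 2 * P
    i_mu_d0 = o
    i_mu_dl = o + 1
    i_mu_b1 = o + 2
    i_ls = o + 3
    o_zd0 = o + 8
    o_zdl = o_zd0 + C
    o_zg0 = o_zdl + C
    o_zgl = o_zg0 + K
    o_zb1 = o_zgl + K

    mu_d0 = theta[i_mu_d0]
    mu_dl = theta[i_mu_dl]
    mu_b1 = theta[i_mu_b1]
    sig = np.empty(5)
    for j in range(5):
        sig[j] = math.exp(theta[i_ls + j])

    # assembled per-pair quantities
    b0 = np.empty(K)
    ll = np.empty(K)
    beta1 = np.empty(K)
    lam = np.empty(K)
    integral = np.empty(K)
    for k in range(K):
        ip = k // C
        ic = k % C
        d0 = mu_d0 + sig[0] * theta[o_zd0 + ic]
        dl = mu_dl + sig[1] * theta[o_zdl + ic]
        b0[k] = theta[ip] + d0 + sig[2] * theta[o_zg0 + k]
        ll[k] = theta[P + ip] + dl + sig[3] * theta[o_zgl + k]
        lb1 = mu_b1 + sig[4] * theta[o_zb1 + k]
        if lb1 > 690.0 or ll[k] > 690.0:
            return neg_inf, grad
        beta1[k] = math.exp(lb1)
        lam[k] = math.exp(ll[k])
        # softplus(b0) / beta1
        x = b0[k]
        sp = x + math.log1p(math.exp(-x)) if x > 0 else math.log1p(math.exp(x))
        integral[k] = sp / beta1[k]

    lp = 0.0
    g_b0 = np.zeros(K)
    g_ll = np.zeros(K)
    g_lb1 = np.zeros(K)

    # laboratory likelihood: Bernoulli-logit per (pair, delay) cell
    for c in range(lab_pair.shape[0]):
        k = lab_pair[c]
        eta = b0[k] - beta1[k] * lab_t[c]
        if eta > 0:
            sp = eta + math.log1p(math.exp(-eta))
            p = 1.0 / (1.0 + math.exp(-eta))
        else:
            e = math.exp(eta)
            sp = math.log1p(e)
            p = e / (1.0 + e)
        lp += lab_k[c] * eta - lab_n[c] * sp
        u = lab_k[c] - lab_n[c] * p
        g_b0[k] += u
        g_lb1[k] -= u * lab_t[c] * beta1[k]

    # field likelihood: p = 1 - exp(-lam * I) per pair cell
    for c in range(field_pair.shape[0]):
        k = field_pair[c]
        m = lam[k] * integral[k]
        if m > 700.0:
            m = 700.0
        em = -math.expm1(-m)        # p
        if em <= 0.0:
            if field_k[c] > 0:
                return neg_inf, grad
            continue
        nk = field_n[c] - field_k[c]
        lp += field_k[c] * math.log(em) - nk * m
        em1 = math.expm1(m)
        if em1 < 1e-300:
            em1 = 1e-300
        w = field_k[c] / em1 - nk
        wm = w * m
        g_ll[k] += wm
        g_lb1[k] -= wm
        pb0 = 1.0 / (1.0 + math.exp(-b0[k]))
        g_b0[k] += w * lam[k] * pb0 / beta1[k]

    if not math.isfinite(lp):
        return neg_inf, np.zeros(dim)

    # priors (constants dropped)
    for ip in range(P):
        ra = (theta[ip] - hp[0]) / hp[1]
        rl = (theta[P + ip] - hp[2]) / hp[3]
        lp += -0.5 * (ra * ra + rl * rl)
    for i in range(o_zd0, dim):
        lp += -0.5 * theta[i] * theta[i]
    rm0 = (mu_d0 - hp[4]) / hp[5]
    rm1 = (mu_dl - hp[6]) / hp[7]
    rm2 = (mu_b1 - hp[8]) / hp[9]
    lp += -0.5 * (rm0 * rm0 + rm1 * rm1 + rm2 * rm2)
    for j in range(5):
        sr = sig[j] / hp[10 + j]
        lp += theta[i_ls + j] - 0.5 * sr * sr
    if not math.isfinite(lp):
        return neg_inf, np.zeros(dim)

    # gradient assembly
    g_ls = np.zeros(5)
    for k in range(K):
        ip = k // C
        ic = k % C
        gb = g_b0[k]
        gl = g_ll[k]
        grad[ip] += gb
        grad[P + ip] += gl
        grad[i_mu_d0] += gb
        grad[i_mu_dl] += gl
        grad[i_mu_b1] += g_lb1[k]
        grad[o_zd0 + ic] += sig[0] * gb
        grad[o_zdl + ic] += sig[1] * gl
        grad[o_zg0 + k] = sig[2] * gb - theta[o_zg0 + k]
        grad[o_zgl + k] = sig[3] * gl - theta[o_zgl + k]
        grad[o_zb1 + k] = sig[4] * g_lb1[k] - theta[o_zb1 + k]
        g_ls[0] += sig[0] * theta[o_zd0 + ic] * gb
        g_ls[1] += sig[1] * theta[o_zdl + ic] * gl
        g_ls[2] += sig[2] * theta[o_zg0 + k] * gb
        g_ls[3] += sig[3] * theta[o_zgl + k] * gl
        g_ls[4] += sig[4] * theta[o_zb1 + k] * g_lb1[k]
    for ip in range(P):
        grad[ip] -= (theta[ip] - hp[0]) / (hp[1] * hp[1])
        grad[P + ip] -= (theta[P + ip] - hp[2]) / (hp[3] * hp[3])
    for ic in range(C):
        grad[o_zd0 + ic] -= theta[o_zd0 + ic]
        grad[o_zdl + ic] -= theta[o_zdl + ic]
    grad[i_mu_d0] -= (mu_d0 - hp[4]) / (hp[5] * hp[5])
    grad[i_mu_dl] -= (mu_dl - hp[6]) / (hp[7] * hp[7])
    grad[i_mu_b1] -= (mu_b1 - hp[8]) / (hp[9] * hp[9])
    for j in range(5):
        sr = sig[j] / hp[10 + j]
        grad[i_ls + j] = g_ls[j] + 1.0 - sr * sr
    for i in range(dim):
        if not math.isfinite(grad[i]):
            return neg_inf, np.zeros(dim)
    return lp, grad
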