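"""Compiled fixed-step RK4 kernels for batches of oscillator networks.

These kernels are the hot path: classifying one dataset means integrating
thousands of independent 3-oscillator networks for ~2e5 steps each.  They are
written as explicit scalar loops so numba can compile them to tight machine
code; fastmath is left off so results are bit-reproducible across runs.

Status codes returned by the kernels:
  0  integration completed
  1  numerical instability (non-finite state, |u| or |v| > 1e3, or an
     activator below -1e-6)
"""

import numpy as np
from numba import njit

#: blow-up threshold on |u|, |v|
_BLOWUP = 1.0e3
#: activators below this are treated as numerical instability, not noise
_NEG_TOL = -1.0e-6


@njit(cache=True, inline="always")
def _phi_of_t(t, t_il, amp, off, steep, cphi):
    """Illumination term at time t; cphi==NaN means use the tanh profile."""
    if cphi == cphi:  # not NaN: hold phi constant
        return cphi
    a = -steep * (t - t_il)
    # tanh saturates to +/-1 within double precision for |a| > 20; skipping
    # the libm call there removes most of its cost from the inner loop.
    if a > 20.0:
        th = 1.0
    elif a < -20.0:
        th = -1.0
    else:
        th = np.tanh(a)
    return amp * (off + th)


@njit(cache=True, inline="always")
def _deriv(u, v, t, t_il, cphi, amp, off, steep,
           eps, q, f, alpha, beta, adj, deg, du, dv):
    """Oregonator network right-hand side, written into du/dv in place."""
    n = u.shape[0]
    for j in range(n):
        s = 0.0
        for i in range(n):
            if i != j and adj[j, i]:
                s += u[i]
        ph = _phi_of_t(t, t_il[j], amp, off, steep, cphi[j])
        uj = u[j]
        du[j] = (uj - uj * uj - (f * v[j] + ph) * (uj - q) / (uj + q)) / eps \
            - (alpha + deg[j] * beta) * uj + beta * s
        dv[j] = uj - v[j]


@njit(cache=True)
def rk4_count_batch(u0, v0, t_il_b, cphi_b, amp, off, steep,
                    eps, q, f, alpha, beta, adj, deg,
                    h, n_steps, stride, thresh):
    """Integrate a batch of networks and count activator maxima on the fly.

    u0, v0        : (B, n) initial states
    t_il_b, cphi_b: (B, n) per-record illumination switch-off times / overrides
    adj           : (n, n) boolean coupling adjacency (diagonal ignored)
    deg           : (n,) neighbour counts

    Counting is done on the stored-sample grid (every `stride` steps plus the
    final state), with exactly the rule used on stored trajectories: an
    interior sample is a maximum iff left < mid, mid >= right and
    mid > thresh.  Returns (counts (B, n) int64, status (B,) int64).
    """
    B, n = u0.shape
    counts = np.zeros((B, n), np.int64)
    status = np.zeros(B, np.int64)
    for b in range(B):
        u = u0[b].copy()
        v = v0[b].copy()
        t_il = t_il_b[b]
        cphi = cphi_b[b]
        ku1 = np.empty(n); kv1 = np.empty(n)
        ku2 = np.empty(n); kv2 = np.empty(n)
        ku3 = np.empty(n); kv3 = np.empty(n)
        ku4 = np.empty(n); kv4 = np.empty(n)
        ut = np.empty(n); vt = np.empty(n)
        p2 = np.empty(n)  # sample before last
        p1 = np.empty(n)  # last sample
        for j in range(n):
            p1[j] = u[j]
        nseen = 1
        for step in range(n_steps):
            t = step * h
            _deriv(u, v, t, t_il, cphi, amp, off, steep,
                   eps, q, f, alpha, beta, adj, deg, ku1, kv1)
            for j in range(n):
                ut[j] = u[j] + 0.5 * h * ku1[j]
                vt[j] = v[j] + 0.5 * h * kv1[j]
            _deriv(ut, vt, t + 0.5 * h, t_il, cphi, amp, off, steep,
                   eps, q, f, alpha, beta, adj, deg, ku2, kv2)
            for j in range(n):
                ut[j] = u[j] + 0.5 * h * ku2[j]
                vt[j] = v[j] + 0.5 * h * kv2[j]
            _deriv(ut, vt, t + 0.5 * h, t_il, cphi, amp, off, steep,
                   eps, q, f, alpha, beta, adj, deg, ku3, kv3)
            for j in range(n):
                ut[j] = u[j] + h * ku3[j]
                vt[j] = v[j] + h * kv3[j]
            _deriv(ut, vt, t + h, t_il, cphi, amp, off, steep,
                   eps, q, f, alpha, beta, adj, deg, ku4, kv4)
            for j in range(n):
                u[j] += h / 6.0 * (ku1[j] + 2.0 * ku2[j] + 2.0 * ku3[j] + ku4[j])
                v[j] += h / 6.0 * (kv1[j] + 2.0 * kv2[j] + 2.0 * kv3[j] + kv4[j])
            sp = step + 1
            if sp % stride == 0 or sp == n_steps:
                for j in range(n):
                    w = u[j]
                    if not (w == w) or w > _BLOWUP or w < -_BLOWUP or w < _NEG_TOL:
                        status[b] = 1
                    wv = v[j]
                    if not (wv == wv) or wv > _BLOWUP or wv < -_BLOWUP:
                        status[b] = 1
                    if nseen >= 2:
                        if p2[j] < p1[j] and p1[j] >= w and p1[j] > thresh:
                            counts[b, j] += 1
                    p2[j] = p1[j]
                    p1[j] = w
                nseen += 1
                if status[b] != 0:
                    break
    return counts, status


@njit(cache=True, inline="always")
def _du3(u, v, ph, s_other, eps, q, f, g2, beta):
    """Activator derivative of one oscillator of an all-to-all triple;
    g2 = alpha + 2*beta, s_other = sum of the two neighbour activators.
    Arithmetic order matches the generic kernel exactly."""
    return (u - u * u - (f * v + ph) * (u - q) / (u + q)) / eps - g2 * u + beta * s_other


@njit(cache=True)
def rk4_count_batch3(u0, v0, t_il_b, cphi_b, amp, off, steep,
                     eps, q, f, alpha, beta,
                     h, n_steps, stride, thresh):
    """All-to-all 3-oscillator specialisation of rk4_count_batch.

    State lives in scalar registers; same arithmetic order per oscillator as
    the generic kernel's summed-neighbour form rewritten via the cancelled
    self term: -(alpha+3*beta)*u_j + beta*(u1+u2+u3).
    """
    B = u0.shape[0]
    counts = np.zeros((B, 3), np.int64)
    status = np.zeros(B, np.int64)
    g2 = alpha + 2.0 * beta
    hh = 0.5 * h
    h6 = h / 6.0
    for b in range(B):
        u1 = u0[b, 0]; u2 = u0[b, 1]; u3 = u0[b, 2]
        v1 = v0[b, 0]; v2 = v0[b, 1]; v3 = v0[b, 2]
        l1 = t_il_b[b, 0]; l2 = t_il_b[b, 1]; l3 = t_il_b[b, 2]
        c1 = cphi_b[b, 0]; c2 = cphi_b[b, 1]; c3 = cphi_b[b, 2]
        p2_1 = 0.0; p2_2 = 0.0; p2_3 = 0.0
        p1_1 = u1; p1_2 = u2; p1_3 = u3
        nseen = 1
        for step in range(n_steps):
            t = step * h
            pa1 = _phi_of_t(t, l1, amp, off, steep, c1)
            pa2 = _phi_of_t(t, l2, amp, off, steep, c2)
            pa3 = _phi_of_t(t, l3, amp, off, steep, c3)
            tm = t + hh
            pb1 = _phi_of_t(tm, l1, amp, off, steep, c1)
            pb2 = _phi_of_t(tm, l2, amp, off, steep, c2)
            pb3 = _phi_of_t(tm, l3, amp, off, steep, c3)
            te = t + h
            pc1 = _phi_of_t(te, l1, amp, off, steep, c1)
            pc2 = _phi_of_t(te, l2, amp, off, steep, c2)
            pc3 = _phi_of_t(te, l3, amp, off, steep, c3)
            ku1_1 = _du3(u1, v1, pa1, u2 + u3, eps, q, f, g2, beta)
            ku1_2 = _du3(u2, v2, pa2, u1 + u3, eps, q, f, g2, beta)
            ku1_3 = _du3(u3, v3, pa3, u1 + u2, eps, q, f, g2, beta)
            kv1_1 = u1 - v1; kv1_2 = u2 - v2; kv1_3 = u3 - v3
            a1 = u1 + hh * ku1_1; a2 = u2 + hh * ku1_2; a3 = u3 + hh * ku1_3
            b1 = v1 + hh * kv1_1; b2 = v2 + hh * kv1_2; b3 = v3 + hh * kv1_3
            ku2_1 = _du3(a1, b1, pb1, a2 + a3, eps, q, f, g2, beta)
            ku2_2 = _du3(a2, b2, pb2, a1 + a3, eps, q, f, g2, beta)
            ku2_3 = _du3(a3, b3, pb3, a1 + a2, eps, q, f, g2, beta)
            kv2_1 = a1 - b1; kv2_2 = a2 - b2; kv2_3 = a3 - b3
            a1 = u1 + hh * ku2_1; a2 = u2 + hh * ku2_2; a3 = u3 + hh * ku2_3
            b1 = v1 + hh * kv2_1; b2 = v2 + hh * kv2_2; b3 = v3 + hh * kv2_3
            ku3_1 = _du3(a1, b1, pb1, a2 + a3, eps, q, f, g2, beta)
            ku3_2 = _du3(a2, b2, pb2, a1 + a3, eps, q, f, g2, beta)
            ku3_3 = _du3(a3, b3, pb3, a1 + a2, eps, q, f, g2, beta)
            kv3_1 = a1 - b1; kv3_2 = a2 - b2; kv3_3 = a3 - b3
            a1 = u1 + h * ku3_1; a2 = u2 + h * ku3_2; a3 = u3 + h * ku3_3
            b1 = v1 + h * kv3_1; b2 = v2 + h * kv3_2; b3 = v3 + h * kv3_3
            ku4_1 = _du3(a1, b1, pc1, a2 + a3, eps, q, f, g2, beta)
            ku4_2 = _du3(a2, b2, pc2, a1 + a3, eps, q, f, g2, beta)
            ku4_3 = _du3(a3, b3, pc3, a1 + a2, eps, q, f, g2, beta)
            kv4_1 = a1 - b1; kv4_2 = a2 - b2; kv4_3 = a3 - b3
            u1 += h6 * (ku1_1 + 2.0 * ku2_1 + 2.0 * ku3_1 + ku4_1)
            u2 += h6 * (ku1_2 + 2.0 * ku2_2 + 2.0 * ku3_2 + ku4_2)
            u3 += h6 * (ku1_3 + 2.0 * ku2_3 + 2.0 * ku3_3 + ku4_3)
            v1 += h6 * (kv1_1 + 2.0 * kv2_1 + 2.0 * kv3_1 + kv4_1)
            v2 += h6 * (kv1_2 + 2.0 * kv2_2 + 2.0 * kv3_2 + kv4_2)
            v3 += h6 * (kv1_3 + 2.0 * kv2_3 + 2.0 * kv3_3 + kv4_3)
            sp = step + 1
            if sp % stride == 0 or sp == n_steps:
                bad = False
                for w in (u1, u2, u3, v1, v2, v3):
                    if not (w == w) or w > _BLOWUP or w < -_BLOWUP:
                        bad = True
                if u1 < _NEG_TOL or u2 < _NEG_TOL or u3 < _NEG_TOL:
                    bad = True
                if bad:
                    status[b] = 1
                if nseen >= 2:
                    if p2_1 < p1_1 and p1_1 >= u1 and p1_1 > thresh:
                        counts[b, 0] += 1
                    if p2_2 < p1_2 and p1_2 >= u2 and p1_2 > thresh:
                        counts[b, 1] += 1
                    if p2_3 < p1_3 and p1_3 >= u3 and p1_3 > thresh:
                        counts[b, 2] += 1
                p2_1 = p1_1; p2_2 = p1_2; p2_3 = p1_3
                p1_1 = u1; p1_2 = u2; p1_3 = u3
                nseen += 1
                if status[b] != 0:
                    break
    return counts, status


@njit(cache=True)
def rk4_trajectory(u0, v0, t_il, cphi, amp, off, steep,
                   eps, q, f, alpha, beta, adj, deg,
                   h, n_steps, stride):
    """Integrate one network, storing every `stride`-th step plus the final.

    Returns (t_out, U, V, status) with U, V of shape (n_stored, n).
    """
    n = u0.shape[0]
    n_stored = n_steps // stride + 1
    if n_steps % stride != 0:
        n_stored += 1
    t_out = np.empty(n_stored)
    U = np.empty((n_stored, n))
    V = np.empty((n_stored, n))
    status = 0
    u = u0.copy()
    v = v0.copy()
    ku1 = np.empty(n); kv1 = np.empty(n)
    ku2 = np.empty(n); kv2 = np.empty(n)
    ku3 = np.empty(n); kv3 = np.empty(n)
    ku4 = np.empty(n); kv4 = np.empty(n)
    ut = np.empty(n); vt = np.empty(n)
    t_out[0] = 0.0
    for j in range(n):
        U[0, j] = u[j]
        V[0, j] = v[j]
    k = 1
    for step in range(n_steps):
        t = step * h
        _deriv(u, v, t, t_il, cphi, amp, off, steep,
               eps, q, f, alpha, beta, adj, deg, ku1, kv1)
        for j in range(n):
            ut[j] = u[j] + 0.5 * h * ku1[j]
            vt[j] = v[j] + 0.5 * h * kv1[j]
        _deriv(ut, vt, t + 0.5 * h, t_il, cphi, amp, off, steep,
               eps, q, f, alpha, beta, adj, deg, ku2, kv2)
        for j in range(n):
            ut[j] = u[j] + 0.5 * h * ku2[j]
            vt[j] = v[j] + 0.5 * h * kv2[j]
        _deriv(ut, vt, t + 0.5 * h, t_il, cphi, amp, off, steep,
               eps, q, f, alpha, beta, adj, deg, ku3, kv3)
        for j in range(n):
            ut[j] = u[j] + h * ku3[j]
            vt[j] = v[j] + h * kv3[j]
        _deriv(ut, vt, t + h, t_il, cphi, amp, off, steep,
               eps, q, f, alpha, beta, adj, deg, ku4, kv4)
        for j in range(n):
            u[j] += h / 6.0 * (ku1[j] + 2.0 * ku2[j] + 2.0 * ku3[j] + ku4[j])
            v[j] += h / 6.0 * (kv1[j] + 2.0 * kv2[j] + 2.0 * kv3[j] + kv4[j])
        sp = step + 1
        if sp % stride == 0 or sp == n_steps:
            t_out[k] = sp * h
            for j in range(n):
                U[k, j] = u[j]
                V[k, j] = v[j]
                w = u[j]
                if not (w == w) or w > _BLOWUP or w < -_BLOWUP or w < _NEG_TOL:
                    status = 1
                wv = v[j]
                if not (wv == wv) or wv > _BLOWUP or wv < -_BLOWUP:
                    status = 1
            k += 1
            if status != 0:
                break
    return t_out[:k], U[:k], V[:k], status
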