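"""Numba time-stepping kernel for the multicompartment cable model.

The kernel advances the full model state with a fixed step dt (ms):

1. channel states are updated at the current voltage — HH gates by the exact
   exponential update, Markov occupancies by a tabulated backward-Euler
   propagator interpolated in voltage;
2. the cable equation is solved implicitly (backward Euler) for the new
   voltages with all conductances frozen at their just-updated values, using
   Hines elimination on the compartment tree (children are indexed before
   their parents, root last);
3. the per-compartment Ca pool relaxes toward rest and receives influx
   proportional to the rectified inward Na current density.

Everything voltage-dependent is pre-tabulated on a uniform grid (v0, dv, nv)
by the caller; voltages outside the table are clamped and |V| > 200 mV marks
divergence.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["integrate"]


@njit(cache=True)
def _markov_block(v, comp, g, p, table, v0, dv, nv, nstate,
                  g_tot, g_e, na_in, e_na, is_na, tmp):
    for k in range(comp.size):
        i = comp[k]
        x = (v[i] - v0) / dv
        if x < 0.0:
            x = 0.0
        elif x > nv - 1.001:
            x = nv - 1.001
        i0 = int(x)
        w = x - i0
        for a in range(nstate):
            s = 0.0
            for b in range(nstate):
                s += ((1.0 - w) * table[i0, a, b] + w * table[i0 + 1, a, b]) * p[k, b]
            tmp[a] = s
        tot = 0.0
        for a in range(nstate):
            if tmp[a] < 0.0:
                tmp[a] = 0.0
            tot += tmp[a]
        for a in range(nstate):
            p[k, a] = tmp[a] / tot
        go = g[k] * p[k, 3]  # state 3 is the open state in all Nav schemes
        g_tot[i] += go
        g_e[i] += go * e_na
        if is_na:
            na_in[i] += go * (v[i] - e_na)


@njit(cache=True)
def _hh_block(v, comp, g, x, inf_t, dec_t, v0, dv, nv, p0, p1,
              g_tot, g_e, e_rev):
    ngate = x.shape[1]
    for k in range(comp.size):
        i = comp[k]
        xx = (v[i] - v0) / dv
        if xx < 0.0:
            xx = 0.0
        elif xx > nv - 1.001:
            xx = nv - 1.001
        i0 = int(xx)
        w = xx - i0
        for gidx in range(ngate):
            inf = (1.0 - w) * inf_t[i0, gidx] + w * inf_t[i0 + 1, gidx]
            dec = (1.0 - w) * dec_t[i0, gidx] + w * dec_t[i0 + 1, gidx]
            x[k, gidx] = inf + (x[k, gidx] - inf) * dec
        o = x[k, 0] ** p0
        if ngate > 1:
            o *= x[k, 1] ** p1
        go = g[k] * o
        g_tot[i] += go
        g_e[i] += go * e_rev


@njit(cache=True)
def integrate(
    v, parent, g_ax, c_dt, g_leak, e_leak_arr,
    drive, dcomp, dfrac, e_drive,
    ca, ca_rest, tau_ca, phi, inv_area,
    v0, dv, nv,
    m11_comp, m11_g, m11_p, m11_t,
    m16_comp, m16_g, m16_p, m16_t,
    m17_comp, m17_g, m17_p, m17_t,
    kv1_comp, kv1_g, kv1_x, kv1_inf, kv1_dec,
    kv33_comp, kv33_g, kv33_x, kv33_inf, kv33_dec,
    kcnq_comp, kcnq_g, kcnq_x, kcnq_inf, kcnq_dec,
    sk_comp, sk_g, sk_a, sk_inv_cahalf, sk_hill, sk_dec,
    e_na, e_k,
    rec_idx, dt, n_steps, v_rec, ca_rec,
):
    """Advance ``n_steps`` steps; record voltages (and terminal Ca) each step.

    Returns 0 on success, 1 on divergence (|V| > 200 mV).
    """
    n = v.size
    g_tot = np.empty(n)
    g_e = np.empty(n)
    na_in = np.empty(n)
    d = np.empty(n)
    b = np.empty(n)
    tmp = np.empty(16)

    for step in range(n_steps):
        for i in range(n):
            g_tot[i] = g_leak[i]
            g_e[i] = g_leak[i] * e_leak_arr[i]
            na_in[i] = 0.0
        gd = drive[step]
        for k in range(dcomp.size):
            i = dcomp[k]
            gg = gd * dfrac[k]
            g_tot[i] += gg
            g_e[i] += gg * e_drive

        _markov_block(v, m11_comp, m11_g, m11_p, m11_t, v0, dv, nv, 10,
                      g_tot, g_e, na_in, e_na, True, tmp)
        _markov_block(v, m16_comp, m16_g, m16_p, m16_t, v0, dv, nv, 10,
                      g_tot, g_e, na_in, e_na, True, tmp)
        _markov_block(v, m17_comp, m17_g, m17_p, m17_t, v0, dv, nv, 6,
                      g_tot, g_e, na_in, e_na, True, tmp)
        _hh_block(v, kv1_comp, kv1_g, kv1_x, kv1_inf, kv1_dec, v0, dv, nv,
                  4, 1, g_tot, g_e, e_k)
        _hh_block(v, kv33_comp, kv33_g, kv33_x, kv33_inf, kv33_dec, v0, dv, nv,
                  2, 1, g_tot, g_e, e_k)
        _hh_block(v, kcnq_comp, kcnq_g, kcnq_x, kcnq_inf, kcnq_dec, v0, dv, nv,
                  1, 1, g_tot, g_e, e_k)

        # SK2: Ca-gated, first-order kinetics toward the Hill steady state
        for k in range(sk_comp.size):
            i = sk_comp[k]
            c = ca[i] * sk_inv_cahalf
            ch = c ** sk_hill
            inf = ch / (1.0 + ch)
            sk_a[k] = inf + (sk_a[k] - inf) * sk_dec
            go = sk_g[k] * sk_a[k]
            g_tot[i] += go
            g_e[i] += go * e_k

        # assemble and solve the implicit cable system (Hines)
        for i in range(n):
            d[i] = c_dt[i] + g_tot[i]
            b[i] = c_dt[i] * v[i] + g_e[i]
        for i in range(n - 1):
            d[i] += g_ax[i]
            d[parent[i]] += g_ax[i]
        for i in range(n - 1):
            f = g_ax[i] / d[i]
            d[parent[i]] -= f * g_ax[i]
            b[parent[i]] += f * b[i]
        v[n - 1] = b[n - 1] / d[n - 1]
        for i in range(n - 2, -1, -1):
            v[i] = (b[i] + g_ax[i] * v[parent[i]]) / d[i]

        # Ca pools: decay toward rest plus spike-coupled influx. The source
        # is a high-voltage-activated entry gated on local depolarization
        # (opens briefly during each action potential), so the influx per
        # spike is fixed per unit membrane area.
        for i in range(n):
            gate = 1.0 / (1.0 + np.exp(-(v[i] + 25.0) / 3.0))
            ca[i] += dt * (phi * gate - (ca[i] - ca_rest) / tau_ca)
            if ca[i] < 0.0:
                ca[i] = 0.0

        for k in range(rec_idx.size):
            v_rec[k, step] = v[rec_idx[k]]
        ca_rec[step] = ca[rec_idx[0]]

        if step % 200 == 0:
            bad = False
            for i in range(n):
                if not (-200.0 < v[i] < 200.0):
                    bad = True
            if bad:
                return 1
    return 0
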