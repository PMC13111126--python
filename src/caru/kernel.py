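"""Compiled whole-cell simulation loop.

Paced protocols at dt = 0.001 ms take ~10^6 steps per beat; this module
fuses the full per-step update (channel populations, calcium cycling,
background currents, membrane potential) into one numba-jitted loop.
The update order and all formulas are identical to the reference
implementation in :mod:`caru.cell`; a test asserts the equivalence.

The stochastic path draws per-state multinomial transition counts by
sequential conditional binomials, which reproduces the joint
multinomial law exactly; the RNG is numba's own, seeded once per
simulation from the supplied seed, so trajectories are bit-reproducible
for a fixed (seed, config) pair.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .parameters import INITIAL_STATE, CellParameters, KernelParams, kernel_params

__all__ = ["simulate", "SimulationResult", "initial_state_vector", "STATE_FIELDS"]

# state-vector layout for snapshots/restarts
STATE_FIELDS = (
    ["V", "Na_i", "K_i", "Ca_i_free", "Ca_sr_free", "Ca_ss_free",
     "m", "h", "j", "xr1", "xr2", "xs", "r", "s"]
    + [f"lcc_{s}" for s in ("C", "Cp", "O", "If", "If2", "ICa", "IfCa")]
    + [f"ryr_{s}" for s in ("R", "O", "RI", "I")]
)

# (source, target) index pairs; LCC states C=0 Cp=1 O=2 If=3 If2=4 ICa=5 IfCa=6
LCC_EDGE_TABLE = np.array(
    [
        (0, 1), (1, 0), (1, 2), (2, 1), (2, 3), (3, 2), (2, 4),
        (4, 2), (2, 5), (5, 2), (3, 6), (6, 3), (5, 6), (6, 5),
        (1, 3),
    ],
    dtype=np.int64,
)
# RyR states R=0 O=1 RI=2 I=3
RYR_EDGE_TABLE = np.array(
    [(0, 1), (1, 0), (0, 2), (2, 0), (1, 3), (3, 1), (2, 3), (3, 2)],
    dtype=np.int64,
)


def _group_edges(edges: np.ndarray, n_states: int):
    """Sort edges by source state for O(edges) per-step scans.

    Returns (targets, rate_index, offsets): edges of state s are the
    slice offsets[s]:offsets[s+1]; ``rate_index`` maps back into the
    rate vector laid out in table order.
    """
    order = np.argsort(edges[:, 0], kind="stable").astype(np.int64)
    srcs = edges[order, 0]
    targets = edges[order, 1].copy()
    offsets = np.zeros(n_states + 1, dtype=np.int64)
    for s in srcs:
        offsets[s + 1] += 1
    offsets = np.cumsum(offsets)
    return targets, order, offsets


LCC_GROUPED = _group_edges(LCC_EDGE_TABLE, 7)
RYR_GROUPED = _group_edges(RYR_EDGE_TABLE, 4)


@njit(cache=True)
def lcc_rate_vector(v, ca_ss, eta, phi, x7, out):
    """14 LCC edge rates (ms^-1) in LCC_EDGE_TABLE order."""
    d_inf = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    tau_d = ad * bd + gd
    dp = d_inf / tau_d
    dm = (1.0 - d_inf) / tau_d

    f_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tau_f = (
        1102.5 * np.exp(-((v + 27.0) ** 2) / 225.0)
        + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0))
        + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0))
        + 20.0
    )
    fp = f_inf / tau_f
    fm = eta * (1.0 - f_inf) / tau_f

    f2_inf = 0.67 / (1.0 + np.exp((v + 35.0) / 7.0)) + 0.33
    tau_f2 = (
        562.0 * np.exp(-((v + 27.0) ** 2) / 240.0)
        + 31.0 / (1.0 + np.exp((25.0 - v) / 10.0))
        + 80.0 / (1.0 + np.exp((v + 30.0) / 10.0))
    )
    f2p = f2_inf / tau_f2
    f2m = eta * (1.0 - f2_inf) / tau_f2

    x = (ca_ss / 0.05) ** 2
    fca_inf = 0.6 / (1.0 + x) + 0.4
    tau_fca = 80.0 / (1.0 + x) + 2.0
    fcap = fca_inf / tau_fca
    fcam = (1.0 - fca_inf) / tau_fca

    out[0] = dp
    out[1] = dm
    out[2] = phi * x7 * dp
    out[3] = x7 * dm
    out[4] = fm
    out[5] = fp
    out[6] = f2m
    out[7] = f2p
    out[8] = fcam
    out[9] = fcap
    out[10] = fcam
    out[11] = fcap
    out[12] = fm
    out[13] = fp
    out[14] = fm


@njit(cache=True)
def ryr_rate_vector(ca_ss, ca_sr, k1p, k2p, k3, k4, maxsr, minsr, ec,
                    phi, gamma, literal_product, out):
    """8 RyR edge rates (ms^-1) in RYR_EDGE_TABLE order."""
    kc = maxsr - (maxsr - minsr) / (1.0 + (ec / ca_sr) ** 2)
    if literal_product > 0.5:
        k1 = phi * k1p * kc
    else:
        k1 = phi * k1p / kc
    k2 = k2p * kc * gamma
    k_open = k1 * ca_ss * ca_ss
    k_inact = k2 * ca_ss
    out[0] = k_open
    out[1] = k3
    out[2] = k_inact
    out[3] = k4
    out[4] = k_inact
    out[5] = k4
    out[6] = k_open
    out[7] = k3


@njit(cache=True)
def _tau_leap_counts(counts, edges, rates, dt, new_counts):
    """One multinomial tau-leap over an ungrouped edge table (in place).

    Exact sequential decomposition of the multinomial: first the total
    number leaving the state, Binomial(n, 1-exp(-k_tot*dt)), then the
    partition over edges with conditional binomials on k_i/k_tot.
    Reference version used by tests; the simulation loop uses the
    grouped-edge variant below.
    """
    n_states = counts.shape[0]
    for s in range(n_states):
        n = counts[s]
        if n == 0:
            continue
        k_tot = 0.0
        for e in range(edges.shape[0]):
            if edges[e, 0] == s:
                k_tot += rates[e]
        if k_tot <= 0.0:
            new_counts[s] += n
            continue
        p_leave = -np.expm1(-k_tot * dt)
        leavers = np.random.binomial(n, p_leave)
        new_counts[s] += n - leavers
        if leavers == 0:
            continue
        rem_n = leavers
        rem_k = k_tot
        for e in range(edges.shape[0]):
            if edges[e, 0] != s or rem_n == 0:
                continue
            cond = rates[e] / rem_k
            if cond >= 1.0:
                draw = rem_n
            else:
                draw = np.random.binomial(rem_n, cond)
            new_counts[edges[e, 1]] += draw
            rem_n -= draw
            rem_k -= rates[e]
        new_counts[s] += rem_n  # numerically orphaned leavers stay put


@njit(cache=True, inline="always")
def _tau_leap_grouped(counts, targets, order, offsets, rates, new_counts, dt):
    """Grouped-edge multinomial tau-leap; same law as _tau_leap_counts."""
    for s in range(counts.shape[0]):
        n = counts[s]
        start = offsets[s]
        end = offsets[s + 1]
        if n == 0:
            continue
        if start == end:
            new_counts[s] += n
            continue
        k_tot = 0.0
        for e in range(start, end):
            k_tot += rates[order[e]]
        if k_tot <= 0.0:
            new_counts[s] += n
            continue
        p_leave = -np.expm1(-k_tot * dt)
        leavers = np.random.binomial(n, p_leave)
        new_counts[s] += n - leavers
        if leavers == 0:
            continue
        rem_n = leavers
        rem_k = k_tot
        for e in range(start, end):
            if rem_n == 0:
                break
            k_e = rates[order[e]]
            cond = k_e / rem_k
            if cond >= 1.0:
                draw = rem_n
            else:
                draw = np.random.binomial(rem_n, cond)
            new_counts[targets[e]] += draw
            rem_n -= draw
            rem_k -= k_e
        new_counts[s] += rem_n


@njit(cache=True)
def _euler_fractions(frac, edges, rates, dt, out):
    for i in range(frac.shape[0]):
        out[i] = frac[i]
    for e in range(edges.shape[0]):
        flow = dt * rates[e] * frac[edges[e, 0]]
        out[edges[e, 0]] -= flow
        out[edges[e, 1]] += flow


@njit(cache=True)
def _buffered_free(total, buf, k_buf):
    b = buf + k_buf - total
    return (-b + np.sqrt(b * b + 4.0 * k_buf * total)) / 2.0


@njit(cache=True)
def _buffered_total(free, buf, k_buf):
    return free + free * buf / (free + k_buf)


@njit(cache=True)
def apd_core(v_buf, dt, frac):
    """Action potential duration at repolarization fraction ``frac``.

    Threshold = V_peak - frac*(V_peak - V_start); duration between the
    upstroke and downstroke threshold crossings (linear interpolation).
    Returns NaN when no downstroke crossing exists within the trace.
    """
    n = v_buf.shape[0]
    v_dia = v_buf[0]
    ip = 0
    v_peak = v_buf[0]
    for i in range(n):
        if v_buf[i] > v_peak:
            v_peak = v_buf[i]
            ip = i
    if v_peak - v_dia < 1.0:
        return np.nan
    thr = v_peak - frac * (v_peak - v_dia)
    t_up = np.nan
    for i in range(1, ip + 1):
        if v_buf[i] >= thr and v_buf[i - 1] < thr:
            if v_buf[i] > v_buf[i - 1]:
                t_up = (i - 1 + (thr - v_buf[i - 1]) / (v_buf[i] - v_buf[i - 1])) * dt
            else:
                t_up = i * dt
            break
    if np.isnan(t_up):
        t_up = ip * dt
    for i in range(ip + 1, n):
        if v_buf[i] <= thr and v_buf[i - 1] > thr:
            if v_buf[i - 1] > v_buf[i]:
                t_dn = (i - 1 + (v_buf[i - 1] - thr) / (v_buf[i - 1] - v_buf[i])) * dt
            else:
                t_dn = i * dt
            return t_dn - t_up
    return np.nan


@njit(cache=True)
def _run(
    p: KernelParams,
    stochastic: int,
    n_lcc: int,
    n_ryr: int,
    dt: float,
    period: float,
    n_beats: int,
    stim_amp: float,
    stim_dur: float,
    seed: int,
    record_stride: int,
    y0: np.ndarray,
    lcc_edges: np.ndarray,
    ryr_edges: np.ndarray,
    lcc_targets: np.ndarray,
    lcc_order: np.ndarray,
    lcc_offsets: np.ndarray,
    ryr_targets: np.ndarray,
    ryr_order: np.ndarray,
    ryr_offsets: np.ndarray,
):
    np.random.seed(seed)
    vt = p.rr * p.tt / p.ff

    v = y0[0]
    na_i = y0[1]
    k_i = y0[2]
    cai = y0[3]
    casr = y0[4]
    cass = y0[5]
    m = y0[6]
    h = y0[7]
    jg = y0[8]
    xr1 = y0[9]
    xr2 = y0[10]
    xs = y0[11]
    rg = y0[12]
    sg = y0[13]

    lcc_frac = y0[14:21].copy()
    ryr_frac = y0[21:25].copy()
    lcc_counts = np.zeros(7, dtype=np.int64)
    ryr_counts = np.zeros(4, dtype=np.int64)
    if stochastic == 1:
        # largest-remainder rounding of the fraction vector onto N channels
        acc = 0
        for i in range(7):
            c = int(np.floor(lcc_frac[i] * n_lcc + 0.5))
            lcc_counts[i] = c
            acc += c
        lcc_counts[0] += n_lcc - acc
        acc = 0
        for i in range(4):
            c = int(np.floor(ryr_frac[i] * n_ryr + 0.5))
            ryr_counts[i] = c
            acc += c
        ryr_counts[0] += n_ryr - acc

    steps_per_beat = int(round(period / dt))
    lcc_k = np.zeros(lcc_edges.shape[0])
    ryr_k = np.zeros(ryr_edges.shape[0])
    new_lcc = np.zeros(7, dtype=np.int64)
    new_ryr = np.zeros(4, dtype=np.int64)
    lcc_next = np.zeros(7)
    ryr_next = np.zeros(4)
    v_buf = np.zeros(steps_per_beat)

    summaries = np.zeros((n_beats, 5))
    if record_stride > 0:
        n_rec = (n_beats * steps_per_beat + record_stride - 1) // record_stride
    else:
        n_rec = 0
    traces = np.zeros((n_rec, 6))
    rec_i = 0
    status = 0  # 0 ok, 1 diverged

    gstep = 0
    for beat in range(n_beats):
        sbar = 0.0
        peak_cai = cai
        for i in range(steps_per_beat):
            v_buf[i] = v
            t_in_beat = i * dt

            lcc_rate_vector(v, cass, p.eta, p.phi_lcc, p.x7, lcc_k)
            ryr_rate_vector(
                cass, casr, p.k1p, p.k2p, p.k3, p.k4, p.maxsr, p.minsr,
                p.ec, p.phi_ryr, p.gamma_ryr, p.kcasr_product, ryr_k,
            )

            if stochastic == 1:
                for q in range(7):
                    new_lcc[q] = 0
                for q in range(4):
                    new_ryr[q] = 0
                _tau_leap_grouped(lcc_counts, lcc_targets, lcc_order,
                                  lcc_offsets, lcc_k, new_lcc, dt)
                _tau_leap_grouped(ryr_counts, ryr_targets, ryr_order,
                                  ryr_offsets, ryr_k, new_ryr, dt)
                for q in range(7):
                    lcc_counts[q] = new_lcc[q]
                for q in range(4):
                    ryr_counts[q] = new_ryr[q]
                o_lcc = lcc_counts[2] / n_lcc
                o_ryr = ryr_counts[1] / n_ryr
            else:
                _euler_fractions(lcc_frac, lcc_edges, lcc_k, dt, lcc_next)
                _euler_fractions(ryr_frac, ryr_edges, ryr_k, dt, ryr_next)
                for q in range(7):
                    lcc_frac[q] = lcc_next[q]
                for q in range(4):
                    ryr_frac[q] = ryr_next[q]
                o_lcc = lcc_frac[2]
                o_ryr = ryr_frac[1]

            # L-type current (GHK form, removable singularity by series)
            z = 2.0 * (v - 15.0) * p.ff / (p.rr * p.tt)
            if np.abs(z) < 1e-5:
                zfac = 1.0 - z / 2.0 + z * z / 12.0
            else:
                zfac = z / np.expm1(z)
            i_cal = (
                o_lcc * p.g_cal * p.lcc_gain * 2.0 * p.ff
                * (0.25 * cass * np.exp(z) - p.ca_o) * zfac
            )
            i_rel = o_ryr * p.v_rel * (casr - cass)

            # sarcolemmal calcium currents
            e1 = np.exp(p.gamma_ncx * v / vt)
            e2 = np.exp((p.gamma_ncx - 1.0) * v / vt)
            i_naca = (
                p.k_naca
                * (e1 * na_i**3 * p.ca_o - e2 * p.na_o**3 * cai * p.alpha_ncx)
                / (
                    (p.km_nai**3 + p.na_o**3)
                    * (p.km_ca + p.ca_o)
                    * (1.0 + p.k_sat * e2)
                )
            )
            i_pca = p.g_pca * cai / (p.k_pca + cai)
            e_ca = 0.5 * vt * np.log(p.ca_o / cai)
            i_bca = p.g_bca * (v - e_ca)

            # calcium cycling on totals
            k_eff = p.k_up / p.phi_up
            if cai > 0.0:
                i_up = p.v_max_up / (1.0 + (k_eff / cai) ** 2)
            else:
                i_up = 0.0
            i_leak = p.v_leak * (casr - cai)
            i_xfer = p.v_xfer * (cass - cai)
            d_cai = (
                -(i_bca + i_pca - 2.0 * i_naca) * p.c_m / (2.0 * p.v_c * p.ff)
                + (p.v_sr / p.v_c) * (i_leak - i_up)
                + i_xfer
            )
            d_casr = i_up - i_leak - i_rel
            d_cass = (
                -i_cal * p.c_m / (2.0 * p.v_ss * p.ff)
                + (p.v_sr / p.v_ss) * i_rel
                - (p.v_c / p.v_ss) * i_xfer
            )
            cai_tot = _buffered_total(cai, p.buf_c, p.k_buf_c) + dt * d_cai
            casr_tot = _buffered_total(casr, p.buf_sr, p.k_buf_sr) + dt * d_casr
            cass_tot = _buffered_total(cass, p.buf_ss, p.k_buf_ss) + dt * d_cass
            if cai_tot < 0.0 or casr_tot < 0.0 or cass_tot < 0.0:
                status = 1
                break
            cai_new = _buffered_free(cai_tot, p.buf_c, p.k_buf_c)
            casr_new = _buffered_free(casr_tot, p.buf_sr, p.k_buf_sr)
            cass_new = _buffered_free(cass_tot, p.buf_ss, p.k_buf_ss)

            # background currents
            e_na = vt * np.log(p.na_o / na_i)
            e_k = vt * np.log(p.k_o / k_i)
            e_ks = vt * np.log((p.k_o + p.p_kna * p.na_o) / (k_i + p.p_kna * na_i))
            i_na = p.g_na * m**3 * h * jg * (v - e_na)
            a_k1 = 0.1 / (1.0 + np.exp(0.06 * (v - e_k - 200.0)))
            b_k1 = (
                3.0 * np.exp(0.0002 * (v - e_k + 100.0))
                + np.exp(0.1 * (v - e_k - 10.0))
            ) / (1.0 + np.exp(-0.5 * (v - e_k)))
            i_k1 = p.g_k1 * (a_k1 / (a_k1 + b_k1)) * np.sqrt(p.k_o / 5.4) * (v - e_k)
            i_to = p.g_to * rg * sg * (v - e_k)
            i_kr = p.g_kr * np.sqrt(p.k_o / 5.4) * xr1 * xr2 * (v - e_k)
            i_ks = p.g_ks * xs * xs * (v - e_ks)
            i_nak = (
                p.p_nak * p.k_o * na_i
                / (
                    (p.k_o + p.km_k)
                    * (na_i + p.km_na)
                    * (1.0 + 0.1245 * np.exp(-0.1 * v / vt) + 0.0353 * np.exp(-v / vt))
                )
            )
            i_pk = p.g_pk * (v - e_k) / (1.0 + np.exp((25.0 - v) / 5.98))
            i_bna = p.g_bna * (v - e_na)

            i_st = stim_amp if t_in_beat < stim_dur else 0.0
            conv = p.c_m / (p.v_c * p.ff)
            na_i = na_i - dt * conv * (i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca)
            k_i = k_i - dt * conv * (
                i_k1 + i_to + i_kr + i_ks - 2.0 * i_nak + i_pk - i_st
            )

            # gates (explicit Euler, frozen V of this step)
            m_inf = 1.0 / (1.0 + np.exp((-56.86 - v) / 9.03)) ** 2
            am = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
            bm = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) + 0.1 / (
                1.0 + np.exp((v - 50.0) / 200.0)
            )
            m = m + dt * (m_inf - m) / (am * bm)
            h_inf = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
            if v < -40.0:
                ah = 0.057 * np.exp(-(v + 80.0) / 6.8)
                bh = 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v)
            else:
                ah = 0.0
                bh = 0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
            h = h + dt * (h_inf - h) * (ah + bh)
            if v < -40.0:
                aj = (
                    (-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
                    * (v + 37.78)
                    / (1.0 + np.exp(0.311 * (v + 79.23)))
                )
                bj = 0.02424 * np.exp(-0.01052 * v) / (
                    1.0 + np.exp(-0.1378 * (v + 40.14))
                )
            else:
                aj = 0.0
                bj = 0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
            jg = jg + dt * (h_inf - jg) * (aj + bj)
            xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
            axr1 = 450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
            bxr1 = 6.0 / (1.0 + np.exp((v + 30.0) / 11.5))
            xr1 = xr1 + dt * (xr1_inf - xr1) / (axr1 * bxr1)
            xr2_inf = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
            axr2 = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
            bxr2 = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
            xr2 = xr2 + dt * (xr2_inf - xr2) / (axr2 * bxr2)
            xs_inf = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
            axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))
            bxs = 1.0 / (1.0 + np.exp((v - 35.0) / 15.0))
            xs = xs + dt * (xs_inf - xs) / (axs * bxs + 80.0)
            r_inf = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
            tau_r = 9.5 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
            rg = rg + dt * (r_inf - rg) / tau_r
            s_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))
            tau_s = (
                85.0 * np.exp(-((v + 45.0) ** 2) / 320.0)
                + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0))
                + 3.0
            )
            sg = sg + dt * (s_inf - sg) / tau_s

            i_ion = (
                i_na + i_k1 + i_to + i_kr + i_ks + i_nak + i_pk + i_bna
                + i_cal + i_naca + i_pca + i_bca
            )
            v = v + dt * (-i_ion + i_st)
            cai = cai_new
            casr = casr_new
            cass = cass_new
            if not np.isfinite(v):
                status = 1
                break

            sbar += i_rel
            if cai > peak_cai:
                peak_cai = cai
            if record_stride > 0 and gstep % record_stride == 0:
                traces[rec_i, 0] = gstep * dt
                traces[rec_i, 1] = v
                traces[rec_i, 2] = cai
                traces[rec_i, 3] = cass
                traces[rec_i, 4] = i_cal
                traces[rec_i, 5] = i_rel
                rec_i += 1
            gstep += 1
        if status == 1:
            break
        summaries[beat, 0] = sbar * dt
        summaries[beat, 1] = apd_core(v_buf, dt, 0.5)
        summaries[beat, 2] = apd_core(v_buf, dt, 0.9)
        summaries[beat, 3] = peak_cai
        summaries[beat, 4] = casr

    y_end = np.zeros(25)
    y_end[0] = v
    y_end[1] = na_i
    y_end[2] = k_i
    y_end[3] = cai
    y_end[4] = casr
    y_end[5] = cass
    y_end[6] = m
    y_end[7] = h
    y_end[8] = jg
    y_end[9] = xr1
    y_end[10] = xr2
    y_end[11] = xs
    y_end[12] = rg
    y_end[13] = sg
    if stochastic == 1:
        for q in range(7):
            y_end[14 + q] = lcc_counts[q] / n_lcc
        for q in range(4):
            y_end[21 + q] = ryr_counts[q] / n_ryr
    else:
        for q in range(7):
            y_end[14 + q] = lcc_frac[q]
        for q in range(4):
            y_end[21 + q] = ryr_frac[q]
    return summaries, traces[:rec_i], y_end, status


class SimulationResult:
    """Per-beat summaries and optional downsampled traces of one run."""

    def __init__(self, summaries, traces, y_end, status, dt, period, record_stride):
        self.sbar = summaries[:, 0]
        self.apd50 = summaries[:, 1]
        self.apd90 = summaries[:, 2]
        self.peak_cai = summaries[:, 3]
        self.diastolic_casr = summaries[:, 4]
        self.summaries = summaries
        self.traces = traces
        self.y_end = y_end
        self.status = int(status)
        self.dt = dt
        self.period = period
        self.record_stride = record_stride

    @property
    def ok(self) -> bool:
        return self.status == 0

    @property
    def n_beats(self) -> int:
        return self.summaries.shape[0]

    def trace(self, name: str) -> np.ndarray:
        cols = {"t": 0, "V": 1, "Ca_i": 2, "Ca_ss": 3, "I_CaL": 4, "I_rel": 5}
        return self.traces[:, cols[name]]


def initial_state_vector(params: CellParameters | None = None) -> np.ndarray:
    """Reference resting state as a flat vector (fractions for populations)."""
    s = INITIAL_STATE
    y0 = np.zeros(25)
    for i, name in enumerate(
        ["V", "Na_i", "K_i", "Ca_i_free", "Ca_sr_free", "Ca_ss_free",
         "m", "h", "j", "xr1", "xr2", "xs", "r", "s"]
    ):
        y0[i] = s[name]
    y0[14] = 1.0          # all LCC in C
    y0[21] = 0.9          # RyR mostly resting
    y0[23] = 0.1          # remainder resting-inactivated
    return y0


def simulate(
    params: CellParameters,
    mode: str = "deterministic",
    n_lcc: int = 128,
    n_ryr: int | None = None,
    dt: float = 0.001,
    period: float = 1000.0,
    n_beats: int = 5,
    stim_amplitude: float = 52.0,
    stim_duration: float = 1.0,
    seed: int = 0,
    record_stride: int = 0,
    y0: np.ndarray | None = None,
) -> SimulationResult:
    """Run a paced simulation and return per-beat summaries.

    ``record_stride`` > 0 additionally records (t, V, Ca_i, Ca_ss,
    I_CaL, I_rel) every that many steps.  A run that goes numerically
    unstable is returned with ``status`` = 1 rather than raising, so
    sweeps can record the failure and continue.
    """
    if mode not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_ryr is None:
        n_ryr = 5 * n_lcc
    if n_lcc < 1 or n_ryr < 1:
        raise ValueError("channel counts must be >= 1")
    if dt <= 0 or period <= 0 or n_beats < 1:
        raise ValueError("dt, period and n_beats must be positive")
    kp = kernel_params(params)
    if y0 is None:
        y0 = initial_state_vector(params)
    summaries, traces, y_end, status = _run(
        kp,
        1 if mode == "stochastic" else 0,
        n_lcc,
        n_ryr,
        dt,
        period,
        n_beats,
        stim_amplitude,
        stim_duration,
        seed,
        record_stride,
        np.asarray(y0, dtype=np.float64),
        LCC_EDGE_TABLE,
        RYR_EDGE_TABLE,
        *LCC_GROUPED,
        *RYR_GROUPED,
    )
    return SimulationResult(summaries, traces, y_end, status, dt, period, record_stride)
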