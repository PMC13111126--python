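"""Background sodium/potassium membrane currents (reference model, epicardial).

Hodgkin–Huxley formulations adopted unchanged from the ten Tusscher–
Panfilov human ventricular model: fast sodium, inward rectifier,
transient outward, rapid/slow delayed rectifiers, Na/K pump, plateau
potassium and background sodium.  These stay deterministic in both
simulation modes; only the calcium-release machinery is stochastic.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .parameters import BackgroundParameters

__all__ = ["BackgroundCurrents", "gate_steady_states", "background_currents",
           "advance_gates"]

GATE_NAMES = ("m", "h", "j", "xr1", "xr2", "xs", "r", "s")


class BackgroundCurrents(NamedTuple):
    i_na: float
    i_k1: float
    i_to: float
    i_kr: float
    i_ks: float
    i_nak: float
    i_pk: float
    i_bna: float

    @property
    def total(self) -> float:
        return sum(self)


def _m_gate(v):
    m_inf = 1.0 / (1.0 + np.exp((-56.86 - v) / 9.03)) ** 2
    a = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    b = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((v - 50.0) / 200.0))
    return m_inf, a * b


def _h_gate(v):
    h_inf = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
    if v < -40.0:
        a = 0.057 * np.exp(-(v + 80.0) / 6.8)
        b = 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v)
    else:
        a = 0.0
        b = 0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
    return h_inf, 1.0 / (a + b)


def _j_gate(v):
    j_inf = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
    if v < -40.0:
        a = (
            (-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + np.exp(0.311 * (v + 79.23)))
        )
        b = 0.02424 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    else:
        a = 0.0
        b = 0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    return j_inf, 1.0 / (a + b)


def _xr1_gate(v):
    inf = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
    a = 450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
    b = 6.0 / (1.0 + np.exp((v + 30.0) / 11.5))
    return inf, a * b


def _xr2_gate(v):
    inf = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
    a = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
    b = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
    return inf, a * b


def _xs_gate(v):
    inf = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
    a = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))
    b = 1.0 / (1.0 + np.exp((v - 35.0) / 15.0))
    return inf, a * b + 80.0


def _r_gate(v):
    inf = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
    return inf, 9.5 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8


def _s_gate(v):
    inf = 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))
    tau = (
        85.0 * np.exp(-((v + 45.0) ** 2) / 320.0)
        + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0))
        + 3.0
    )
    return inf, tau


_GATES = {
    "m": _m_gate, "h": _h_gate, "j": _j_gate, "xr1": _xr1_gate,
    "xr2": _xr2_gate, "xs": _xs_gate, "r": _r_gate, "s": _s_gate,
}


def gate_steady_states(v: float) -> dict[str, tuple[float, float]]:
    """(x_inf, tau_x) of every background gate at membrane potential ``v``."""
    return {name: fn(v) for name, fn in _GATES.items()}


def advance_gates(
    gates: dict[str, float], v: float, dt: float, rush_larsen: bool = False
) -> dict[str, float]:
    """One time step of every gate; explicit Euler by default.

    ``rush_larsen=True`` uses the exponential update
    x + (x_inf - x)*(1 - exp(-dt/tau)), exact for frozen V.
    """
    out = {}
    for name, x in gates.items():
        inf, tau = _GATES[name](v)
        if rush_larsen:
            out[name] = inf + (x - inf) * np.exp(-dt / tau)
        else:
            out[name] = x + dt * (inf - x) / tau
    return out


def background_currents(
    v: float,
    gates: dict[str, float],
    na_i: float,
    k_i: float,
    params: BackgroundParameters,
) -> BackgroundCurrents:
    """All eight background current densities (pA/pF) at one state point."""
    c = params.constants
    vt = c.vt
    e_na = vt * np.log(params.na_o / na_i)
    e_k = vt * np.log(params.k_o / k_i)
    e_ks = vt * np.log(
        (params.k_o + params.p_kna * params.na_o) / (k_i + params.p_kna * na_i)
    )

    i_na = params.g_na * gates["m"] ** 3 * gates["h"] * gates["j"] * (v - e_na)

    a_k1 = 0.1 / (1.0 + np.exp(0.06 * (v - e_k - 200.0)))
    b_k1 = (
        3.0 * np.exp(0.0002 * (v - e_k + 100.0)) + np.exp(0.1 * (v - e_k - 10.0))
    ) / (1.0 + np.exp(-0.5 * (v - e_k)))
    xk1 = a_k1 / (a_k1 + b_k1)
    i_k1 = params.g_k1 * xk1 * np.sqrt(params.k_o / 5.4) * (v - e_k)

    i_to = params.g_to * gates["r"] * gates["s"] * (v - e_k)
    i_kr = (
        params.g_kr * np.sqrt(params.k_o / 5.4) * gates["xr1"] * gates["xr2"] * (v - e_k)
    )
    i_ks = params.g_ks * gates["xs"] ** 2 * (v - e_ks)

    i_nak = (
        params.p_nak
        * params.k_o
        * na_i
        / (
            (params.k_o + params.km_k)
            * (na_i + params.km_na)
            * (1.0 + 0.1245 * np.exp(-0.1 * v / vt) + 0.0353 * np.exp(-v / vt))
        )
    )
    i_pk = params.g_pk * (v - e_k) / (1.0 + np.exp((25.0 - v) / 5.98))
    i_bna = params.g_bna * (v - e_na)

    out = BackgroundCurrents(i_na, i_k1, i_to, i_kr, i_ks, i_nak, i_pk, i_bna)
    for name, val in zip(out._fields, out):
        if not np.isfinite(val):
            raise FloatingPointError(f"background current {name} non-finite at V={v}")
    return out
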