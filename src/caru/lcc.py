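"""Seven-state Markov scheme of the L-type calcium channel (LCC).

The scheme replaces the reference model's gate product d*f*f2*fCass with
an explicit state diagram so that single channels (and finite channel
populations) can be simulated stochastically::

                                     If2
                                f2- //  f2+
            d+            phi*x7*d+ //        f-
      C  <------>  C'  <----------->  O  <------>  If
            d-              x7*d-      |    f+      |
                                  fca- || fca+      || fca- / fca+
                                       v    f-      v
                                      ICa <------> IfCa
                                            f+

States: C resting closed, C' activated closed, O open conducting,
If / If2 voltage-inactivated (fast / deep), ICa calcium-inactivated,
IfCa doubly (voltage and calcium) inactivated.  The O/If/ICa/IfCa
square is the exact product of the fast voltage-inactivation and
calcium-inactivation gates; the deep branch If2 and the activation
ladder C-C'-O attach to the available corner.

The per-edge rate functions are built from the reference model's gate
kinetics: for a two-state gate with steady state x_inf(V) and time
constant tau_x(V), the forward rate is x_inf/tau_x and the backward rate
(1 - x_inf)/tau_x.  The regulation hooks enter exactly here:

* ``eta`` multiplies the voltage-inactivation on-rates
  f- = eta*(1 - f_inf)/tau_f and f2- = eta*(1 - f2_inf)/tau_f2
  on every edge that carries them,
* ``phi`` multiplies only the opening transition C' -> O = phi*x7*d+.
"""

from __future__ import annotations

import numpy as np

from .engine import RateSpec
from .parameters import LCCParameters

__all__ = [
    "LCC_STATES",
    "lcc_gate_rates",
    "lcc_rates",
    "ical_current",
]

#: State order of the scheme; index 2 is the open state.
LCC_STATES: tuple[str, ...] = ("C", "Cp", "O", "If", "If2", "ICa", "IfCa")
LCC_OPEN: int = LCC_STATES.index("O")


def _dv_gate(v: float) -> tuple[float, float]:
    """Activation gate: steady state and time constant (ms)."""
    d_inf = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
    a = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    b = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    g = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    return d_inf, a * b + g


def _f_gate(v: float) -> tuple[float, float]:
    """Fast voltage-inactivation gate."""
    f_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tau = (
        1102.5 * np.exp(-((v + 27.0) ** 2) / 225.0)
        + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0))
        + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0))
        + 20.0
    )
    return f_inf, tau


def _f2_gate(v: float) -> tuple[float, float]:
    """Deep voltage-inactivation gate."""
    f2_inf = 0.67 / (1.0 + np.exp((v + 35.0) / 7.0)) + 0.33
    tau = (
        562.0 * np.exp(-((v + 27.0) ** 2) / 240.0)
        + 31.0 / (1.0 + np.exp((25.0 - v) / 10.0))
        + 80.0 / (1.0 + np.exp((v + 30.0) / 10.0))
    )
    return f2_inf, tau


def _fca_gate(ca_ss: float) -> tuple[float, float]:
    """Calcium-dependent inactivation gate (driven by subspace calcium)."""
    x = (ca_ss / 0.05) ** 2
    fca_inf = 0.6 / (1.0 + x) + 0.4
    tau = 80.0 / (1.0 + x) + 2.0
    return fca_inf, tau


def lcc_gate_rates(v: float, ca_ss: float, params: LCCParameters) -> dict[str, float]:
    """Elementary per-edge rates (ms^-1) at one operating point.

    Returns d+, d-, f+, f-, f2+, f2-, fca+, fca- with the eta scaling
    already applied to f- and f2-.
    """
    d_inf, tau_d = _dv_gate(v)
    f_inf, tau_f = _f_gate(v)
    f2_inf, tau_f2 = _f2_gate(v)
    fca_inf, tau_fca = _fca_gate(ca_ss)
    return {
        "d+": d_inf / tau_d,
        "d-": (1.0 - d_inf) / tau_d,
        "f+": f_inf / tau_f,
        "f-": params.eta * (1.0 - f_inf) / tau_f,
        "f2+": f2_inf / tau_f2,
        "f2-": params.eta * (1.0 - f2_inf) / tau_f2,
        "fca+": fca_inf / tau_fca,
        "fca-": (1.0 - fca_inf) / tau_fca,
    }


def lcc_rates(v: float, ca_ss: float, params: LCCParameters) -> RateSpec:
    """Full 7-state edge set evaluated at (V, Ca_ss).

    Raises a numeric error naming the offending edge if any rate
    evaluates non-finite.
    """
    g = lcc_gate_rates(v, ca_ss, params)
    edges = [
        ("C", "Cp", g["d+"]),
        ("Cp", "C", g["d-"]),
        ("Cp", "O", params.phi * params.x7 * g["d+"]),
        ("O", "Cp", params.x7 * g["d-"]),
        ("O", "If", g["f-"]),
        ("If", "O", g["f+"]),
        ("O", "If2", g["f2-"]),
        ("If2", "O", g["f2+"]),
        ("O", "ICa", g["fca-"]),
        ("ICa", "O", g["fca+"]),
        ("If", "IfCa", g["fca-"]),
        ("IfCa", "If", g["fca+"]),
        ("ICa", "IfCa", g["f-"]),
        ("IfCa", "ICa", g["f+"]),
        # closed-state voltage inactivation: the f gate runs whether or
        # not the activation ladder is complete (gate independence in
        # the source formulation); recovery returns through O.
        ("Cp", "If", g["f-"]),
    ]
    idx = {s: i for i, s in enumerate(LCC_STATES)}
    for s, t, k in edges:
        if not np.isfinite(k) or k < 0:
            raise FloatingPointError(
                f"LCC rate {s}->{t} evaluated to {k!r} at V={v}, Ca_ss={ca_ss}"
            )
    return RateSpec(
        LCC_STATES,
        edges=np.array([(idx[s], idx[t]) for s, t, _ in edges]),
        rates=np.array([k for _, _, k in edges]),
    )


def ical_current(
    open_fraction: float, v: float, ca_ss: float, params: LCCParameters
) -> float:
    """Whole-cell L-type current density (pA/pF).

    Goldman–Hodgkin–Katz form driven by DV = V - 15 mV:

        I_CaL = O * G * 2F * (0.25*Ca_ss*e^z - Ca_o) * z/(e^z - 1),

    with z = 2*DV*F/(R*T).  ``open_fraction`` is the occupied fraction
    of the open state (count/N in stochastic mode), so the whole-cell
    current is independent of the number of channels by construction.
    The removable singularity at DV = 0 is evaluated by series.
    """
    if not 0.0 <= open_fraction <= 1.0:
        raise ValueError("open_fraction must lie in [0, 1]")
    c = params.constants
    z = 2.0 * (v - 15.0) * c.F / (c.R * c.T)
    if abs(z) < 1e-5:
        zfac = 1.0 - z / 2.0 + z * z / 12.0
    else:
        zfac = z / np.expm1(z)
    g = params.g_cal * params.gain
    return float(
        open_fraction * g * 2.0 * c.F * (0.25 * ca_ss * np.exp(z) - params.ca_o) * zfac
    )
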