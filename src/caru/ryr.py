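"""Four-state ryanodine receptor (RyR2) scheme and the SR release flux.

States: R resting closed, O open conducting, RI resting-inactivated,
I inactivated.  Opening is driven by subspace calcium squared (CICR),
inactivation linearly by subspace calcium (calmodulin-like), and both
calcium-sensitive rates are modulated by the SR load through
``kcasr``::

             k1*Ca_ss^2              k2*Ca_ss
        R  ------------>  O     O  ------------>  I
        R  <------------  O     O  <------------  I
              k3                      k4
        R  ------------>  RI    RI ------------>  I
           k2*Ca_ss                k1*Ca_ss^2
        R  <------------  RI    RI <------------  I
              k4                      k3

with k1 = phi*k1p/kcasr and k2 = k2p*kcasr*gamma.  kcasr decreases with
SR load, so a fuller SR opens channels faster and inactivates them
slower (luminal facilitation).
"""

from __future__ import annotations

import numpy as np

from .engine import RateSpec
from .parameters import RyRParameters

__all__ = ["RYR_STATES", "kcasr", "ryr_rates", "irel_flux"]

#: State order; index 1 is the open state.
RYR_STATES: tuple[str, ...] = ("R", "O", "RI", "I")
RYR_OPEN: int = RYR_STATES.index("O")


def kcasr(ca_sr: float, params: RyRParameters) -> float:
    """SR-load modulation factor, strictly between minsr and maxsr.

    kcasr = maxsr - (maxsr - minsr)/(1 + (EC/Ca_SR)^2): tends to maxsr
    for an empty SR and to minsr for an overloaded one.  Because the
    opening rate carries k1p/kcasr, a fuller SR gates the channel open
    faster.
    """
    if ca_sr <= 0:
        raise ValueError("Ca_SR must be positive")
    return params.maxsr - (params.maxsr - params.minsr) / (
        1.0 + (params.ec / ca_sr) ** 2
    )


def ryr_rates(ca_ss: float, ca_sr: float, params: RyRParameters) -> RateSpec:
    """Full 4-state edge set evaluated at (Ca_ss, Ca_SR)."""
    if ca_ss < 0:
        raise ValueError("Ca_ss must be non-negative")
    kc = kcasr(ca_sr, params)
    if params.kcasr_literal_product:
        k1 = params.phi * params.k1p * kc
    else:
        k1 = params.phi * params.k1p / kc
    k2 = params.k2p * kc * params.gamma
    k_open = k1 * ca_ss**2
    k_inact = k2 * ca_ss
    edges = [
        ("R", "O", k_open),
        ("O", "R", params.k3),
        ("R", "RI", k_inact),
        ("RI", "R", params.k4),
        ("O", "I", k_inact),
        ("I", "O", params.k4),
        ("RI", "I", k_open),
        ("I", "RI", params.k3),
    ]
    idx = {s: i for i, s in enumerate(RYR_STATES)}
    for s, t, k in edges:
        if not np.isfinite(k):
            raise FloatingPointError(
                f"RyR rate {s}->{t} evaluated to {k!r} at "
                f"Ca_ss={ca_ss}, Ca_SR={ca_sr}"
            )
    return RateSpec(
        RYR_STATES,
        edges=np.array([(idx[s], idx[t]) for s, t, _ in edges]),
        rates=np.array([k for _, _, k in edges]),
    )


def irel_flux(
    open_fraction: float, ca_sr: float, ca_ss: float, v_rel: float
) -> float:
    """SR release flux (mM/ms), proportional to the SR-subspace gradient.

    ``open_fraction`` is the occupied fraction of the open state, so the
    whole-cell flux is independent of the number of receptors.
    """
    if not 0.0 <= open_fraction <= 1.0:
        raise ValueError("open_fraction must lie in [0, 1]")
    return float(open_fraction * v_rel * (ca_sr - ca_ss))
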