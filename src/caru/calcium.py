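"""Three-compartment calcium cycling with instantaneous buffering.

Free calcium in cytosol, SR and subsarcolemmal subspace exchanges
through SERCA uptake, SR leak, RyR release, subspace-to-cytosol
transfer, and the sarcolemmal calcium currents (NCX, plasma-membrane
pump, background).  Buffering is an algebraic equilibrium: the model
evolves *total* calcium per compartment and recovers the free
concentration by solving the single-buffer binding relation each step.
"""

from __future__ import annotations

import numpy as np

from .parameters import CalciumParameters

__all__ = [
    "buffered_free",
    "buffered_total",
    "iup",
    "ileak",
    "ixfer",
    "incx",
    "ipca",
    "ibca",
    "calcium_derivatives",
]


def buffered_free(total: float, buf: float, k_buf: float) -> float:
    """Free calcium given total calcium and one instantaneous buffer.

    Solves free + free*Buf/(free + K_buf) = total for the unique
    non-negative root of the quadratic.
    """
    if total < 0:
        raise ValueError("total calcium must be non-negative")
    b = buf + k_buf - total
    return float((-b + np.sqrt(b * b + 4.0 * k_buf * total)) / 2.0)


def buffered_total(free: float, buf: float, k_buf: float) -> float:
    """Forward binding relation: total = free + free*Buf/(free + K_buf)."""
    if free < 0:
        raise ValueError("free calcium must be non-negative")
    return float(free + free * buf / (free + k_buf))


def iup(ca_i_free: float, phi: float, params: CalciumParameters) -> float:
    """SERCA uptake flux (mM/ms), Hill coefficient 2.

    Phosphorylation lowers the effective affinity constant to K_up/phi,
    so a higher phi pumps harder at the same cytosolic calcium.
    """
    if ca_i_free < 0:
        raise ValueError("Ca_i_free must be non-negative")
    if ca_i_free == 0.0:
        return 0.0
    k_eff = params.k_up / phi
    return float(params.v_max_up / (1.0 + (k_eff / ca_i_free) ** 2))


def ileak(ca_sr_free: float, ca_i_free: float, v_leak: float) -> float:
    """Passive SR-to-cytosol leak (mM/ms), linear in the gradient."""
    return float(v_leak * (ca_sr_free - ca_i_free))


def ixfer(ca_ss_free: float, ca_i_free: float, v_xfer: float) -> float:
    """Subspace-to-cytosol diffusive transfer (mM/ms)."""
    return float(v_xfer * (ca_ss_free - ca_i_free))


def incx(v: float, na_i: float, ca_i_free: float, params: CalciumParameters) -> float:
    """Sodium-calcium exchanger current (pA/pF)."""
    c = params.constants
    vt = c.vt
    e1 = np.exp(params.gamma_ncx * v / vt)
    e2 = np.exp((params.gamma_ncx - 1.0) * v / vt)
    num = e1 * na_i**3 * params.ca_o - e2 * params.na_o**3 * ca_i_free * params.alpha_ncx
    den = (
        (params.km_nai**3 + params.na_o**3)
        * (params.km_ca + params.ca_o)
        * (1.0 + params.k_sat * e2)
    )
    out = params.k_naca * num / den
    if not np.isfinite(out):
        raise FloatingPointError(f"I_NaCa non-finite at V={v}")
    return float(out)


def ipca(ca_i_free: float, params: CalciumParameters) -> float:
    """Sarcolemmal calcium pump current (pA/pF), saturating."""
    return float(params.g_pca * ca_i_free / (params.k_pca + ca_i_free))


def ibca(v: float, ca_i_free: float, params: CalciumParameters) -> float:
    """Background calcium current (pA/pF) toward the calcium Nernst potential."""
    c = params.constants
    e_ca = 0.5 * c.vt * np.log(params.ca_o / ca_i_free)
    return float(params.g_bca * (v - e_ca))


def calcium_derivatives(
    ca_i_free: float,
    ca_sr_free: float,
    ca_ss_free: float,
    i_cal: float,
    i_rel: float,
    i_bca: float,
    i_pca: float,
    i_naca: float,
    params: CalciumParameters,
) -> tuple[float, float, float]:
    """Time derivatives of *total* calcium per compartment (mM/ms).

    Internal fluxes cancel in the volume-weighted sum
    V_c*dCa_i + V_sr*dCa_SR + V_ss*dCa_ss, so with the sarcolemmal
    currents zeroed the total cell calcium is conserved exactly; the
    current terms carry the capacitance-to-volume conversion
    C_m/(2*V*F).
    """
    c = params.constants
    up = iup(ca_i_free, params.phi, params)
    leak = ileak(ca_sr_free, ca_i_free, params.v_leak)
    xfer = ixfer(ca_ss_free, ca_i_free, params.v_xfer)
    d_cai = (
        -(i_bca + i_pca - 2.0 * i_naca) * params.c_m / (2.0 * params.v_c * c.F)
        + (params.v_sr / params.v_c) * (leak - up)
        + xfer
    )
    d_casr = up - leak - i_rel
    d_cass = (
        -i_cal * params.c_m / (2.0 * params.v_ss * c.F)
        + (params.v_sr / params.v_ss) * i_rel
        - (params.v_c / params.v_ss) * xfer
    )
    return d_cai, d_casr, d_cass
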