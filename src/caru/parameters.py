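"""Model constants and parameter containers.

Every numeric constant of the model lives here, in one versioned table,
grouped by subsystem.  Three provenance classes are marked per entry:

* ``[RyR table]``   -- printed with the four-state RyR scheme,
* ``[reference]``   -- adopted unchanged from the ten Tusscher--Panfilov
  human ventricular (epicardial) reference model,
* ``[this model]``  -- introduced by this package (Markov-chain LCC
  reconstruction, regulation hooks, numerical controls).

Units are mV, ms, mM, pA/pF throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "PhysicalConstants",
    "LCCParameters",
    "RyRParameters",
    "CalciumParameters",
    "BackgroundParameters",
    "CellParameters",
    "KernelParams",
    "kernel_params",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Gas constant, temperature and Faraday constant.

    The combination R*T/F is the thermal voltage (~26.71 mV at 310 K);
    units follow the reference model (mJ/(mol K), K, C/mmol).
    """

    R: float = 8314.472   # [reference]
    T: float = 310.0      # [reference]
    F: float = 96485.3415  # [reference]

    @property
    def vt(self) -> float:
        """Thermal voltage R*T/F in mV."""
        return self.R * self.T / self.F


@dataclass(frozen=True)
class LCCParameters:
    """Seven-state L-type calcium channel scheme.

    The voltage-dependent activation (d) and inactivation (f, f2) rates
    and the calcium-dependent inactivation (fca) rates are derived from
    the reference model's gate steady states and time constants:
    forward rate = x_inf/tau_x, backward rate = (1 - x_inf)/tau_x.

    ``eta`` multiplies the two voltage-inactivation on-rates
    f- = eta*(1 - f_inf)/tau_f and f2- = eta*(1 - f2_inf)/tau_f2
    (eta < 1: channels stay available longer, i.e. functional
    upregulation; eta > 1: downregulation).  ``phi`` (phosphorylation)
    multiplies only the final opening transition C' -> O = phi*x7*d+.
    """

    g_cal: float = 3.98e-5     # [reference] whole-cell conductance scale
    gain: float = 0.9          # [this model] calibration factor on g_cal
    x7: float = 1.0            # [this model] C'->O opening rate scale
    eta: float = 1.0           # [this model] inactivation-rate regulation
    phi: float = 1.0           # [this model] phosphorylation level
    ca_o: float = 2.0          # [reference] extracellular calcium, mM
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)


@dataclass(frozen=True)
class RyRParameters:
    """Four-state ryanodine receptor scheme with luminal (SR) control.

    kcasr(Ca_SR) = maxsr - (maxsr - minsr)/(1 + (EC/Ca_SR)^2) decreases
    from maxsr (empty SR) to minsr (overloaded SR); the opening rate
    k1 = phi*k1p/kcasr therefore *increases* with SR load (luminal
    facilitation), while the inactivation rate k2 = k2p*kcasr*gamma
    decreases.

    ``k4`` note: the printed value alongside the scheme (1.5e-5 ms^-1)
    gives a ~67 s recovery time constant, which empties the available
    RyR pool within a few 1 Hz beats and abolishes release; the
    reference model's 0.005 ms^-1 is used as the default (see
    docs/methods.md).
    """

    k1p: float = 0.15      # [RyR table] mM^-2 ms^-1
    k2p: float = 0.045     # [RyR table] mM^-1 ms^-1
    k3: float = 0.060      # [RyR table] ms^-1
    k4: float = 0.005      # [reference] ms^-1; printed table value 1.5e-5
    maxsr: float = 2.5     # [RyR table] dimensionless
    minsr: float = 1.0     # [RyR table] dimensionless
    ec: float = 1.5        # [RyR table] mM
    v_rel: float = 0.102   # [reference] mM/ms, whole-cell release scale
    phi: float = 1.0       # [this model] phosphorylation level
    gamma: float = 1.0     # [this model] k2 modulation hook
    kcasr_literal_product: bool = False  # sensitivity switch: k1 = phi*k1p*kcasr


@dataclass(frozen=True)
class CalciumParameters:
    """Three-compartment calcium cycling (cytosol, SR, subspace)."""

    # compartment volumes [reference]
    v_c: float = 0.016404
    v_sr: float = 0.001094
    v_ss: float = 0.00005468
    c_m: float = 0.185          # [reference] membrane capacitance
    # instantaneous buffers [reference]
    buf_c: float = 0.2
    k_buf_c: float = 0.001
    buf_sr: float = 10.0
    k_buf_sr: float = 0.3
    buf_ss: float = 0.4
    k_buf_ss: float = 0.00025
    # SERCA uptake, leak, subspace-cytosol transfer [reference]
    v_max_up: float = 0.006375
    k_up: float = 0.00025
    v_leak: float = 0.00036
    v_xfer: float = 0.0038
    # sarcolemmal calcium handling [reference]
    k_naca: float = 1000.0
    gamma_ncx: float = 0.35
    km_nai: float = 87.5
    km_ca: float = 1.38
    k_sat: float = 0.1
    alpha_ncx: float = 2.5
    g_pca: float = 0.1238
    k_pca: float = 0.0005
    g_bca: float = 0.000592
    na_o: float = 140.0
    ca_o: float = 2.0
    phi: float = 1.0            # [this model] SERCA affinity scaling K_up/phi
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)


@dataclass(frozen=True)
class BackgroundParameters:
    """Sodium/potassium membrane currents of the reference model (epicardial)."""

    g_na: float = 14.838
    g_k1: float = 5.405
    g_to: float = 0.294
    g_kr: float = 0.153
    g_ks: float = 0.392
    g_bna: float = 0.00029
    g_pk: float = 0.0146
    p_nak: float = 2.724
    km_k: float = 1.0
    km_na: float = 40.0
    k_o: float = 5.4
    na_o: float = 140.0
    p_kna: float = 0.03
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)


@dataclass(frozen=True)
class CellParameters:
    """Complete parameter set of the coupled cell model."""

    lcc: LCCParameters = field(default_factory=LCCParameters)
    ryr: RyRParameters = field(default_factory=RyRParameters)
    calcium: CalciumParameters = field(default_factory=CalciumParameters)
    background: BackgroundParameters = field(default_factory=BackgroundParameters)
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def with_scenario(self, phi: float = 1.0, eta: float = 1.0) -> "CellParameters":
        """Return a copy with the two regulation dials applied.

        ``phi`` scales LCC opening, RyR opening and SERCA affinity
        together (a single phosphorylation level); ``eta`` scales the
        LCC voltage-inactivation on-rates.
        """
        if phi <= 0 or eta <= 0:
            raise ValueError("phi and eta must be positive")
        return replace(
            self,
            lcc=replace(self.lcc, phi=phi, eta=eta),
            ryr=replace(self.ryr, phi=phi),
            calcium=replace(self.calcium, phi=phi),
        )


class KernelParams(NamedTuple):
    """Flat scalar bundle consumed by the compiled simulation kernel."""

    # physical
    rr: float
    tt: float
    ff: float
    # LCC
    g_cal: float
    lcc_gain: float
    x7: float
    eta: float
    phi_lcc: float
    ca_o: float
    # RyR
    k1p: float
    k2p: float
    k3: float
    k4: float
    maxsr: float
    minsr: float
    ec: float
    v_rel: float
    phi_ryr: float
    gamma_ryr: float
    kcasr_product: float
    # calcium cycling
    v_c: float
    v_sr: float
    v_ss: float
    c_m: float
    buf_c: float
    k_buf_c: float
    buf_sr: float
    k_buf_sr: float
    buf_ss: float
    k_buf_ss: float
    v_max_up: float
    k_up: float
    v_leak: float
    v_xfer: float
    k_naca: float
    gamma_ncx: float
    km_nai: float
    km_ca: float
    k_sat: float
    alpha_ncx: float
    g_pca: float
    k_pca: float
    g_bca: float
    na_o: float
    phi_up: float
    # background
    g_na: float
    g_k1: float
    g_to: float
    g_kr: float
    g_ks: float
    g_bna: float
    g_pk: float
    p_nak: float
    km_k: float
    km_na: float
    k_o: float
    p_kna: float


def kernel_params(p: CellParameters) -> KernelParams:
    """Flatten a :class:`CellParameters` tree for the compiled kernel."""
    c, l, r, ca, bg = p.constants, p.lcc, p.ryr, p.calcium, p.background
    return KernelParams(
        rr=c.R, tt=c.T, ff=c.F,
        g_cal=l.g_cal, lcc_gain=l.gain, x7=l.x7, eta=l.eta, phi_lcc=l.phi,
        ca_o=l.ca_o,
        k1p=r.k1p, k2p=r.k2p, k3=r.k3, k4=r.k4, maxsr=r.maxsr, minsr=r.minsr,
        ec=r.ec, v_rel=r.v_rel, phi_ryr=r.phi, gamma_ryr=r.gamma,
        kcasr_product=1.0 if r.kcasr_literal_product else 0.0,
        v_c=ca.v_c, v_sr=ca.v_sr, v_ss=ca.v_ss, c_m=ca.c_m,
        buf_c=ca.buf_c, k_buf_c=ca.k_buf_c, buf_sr=ca.buf_sr,
        k_buf_sr=ca.k_buf_sr, buf_ss=ca.buf_ss, k_buf_ss=ca.k_buf_ss,
        v_max_up=ca.v_max_up, k_up=ca.k_up, v_leak=ca.v_leak,
        v_xfer=ca.v_xfer, k_naca=ca.k_naca, gamma_ncx=ca.gamma_ncx,
        km_nai=ca.km_nai, km_ca=ca.km_ca, k_sat=ca.k_sat,
        alpha_ncx=ca.alpha_ncx, g_pca=ca.g_pca, k_pca=ca.k_pca,
        g_bca=ca.g_bca, na_o=ca.na_o, phi_up=ca.phi,
        g_na=bg.g_na, g_k1=bg.g_k1, g_to=bg.g_to, g_kr=bg.g_kr,
        g_ks=bg.g_ks, g_bna=bg.g_bna, g_pk=bg.g_pk, p_nak=bg.p_nak,
        km_k=bg.km_k, km_na=bg.km_na, k_o=bg.k_o, p_kna=bg.p_kna,
    )


#: Reference-model steady state at 1 Hz pacing (epicardial variant),
#: used as the default initial condition; the transient-discard block of
#: the pacing protocol absorbs the remaining adjustment to this model.
INITIAL_STATE = {
    "V": -85.23,
    "Na_i": 8.604,
    "K_i": 136.89,
    "Ca_i_free": 0.000126,
    "Ca_sr_free": 3.64,
    "Ca_ss_free": 0.00036,
    "m": 0.00172,
    "h": 0.7444,
    "j": 0.7045,
    "xr1": 0.000621,
    "xr2": 0.4712,
    "xs": 0.00303,
    "r": 2.42e-8,
    "s": 0.999998,
}
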