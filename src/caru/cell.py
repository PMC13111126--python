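"""Coupled whole-cell model: membrane potential, background currents,
ion bookkeeping, calcium cycling, and the two channel populations.

This module is the readable reference implementation; it advances the
full state with explicit Euler at a shared time step and delegates the
channel populations to the generic Markov-chain engine (tau-leaping in
stochastic mode, the occupancy ODE in deterministic mode).  Long paced
protocols use the compiled kernel in :mod:`caru.kernel`, which
implements the identical update order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import background as bg
from . import calcium as cacyc
from .engine import ChannelPopulation, deterministic_step, tau_leap_step
from .lcc import LCC_STATES, ical_current, lcc_rates
from .parameters import INITIAL_STATE, CellParameters
from .ryr import RYR_STATES, irel_flux, ryr_rates

__all__ = ["CellState", "StimulusConfig", "stimulus", "initial_state", "step"]


@dataclass(frozen=True)
class StimulusConfig:
    """Rectangular pacing pulse: period, amplitude and duration.

    Amplitude is the depolarizing current density in pA/pF entering
    the voltage equation as +I_st (default 52 pA/pF for 1 ms, the
    reference model's pacing stimulus).
    """

    period: float = 1000.0
    amplitude: float = 52.0
    duration: float = 1.0


def stimulus(t: float, config: StimulusConfig) -> float:
    """Pacing current I_st (pA/pF) at absolute time ``t`` (ms)."""
    phase = t % config.period
    return config.amplitude if phase < config.duration else 0.0


@dataclass
class CellState:
    """Full state of the cell at one instant."""

    v: float
    na_i: float
    k_i: float
    ca_i_free: float
    ca_sr_free: float
    ca_ss_free: float
    gates: dict[str, float]
    lcc: ChannelPopulation
    ryr: ChannelPopulation
    t: float = 0.0

    def copy(self) -> "CellState":
        return CellState(
            v=self.v, na_i=self.na_i, k_i=self.k_i,
            ca_i_free=self.ca_i_free, ca_sr_free=self.ca_sr_free,
            ca_ss_free=self.ca_ss_free, gates=dict(self.gates),
            lcc=replace(self.lcc), ryr=replace(self.ryr), t=self.t,
        )


def initial_state(
    mode: str = "deterministic", n_lcc: int = 1, n_ryr: int = 5
) -> CellState:
    """Reference resting state with all LCCs closed and RyRs mostly resting."""
    s = INITIAL_STATE
    gates = {k: s[k] for k in bg.GATE_NAMES}
    if mode == "deterministic":
        lcc_frac = np.zeros(len(LCC_STATES))
        lcc_frac[0] = 1.0
        ryr_frac = np.array([0.9, 0.0, 0.1, 0.0])
        lcc = ChannelPopulation(LCC_STATES, fractions=lcc_frac)
        ryr = ChannelPopulation(RYR_STATES, fractions=ryr_frac)
    elif mode == "stochastic":
        lcc = ChannelPopulation.stochastic_init(LCC_STATES, n_lcc, "C")
        counts = np.zeros(len(RYR_STATES), dtype=np.int64)
        counts[0] = int(round(0.9 * n_ryr))
        counts[2] = n_ryr - counts[0]
        ryr = ChannelPopulation(RYR_STATES, counts=counts, total=n_ryr)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CellState(
        v=s["V"], na_i=s["Na_i"], k_i=s["K_i"],
        ca_i_free=s["Ca_i_free"], ca_sr_free=s["Ca_sr_free"],
        ca_ss_free=s["Ca_ss_free"], gates=gates, lcc=lcc, ryr=ryr,
    )


def step(
    state: CellState,
    params: CellParameters,
    dt: float = 0.001,
    mode: str = "deterministic",
    rng: np.random.Generator | None = None,
    stim: StimulusConfig | None = None,
    rush_larsen: bool = False,
) -> CellState:
    """One full explicit-Euler update of the coupled model.

    Order of operations: rates at the current state -> channel
    populations -> L-type and release fluxes from the *updated* open
    fractions -> calcium compartments -> Na/K -> gates -> V.
    """
    if mode not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "stochastic" and rng is None:
        raise ValueError("stochastic mode needs an rng")
    stim = stim or StimulusConfig()
    ca = params.calcium
    out = state.copy()

    lr = lcc_rates(state.v, state.ca_ss_free, params.lcc)
    rr = ryr_rates(state.ca_ss_free, state.ca_sr_free, params.ryr)
    if mode == "stochastic":
        out.lcc = tau_leap_step(state.lcc, lr, dt, rng)
        out.ryr = tau_leap_step(state.ryr, rr, dt, rng)
    else:
        out.lcc = ChannelPopulation(
            LCC_STATES, fractions=deterministic_step(state.lcc.fractions, lr, dt)
        )
        out.ryr = ChannelPopulation(
            RYR_STATES, fractions=deterministic_step(state.ryr.fractions, rr, dt)
        )

    i_cal = ical_current(out.lcc.occupancy("O"), state.v, state.ca_ss_free, params.lcc)
    i_rel = irel_flux(
        out.ryr.occupancy("O"), state.ca_sr_free, state.ca_ss_free, params.ryr.v_rel
    )

    i_bca = cacyc.ibca(state.v, state.ca_i_free, ca)
    i_pca = cacyc.ipca(state.ca_i_free, ca)
    i_naca = cacyc.incx(state.v, state.na_i, state.ca_i_free, ca)
    d_cai, d_casr, d_cass = cacyc.calcium_derivatives(
        state.ca_i_free, state.ca_sr_free, state.ca_ss_free,
        i_cal, i_rel, i_bca, i_pca, i_naca, ca,
    )
    cai_tot = cacyc.buffered_total(state.ca_i_free, ca.buf_c, ca.k_buf_c) + dt * d_cai
    casr_tot = cacyc.buffered_total(state.ca_sr_free, ca.buf_sr, ca.k_buf_sr) + dt * d_casr
    cass_tot = cacyc.buffered_total(state.ca_ss_free, ca.buf_ss, ca.k_buf_ss) + dt * d_cass
    if min(cai_tot, casr_tot, cass_tot) < 0:
        raise FloatingPointError("negative total calcium -- unstable step")
    out.ca_i_free = cacyc.buffered_free(cai_tot, ca.buf_c, ca.k_buf_c)
    out.ca_sr_free = cacyc.buffered_free(casr_tot, ca.buf_sr, ca.k_buf_sr)
    out.ca_ss_free = cacyc.buffered_free(cass_tot, ca.buf_ss, ca.k_buf_ss)

    cur = bg.background_currents(
        state.v, state.gates, state.na_i, state.k_i, params.background
    )
    i_st = stimulus(state.t, stim)
    conv = ca.c_m / (ca.v_c * params.constants.F)
    out.na_i = state.na_i - dt * conv * (
        cur.i_na + cur.i_bna + 3.0 * cur.i_nak + 3.0 * i_naca
    )
    out.k_i = state.k_i - dt * conv * (
        cur.i_k1 + cur.i_to + cur.i_kr + cur.i_ks - 2.0 * cur.i_nak + cur.i_pk - i_st
    )

    out.gates = bg.advance_gates(state.gates, state.v, dt, rush_larsen)

    i_ion = cur.total + i_cal + i_naca + i_pca + i_bca
    out.v = state.v + dt * (-i_ion + i_st)
    if not np.isfinite(out.v):
        raise FloatingPointError(f"membrane potential diverged at t={state.t}")
    out.t = state.t + dt
    return out
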