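"""Markov-chain population propagation.

Three interchangeable integrators act on a population of identical,
independent channels distributed over the states of a small Markov
scheme:

* :func:`tau_leap_step` -- binomial/multinomial tau-leaping, the
  production stochastic integrator.  For each occupied state the number
  of channels leaving within ``dt`` is binomial with success
  probability ``1 - exp(-k_tot*dt)`` and is partitioned over the
  outgoing transitions proportionally to their rates, so every
  per-transition count is marginally ``Binomial(n, ~1 - exp(-k*dt))``
  while non-negativity and exact channel-number conservation hold by
  construction.
* :func:`ssa_exact` -- an event-by-event Gillespie simulation with
  frozen rates, statistically exact; the validation oracle for the
  tau-leap scheme on small systems.
* :func:`deterministic_step` -- explicit-Euler update of the
  master-equation (mean-field occupancy) ODE, the infinite-population
  limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelPopulation",
    "RateSpec",
    "transition_probability",
    "tau_leap_step",
    "ssa_exact",
    "deterministic_step",
]


@dataclass
class ChannelPopulation:
    """Occupancy of a channel population over a named state set.

    Exactly one of ``counts`` (non-negative integers, stochastic mode)
    or ``fractions`` (reals in [0, 1], deterministic mode) is set.
    """

    state_names: tuple[str, ...]
    counts: np.ndarray | None = None
    fractions: np.ndarray | None = None
    total: int = 0

    def __post_init__(self) -> None:
        self.state_names = tuple(self.state_names)
        if (self.counts is None) == (self.fractions is None):
            raise ValueError("set exactly one of counts or fractions")
        n = len(self.state_names)
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=np.int64)
            if self.counts.shape != (n,):
                raise ValueError("counts shape does not match state set")
            if (self.counts < 0).any():
                raise ValueError("negative channel count")
            tot = int(self.counts.sum())
            if self.total == 0:
                self.total = tot
            elif tot != self.total:
                raise ValueError("counts do not sum to total")
        else:
            self.fractions = np.asarray(self.fractions, dtype=np.float64)
            if self.fractions.shape != (n,):
                raise ValueError("fractions shape does not match state set")
            if (self.fractions < -1e-12).any() or (self.fractions > 1 + 1e-12).any():
                raise ValueError("fractions outside [0, 1]")
            if abs(self.fractions.sum() - 1.0) > 1e-10:
                raise ValueError("fractions do not sum to 1")

    @property
    def stochastic(self) -> bool:
        return self.counts is not None

    def occupancy(self, name: str) -> float:
        """Occupied fraction of one state (count/total or fraction)."""
        i = self.state_names.index(name)
        if self.stochastic:
            return float(self.counts[i]) / self.total
        return float(self.fractions[i])

    @classmethod
    def stochastic_init(cls, state_names, total: int, state: str | int = 0):
        """All ``total`` channels placed in one state."""
        names = tuple(state_names)
        idx = state if isinstance(state, int) else names.index(state)
        counts = np.zeros(len(names), dtype=np.int64)
        counts[idx] = total
        return cls(names, counts=counts, total=total)


@dataclass
class RateSpec:
    """Directed transitions of one scheme at a frozen operating point.

    ``edges`` is an integer (m, 2) array of (source, target) state
    indices; ``rates`` the matching per-ms rate constants.
    """

    state_names: tuple[str, ...]
    edges: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.state_names = tuple(self.state_names)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.rates = np.asarray(self.rates, dtype=np.float64).reshape(-1)
        n = len(self.state_names)
        if self.edges.shape[0] != self.rates.shape[0]:
            raise ValueError("edges and rates length mismatch")
        if (self.edges < 0).any() or (self.edges >= n).any():
            raise ValueError("edge endpoint outside the state set")
        if (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ValueError("self-transitions are not allowed")
        if not np.isfinite(self.rates).all() or (self.rates < 0).any():
            bad = np.flatnonzero(~np.isfinite(self.rates) | (self.rates < 0))
            raise ValueError(f"non-finite or negative rate on edges {bad.tolist()}")

    def rate(self, source: str, target: str) -> float:
        """Rate constant on one named edge (0 if the edge is absent)."""
        s = self.state_names.index(source)
        t = self.state_names.index(target)
        hit = (self.edges[:, 0] == s) & (self.edges[:, 1] == t)
        return float(self.rates[hit].sum())

    def generator_matrix(self) -> np.ndarray:
        """Column-stochastic generator Q with dx/dt = Q @ x."""
        n = len(self.state_names)
        q = np.zeros((n, n))
        for (s, t), k in zip(self.edges, self.rates):
            q[t, s] += k
            q[s, s] -= k
        return q


def transition_probability(k: float, dt: float) -> float:
    """Per-channel success probability 1 - exp(-k*dt) of one transition.

    ``k`` is the transition rate in ms^-1 and ``dt`` the step in ms.
    """
    if k < 0:
        raise ValueError("rate must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return float(-np.expm1(-k * dt))


def tau_leap_step(
    pop: ChannelPopulation,
    rates: RateSpec,
    dt: float,
    rng: np.random.Generator,
) -> ChannelPopulation:
    """Advance a stochastic population by one binomial tau-leap of ``dt`` ms.

    Channel number is conserved exactly and no count can go negative:
    the channels leaving each state are drawn jointly (multinomial over
    the outgoing edges plus "stay"), so the total departures never
    exceed the state's occupancy.
    """
    if not pop.stochastic:
        raise ValueError("tau_leap_step requires a stochastic-mode population")
    if dt <= 0:
        raise ValueError("dt must be positive")
    counts = pop.counts.copy()
    edges, k = rates.edges, rates.rates
    for s in np.unique(edges[:, 0]):
        n = int(pop.counts[s])
        if n == 0:
            continue
        out = np.flatnonzero(edges[:, 0] == s)
        ks = k[out]
        k_tot = ks.sum()
        if k_tot == 0.0:
            continue
        p_leave = transition_probability(k_tot, dt)
        probs = np.append(p_leave * ks / k_tot, 1.0 - p_leave)
        moves = rng.multinomial(n, probs)[:-1]
        counts[s] -= moves.sum()
        np.add.at(counts, edges[out, 1], moves)
    if (counts < 0).any() or counts.sum() != pop.total:  # pragma: no cover
        raise RuntimeError("tau-leap bookkeeping violated conservation")
    return ChannelPopulation(pop.state_names, counts=counts, total=pop.total)


def ssa_exact(
    pop: ChannelPopulation,
    rates: RateSpec,
    t_end: float,
    rng: np.random.Generator,
):
    """Exact stochastic simulation (Gillespie) with frozen rates.

    Returns ``(times, trajectory)`` where ``trajectory[i]`` is the count
    vector after the event at ``times[i]``; index 0 is the initial state
    at t = 0.  Intended for small validation systems only.
    """
    if not pop.stochastic:
        raise ValueError("ssa_exact requires a stochastic-mode population")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    counts = pop.counts.copy()
    edges, k = rates.edges, rates.rates
    times = [0.0]
    traj = [counts.copy()]
    t = 0.0
    while True:
        propensity = k * counts[edges[:, 0]]
        a0 = propensity.sum()
        if a0 <= 0.0:
            break
        t += rng.exponential(1.0 / a0)
        if t >= t_end:
            break
        e = rng.choice(len(k), p=propensity / a0)
        counts[edges[e, 0]] -= 1
        counts[edges[e, 1]] += 1
        times.append(t)
        traj.append(counts.copy())
    return np.asarray(times), np.asarray(traj)


def deterministic_step(
    fractions: np.ndarray,
    rates: RateSpec,
    dt: float,
) -> np.ndarray:
    """Explicit-Euler update of the mean-field occupancy ODE.

    dx_i/dt = sum_j (k_ji x_j - k_ij x_i); the fraction sum is preserved
    to round-off because every term appears once with each sign.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(fractions, dtype=np.float64)
    flow = rates.rates * x[rates.edges[:, 0]]
    dx = np.zeros_like(x)
    np.subtract.at(dx, rates.edges[:, 0], flow)
    np.add.at(dx, rates.edges[:, 1], flow)
    out = x + dt * dx
    if (out < -1e-9).any() or (out > 1 + 1e-9).any():
        raise FloatingPointError(
            "occupancy left [0, 1]; the explicit-Euler step is unstable "
            "at this dt -- reduce dt"
        )
    return out
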