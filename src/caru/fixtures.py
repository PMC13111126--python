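"""Deterministic fixture generator for tests and examples.

Produces (a) a reference one-beat deterministic trace bundle, (b) toy
Markov schemes with analytic solutions attached, and (c) synthetic
per-beat release samples (unimodal, bimodal and pure-sampling-noise
families) for the statistics layer.  Everything is derived from a
single seed; the same seed yields byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import RateSpec
from .kernel import simulate
from .parameters import CellParameters

__all__ = ["toy_two_state", "toy_three_state", "generate_fixtures"]


def toy_two_state(k12: float = 0.3, k21: float = 0.1) -> dict:
    """Two-state scheme A<->B with its analytic equilibrium attached."""
    spec = RateSpec(("A", "B"), edges=[(0, 1), (1, 0)], rates=[k12, k21])
    return {
        "rates": spec,
        "equilibrium": (k21 / (k12 + k21), k12 / (k12 + k21)),
        "relaxation_rate": k12 + k21,
    }


def toy_three_state(k12: float = 0.5, k23: float = 0.2, k31: float = 0.05) -> dict:
    """Irreversible three-state cycle A->B->C->A (no detailed balance)."""
    spec = RateSpec(
        ("A", "B", "C"), edges=[(0, 1), (1, 2), (2, 0)], rates=[k12, k23, k31]
    )
    # stationary occupancy of a cycle is proportional to 1/exit-rate
    w = np.array([1.0 / k12, 1.0 / k23, 1.0 / k31])
    return {"rates": spec, "equilibrium": tuple(w / w.sum())}


def _sbar_families(rng: np.random.Generator) -> dict[str, np.ndarray]:
    unimodal = rng.normal(3.0, 0.15, size=400)
    bimodal = np.concatenate(
        [rng.normal(2.0, 0.1, size=240), rng.normal(4.0, 0.1, size=160)]
    )
    rng.shuffle(bimodal)
    families = {"sbar_unimodal": unimodal, "sbar_bimodal": bimodal}
    # pure sampling noise: dispersion ~ 1/sqrt(N), no sharp collapse
    for n in (16, 32, 64, 128, 256, 512):
        families[f"sbar_noise_n{n}"] = rng.normal(3.0, 1.2 / np.sqrt(n), size=200)
    return families


def generate_fixtures(seed: int = 0, out_dir=None, beat_stride: int = 1000) -> dict:
    """Build the fixture set; optionally write it under ``out_dir``.

    Returns a dict with the toy schemes, the synthetic release-sample
    families, and a one-beat deterministic trace bundle (downsampled by
    ``beat_stride`` steps).
    """
    rng = np.random.default_rng(seed)
    fixtures: dict = {
        "seed": seed,
        "two_state": toy_two_state(),
        "three_state": toy_three_state(),
    }
    fixtures.update(_sbar_families(rng))

    res = simulate(
        CellParameters(), mode="deterministic", n_lcc=1, n_ryr=5,
        n_beats=1, record_stride=beat_stride,
    )
    fixtures["det_beat"] = pd.DataFrame(
        res.traces, columns=["t", "V", "Ca_i", "Ca_ss", "I_CaL", "I_rel"]
    )
    fixtures["det_beat_summary"] = {
        "sbar": float(res.sbar[0]),
        "apd50": float(res.apd50[0]),
        "apd90": float(res.apd90[0]),
        "peak_cai": float(res.peak_cai[0]),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, fx in fixtures.items():
            if isinstance(fx, np.ndarray):
                np.savetxt(out / f"{name}.txt", fx, fmt="%.17g")
            elif isinstance(fx, pd.DataFrame):
                fx.to_csv(out / f"{name}.csv", index=False)
            elif isinstance(fx, dict) and "rates" in fx:
                spec = fx["rates"]
                payload = {
                    "state_names": list(spec.state_names),
                    "edges": spec.edges.tolist(),
                    "rates": spec.rates.tolist(),
                    "equilibrium": list(fx["equilibrium"]),
                }
                if "relaxation_rate" in fx:
                    payload["relaxation_rate"] = fx["relaxation_rate"]
                (out / f"{name}.json").write_text(
                    json.dumps(payload, indent=2, sort_keys=True)
                )
            elif isinstance(fx, dict):
                (out / f"{name}.json").write_text(
                    json.dumps(fx, indent=2, sort_keys=True)
                )
    return fixtures
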