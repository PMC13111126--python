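"""Simulation configuration, result tables and state snapshots.

Configurations are plain YAML mappings validated exhaustively (every
violation is reported, not only the first).  Result tables are tidy
delimited text with a ``#``-prefixed metadata header carrying the
config hash, the seed and per-column units, so every output is
reproducible from its own header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "load_config",
    "save_config",
    "write_results",
    "read_table",
    "write_table",
    "save_snapshot",
    "load_snapshot",
]

_UNITS = {
    "scenario": "-", "mode": "-", "n_lcc": "channels", "ratio": "-",
    "beat": "-", "sbar": "mM", "apd50": "ms", "apd90": "ms",
    "peak_cai": "mM", "diastolic_casr": "mM", "n_beats": "-",
    "mean": "mM", "median": "mM", "q25": "mM", "q75": "mM", "iqr": "mM",
    "rel_dispersion": "-", "det_sbar": "mM",
}


@dataclass
class SimulationConfig:
    """Validated description of one protocol run.

    ``n_lcc`` may be a single channel count or a list (a sweep grid);
    the RyR count is ``ratio * n_lcc`` throughout.  The full-scale
    protocol is 1100 beats with the first 100 discarded; the default
    here is the scaled 60/10 protocol used for desk-sized runs.
    """

    mode: str = "deterministic"
    n_lcc: int | list = 128
    ratio: int = 5
    phi: float = 1.0
    eta: float = 1.0
    dt: float = 0.001
    period: float = 1000.0
    total_beats: int = 60
    discard_beats: int = 10
    seed: int = 0
    stim_amplitude: float = 52.0
    stim_duration: float = 1.0
    record_stride: int = 0
    output_dir: str | None = None
    transition_threshold: float = 2.0

    @property
    def n_lcc_list(self) -> list[int]:
        return list(self.n_lcc) if isinstance(self.n_lcc, (list, tuple)) else [self.n_lcc]

    @property
    def analyzed_beats(self) -> int:
        """Beats retained for analysis after the transient discard."""
        return self.total_beats - self.discard_beats

    @property
    def scenario_name(self) -> str:
        if self.phi == 1.0 and self.eta == 1.0:
            return "control"
        if self.phi != 1.0 and self.eta == 1.0:
            return f"phi={self.phi:g}"
        if self.eta != 1.0 and self.phi == 1.0:
            return f"eta={self.eta:g}"
        return f"phi={self.phi:g},eta={self.eta:g}"

    def validate(self) -> "SimulationConfig":
        """Raise ValueError listing *all* violations, or return self."""
        errors = []
        if self.mode not in ("deterministic", "stochastic"):
            errors.append(f"mode must be deterministic|stochastic, got {self.mode!r}")
        for n in self.n_lcc_list:
            if not isinstance(n, (int, np.integer)) or n < 1:
                errors.append(f"n_lcc entries must be integers >= 1, got {n!r}")
        if self.ratio < 1:
            errors.append(f"ratio must be >= 1, got {self.ratio}")
        if self.phi <= 0:
            errors.append(f"phi must be > 0, got {self.phi}")
        if self.eta <= 0:
            errors.append(f"eta must be > 0, got {self.eta}")
        if self.dt <= 0:
            errors.append(f"dt must be > 0, got {self.dt}")
        if self.period <= 0:
            errors.append(f"period must be > 0, got {self.period}")
        if self.total_beats < 1:
            errors.append(f"total_beats must be >= 1, got {self.total_beats}")
        if self.discard_beats < 0:
            errors.append(f"discard_beats must be >= 0, got {self.discard_beats}")
        if 0 <= self.discard_beats and self.discard_beats >= self.total_beats:
            errors.append(
                f"discard_beats ({self.discard_beats}) must leave at least one "
                f"analyzed beat out of total_beats ({self.total_beats})"
            )
        if self.stim_duration <= 0 or self.stim_duration >= self.period:
            errors.append("stim_duration must lie in (0, period)")
        if self.record_stride < 0:
            errors.append("record_stride must be >= 0")
        if errors:
            raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
        return self

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> SimulationConfig:
    """Read and validate a YAML configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("configuration file must contain a mapping")
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown configuration keys: {', '.join(unknown)}")
    return SimulationConfig(**raw).validate()


def save_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def _metadata_lines(meta: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Tidy CSV with a '#'-prefixed metadata header (units per column)."""
    meta = dict(metadata or {})
    meta.setdefault(
        "units", " ".join(f"{c}={_UNITS.get(c, '?')}" for c in df.columns)
    )
    with open(path, "w") as fh:
        fh.write(_metadata_lines(meta))
        df.to_csv(fh, index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read back a table written by :func:`write_table`."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta


def write_results(result, out_dir, downsample: int = 1) -> dict[str, Path]:
    """Write a SweepResult as tidy tables; returns the written paths.

    ``downsample`` records the trace downsampling factor in the
    metadata of every file (1 = full resolution of what was recorded).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    meta = {
        "config_hash": cfg.hash() if cfg is not None else "none",
        "seed": cfg.seed if cfg is not None else "none",
        "downsample": downsample,
    }
    paths = {}
    for name, df in (
        ("beats", result.beats),
        ("summary", result.summary),
        ("deterministic", result.deterministic),
    ):
        p = out / f"{name}.csv"
        write_table(df, p, meta)
        paths[name] = p
    if cfg is not None:
        save_config(cfg, out / "config.yaml")
        paths["config"] = out / "config.yaml"
    return paths


def save_snapshot(y: np.ndarray, path, metadata: dict | None = None) -> None:
    """Columnar text snapshot of a cell state vector for restarts."""
    from .kernel import STATE_FIELDS

    y = np.asarray(y, dtype=float)
    if y.shape != (len(STATE_FIELDS),):
        raise ValueError(f"state vector must have {len(STATE_FIELDS)} entries")
    with open(path, "w") as fh:
        fh.write(_metadata_lines(metadata or {}))
        for name, val in zip(STATE_FIELDS, y):
            fh.write(f"{name}\t{float(val)!r}\n")


def load_snapshot(path) -> np.ndarray:
    from .kernel import STATE_FIELDS

    values = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            name, val = line.split("\t")
            values[name] = float(val)
    missing = [f for f in STATE_FIELDS if f not in values]
    if missing:
        raise ValueError(f"snapshot missing fields: {missing}")
    return np.array([values[f] for f in STATE_FIELDS])
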