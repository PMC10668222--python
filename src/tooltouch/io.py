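"""File I/O, configuration, and seed handling for the pipeline.

One canonical trials CSV schema is shared by the synthetic generator and any
externally supplied data mapped onto it:

    participant, task, location_cm, trial, raw_response, response_units

with task in {image, space} and response_units in {px, cm}.  All internal
computation is in percent of tool space.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("tooltouch")

TRIALS_COLUMNS = ["participant", "task", "location_cm", "trial", "raw_response", "response_units"]
VALID_TASKS = {"image", "space"}


class SchemaError(ValueError):
    """A trials table does not match the documented schema."""


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trials CSV.

    Raises :class:`SchemaError` naming the offending columns/rows; an empty
    file yields an empty frame with a warning.
    """
    df = pd.read_csv(path)
    if df.empty:
        log.warning("trials file %s is empty", path)
        return pd.DataFrame(columns=TRIALS_COLUMNS)
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trials file {path} missing columns: {missing}")
    bad_task = df[~df["task"].isin(VALID_TASKS)]
    if len(bad_task):
        raise SchemaError(
            f"unknown task label(s) {sorted(bad_task['task'].unique())} at rows {bad_task.index.tolist()[:10]}"
        )
    for col in ("location_cm", "raw_response"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[vals.isna()]
        if len(bad):
            raise SchemaError(f"non-numeric {col} at rows {bad.index.tolist()[:10]}")
        df[col] = vals
    if not np.all(np.isfinite(df["raw_response"])):
        raise SchemaError("non-finite raw_response values")
    return df[TRIALS_COLUMNS]


def write_atomic(path, writer) -> None:
    """Write a file atomically: write to a temp file, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_csv(path, df: pd.DataFrame) -> None:
    write_atomic(path, lambda tmp: df.to_csv(tmp, index=False, float_format="%.10g"))


def write_json(path, obj: Any) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    write_atomic(path, lambda tmp: Path(tmp).write_text(json.dumps(obj, indent=2, default=_default) + "\n"))


@dataclass
class RunConfig:
    """Run-level configuration: seed, run sizes, and parameter overrides.

    ``network``, ``design``, ``priors`` hold keyword overrides applied to the
    corresponding dataclass defaults.  Round-trips losslessly through YAML
    and JSON.
    """

    seed: Optional[int] = None
    n_runs: int = 5000
    network: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def dump(self, path) -> None:
        write_atomic(path, lambda tmp: Path(tmp).write_text(yaml.safe_dump(asdict(self), sort_keys=True)))

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def require_seed(seed: Optional[int], allow_unseeded: bool = False) -> Optional[int]:
    """Enforce the everything-seeded contract for stochastic commands."""
    if seed is None and not allow_unseeded:
        raise ValueError("stochastic run requires --seed (or an explicit no-seed opt-out)")
    return seed
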