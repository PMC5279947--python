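"""Configuration loading, CSV serialization and run manifests.

CSV is the single tabular interchange format; the recordings this package
analyzes exist only as summary tables, so no binary electrophysiology
container is emulated.  All writers are deterministic: re-running a
command with the same config and seed reproduces byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .ephys import SWEEP_COLUMNS, EventTrain
from .model import Trajectory
from .params import GeneratorConfig, ModelParams

__all__ = [
    "load_config",
    "read_sweeps",
    "write_sweeps",
    "read_event_trains",
    "write_event_trains",
    "write_trajectories",
    "write_ratio",
    "write_manifest",
]

log = logging.getLogger("synredist")

_FLOAT_FMT = "%.10g"

EVENT_COLUMNS = ("cell_id", "group", "duration_s", "time_s", "amplitude_pa")


def load_config(path: str | Path, kind: str = "model") -> ModelParams | GeneratorConfig:
    """Load a flat key-value config file (JSON or YAML) into typed params.

    ``kind`` selects the target type (``model`` or ``generator``).  An
    empty file yields all defaults; unknown keys raise ``ValueError``.
    Every resolved parameter is echoed at INFO level for provenance.
    """
    text = Path(path).read_text()
    data: Any = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    if kind == "model":
        params: ModelParams | GeneratorConfig = ModelParams.from_mapping(data)
    elif kind == "generator":
        params = GeneratorConfig.from_mapping(data)
    else:
        raise ValueError(f"unknown config kind {kind!r}")
    for key, value in params.to_dict().items():
        log.info("config %s = %r", key, value)
    return params


def read_sweeps(path: str | Path) -> pd.DataFrame:
    """Read a sweep table CSV; normalizes signs and the saturated flag."""
    df = pd.read_csv(path)
    missing = set(SWEEP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(sorted(missing))}")
    for col in ("stimulus_v", "fv_uv", "fepsp_slope", "epsc_pa"):
        df[col] = df[col].astype(float)
    for col in ("fv_uv", "fepsp_slope", "epsc_pa"):
        df[col] = df[col].abs()  # magnitudes: inward currents reported positive
    df["saturated"] = df["saturated"].astype(bool)
    return df[list(SWEEP_COLUMNS)]


def write_sweeps(sweeps: pd.DataFrame, path: str | Path) -> None:
    sweeps.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_event_trains(
    trains: Iterable[EventTrain], group: str, path: str | Path
) -> None:
    """Write event trains as long-form CSV (one row per event).

    A cell with no events is declared by a single row with blank
    ``time_s``/``amplitude_pa`` so its duration still enters frequency
    estimates.
    """
    records = []
    for tr in trains:
        if len(tr) == 0:
            records.append((tr.cell_id, group, tr.duration, np.nan, np.nan))
        for t, a in zip(tr.times, tr.amplitudes):
            records.append((tr.cell_id, group, tr.duration, t, a))
    pd.DataFrame(records, columns=list(EVENT_COLUMNS)).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_event_trains(path: str | Path) -> list[EventTrain]:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(sorted(missing))}")
    trains = []
    for cell_id, cell in df.groupby("cell_id", sort=True):
        events = cell.dropna(subset=["time_s"]).sort_values("time_s")
        trains.append(
            EventTrain(
                cell_id=str(cell_id),
                duration=float(cell["duration_s"].iloc[0]),
                times=events["time_s"].to_numpy(dtype=float),
                amplitudes=events["amplitude_pa"].to_numpy(dtype=float),
            )
        )
    return trains


def write_trajectories(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    frame = pd.concat([t.to_frame() for t in trajectories], ignore_index=True)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_ratio(ratio: pd.DataFrame, path: str | Path) -> None:
    ratio.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: Mapping[str, Any],
    outputs: Iterable[str | Path],
    seed: int | None = None,
) -> Path:
    """Write a run manifest (command, config digest, seed, outputs) next to outputs."""
    digest = hashlib.sha256(
        json.dumps(dict(config), sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "command": command,
        "config_hash": digest,
        "seed": seed,
        "outputs": [str(p) for p in outputs],
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
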