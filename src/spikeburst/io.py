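"""Readers and writers for the tabular formats the pipeline touches.

Spike tables are TSV (unit_id, spike_time_s); phy-style sorter directories
hold ``spike_times.npy`` (sample indices), ``spike_clusters.npy`` and a
``params.py`` declaring ``sample_rate``. Event tables are TSV (label,
onset_s, duration_s, extra columns preserved as attributes); behaviour logs
are CSV (animal, day, trial, colour, licks, rewarded). All writers round
times to microsecond precision, and write/read round-trips reproduce the
objects exactly at that precision.
"""
from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd
import yaml

from .core import BehaviorSession, EventSeries, SpikeTrainSet

__all__ = [
    "load_spike_data",
    "write_spike_data",
    "load_events",
    "write_events",
    "load_behavior_log",
    "write_behavior_log",
    "write_results",
    "read_results",
    "load_config",
    "save_config",
]

log = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE = 30_000.0  # Hz, typical extracellular acquisition rate
_TIME_FMT = "%.6f"  # microsecond precision


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")


def load_spike_data(
    path,
    dialect: str = "table",
    sample_rate: float = None,
    t_start: float = None,
    t_stop: float = None,
) -> SpikeTrainSet:
    """Load spike-sorted unit data.

    ``dialect='table'``: TSV with columns unit_id, spike_time_s.
    ``dialect='phy_dir'``: directory with spike_times.npy (sample indices),
    spike_clusters.npy and params.py (``sample_rate = ...``); units declared
    in cluster_group.tsv are retained even with zero spikes. Times are sorted
    per unit on load; collapsed duplicates are counted and logged.
    """
    path = Path(path)
    if dialect == "table":
        df = pd.read_csv(path, sep="\t")
        _require_columns(df, ["unit_id", "spike_time_s"], path)
        spikes = {
            uid: grp["spike_time_s"].to_numpy(dtype=float)
            for uid, grp in df.groupby("unit_id", sort=True)
        }
    elif dialect == "phy_dir":
        times_path = path / "spike_times.npy"
        clusters_path = path / "spike_clusters.npy"
        samples = np.load(times_path).ravel()
        clusters = np.load(clusters_path).ravel()
        if samples.size != clusters.size:
            raise ValueError(
                f"{path}: spike_times.npy has {samples.size} entries but "
                f"spike_clusters.npy has {clusters.size}"
            )
        if sample_rate is None:
            sample_rate = _read_phy_sample_rate(path / "params.py")
        spikes = {}
        group_file = path / "cluster_group.tsv"
        if group_file.exists():
            groups = pd.read_csv(group_file, sep="\t")
            _require_columns(groups, ["cluster_id"], group_file)
            for cid in groups["cluster_id"]:
                spikes[int(cid)] = np.empty(0)
        for cid in np.unique(clusters):
            spikes[int(cid)] = samples[clusters == cid] / sample_rate
    else:
        raise ValueError(
            f"unknown dialect {dialect!r}; supported: 'table', 'phy_dir'"
        )

    n_raw = sum(np.asarray(v).size for v in spikes.values())
    all_times = np.concatenate([np.asarray(v, dtype=float) for v in spikes.values()]) \
        if spikes else np.empty(0)
    lo = 0.0 if t_start is None else t_start
    hi = t_stop if t_stop is not None else (
        float(all_times.max()) if all_times.size else 1.0
    )
    if hi <= lo:
        hi = lo + 1.0
    sts = SpikeTrainSet(spikes, lo, hi, meta={"source": str(path)})
    dropped = n_raw - sts.n_spikes()
    if dropped:
        log.info("collapsed %d duplicate spike times on load from %s", dropped, path)
    return sts


def _read_phy_sample_rate(params_path: Path) -> float:
    if not params_path.exists():
        log.warning("%s not found; assuming %.0f Hz", params_path,
                    DEFAULT_SAMPLE_RATE)
        return DEFAULT_SAMPLE_RATE
    text = params_path.read_text()
    match = re.search(r"sample_rate\s*=\s*([0-9.eE+]+)", text)
    if match is None:
        raise ValueError(f"{params_path}: no sample_rate declaration found")
    return float(match.group(1))


def write_spike_data(spikes: SpikeTrainSet, path) -> Path:
    """Write a spike table as TSV (unit_id, spike_time_s)."""
    path = Path(path)
    rows = [
        (uid, float(_TIME_FMT % t))
        for uid, times in spikes.spikes.items()
        for t in times
    ]
    df = pd.DataFrame(rows, columns=["unit_id", "spike_time_s"])
    df.to_csv(path, sep="\t", index=False, float_format=_TIME_FMT)
    return path


def load_events(path, label: str = None) -> EventSeries:
    """Load an event table (TSV: label, onset_s, duration_s).

    Unknown columns are preserved as per-event attributes. Pass ``label`` to
    select one label from a mixed file; a mixed file without a filter is an
    error. Non-monotone onsets fail naming the first offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["label", "onset_s", "duration_s"], path)
    if label is not None:
        df = df[df["label"] == label]
    labels = df["label"].unique()
    if len(labels) > 1:
        raise ValueError(
            f"{path}: multiple event labels {sorted(labels)}; pass label= to select"
        )
    onsets = df["onset_s"].to_numpy(dtype=float)
    if onsets.size > 1 and np.any(np.diff(onsets) < 0):
        row = int(np.argmax(np.diff(onsets) < 0)) + 1
        raise ValueError(f"{path}: onsets not ascending at data row {row}")
    extra = {
        c: df[c].to_numpy()
        for c in df.columns
        if c not in {"label", "onset_s", "duration_s"}
    }
    name = str(labels[0]) if len(labels) else (label or "custom")
    return EventSeries(name, onsets, df["duration_s"].to_numpy(dtype=float), extra)


def write_events(events: EventSeries, path) -> Path:
    """Write an event table as TSV; attributes become extra columns."""
    path = Path(path)
    df = pd.DataFrame({
        "label": events.label,
        "onset_s": np.round(events.onsets, 6),
        "duration_s": np.round(events.durations, 6),
    })
    for key, col in events.attributes.items():
        df[key] = col
    df.to_csv(path, sep="\t", index=False, float_format=_TIME_FMT)
    return path


def load_behavior_log(path) -> List[BehaviorSession]:
    """Load a behaviour CSV (animal, day, trial, colour, licks, rewarded).

    Returns one BehaviorSession per (animal, day), ordered by animal then day.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["animal", "day", "trial", "colour", "licks", "rewarded"],
                     path)
    sessions = []
    for (animal, day), grp in df.groupby(["animal", "day"], sort=True):
        trials = grp.sort_values("trial")[["trial", "colour", "licks", "rewarded"]]
        trials = trials.reset_index(drop=True).astype(
            {"colour": int, "licks": int, "rewarded": bool}
        )
        sessions.append(BehaviorSession(str(animal), int(day), trials))
    return sessions


def write_behavior_log(sessions: Iterable[BehaviorSession], path) -> Path:
    """Write sessions to one behaviour CSV."""
    path = Path(path)
    frames = []
    for s in sessions:
        df = s.trials.copy()
        if "trial" not in df.columns:
            df.insert(0, "trial", np.arange(len(df)))
        df.insert(0, "day", s.day)
        df.insert(0, "animal", s.animal)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(results: dict, out_dir) -> Path:
    """Write a results mapping to ``results.json`` under ``out_dir``.

    DataFrames are written as sibling TSV files and referenced by filename.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {}
    for key, value in results.items():
        if isinstance(value, pd.DataFrame):
            fname = f"{key}.tsv"
            value.to_csv(out_dir / fname, sep="\t", index=False,
                         float_format=_TIME_FMT)
            payload[key] = {"_table": fname}
        else:
            payload[key] = _jsonable(value)
    target = out_dir / "results.json"
    target.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return target


def read_results(out_dir) -> dict:
    """Inverse of :func:`write_results`."""
    out_dir = Path(out_dir)
    payload = json.loads((out_dir / "results.json").read_text())
    for key, value in payload.items():
        if isinstance(value, dict) and set(value) == {"_table"}:
            payload[key] = pd.read_csv(out_dir / value["_table"], sep="\t")
    return payload


CONFIG_SCHEMA_VERSION = 1


def save_config(config: dict, path) -> Path:
    """Write a config mapping as versioned YAML."""
    path = Path(path)
    body = {"schema_version": CONFIG_SCHEMA_VERSION, **_jsonable(config)}
    path.write_text(yaml.safe_dump(body, sort_keys=False))
    return path


def load_config(path) -> dict:
    """Read a versioned YAML config written by :func:`save_config`."""
    path = Path(path)
    body = yaml.safe_load(path.read_text())
    version = body.pop("schema_version", None)
    if version != CONFIG_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unsupported config schema version {version!r} "
            f"(expected {CONFIG_SCHEMA_VERSION})"
        )
    return body
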