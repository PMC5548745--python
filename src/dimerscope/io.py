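"""Plain-text readers and writers: TSV tables with JSON sidecars.

Traces, correlation curves and FRAP records are stored as tab-separated
tables next to a `<name>.json` sidecar carrying sampling metadata and full
provenance (tool version, seed, generating parameters). Round-tripping
preserves values to the documented float precision (repr-exact for counts,
17 significant digits for floats).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ffs_sim import IntensityTrace
from .correlate import CorrelationCurve
from .frap_analysis import FrapChannel, FrapRecord

__all__ = [
    "read_trace", "write_trace",
    "read_curve", "write_curve",
    "read_frap", "write_frap",
    "config_hash",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(config) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    canon = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_sidecar(path: Path, payload: dict):
    payload = dict(payload)
    payload["tool_version"] = __version__
    _sidecar_path(path).write_text(json.dumps(_jsonable(payload), indent=1))


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    return json.loads(sc.read_text()) if sc.exists() else {}


# ---------------------------------------------------------------------------
# Intensity traces
# ---------------------------------------------------------------------------

def write_trace(trace: IntensityTrace, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "time_s": np.round(trace.time, 9),
        "counts_green": trace.counts_green,
        "counts_red": trace.counts_red,
    })
    df.to_csv(path, sep="\t", index=False)
    _write_sidecar(path, {"dt": trace.dt, "duration": trace.duration,
                          **trace.metadata})
    return path


def read_trace(path) -> IntensityTrace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", "counts_green", "counts_red"):
        if col not in df.columns:
            raise ValueError(f"trace file {path} missing column {col!r}")
    t = df["time_s"].to_numpy()
    if len(t) >= 2:
        steps = np.diff(t)
        if np.any(steps <= 0):
            bad = int(np.argmax(steps <= 0)) + 2
            raise ValueError(f"trace file {path}: non-increasing time at "
                             f"line {bad}")
        dt = float(np.median(steps))
    else:
        dt = float(_read_sidecar(path).get("dt", 1.0))
    meta = _read_sidecar(path)
    dt = float(meta.get("dt", dt))
    return IntensityTrace(
        dt=dt,
        counts_green=df["counts_green"].to_numpy(dtype=np.int64),
        counts_red=df["counts_red"].to_numpy(dtype=np.int64),
        metadata=meta)


# ---------------------------------------------------------------------------
# Correlation curves
# ---------------------------------------------------------------------------

def write_curve(curve: CorrelationCurve, path) -> Path:
    path = Path(path)
    data = {"lag_s": curve.lags, "G_minus_1": curve.values,
            "pair": curve.pair, "n_samples": curve.n_samples}
    if curve.sd is not None:
        data["sd"] = curve.sd
    pd.DataFrame(data).to_csv(path, sep="\t", index=False,
                              float_format="%.17g")
    _write_sidecar(path, dict(curve.metadata))
    return path


def read_curve(path) -> CorrelationCurve:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("lag_s", "G_minus_1", "pair"):
        if col not in df.columns:
            raise ValueError(f"curve file {path} missing column {col!r}")
    pairs = df["pair"].unique()
    if len(pairs) != 1:
        raise ValueError(f"curve file {path} must contain exactly one pair "
                         f"label, found {list(pairs)}")
    sd = df["sd"].to_numpy() if "sd" in df.columns else None
    n = (df["n_samples"].to_numpy() if "n_samples" in df.columns
         else np.ones(len(df), dtype=int))
    return CorrelationCurve(str(pairs[0]), df["lag_s"].to_numpy(),
                            df["G_minus_1"].to_numpy(), n, sd,
                            metadata=_read_sidecar(path))


# ---------------------------------------------------------------------------
# FRAP records
# ---------------------------------------------------------------------------

def write_frap(record: FrapRecord, path) -> Path:
    path = Path(path)
    frames = []
    for name, ch in record.channels.items():
        frames.append(pd.DataFrame({
            "time_s": record.time_s, "channel": name, "roi": ch.roi,
            "reference": ch.reference, "background": ch.background}))
    pd.concat(frames).to_csv(path, sep="\t", index=False,
                             float_format="%.17g")
    _write_sidecar(path, {
        "bleach_time_s": float(record.time_s[record.bleach_index]),
        "bleach_index": record.bleach_index,
        "condition": record.condition,
        "roi_size_um": record.roi_size_um,
        **record.metadata})
    return path


def read_frap(path) -> FrapRecord:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", "channel", "roi", "reference", "background"):
        if col not in df.columns:
            raise ValueError(f"FRAP file {path} missing column {col!r}")
    meta = _read_sidecar(path)
    channels = {}
    time = None
    for name, sub in df.groupby("channel", sort=False):
        t = sub["time_s"].to_numpy()
        if time is None:
            time = t
        elif len(t) != len(time) or not np.allclose(t, time):
            raise ValueError(f"FRAP file {path}: channel time grids differ")
        channels[str(name)] = FrapChannel(sub["roi"].to_numpy(),
                                          sub["reference"].to_numpy(),
                                          sub["background"].to_numpy())
    if "bleach_index" in meta:
        bleach_index = int(meta["bleach_index"])
    elif "bleach_time_s" in meta:
        bleach_index = int(np.searchsorted(time, float(meta["bleach_time_s"])))
    else:
        raise ValueError(f"FRAP file {path}: sidecar lacks bleach annotation")
    return FrapRecord(time, channels, bleach_index,
                      condition=str(meta.get("condition", "")),
                      roi_size_um=float(meta.get("roi_size_um", 1.8)),
                      metadata=meta)
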