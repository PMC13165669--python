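"""Delimited-text segment store shared by all pipeline stages.

Layout: one directory per subject; each segment is a CSV
(columns ``t,i,q,x,ecg`` plus any derived columns ``x_rec``, ``x_card``,
``ecg_clean``) with a JSON sidecar holding subject, scenario, sampling rate
and the generator's ground-truth R-peak times.  A dataset-level
``manifest.json`` lists every segment, the scenario table and the radar
configuration, so a store round-trips losslessly (floats are written with 17
significant digits).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import (RadarEcgDataset, RadarSimConfig, ScenarioSpec,
                        SignalSegment)

__all__ = ["FormatError", "write_segment_store", "read_segment_store"]

_DERIVED = ("x_rec", "x_card", "ecg_clean")


class FormatError(ValueError):
    """Segment store file is missing, malformed or inconsistent."""


def _seg_frame(seg: SignalSegment) -> pd.DataFrame:
    cols = {"t": seg.t, "i": seg.i_chan, "q": seg.q_chan,
            "x": seg.displacement, "ecg": seg.ecg}
    for name in _DERIVED:
        v = getattr(seg, name)
        if v is not None:
            cols[name] = v
    return pd.DataFrame(cols)


def write_segment_store(dataset: RadarEcgDataset, path) -> None:
    """Write a dataset to ``path`` (created if needed), ordered by subject."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    entries = []
    counters: dict[str, int] = {}
    for seg in dataset.segments:
        k = counters.get(seg.subject_id, 0)
        counters[seg.subject_id] = k + 1
        sub = root / seg.subject_id
        sub.mkdir(exist_ok=True)
        rel_csv = f"{seg.subject_id}/seg{k:04d}.csv"
        rel_json = f"{seg.subject_id}/seg{k:04d}.json"
        _seg_frame(seg).to_csv(root / rel_csv, index=False,
                               float_format="%.17g")
        sidecar = {"subject_id": seg.subject_id, "scenario": seg.scenario,
                   "fs": dataset.radar_config.fs, "seed": dataset.seed,
                   "r_peak_times": [float(t) for t in seg.r_peak_times]}
        (root / rel_json).write_text(json.dumps(sidecar, indent=1))
        entries.append({"subject_id": seg.subject_id, "scenario": seg.scenario,
                        "data": rel_csv, "sidecar": rel_json})
    manifest = {
        "n_segments": len(entries),
        "segment_len": dataset.radar_config.segment_len,
        "seed": dataset.seed,
        "radar_config": dataclasses.asdict(dataset.radar_config),
        "scenarios": [dataclasses.asdict(s) for s in dataset.scenarios],
        "segments": entries,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_segment_store(path) -> RadarEcgDataset:
    """Read a dataset, validating the manifest and every segment file."""
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise FormatError(f"manifest not found: {mpath}")
    manifest = json.loads(mpath.read_text())
    cfg = RadarSimConfig(**manifest["radar_config"])
    scenarios = [ScenarioSpec(**d) for d in manifest["scenarios"]]
    seg_len = int(manifest["segment_len"])
    segments = []
    for entry in manifest["segments"]:
        csv_path = root / entry["data"]
        json_path = root / entry["sidecar"]
        for p in (csv_path, json_path):
            if not p.exists():
                raise FormatError(f"manifest references missing file: {p}")
        df = pd.read_csv(csv_path, float_precision="round_trip")
        for col in ("t", "i", "q", "x", "ecg"):
            if col not in df.columns:
                raise FormatError(f"{csv_path}: missing column {col!r}")
        if len(df) != seg_len:
            raise FormatError(
                f"{csv_path}: expected {seg_len} rows, found {len(df)}")
        side = json.loads(json_path.read_text())
        if side["subject_id"] != entry["subject_id"]:
            raise FormatError(f"{json_path}: subject mismatch with manifest")
        seg = SignalSegment(
            subject_id=side["subject_id"], scenario=side["scenario"],
            t=df["t"].to_numpy(), i_chan=df["i"].to_numpy(),
            q_chan=df["q"].to_numpy(), displacement=df["x"].to_numpy(),
            ecg=df["ecg"].to_numpy(),
            r_peak_times=np.asarray(side["r_peak_times"], dtype=float))
        for name in _DERIVED:
            if name in df.columns:
                setattr(seg, name, df[name].to_numpy())
        segments.append(seg)
    segments.sort(key=lambda s: s.subject_id)
    return RadarEcgDataset(segments, scenarios, cfg, manifest.get("seed"))
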