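"""File adapters: plain CSV/TSV/JSON, UTF-8, '.' decimal, seconds.

Formats
-------
ECoG: CSV with a ``time_s`` column plus one column per channel, and a JSON
sidecar (same stem, ``.json``) with ``fs`` and ``channels``.
Spikes: CSV ``time_s, unit_id, label`` with label CS/SS (case-insensitive
on read, canonicalized to upper case).
Episodes: JSON (full spike times) and a BED-like TSV ``start, end,
n_spikes, median_interval``.
Ca2+ traces: CSV ``frame_time_s`` plus one column per ROI.
Ground truth and results: JSON.

Every writer/reader pair round-trips losslessly for the synthetic bundles.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calcium import CalciumTrace
from .gswd import EcogRecording, GswdEpisode
from .trains import LabeledSpikeTrain

FLOAT_FMT = "%.9g"


def write_ecog(rec: EcogRecording, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": rec.times})
    for i, name in enumerate(rec.channel_names):
        df[name] = rec.data[:, i]
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    meta = {"fs": rec.fs, "channels": rec.channel_names}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_ecog(path: str | Path) -> EcogRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    missing = [c for c in meta["channels"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing channel columns {missing}")
    data = df[meta["channels"]].to_numpy(dtype=float)
    return EcogRecording(fs=float(meta["fs"]), data=data, channel_names=list(meta["channels"]))


def write_spikes(trains: list[LabeledSpikeTrain], path: str | Path) -> None:
    rows = []
    for tr in trains:
        for t, lab in zip(tr.times, tr.labels):
            rows.append((t, tr.unit_id, lab))
    df = pd.DataFrame(rows, columns=["time_s", "unit_id", "label"])
    df.to_csv(Path(path), index=False, float_format=FLOAT_FMT)


def read_spikes(path: str | Path, duration: float | None = None) -> list[LabeledSpikeTrain]:
    df = pd.read_csv(Path(path))
    for col in ("time_s", "unit_id", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    labels = df["label"].astype(str).str.strip().str.upper()
    bad = df.index[~labels.isin(["CS", "SS"])]
    if len(bad):
        raise ValueError(f"{path}: unknown label {df['label'][bad[0]]!r} at row {int(bad[0]) + 2}")
    if df["time_s"].isna().any():
        row = int(df.index[df["time_s"].isna()][0]) + 2
        raise ValueError(f"{path}: malformed time at row {row}")
    df = df.assign(label=labels)
    trains = []
    for unit, g in df.groupby("unit_id", sort=True):
        g = g.sort_values("time_s", kind="stable")
        times = g["time_s"].to_numpy(dtype=float)
        dur = duration if duration is not None else (float(times[-1]) if times.size else 0.0)
        trains.append(
            LabeledSpikeTrain(times=times, labels=g["label"].to_numpy(), duration=dur,
                              unit_id=str(unit))
        )
    return trains


def write_episodes(episodes: list[GswdEpisode], path: str | Path) -> None:
    """JSON with spike times plus a BED-like .tsv next to it."""
    path = Path(path)
    payload = [
        {
            "start": ep.start,
            "end": ep.end,
            "ecog_spike_times": ep.ecog_spike_times.tolist(),
            "median_interval": ep.median_interval,
        }
        for ep in episodes
    ]
    path.write_text(json.dumps(payload, indent=2))
    tsv = pd.DataFrame(
        [(ep.start, ep.end, ep.n_spikes, ep.median_interval) for ep in episodes],
        columns=["start", "end", "n_spikes", "median_interval"],
    )
    tsv.to_csv(path.with_suffix(".tsv"), sep="\t", index=False, float_format=FLOAT_FMT)


def read_episodes(path: str | Path) -> list[GswdEpisode]:
    payload = json.loads(Path(path).read_text())
    episodes = []
    for i, d in enumerate(payload):
        if not d["start"] < d["end"]:
            raise ValueError(f"{path}: episode {i} has end <= start")
        episodes.append(
            GswdEpisode(
                start=float(d["start"]),
                end=float(d["end"]),
                ecog_spike_times=np.asarray(d["ecog_spike_times"], dtype=float),
                median_interval=float(d["median_interval"]),
            )
        )
    return episodes


def write_traces(traces: list, path: str | Path) -> None:
    df = pd.DataFrame({"frame_time_s": traces[0].frame_times})
    for tr in traces:
        df[tr.roi_id] = tr.dff
    df.to_csv(Path(path), index=False, float_format=FLOAT_FMT)


def read_traces(path: str | Path) -> list[CalciumTrace]:
    df = pd.read_csv(Path(path))
    if "frame_time_s" not in df.columns:
        raise ValueError(f"{path}: missing column 'frame_time_s'")
    t = df["frame_time_s"].to_numpy(dtype=float)
    return [
        CalciumTrace(frame_times=t, dff=df[c].to_numpy(dtype=float), roi_id=str(c))
        for c in df.columns
        if c != "frame_time_s"
    ]


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")
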