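"""Detection of generalized spike-and-wave discharges (GSWDs) in ECoG.

A GSWD episode is a run of sharp negative ECoG deflections ("ECoG spikes")
repeating at 6-9 Hz, each followed by a slow wave. Detection proceeds in
three steps: threshold negative peaks (robust MAD-based threshold), group
successive peaks whose inter-peak intervals fall in the 6-9 Hz band into
candidate runs, then merge runs separated by less than the merge gap and
discard runs shorter than the minimum episode duration.

Episode boundaries are placed half a cycle outside the first/last accepted
peak, so the episode covers whole spike-wave cycles. Interictal intervals
exclude a guard band (default 2 s) on both sides of every episode.
All intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

#: 1/Phi^-1(3/4): scales the median absolute deviation to the SD of a normal.
MAD_SCALE = 1.4826


@dataclass
class EcogRecording:
    """Continuous multichannel ECoG with sampling-rate metadata."""

    fs: float                      # Hz
    data: np.ndarray               # (n_samples, n_channels)
    channel_names: list[str] = field(default_factory=lambda: ["M1"])

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] == 1 and self.data.shape[1] > 1 and len(self.channel_names) == 1:
            self.data = self.data.T
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channel_names):
            raise ValueError("data must be (n_samples, n_channels) matching channel_names")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ECoG contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None
        return self.data[:, i]


@dataclass
class GswdEpisode:
    """One detected spike-and-wave episode."""

    start: float                   # s
    end: float                     # s
    ecog_spike_times: np.ndarray   # s, negative-peak times inside the episode
    median_interval: float         # s, median successive spike-time difference

    def __post_init__(self) -> None:
        self.ecog_spike_times = np.asarray(self.ecog_spike_times, dtype=float)
        if not self.start < self.end:
            raise ValueError("episode start must precede end")
        t = self.ecog_spike_times
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < self.start or t[-1] > self.end):
            raise ValueError("spike times must be sorted and inside [start, end]")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_spikes(self) -> int:
        return self.ecog_spike_times.size


def detect_gswds(
    ecog: EcogRecording,
    channel: str = "M1",
    mad_k: float = 4.0,
    band: tuple[float, float] = (6.0, 9.0),
    min_episode: float = 1.0,
    merge_gap: float = 1.0,
    interval_tol: float = 0.02,
    max_outliers: int = 1,
) -> list[GswdEpisode]:
    """Detect GSWD episodes on one ECoG channel.

    Parameters
    ----------
    mad_k
        Negative-peak threshold in robust SDs (MAD scaled to normal SD).
    band
        Spike repetition band in Hz; successive inter-peak intervals must
        lie in ``[1/band[1] - tol, 1/band[0] + tol]`` to extend a run, with
        at most ``max_outliers`` longer intervals (missed cycles) tolerated
        per run.
    """
    lo_f, hi_f = band
    if ecog.fs < 2 * hi_f:
        raise ValueError(
            f"undersampled: fs={ecog.fs} Hz is below 2x the maximum band frequency {hi_f} Hz"
        )
    x = ecog.channel(channel)
    sigma = MAD_SCALE * np.median(np.abs(x - np.median(x)))
    if sigma == 0:
        return []
    # refractory distance well below the shortest in-band cycle (1/9 s)
    peaks, _ = find_peaks(-x, height=mad_k * sigma, distance=max(1, int(round(0.07 * ecog.fs))))
    if peaks.size == 0:
        return []
    pt = peaks / ecog.fs

    lo_dt, hi_dt = 1.0 / hi_f - interval_tol, 1.0 / lo_f + interval_tol
    runs: list[list[float]] = []
    cur = [pt[0]]
    outliers = 0
    for t in pt[1:]:
        dt = t - cur[-1]
        if lo_dt <= dt <= hi_dt:
            cur.append(t)
        elif dt < 2.0 / lo_f and outliers < max_outliers and len(cur) >= 2:
            # one tolerated gap (e.g. a missed cycle) inside an ongoing run
            cur.append(t)
            outliers += 1
        else:
            runs.append(cur)
            cur = [t]
            outliers = 0
    runs.append(cur)

    # keep runs that oscillate (>= 3 peaks, so >= 2 in-band intervals)
    cands = []
    for r in runs:
        if len(r) < 3:
            continue
        med = float(np.median(np.diff(r)))
        cands.append((r[0] - med / 2.0, r[-1] + med / 2.0, list(r)))

    # merge candidates separated by < merge_gap, then enforce min duration
    merged: list[list] = []
    for s, e, spikes in cands:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
            merged[-1][2].extend(spikes)
        else:
            merged.append([s, e, list(spikes)])

    episodes = []
    for s, e, spikes in merged:
        if e - s < min_episode:
            continue
        spikes = np.asarray(spikes)
        episodes.append(
            GswdEpisode(
                start=max(0.0, s),
                end=min(ecog.duration, e),
                ecog_spike_times=spikes,
                median_interval=float(np.median(np.diff(spikes))),
            )
        )
    return episodes


def ictal_intervals(episodes: list[GswdEpisode]) -> list[tuple[float, float]]:
    """Half-open [start, end) intervals of the given episodes."""
    return [(ep.start, ep.end) for ep in episodes]


def interictal_intervals(
    episodes: list[GswdEpisode] | list[tuple[float, float]],
    recording_span: tuple[float, float],
    guard: float = 2.0,
) -> list[tuple[float, float]]:
    """Maximal intervals excluding every episode padded by ``guard`` seconds.

    Implements the rule that interictal time runs from ``guard`` seconds
    after one seizure to ``guard`` seconds before the next; recording edges
    bound the first and last interval; empty intervals are dropped.
    Episodes may be given as GswdEpisode objects or (start, end) pairs.
    """
    span_lo, span_hi = recording_span
    bounds = sorted(
        tuple(ep) if isinstance(ep, (tuple, list)) else (ep.start, ep.end)
        for ep in episodes
    )
    for (s0, e0), (s1, _e1) in zip(bounds, bounds[1:]):
        if s1 < e0:
            raise ValueError("episodes overlap")
    out = []
    cursor = span_lo
    for s, e in bounds:
        lo, hi = cursor, min(s - guard, span_hi)
        if hi > lo:
            out.append((lo, hi))
        cursor = max(cursor, e + guard)
    if span_hi > cursor:
        out.append((cursor, span_hi))
    return out
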