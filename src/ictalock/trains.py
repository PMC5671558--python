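"""Labeled Purkinje-cell spike trains and firing-pattern statistics.

A Purkinje cell emits two event types: complex spikes (CS, climbing-fiber
driven, ~1 Hz) and simple spikes (SS, tens of Hz). A unit is accepted as a
Purkinje cell when both types are present and the median pause in SS firing
after each CS (the climbing-fiber pause) is at least 10 ms.

Firing-pattern statistics (rates, CV, CV2, burst index, median CF pause)
are computed separately for ictal and interictal periods by restricting the
train to half-open intervals; interspike intervals never span an interval
gap. Statistics that cannot be computed are reported as ``None``, never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

CS = "CS"
SS = "SS"


@dataclass
class LabeledSpikeTrain:
    """Event times with CS/SS labels for one unit.

    When the train is the result of :func:`restrict`, ``intervals`` holds
    the restriction intervals, ``segment`` the interval index of each event,
    and ``analysis_time`` the summed interval length; otherwise
    ``analysis_time`` equals ``duration``.
    """

    times: np.ndarray
    labels: np.ndarray
    duration: float
    unit_id: str = "unit0"
    location: str | None = None            # "medial" | "lateral"
    intervals: list[tuple[float, float]] | None = None
    segment: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object).astype(str)
        if self.times.shape != self.labels.shape:
            raise ValueError("times and labels must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.times.size and (self.times[0] < 0 or self.times[-1] > self.duration):
            raise ValueError("spike times must lie in [0, duration]")
        bad = set(np.unique(self.labels)) - {CS, SS}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected CS or SS")
        if self.segment is not None:
            self.segment = np.asarray(self.segment, dtype=int)

    @property
    def analysis_time(self) -> float:
        if self.intervals is None:
            return self.duration
        return float(sum(e - s for s, e in self.intervals))

    @property
    def cs_times(self) -> np.ndarray:
        return self.times[self.labels == CS]

    @property
    def ss_times(self) -> np.ndarray:
        return self.times[self.labels == SS]

    def select(self, label: str) -> np.ndarray:
        return self.times[self.labels == label]


@dataclass
class FiringStats:
    """Per-period firing-pattern parameters of one unit (times in seconds)."""

    cs_rate: float | None
    ss_rate: float | None
    cv: float | None              # SD/mean of SS ISIs
    cv2: float | None             # mean of 2|ISI_{n+1}-ISI_n|/(ISI_{n+1}+ISI_n)
    burst_index: float | None     # fraction of SS in bursts (>=3 spikes / 100 ms)
    median_cf_pause: float | None  # s, median CS -> next-SS latency
    analysis_time: float

    def to_dict(self) -> dict:
        return {
            "cs_rate": self.cs_rate,
            "ss_rate": self.ss_rate,
            "cv": self.cv,
            "cv2": self.cv2,
            "burst_index": self.burst_index,
            "median_cf_pause": self.median_cf_pause,
            "analysis_time": self.analysis_time,
        }


@dataclass
class PurkinjeValidation:
    valid: bool
    median_pause: float | None    # s
    reason: str = ""


def restrict(
    train: LabeledSpikeTrain, intervals: list[tuple[float, float]]
) -> LabeledSpikeTrain:
    """Keep events inside the union of half-open intervals.

    Each kept event remembers which interval it fell in so ISI-based
    statistics can skip gap-crossing pairs. An empty interval list yields an
    empty train with zero analysis time.
    """
    intervals = sorted((float(s), float(e)) for s, e in intervals)
    for (s0, e0), (s1, _e1) in zip(intervals, intervals[1:]):
        if s1 < e0:
            raise ValueError("restriction intervals must be disjoint")
    keep = []
    seg = []
    for i, (s, e) in enumerate(intervals):
        lo, hi = np.searchsorted(train.times, [s, e], side="left")
        keep.append(np.arange(lo, hi))
        seg.append(np.full(hi - lo, i))
    idx = np.concatenate(keep) if keep else np.array([], dtype=int)
    return LabeledSpikeTrain(
        times=train.times[idx],
        labels=train.labels[idx],
        duration=train.duration,
        unit_id=train.unit_id,
        location=train.location,
        intervals=intervals,
        segment=np.concatenate(seg) if seg else np.array([], dtype=int),
    )


def validate_purkinje(
    train: LabeledSpikeTrain, min_pause: float = 0.010
) -> PurkinjeValidation:
    """Check the Purkinje-cell identification criterion.

    For every CS, the pause is the latency to the first subsequent SS; the
    unit is accepted when the median pause is at least ``min_pause`` (10 ms).
    """
    cs, ss = train.cs_times, train.ss_times
    if cs.size == 0:
        return PurkinjeValidation(False, None, "no CS")
    if ss.size == 0:
        return PurkinjeValidation(False, None, "no SS")
    pauses = _cf_pauses(cs, ss)
    if pauses.size == 0:
        return PurkinjeValidation(False, None, "no SS after any CS")
    med = float(np.median(pauses))
    return PurkinjeValidation(med >= min_pause, med)


def _cf_pauses(cs: np.ndarray, ss: np.ndarray, seg_cs=None, seg_ss=None) -> np.ndarray:
    """Latency from each CS to the first following SS (same segment if given)."""
    if cs.size == 0 or ss.size == 0:
        return np.array([])
    j = np.searchsorted(ss, cs, side="right")
    ok = j < ss.size
    if seg_cs is not None:
        ok &= np.where(ok, seg_ss[np.minimum(j, ss.size - 1)] == seg_cs, False)
    return ss[j[ok]] - cs[ok]


def _segmented_isis(times: np.ndarray, seg: np.ndarray | None):
    """Successive ISIs and consecutive ISI pairs that stay within one segment."""
    if times.size < 2:
        return np.array([]), np.array([]), np.array([])
    isis = np.diff(times)
    if seg is None:
        same = np.ones(isis.size, dtype=bool)
    else:
        same = seg[1:] == seg[:-1]
    isis_ok = isis[same]
    pair_ok = same[1:] & same[:-1]
    return isis_ok, isis[:-1][pair_ok], isis[1:][pair_ok]


def cv2_of_isis(isi_a: np.ndarray, isi_b: np.ndarray) -> float | None:
    """Local irregularity: mean over consecutive ISI pairs of 2|b-a|/(b+a)."""
    if isi_a.size == 0:
        return None
    return float(np.mean(2.0 * np.abs(isi_b - isi_a) / (isi_b + isi_a)))


def burst_mask(times: np.ndarray, seg: np.ndarray | None = None, span: float = 0.100,
               rule: str = "span") -> np.ndarray:
    """Mark spikes belonging to bursts (>= 3 spikes within 100 ms).

    ``rule="span"`` (default): a spike is a burst member when it belongs to
    some window of 3 consecutive spikes (within one segment) whose
    first-to-last span is at most ``span`` seconds. ``rule="isi"``: a burst
    is a run of >= 3 spikes whose every consecutive ISI is below ``span``
    (a looser reading that saturates at high steady rates).
    """
    mask = np.zeros(times.size, dtype=bool)
    if times.size < 3:
        return mask
    if rule == "span":
        w = times[2:] - times[:-2] <= span
        if seg is not None:
            w &= seg[2:] == seg[:-2]
    elif rule == "isi":
        short = np.diff(times) < span
        if seg is not None:
            short &= seg[1:] == seg[:-1]
        w = short[1:] & short[:-1]
    else:
        raise ValueError(f"unknown burst rule {rule!r}")
    for i in np.flatnonzero(w):
        mask[i : i + 3] = True
    return mask


def firing_stats(
    train: LabeledSpikeTrain,
    intervals: list[tuple[float, float]] | None = None,
    burst_span: float = 0.100,
    burst_rule: str = "span",
) -> FiringStats:
    """Ictal/interictal firing-pattern parameters.

    Rates use the summed interval length; CV, CV2 and burst index are
    computed on SS only; CS statistics are the rate and the median
    climbing-fiber pause. Undefined statistics are ``None``.
    """
    r = restrict(train, intervals) if intervals is not None else train
    T = r.analysis_time
    if T <= 0:
        return FiringStats(None, None, None, None, None, None, 0.0)

    ss_sel = r.labels == SS
    ss, cs = r.times[ss_sel], r.times[~ss_sel]
    seg_ss = r.segment[ss_sel] if r.segment is not None else None
    seg_cs = r.segment[~ss_sel] if r.segment is not None else None

    cs_rate = cs.size / T
    ss_rate = ss.size / T

    isis, isi_a, isi_b = _segmented_isis(ss, seg_ss)
    cv = float(np.std(isis) / np.mean(isis)) if isis.size >= 2 else None
    cv2 = cv2_of_isis(isi_a, isi_b)

    burst_index = None
    if ss.size:
        burst_index = float(np.mean(burst_mask(ss, seg_ss, burst_span, burst_rule)))

    pauses = _cf_pauses(cs, ss, seg_cs, seg_ss)
    med_pause = float(np.median(pauses)) if pauses.size else None

    return FiringStats(cs_rate, ss_rate, cv, cv2, burst_index, med_pause, T)


def check_isolation(train: LabeledSpikeTrain, min_isolation: float = 100.0) -> bool:
    """Warn when a unit has less well-isolated time than the inclusion rule asks."""
    if train.duration < min_isolation:
        warnings.warn(
            f"unit {train.unit_id}: {train.duration:.1f} s of activity is below the "
            f"{min_isolation:.0f} s isolation requirement",
            stacklevel=2,
        )
        return False
    return True


def detect_and_sort(
    voltage: np.ndarray,
    fs: float,
    threshold_k: float = 4.5,
    unit_id: str = "unit0",
    silhouette_cutoff: float = 0.5,
) -> LabeledSpikeTrain:
    """Threshold-and-cluster demonstration spike sorter.

    Extracts negative threshold crossings, computes per-event peak amplitude
    and width at half height, splits events into two clusters and labels the
    larger/wider cluster CS. Intended for template-synthesized demo traces,
    not for real extracellular data. A near-degenerate split (silhouette
    below ``silhouette_cutoff``) sets ``meta['sort_warning']`` and warns.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    v = np.asarray(voltage, dtype=float)
    sigma = 1.4826 * np.median(np.abs(v - np.median(v)))
    height = threshold_k * sigma
    peaks, props = find_peaks(-v, height=height, distance=max(1, int(round(0.001 * fs))))
    if peaks.size < 10:
        raise ValueError(f"insufficient events to cluster ({peaks.size} < 10)")

    amp = props["peak_heights"]
    half = amp / 2.0
    width = np.empty(peaks.size)
    for k, (p, h) in enumerate(zip(peaks, half)):
        i = p
        while i > 0 and -v[i - 1] > h:
            i -= 1
        j = p
        while j < v.size - 1 and -v[j + 1] > h:
            j += 1
        width[k] = (j - i + 1) / fs

    feats = np.column_stack([amp, width])
    z = (feats - feats.mean(0)) / np.where(feats.std(0) > 0, feats.std(0), 1.0)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(z)
    lab = km.labels_
    cs_cluster = int(np.argmax(km.cluster_centers_.sum(axis=1)))
    labels = np.where(lab == cs_cluster, CS, SS)

    meta: dict = {"threshold": height, "n_events": int(peaks.size)}
    if len(set(lab)) == 2:
        sil = float(silhouette_score(z, lab))
        meta["silhouette"] = sil
        if sil < silhouette_cutoff:
            meta["sort_warning"] = "clusters nearly identical; labels unreliable"
            warnings.warn(meta["sort_warning"], stacklevel=2)

    return LabeledSpikeTrain(
        times=peaks / fs,
        labels=labels,
        duration=v.size / fs,
        unit_id=unit_id,
        meta=meta,
    )
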