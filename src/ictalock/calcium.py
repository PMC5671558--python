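"""Ca2+ transient event detection and ictal/interictal event-rate contrast.

Dendritic Ca2+ transients report climbing-fiber (complex-spike) input. The
detector operates on per-ROI dF/F traces sampled at ~50 Hz: a slow
baseline is estimated as a blockwise low percentile (20th over 10 s,
linearly interpolated), the noise SD as the scaled MAD of the residual,
and events are local maxima exceeding baseline + k*SD that show a decay
over the following time constant, with a refractory period of one decay
constant between events.

Event trains feed the synchrony module unchanged; the ictal/interictal
event-frequency contrast reuses the episode guard-band tiling from
:mod:`ictalock.gswd` (the two period definitions can never diverge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy import stats

from .gswd import GswdEpisode, ictal_intervals, interictal_intervals

MAD_SCALE = 1.4826


@dataclass
class CalciumTrace:
    """One ROI's fluorescence trace in dF/F units."""

    frame_times: np.ndarray
    dff: np.ndarray
    roi_id: str = "ROI000"

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.frame_times.size != self.dff.size:
            raise ValueError("frame_times and dff must have equal length")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")
        dt = np.diff(self.frame_times)
        if dt.size and (dt.min() <= 0 or dt.max() / dt.min() > 1.01):
            raise ValueError("frame rate must be uniform within 1%")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.frame_times)))

    @property
    def duration(self) -> float:
        return float(self.frame_times[-1] - self.frame_times[0])


@dataclass
class CalciumEventTrain:
    event_times: np.ndarray
    roi_id: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.event_times.size and np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")


def dff_from_raw(f: np.ndarray, frame_rate: float, window: float = 10.0,
                 pct: float = 20.0) -> np.ndarray:
    """(F - F0)/F0 with F0 a blockwise rolling percentile baseline."""
    f0 = _block_percentile(np.asarray(f, dtype=float), frame_rate, window, pct)
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 must be positive to form dF/F")
    return (f - f0) / f0


def _block_percentile(x: np.ndarray, frame_rate: float, window: float, pct: float) -> np.ndarray:
    """Percentile over non-overlapping blocks, linearly interpolated to frames."""
    n_block = max(1, int(round(window * frame_rate)))
    n = x.size
    centers, vals = [], []
    for s in range(0, n, n_block):
        e = min(n, s + n_block)
        centers.append((s + e - 1) / 2.0)
        vals.append(np.percentile(x[s:e], pct))
    if len(vals) == 1:
        return np.full(n, vals[0])
    return np.interp(np.arange(n), centers, vals)


def detect_ca_events(
    trace: CalciumTrace,
    k: float = 3.5,
    baseline_window: float = 10.0,
    baseline_pct: float = 20.0,
    decay_tau: float = 0.15,
) -> CalciumEventTrain:
    """Detect transient events in one dF/F trace.

    Events are local maxima of the baseline-subtracted trace exceeding
    ``k`` noise SDs, at least one decay constant apart, whose level half a
    decay constant later is still at least 30% of the peak (a one-sided
    rise-then-decay template check that rejects single-sample noise spikes).
    """
    if trace.duration <= 10.0:
        raise ValueError("trace must be longer than 10 s for baseline estimation")
    fr = trace.frame_rate
    baseline = _block_percentile(trace.dff, fr, baseline_window, baseline_pct)
    resid = trace.dff - baseline
    # center on the residual median so the percentile offset does not bias
    # the threshold, and scale by the robust noise SD
    resid = resid - np.median(resid)
    if np.ptp(resid) == 0:
        warnings.warn(f"{trace.roi_id}: flat trace, no events detectable", stacklevel=2)
        return CalciumEventTrain(np.array([]), trace.roi_id, {"k": k, "sigma": 0.0})
    sigma = MAD_SCALE * float(np.median(np.abs(resid)))
    if sigma == 0:
        # noise-free trace: any nonzero excursion is signal
        sigma = 1e-3 * float(np.max(resid))
    peaks, _ = find_peaks(
        resid,
        height=k * sigma,
        prominence=k * sigma,  # rejects noise bumps riding on a decay tail
        distance=max(1, int(round(decay_tau * fr))),
    )
    half = max(1, int(round(0.5 * decay_tau * fr)))
    ok = []
    for p in peaks:
        j = min(resid.size - 1, p + half)
        if resid[j] >= 0.3 * resid[p]:
            ok.append(p)
    times = trace.frame_times[np.asarray(ok, dtype=int)] if ok else np.array([])
    return CalciumEventTrain(
        times,
        trace.roi_id,
        {"k": k, "sigma": sigma, "baseline_window": baseline_window,
         "baseline_pct": baseline_pct, "decay_tau": decay_tau},
    )


@dataclass
class EventRateContrast:
    """Per-ROI ictal vs interictal Ca2+ event rates with a paired t-test."""

    roi_ids: list[str]
    rate_ictal: np.ndarray        # Hz per ROI
    rate_interictal: np.ndarray
    mean_diff: float | None       # mean(ictal - interictal), Hz
    t: float | None
    p: float | None
    excluded: list[str] = field(default_factory=list)


def _rate_in(times: np.ndarray, intervals) -> float | None:
    total = sum(e - s for s, e in intervals)
    if total <= 0:
        return None
    n = sum(int(np.sum((times >= s) & (times < e))) for s, e in intervals)
    return n / total


def event_frequency_contrast(
    events: dict[str, CalciumEventTrain] | dict[str, np.ndarray],
    episodes: list[GswdEpisode],
    recording_span: tuple[float, float],
    guard: float = 2.0,
) -> EventRateContrast:
    """Compare per-ROI event rates between ictal and interictal periods.

    Periods come from the same guard-band tiling used everywhere else.
    ROIs for which either period has zero duration are excluded and listed.
    With fewer than 2 usable ROIs the t-test is undefined (None).
    """
    ict = ictal_intervals(episodes)
    inter = interictal_intervals(episodes, recording_span, guard)
    roi_ids, ri, rn, excluded = [], [], [], []
    for roi, ev in events.items():
        times = ev.event_times if isinstance(ev, CalciumEventTrain) else np.asarray(ev)
        a = _rate_in(times, ict)
        b = _rate_in(times, inter)
        if a is None or b is None:
            excluded.append(roi)
            continue
        roi_ids.append(roi)
        ri.append(a)
        rn.append(b)
    ri, rn = np.asarray(ri), np.asarray(rn)
    if ri.size >= 2:
        if np.allclose(ri, rn):
            t, p = 0.0, 1.0
        else:
            t, p = (float(v) for v in stats.ttest_rel(ri, rn))
        diff = float(np.mean(ri - rn))
    elif ri.size == 1:
        t, p, diff = None, None, float(ri[0] - rn[0])
    else:
        t, p, diff = None, None, None
    return EventRateContrast(roi_ids, ri, rn, diff, t, p, excluded)
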