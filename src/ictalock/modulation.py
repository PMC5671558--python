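"""Classification of seizure-phase-locked firing.

For each unit and event type (CS or SS), event times are binned relative
to every ECoG spike of every episode into a peri-stimulus time histogram
(PSTH, 10 ms bins). Three measures summarize the PSTH:

1. modulation amplitude: peak minus trough of the counts near t = 0
   (within one spike-and-wave cycle of the trigger);
2. modulation frequency: dominant frequency of the mean-subtracted PSTH by
   FFT;
3. mean power in the 6-9 Hz spike-and-wave band.

The chance distribution of amplitude and band power is obtained by
shuffling the interspike-interval sequence of the train 500 times (the ISI
multiset, event count and first event time are preserved) and rebuilding
the PSTH, giving Z = (X - mu)/sigma per measure. CS firing counts as
modulated when the amplitude Z >= 1.96 and the dominant frequency lies in
6-9 Hz; SS firing additionally requires the band-power Z >= 1.96, and the
power Z is the reported "Z-score" for SS (the amplitude Z for CS).

The phase of modulated firing is 360 deg times the latency of the first
significant PSTH peak at t >= 0 divided by the median spike-and-wave
interval, reduced to [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gswd import GswdEpisode


@dataclass
class Psth:
    """Trigger-aligned event-count histogram.

    ``cycle`` is the median ECoG spike interval over the trigger episodes;
    it defines both the near-zero search region for the amplitude and the
    denominator of the phase formula.
    """

    bin_width: float
    window: float
    edges: np.ndarray
    counts: np.ndarray
    n_triggers: int
    cycle: float
    label: str = ""
    rel_times: np.ndarray | None = None   # trigger-relative event times (for sub-bin peaks)

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    @property
    def left_edges(self) -> np.ndarray:
        return self.edges[:-1]


@dataclass
class NullDistribution:
    statistic: str
    values: np.ndarray
    mu: float
    sigma: float


@dataclass
class ShuffleNull:
    """Shuffle-derived nulls for the PSTH measures plus per-bin count stats."""

    amplitude: NullDistribution
    power: NullDistribution
    bin_mu: np.ndarray
    bin_sigma: np.ndarray
    n_shuffles: int


@dataclass
class ModulationResult:
    unit_id: str
    label: str
    amplitude: float
    dominant_freq: float | None
    mean_power_6_9: float
    z_amplitude: float | None
    z_power: float | None
    modulated: bool
    phase_deg: float | None
    reason: str = ""

    @property
    def z_score(self) -> float | None:
        """The reported Z: amplitude-based for CS, band-power-based for SS."""
        return self.z_amplitude if self.label == "CS" else self.z_power


def episode_triggers(episodes: list[GswdEpisode]) -> np.ndarray:
    return (
        np.concatenate([ep.ecog_spike_times for ep in episodes])
        if episodes
        else np.array([])
    )


def median_gswd_interval(episodes: list[GswdEpisode]) -> float:
    """Median ECoG spike interval pooled over episodes ("median GSWD distance")."""
    diffs = [np.diff(ep.ecog_spike_times) for ep in episodes if ep.n_spikes >= 2]
    if not diffs:
        raise ValueError("no episode has two or more ECoG spikes")
    return float(np.median(np.concatenate(diffs)))


def _relative_times(events: np.ndarray, triggers: np.ndarray, window: float) -> np.ndarray:
    """Event times relative to every trigger, within +-window (pooled)."""
    lo = np.searchsorted(events, triggers - window, side="left")
    hi = np.searchsorted(events, triggers + window, side="left")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.array([])
    # gather events[lo_i:hi_i] for all i without a Python loop
    idx = np.repeat(hi - np.cumsum(counts), counts) + np.arange(total)
    return events[idx] - np.repeat(triggers, counts)


def _bin_relative(events: np.ndarray, triggers: np.ndarray, edges: np.ndarray,
                  window: float) -> np.ndarray:
    """Histogram of event times relative to every trigger (summed)."""
    rel = _relative_times(events, triggers, window)
    return np.histogram(rel, bins=edges)[0].astype(float)


def build_psth(
    event_times: np.ndarray,
    episodes: list[GswdEpisode],
    label: str = "",
    bin_width: float = 0.010,
    window: float = 0.5,
    min_total_ictal: float = 2.0,
) -> Psth:
    """Episode-spike-triggered PSTH of the given event times.

    Requires at least ``min_total_ictal`` seconds of summed episode length
    (the inclusion rule for modulation analysis).
    """
    total = sum(ep.duration for ep in episodes)
    if total < min_total_ictal:
        raise ValueError(
            f"insufficient ictal data: total episode length {total:.2f} s < "
            f"{min_total_ictal} s"
        )
    triggers = episode_triggers(episodes)
    n_bins = int(round(2 * window / bin_width))
    edges = -window + np.arange(n_bins + 1) * bin_width
    events = np.asarray(event_times, dtype=float)
    rel = _relative_times(events, triggers, window)
    counts = np.histogram(rel, bins=edges)[0].astype(float)
    return Psth(
        bin_width=bin_width,
        window=window,
        edges=edges,
        counts=counts,
        n_triggers=triggers.size,
        cycle=median_gswd_interval(episodes),
        label=label,
        rel_times=rel,
    )


@dataclass
class ModulationMeasures:
    amplitude: float
    dominant_freq: float | None
    mean_power_6_9: float
    freqs: np.ndarray
    power: np.ndarray


def _fft_power(counts: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Power spectrum of the mean-subtracted, Hann-windowed, zero-padded PSTH."""
    y = counts - counts.mean()
    n = counts.size
    y = y * np.hanning(n)
    nfft = 1 << max(8, int(np.ceil(np.log2(max(n, 2)))))
    spectrum = np.fft.rfft(y, nfft)
    freqs = np.fft.rfftfreq(nfft, bin_width)
    return freqs, np.abs(spectrum) ** 2


def fft_resolution(counts_len: int, bin_width: float) -> float:
    """Frequency grid spacing of the padded PSTH spectrum, Hz."""
    nfft = 1 << max(8, int(np.ceil(np.log2(max(counts_len, 2)))))
    return 1.0 / (nfft * bin_width)


def modulation_measures(
    psth: Psth,
    band: tuple[float, float] = (6.0, 9.0),
    freq_range: tuple[float, float] = (1.0, 50.0),
) -> ModulationMeasures:
    """Amplitude near t = 0, FFT dominant frequency, and mean band power."""
    near = np.abs(psth.centers) <= psth.cycle
    c = psth.counts[near] if near.any() else psth.counts
    amplitude = float(c.max() - c.min()) if c.size else 0.0

    freqs, power = _fft_power(psth.counts, psth.bin_width)
    in_range = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    if psth.counts.any() and in_range.any() and power[in_range].max() > 0:
        dominant = float(freqs[in_range][np.argmax(power[in_range])])
    else:
        dominant = None
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    mean_power = float(power[in_band].mean()) if in_band.any() else 0.0
    return ModulationMeasures(amplitude, dominant, mean_power, freqs, power)


def shuffle_isis(times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute the ISI sequence, preserving the multiset and the first event."""
    if times.size < 3:
        return times.copy()
    isis = np.diff(times)
    return times[0] + np.concatenate([[0.0], np.cumsum(rng.permutation(isis))])


def shuffle_null(
    event_times: np.ndarray,
    episodes: list[GswdEpisode],
    n_shuffles: int = 500,
    seed: int | np.random.SeedSequence = 0,
    bin_width: float = 0.010,
    window: float = 0.5,
    band: tuple[float, float] = (6.0, 9.0),
) -> ShuffleNull:
    """Chance distributions of amplitude and band power under ISI shuffling.

    Each surrogate permutes the train's ISI sequence, rebuilds the PSTH with
    the same triggers, and recomputes both measures. Surrogate ``i`` uses the
    substream ``(seed, i)`` so the set of surrogates is reproducible.
    """
    events = np.asarray(event_times, dtype=float)
    if events.size < 2:
        raise ValueError("need at least 2 events of this label to shuffle")
    triggers = episode_triggers(episodes)
    n_bins = int(round(2 * window / bin_width))
    edges = -window + np.arange(n_bins + 1) * bin_width
    cycle = median_gswd_interval(episodes)
    centers = (edges[:-1] + edges[1:]) / 2.0
    near = np.abs(centers) <= cycle

    amps = np.empty(n_shuffles)
    pows = np.empty(n_shuffles)
    bin_sum = np.zeros(n_bins)
    bin_sq = np.zeros(n_bins)
    base = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    # derived, documented substreams: one child per surrogate
    children = base.spawn(n_shuffles)
    for i in range(n_shuffles):
        rng = np.random.default_rng(children[i])
        surr = shuffle_isis(events, rng)
        counts = _bin_relative(surr, triggers, edges, window)
        c = counts[near] if near.any() else counts
        amps[i] = c.max() - c.min() if c.size else 0.0
        freqs, power = _fft_power(counts, bin_width)
        in_band = (freqs >= band[0]) & (freqs <= band[1])
        pows[i] = power[in_band].mean() if in_band.any() else 0.0
        bin_sum += counts
        bin_sq += counts**2

    mu_b = bin_sum / n_shuffles
    var_b = np.maximum(bin_sq / n_shuffles - mu_b**2, 0.0)
    return ShuffleNull(
        amplitude=NullDistribution("amplitude", amps, float(amps.mean()), float(amps.std())),
        power=NullDistribution("mean_power_6_9", pows, float(pows.mean()), float(pows.std())),
        bin_mu=mu_b,
        bin_sigma=np.sqrt(var_b),
        n_shuffles=n_shuffles,
    )


def zscore(x: float, null: NullDistribution) -> float | None:
    """Z = (X - mu)/sigma against the shuffle null; None when degenerate."""
    if null.sigma == 0:
        return None
    return float((x - null.mu) / null.sigma)


def _peak_time(psth: Psth, i: int) -> float:
    """Sub-bin peak time for peak bin i.

    Mean of the trigger-relative event times falling in bin i and its
    neighbors; events sitting exactly on the trigger therefore give a peak
    time of 0. Falls back to the bin's left edge without stored times.
    """
    lefts = psth.left_edges
    if psth.rel_times is None or psth.rel_times.size == 0:
        return float(lefts[i])
    lo = lefts[max(0, i - 1)]
    hi = lefts[min(psth.counts.size - 1, i + 1)] + psth.bin_width
    sel = (psth.rel_times >= lo) & (psth.rel_times < hi)
    if not sel.any():
        return float(lefts[i])
    return float(psth.rel_times[sel].mean())


def first_peak_time(psth: Psth, nulls: ShuffleNull | None = None, z_crit: float = 1.96) -> float | None:
    """Time of the first significant PSTH peak at t >= 0.

    The peak bin is the first local maximum (left edge >= 0) whose counts
    exceed mu + z_crit * sigma of the per-bin shuffle null; without nulls
    (or if no bin qualifies) the maximum bin within one cycle of t = 0 is
    used. The returned time is the count-weighted centroid of the peak bin
    and its neighbors (left-edge convention). None for an empty PSTH.
    """
    c = psth.counts
    if not c.any():
        return None
    lefts = psth.left_edges
    nonneg = np.flatnonzero(lefts >= -1e-12)
    if nulls is not None:
        thr = nulls.bin_mu + z_crit * nulls.bin_sigma
        for i in nonneg:
            lo, hi = max(0, i - 1), min(c.size - 1, i + 1)
            if c[i] >= c[lo] and c[i] >= c[hi] and c[i] > thr[i]:
                return _peak_time(psth, i)
    sel = nonneg[(lefts[nonneg] <= psth.cycle)]
    if sel.size == 0:
        return None
    return _peak_time(psth, int(sel[np.argmax(c[sel])]))


def phase_from_peak_time(t_peak: float, median_interval: float) -> float:
    """phase = 360 * t_peak / median spike-and-wave interval, wrapped to [0, 360)."""
    if median_interval <= 0:
        raise ValueError("median interval must be positive")
    return float((360.0 * t_peak / median_interval) % 360.0)


def phase_difference(psth: Psth, median_interval: float | None = None,
                     nulls: ShuffleNull | None = None) -> float | None:
    """Phase (degrees in [0, 360)) of the first PSTH peak after the trigger.

    phase = 360 * t_first_peak / median spike-and-wave interval, wrapped.
    """
    interval = psth.cycle if median_interval is None else median_interval
    t = first_peak_time(psth, nulls)
    if t is None:
        return None
    return phase_from_peak_time(t, interval)


def classify_modulation(
    measures: ModulationMeasures,
    nulls: ShuffleNull,
    label: str,
    psth: Psth | None = None,
    unit_id: str = "",
    band: tuple[float, float] = (6.0, 9.0),
    z_crit: float = 1.96,
) -> ModulationResult:
    """Apply the phase-locking classification rules.

    CS: amplitude Z >= z_crit and dominant frequency within the band.
    SS: additionally band-power Z >= z_crit (the reported SS Z-score).
    The phase is computed only for modulated cells (requires ``psth``).
    """
    z_amp = zscore(measures.amplitude, nulls.amplitude)
    z_pow = zscore(measures.mean_power_6_9, nulls.power)
    reason = ""
    if measures.dominant_freq is None:
        modulated, reason = False, "dominant frequency undefined"
    elif z_amp is None or (label == "SS" and z_pow is None):
        modulated, reason = False, "degenerate shuffle null (sigma = 0)"
    else:
        in_band = band[0] <= measures.dominant_freq <= band[1]
        modulated = z_amp >= z_crit and in_band
        if label == "SS":
            modulated = modulated and z_pow >= z_crit
        if not modulated:
            reason = "below chance criteria"
    phase = None
    if modulated and psth is not None:
        phase = phase_difference(psth, nulls=nulls)
    return ModulationResult(
        unit_id=unit_id,
        label=label,
        amplitude=measures.amplitude,
        dominant_freq=measures.dominant_freq,
        mean_power_6_9=measures.mean_power_6_9,
        z_amplitude=z_amp,
        z_power=z_pow,
        modulated=bool(modulated),
        phase_deg=phase,
        reason=reason,
    )


def analyze_modulation(
    train_times: np.ndarray,
    episodes: list[GswdEpisode],
    label: str,
    unit_id: str = "",
    n_shuffles: int = 500,
    seed: int | np.random.SeedSequence = 0,
    bin_width: float = 0.010,
    window: float = 0.5,
    band: tuple[float, float] = (6.0, 9.0),
    z_crit: float = 1.96,
    min_total_ictal: float = 2.0,
) -> ModulationResult:
    """PSTH -> measures -> shuffle null -> classification, in one call."""
    psth = build_psth(train_times, episodes, label, bin_width, window, min_total_ictal)
    measures = modulation_measures(psth, band)
    nulls = shuffle_null(train_times, episodes, n_shuffles, seed, bin_width, window, band)
    return classify_modulation(measures, nulls, label, psth, unit_id, band, z_crit)
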