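"""Synthetic recordings with ground truth.

Generates the three data streams the analysis pipeline consumes, with full
ground truth, so every downstream stage is testable without any recording:

* ECoG with embedded spike-and-wave episodes. Background is band-limited
  Gaussian noise (unit SD); each episode is a train of sharp negative
  spikes followed by slow positive waves, repeating at a per-episode
  frequency drawn from N(7.74, 1.01) Hz clipped to 6-9 Hz, with durations
  drawn from N(3.53, 1.12) s truncated at 1 s. Spike amplitude defaults to
  10 background SDs.
* Labeled Purkinje spike trains: SS as a gamma-renewal process (tens of
  Hz), CS as a Poisson process (~1 Hz). Inside episodes both rates are
  modulated multiplicatively by ``1 + m cos(2 pi f (t - t0) - phi)`` where
  ``t0`` is the episode's first ECoG spike, so phase 0 means firing peaks
  on the ECoG spike. Modulation is realized by exact inhomogeneous
  sampling (time rescaling for the renewal SS, thinning for the Poisson
  CS), never by time-warping a fixed train. After every CS, SS are
  suppressed for the climbing-fiber pause.
* Per-ROI Ca2+ traces: a step-rise/exponential-decay kernel convolved with
  a CS event train, sampled at the imaging frame rate, plus i.i.d.
  Gaussian noise.

Identical seeds give bit-identical output. All times are seconds and
recordings start at t = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .gswd import EcogRecording
from .trains import CS, SS, LabeledSpikeTrain


@dataclass
class SynthConfig:
    """Study conditions for the generator (times s, rates Hz, depths in [0,1])."""

    total_duration: float = 120.0
    fs_ecog: float = 300.0
    n_episodes: int = 10
    gswd_rate_mean: float = 7.74
    gswd_rate_sd: float = 1.01
    episode_dur_mean: float = 3.53
    episode_dur_sd: float = 1.12
    inter_episode_min: float = 2.0    # true gaps must exceed the 1 s merge rule
    edge_margin: float = 1.0           # s kept clear at both recording edges
    spike_amplitude: float = 10.0      # ECoG spike depth in background SDs
    cs_rate: float = 1.0
    ss_rate: float = 60.0
    ss_shape: float = 4.0              # gamma-renewal shape (higher = more regular)
    cf_pause: float = 0.010            # s, SS suppression after each CS
    mod_depth_cs: float = 0.0
    mod_depth_ss: float = 0.0
    ictal_cs_gain: float = 1.0         # multiplicative ictal rate increase for CS
    ictal_ss_gain: float = 1.0
    phase_cs_deg: float = 20.0         # CS peak just after the ECoG spike
    phase_ss_deg: float = 200.0        # SS roughly antiphase to CS
    ca_frame_rate: float = 50.0
    ca_decay_tau: float = 0.15
    ca_noise_sd: float = 0.125
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fs_ecog", "cs_rate", "ss_rate", "ca_frame_rate", "gswd_rate_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mod_depth_cs", "mod_depth_ss"):
            m = getattr(self, name)
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_episodes < 0:
            raise ValueError("n_episodes must be >= 0")
        if self.inter_episode_min < 1.0:
            raise ValueError("inter_episode_min must be >= 1 s")
        if self.cf_pause < 0:
            raise ValueError("cf_pause must be >= 0")
        if self.ictal_cs_gain <= 0 or self.ictal_ss_gain <= 0:
            raise ValueError("ictal gains must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows that a detector must recover."""

    episodes: list[tuple[float, float]] = field(default_factory=list)
    episode_freqs: list[float] = field(default_factory=list)
    ecog_spike_times: np.ndarray = field(default_factory=lambda: np.array([]))
    spikes_per_episode: list[np.ndarray] = field(default_factory=list)
    cs_times: dict[str, np.ndarray] = field(default_factory=dict)
    ss_times: dict[str, np.ndarray] = field(default_factory=dict)
    modulated: dict[str, bool] = field(default_factory=dict)
    phases_deg: dict[str, tuple[float, float]] = field(default_factory=dict)
    ca_event_times: dict[str, np.ndarray] = field(default_factory=dict)


def _rng(config: SynthConfig, *stream: int) -> np.random.Generator:
    """Deterministic substream: master seed + stream identifiers."""
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *stream])


def _place_episodes(config: SynthConfig, rng) -> tuple[list[float], list[float], list[float]]:
    """Draw durations/frequencies and place episodes with the gap constraints.

    Placement allocates the free (non-episode, non-minimum-gap) time
    uniformly over the gap simplex via sorted uniforms, i.e. uniform
    placement conditioned on all gaps >= inter_episode_min.
    """
    n = config.n_episodes
    durs = []
    for i in range(n):
        d = -1.0
        while d < 1.0:  # truncated normal, >= 1 s
            d = rng.normal(config.episode_dur_mean, config.episode_dur_sd)
        durs.append(float(d))
    freqs = np.clip(
        rng.normal(config.gswd_rate_mean, config.gswd_rate_sd, size=n), 6.0, 9.0
    ).tolist()
    if n == 0:
        return [], durs, freqs
    occupied = sum(durs) + (n - 1) * config.inter_episode_min + 2 * config.edge_margin
    free = config.total_duration - occupied
    if free < 0:
        raise ValueError(
            f"{n} episodes (total {sum(durs):.1f} s plus gaps) do not fit in "
            f"total_duration={config.total_duration} s"
        )
    cuts = np.sort(rng.uniform(0.0, free, size=n + 1))
    extra = np.diff(np.concatenate([[0.0], cuts, [free]]))[:n]
    starts = []
    t = config.edge_margin
    for i in range(n):
        t += extra[i] + (config.inter_episode_min if i else 0.0)
        starts.append(t)
        t += durs[i]
    return starts, durs, freqs


def _sw_template(fs: float, amplitude: float) -> tuple[np.ndarray, int]:
    """Biphasic spike-and-wave kernel: narrow negative spike, broad positive wave."""
    t = np.arange(-0.025, 0.111, 1.0 / fs)
    spike = -amplitude * np.exp(-(t**2) / (2 * 0.006**2))
    wave = 0.35 * amplitude * np.exp(-((t - 0.055) ** 2) / (2 * 0.025**2))
    k = spike + wave
    return k, int(np.argmin(k))  # offset of the negative peak


def ecog_from_spike_times(
    spike_times: np.ndarray,
    total_duration: float,
    fs: float = 300.0,
    amplitude: float = 10.0,
    noise_seed: int | None = 0,
) -> EcogRecording:
    """Single-channel ECoG with spike-and-wave kernels at the given times.

    Used to construct edge cases (sub-second bursts, specific gaps) that
    the stochastic generator cannot place deterministically.
    """
    n = int(round(total_duration * fs))
    if noise_seed is None:
        x = np.zeros(n)
    else:
        sos = butter(4, 30.0, btype="low", fs=fs, output="sos")
        x = sosfiltfilt(sos, np.random.default_rng(noise_seed).standard_normal(n))
        x /= np.std(x)
    kernel, peak_off = _sw_template(fs, amplitude)
    for ts in np.asarray(spike_times, dtype=float):
        i0 = int(round(ts * fs)) - peak_off
        j0, j1 = max(0, i0), min(n, i0 + kernel.size)
        x[j0:j1] += kernel[j0 - i0 : j1 - i0]
    return EcogRecording(fs=fs, data=x[:, None], channel_names=["M1"])


def generate_ecog(config: SynthConfig) -> tuple[EcogRecording, GroundTruth]:
    """Synthesize an ECoG recording and its ground truth.

    With ``n_episodes == 0`` the output is flat band-limited noise and the
    ground-truth episode list is empty. Otherwise each episode carries ECoG
    spikes at its own frequency f, starting half a cycle after the episode
    onset; ground-truth intervals span [first spike - 1/(2f), last spike +
    1/(2f)] so boundaries sit half a cycle outside the outermost spikes.
    """
    rng = _rng(config, 0)
    n = int(round(config.total_duration * config.fs_ecog))
    sos = butter(4, 30.0, btype="low", fs=config.fs_ecog, output="sos")
    noise = sosfiltfilt(sos, rng.standard_normal(n))
    noise /= np.std(noise)
    x = noise.copy()

    truth = GroundTruth()
    starts, durs, freqs = _place_episodes(config, rng)
    kernel, peak_off = _sw_template(config.fs_ecog, config.spike_amplitude)
    all_spikes = []
    for s, d, f in zip(starts, durs, freqs):
        cycle = 1.0 / f
        spikes = np.arange(s + 0.5 * cycle, s + d - 0.4 * cycle + 1e-9, cycle)
        if spikes.size == 0:
            continue
        for ts in spikes:
            i0 = int(round(ts * config.fs_ecog)) - peak_off
            j0, j1 = max(0, i0), min(n, i0 + kernel.size)
            x[j0:j1] += kernel[j0 - i0 : j1 - i0]
        truth.episodes.append((float(spikes[0] - 0.5 * cycle), float(spikes[-1] + 0.5 * cycle)))
        truth.episode_freqs.append(float(f))
        truth.spikes_per_episode.append(spikes)
        all_spikes.append(spikes)
    truth.ecog_spike_times = (
        np.concatenate(all_spikes) if all_spikes else np.array([])
    )
    rec = EcogRecording(fs=config.fs_ecog, data=x[:, None], channel_names=["M1"])
    return rec, truth


def _rate_profile(config: SynthConfig, truth: GroundTruth, base: float, m: float,
                  phase_deg: float, t: np.ndarray, gain: float = 1.0) -> np.ndarray:
    """Instantaneous rate on grid t: baseline outside episodes; inside an
    episode the baseline is scaled by ``gain`` and cosine-modulated with
    depth ``m`` at the episode's spike-and-wave frequency."""
    rate = np.full(t.size, base)
    phi = np.deg2rad(phase_deg)
    for (s, e), f, spikes in zip(truth.episodes, truth.episode_freqs, truth.spikes_per_episode):
        if spikes.size == 0 or (m <= 0 and gain == 1.0):
            continue
        sel = (t >= s) & (t < e)
        rate[sel] = base * gain * (1.0 + m * np.cos(2 * np.pi * f * (t[sel] - spikes[0]) - phi))
    return rate


def _sample_inhomogeneous_renewal(rate: np.ndarray, t: np.ndarray, shape: float, rng) -> np.ndarray:
    """Gamma-renewal train with the given rate profile via time rescaling."""
    dt = t[1] - t[0]
    cum = np.concatenate([[0.0], np.cumsum(rate) * dt])
    tgrid = np.concatenate([t, [t[-1] + dt]])
    total = cum[-1]
    n_draw = int(total + 6 * np.sqrt(max(total, 1.0)) + 20)
    isis = rng.gamma(shape, 1.0 / shape, size=n_draw)
    ops = np.cumsum(isis)
    ops = ops[ops < total]
    return np.interp(ops, cum, tgrid)


def _sample_inhomogeneous_poisson(rate: np.ndarray, t: np.ndarray, ceiling: float, rng) -> np.ndarray:
    """Poisson train with the given rate profile via thinning of a ceiling rate."""
    T = t[-1] + (t[1] - t[0])
    n_draw = rng.poisson(ceiling * T)
    cand = np.sort(rng.uniform(0.0, T, size=n_draw))
    accept = rng.uniform(0.0, 1.0, size=n_draw) < np.interp(cand, t, rate) / ceiling
    return cand[accept]


def generate_purkinje_train(
    config: SynthConfig,
    truth: GroundTruth,
    unit_id: str = "PC00",
    unit_index: int = 0,
) -> LabeledSpikeTrain:
    """Generate one labeled Purkinje train phase-locked (or not) to the episodes.

    SS are a gamma renewal process at ``ss_rate`` (shape ``ss_shape``), CS a
    Poisson process at ``cs_rate``; inside episodes both are modulated by
    their configured depth and phase. SS falling within ``cf_pause`` seconds
    after a CS are removed. The train and its truth entries are recorded in
    ``truth``.
    """
    rng = _rng(config, 1, unit_index)
    T = config.total_duration
    t = np.arange(0.0, T, 0.001)

    ss_rate = _rate_profile(config, truth, config.ss_rate, config.mod_depth_ss,
                            config.phase_ss_deg, t, config.ictal_ss_gain)
    ss = _sample_inhomogeneous_renewal(ss_rate, t, config.ss_shape, rng)

    cs_rate = _rate_profile(config, truth, config.cs_rate, config.mod_depth_cs,
                            config.phase_cs_deg, t, config.ictal_cs_gain)
    ceiling = config.cs_rate * max(1.0, config.ictal_cs_gain) * (1.0 + config.mod_depth_cs) + 1e-12
    cs = _sample_inhomogeneous_poisson(cs_rate, t, ceiling, rng)

    if cs.size and ss.size and config.cf_pause > 0:
        j = np.searchsorted(cs, ss, side="right") - 1
        prev = np.where(j >= 0, cs[np.maximum(j, 0)], -np.inf)
        ss = ss[ss - prev >= config.cf_pause]

    times = np.concatenate([cs, ss])
    labels = np.concatenate([np.full(cs.size, CS, object), np.full(ss.size, SS, object)])
    order = np.argsort(times, kind="stable")
    times, labels = times[order], labels[order]
    dup = np.concatenate([[False], np.diff(times) <= 0])
    times, labels = times[~dup], labels[~dup]

    truth.cs_times[unit_id] = cs
    truth.ss_times[unit_id] = ss
    truth.modulated[unit_id] = bool(
        truth.episodes and (config.mod_depth_cs > 0 or config.mod_depth_ss > 0)
    )
    truth.phases_deg[unit_id] = (config.phase_cs_deg, config.phase_ss_deg)

    return LabeledSpikeTrain(times=times, labels=np.asarray(labels), duration=T,
                             unit_id=unit_id)


def ca_kernel(frame_rate: float, tau: float, length_tau: float = 6.0) -> np.ndarray:
    """Step-rise, exponential-decay transient kernel sampled at the frame rate."""
    n = max(2, int(round(length_tau * tau * frame_rate)))
    return np.exp(-np.arange(n) / (tau * frame_rate))


@dataclass
class CalciumTraceData:
    """One ROI's fluorescence trace (dF/F units) at the imaging frame rate."""

    frame_times: np.ndarray
    dff: np.ndarray
    roi_id: str


def generate_calcium(
    config: SynthConfig,
    truth: GroundTruth,
    n_rois: int,
    shared_unit: str | None = None,
    event_rate_scale: float = 1.0,
) -> list[CalciumTraceData]:
    """Per-ROI dF/F traces driven by CS event trains.

    If ``shared_unit`` names a unit in ``truth``, all ROIs share that CS
    train (forcing zero-lag synchrony); otherwise each ROI gets an
    independent CS-like train drawn with the configured rate and ictal
    modulation, scaled by ``event_rate_scale``.
    """
    if config.ca_frame_rate <= 2.0 / config.ca_decay_tau:
        warnings.warn(
            "frame rate too low to resolve transients "
            f"({config.ca_frame_rate} Hz vs decay tau {config.ca_decay_tau} s)",
            stacklevel=2,
        )
    frame_times = np.arange(0.0, config.total_duration, 1.0 / config.ca_frame_rate)
    kern = ca_kernel(config.ca_frame_rate, config.ca_decay_tau)
    traces = []
    for r in range(n_rois):
        rng = _rng(config, 2, r)
        roi = f"ROI{r:03d}"
        if shared_unit is not None:
            events = truth.cs_times[shared_unit]
        else:
            t = np.arange(0.0, config.total_duration, 0.001)
            rate = _rate_profile(config, truth, config.cs_rate * event_rate_scale,
                                 config.mod_depth_cs, config.phase_cs_deg, t,
                                 config.ictal_cs_gain)
            ceiling = (config.cs_rate * event_rate_scale
                       * max(1.0, config.ictal_cs_gain)
                       * (1.0 + config.mod_depth_cs) + 1e-12)
            events = _sample_inhomogeneous_poisson(rate, t, ceiling, rng)
        drive = np.zeros(frame_times.size)
        idx = np.clip(np.round(events * config.ca_frame_rate).astype(int), 0,
                      frame_times.size - 1)
        np.add.at(drive, idx, 1.0)
        dff = np.convolve(drive, kern)[: frame_times.size]
        dff += config.ca_noise_sd * rng.standard_normal(frame_times.size)
        truth.ca_event_times[roi] = events
        traces.append(CalciumTraceData(frame_times=frame_times, dff=dff, roi_id=roi))
    return traces


def generate_voltage_trace(
    config: SynthConfig,
    truth: GroundTruth,
    unit_id: str,
    fs: float = 10_000.0,
    snr: float = 10.0,
    single_template: bool = False,
) -> tuple[np.ndarray, float]:
    """Template-mode extracellular trace for the spike-sorting demo.

    SS use a narrow biphasic template, CS a larger and wider one (unless
    ``single_template``). Noise SD is 1; ``snr`` scales the SS peak.
    """
    rng = _rng(config, 3)
    n = int(round(config.total_duration * fs))
    v = rng.standard_normal(n)

    def template(width_s: float, amp: float) -> np.ndarray:
        tt = np.arange(-3 * width_s, 3 * width_s, 1.0 / fs)
        return -amp * np.exp(-(tt**2) / (2 * width_s**2)) * (1 - (tt / width_s) ** 2 / 3)

    ss_tpl = template(0.0003, snr)
    cs_tpl = ss_tpl if single_template else template(0.0012, 1.8 * snr)
    for times, tpl in ((truth.ss_times[unit_id], ss_tpl), (truth.cs_times[unit_id], cs_tpl)):
        off = int(np.argmin(tpl))
        for ts in times:
            i0 = int(round(ts * fs)) - off
            j0, j1 = max(0, i0), min(n, i0 + tpl.size)
            v[j0:j1] += tpl[j0 - i0 : j1 - i0]
    return v, fs
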