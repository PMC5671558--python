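# Methods

This note records the models, rules and numerical choices behind
`ictalock`, the reasoning where a design was genuinely open, and what the
synthetic benchmarks do and do not establish about real recordings.

## Episode detection

An ECoG spike is a negative peak exceeding `mad_k` (default 4) robust
standard deviations, where the robust SD is 1.4826 × the median absolute
deviation of the whole trace — robust because seizure episodes inflate any
moment-based scale estimate. Peaks closer than 70 ms (well inside the
shortest 6–9 Hz cycle) are collapsed by a refractory rule. Successive peaks
whose intervals fall in [1/9 − 0.02, 1/6 + 0.02] s extend a run; one
interval up to two 6 Hz cycles is tolerated per run so a single missed peak
does not split an episode. Runs with at least three peaks become
candidates; candidates separated by less than `merge_gap` (1 s) are merged,
and merged candidates shorter than `min_episode` (1 s) are discarded.
Merging precedes the duration filter so that two sub-second bursts
separated by a sub-second lull count as one episode, consistent with the
1 s minimal-interval rule.

Episode boundaries are placed half a median cycle outside the first/last
accepted peak. This convention is a choice — peak-based detection has no
intrinsic onset — and the synthetic generator uses the same convention for
its ground-truth intervals, so benchmark boundary errors measure detector
jitter (a few ms at default SNR) rather than bookkeeping disagreements.
Only one channel (M1 by convention) is analyzed; all intervals everywhere
in the package are half-open `[start, end)`.

Interictal periods run from 2 s after one episode to 2 s before the next,
clipped to the recording span; the same tiling function is the single
source of period definitions for spikes and Ca²⁺ events.

## Phase-locking classification

PSTHs use every ECoG spike of every episode as a trigger (overlapping
windows allowed, counts summed), 10 ms bins over ±0.5 s, provided total
episode time is ≥ 2 s. Three measures:

* **amplitude** — max − min of counts within one median GSWD interval of
  *t* = 0 (one cycle contains exactly one peak and one trough; the search
  region had to be fixed somewhere, and ± one cycle is the tightest region
  guaranteed to contain both);
* **dominant frequency** — argmax over 1–50 Hz of the power spectrum of
  the mean-subtracted, Hann-windowed PSTH, zero-padded to ≥ 256 points
  (0.39 Hz grid at 10 ms bins);
* **band power** — mean power over 6–9 Hz.

Nulls come from 500 surrogates that permute the train's ISI sequence
(preserving the ISI multiset, event count and first event time) and rebuild
the PSTH with the same triggers. Surrogate *i* draws from the spawned child
*i* of the master seed, so the surrogate set is reproducible. Z = (X −
μ)/σ against the surrogate distribution; σ = 0 flags the cell instead of
producing an infinite Z.

Classification: CS is phase-locked iff Z_amp ≥ 1.96 and the dominant
frequency lies in 6–9 Hz. SS additionally requires Z_power ≥ 1.96, and
Z_power is the reported SS "Z-score" (CS PSTHs are too sparse for a stable
band-power criterion; the same FFT pipeline is nevertheless applied to both
labels for the frequency gate). Note the conjunctive rules are deliberately
conservative: their joint type-I rate is below the 2.5% of the one-sided
Z-rule alone (measured ~2.5% for CS, ~0% for the triple SS conjunction,
with the Z-rule itself at 4–5%).

**Phase.** The firing phase is 360° × *t*₍peak₎ / median GSWD interval,
wrapped to [0, 360). The peak bin is the first local maximum at *t* ≥ 0
whose counts exceed μ + 1.96σ of the per-bin surrogate null (fallback: the
maximum bin within one cycle). Because a 10 ms bin is 28° at 7.74 Hz,
using a bin edge or center as "the" peak time injects a half-bin bias;
instead the peak time is the mean of the trigger-relative event times
within the peak bin and its two neighbors, which is exact for events
sitting on the trigger and nearly unbiased for smooth peaks (residual bias
~1–2° in the benchmarks).

## Firing-pattern statistics

Computed on the train restricted to the period's intervals; ISIs and
consecutive-ISI pairs never span an interval gap. CV and CV2 (mean of
2|ISIₙ₊₁ − ISIₙ|/(ISIₙ₊₁ + ISIₙ), a within-cell mean over pairs) use SS
ISIs only; CS statistics are the rate and the median climbing-fiber pause
(CS to first subsequent SS within the same interval). For a Poisson train
CV → 1 and E[CV2] = 1 (|b − a|/(a + b) is uniform on (0,1) for i.i.d.
exponentials), which the tests verify to 2% at 10⁵ ISIs.

"Burst" is read as: a spike is a burst member when it lies in a window of
3 consecutive spikes spanning ≤ 100 ms (default), with the looser
every-ISI-< 100 ms run rule available as `burst_rule="isi"`. Either rule
saturates for sustained firing above ~30 Hz, so on healthy simple-spike
rates the burst index is informative mainly for sparse or pause-riddled
periods. Undefined statistics are `None`, never 0. Units with fewer than
100 s of activity produce a warning (the inclusion rule), not an error.

## Pairwise synchrony

Both trains are binned at 10 ms on a shared per-interval grid — per
episode for ictal analysis, per interictal interval otherwise — and the
cross-correlation Σₜ a[t]b[t+ℓ] is summed over intervals for |ℓ| ≤ 250 ms
(no lag spans a gap). Normalization divides by √(Σa² · Σb²), the geometric
mean of the zero-lag autocorrelations, so any train's autocorrelogram is
exactly 1 at lag 0. Positive lag means the second train lags the first;
the peak is the maximum value. 500 bootstrap surrogates ISI-shuffle both
trains within each interval and give per-lag Z-scores; "synchronous at
~0 ms" means max Z over |lag| ≤ one bin exceeds 1.96 (`zero_tol`
configurable). Z is computed per lag (with the near-zero maximum used for
the decision) rather than on the peak only — the per-lag form reports
where the correlation is significant, not merely that it is. CS
correlograms require ≥ 10 ictal CS per train. Period comparisons report
per-pair |peak lag| and peak amplitude with paired t-tests; identical
inputs short-circuit to (t = 0, p = 1) since the t statistic is undefined
at zero variance.

## Ca²⁺ events

The detector is deliberately transparent rather than a reimplementation of
any published black box: baseline = 20th percentile over 10 s blocks,
linearly interpolated; residual centered on its median (otherwise the
percentile offset biases the threshold); noise SD = 1.4826 × MAD; events =
local maxima above k·SD (k = 3.5) with prominence ≥ k·SD (rejects noise
riding on decay tails), a refractory of one decay constant (0.15 s), and a
decay check (value half a τ after the peak ≥ 30% of the peak). Detected
event count is monotone non-increasing in k. dF/F from raw fluorescence is
(F − F₀)/F₀ with the same percentile baseline. Events within one decay
constant of a predecessor are not separable — the dominant recall loss
(~5%) in the benchmarks.

## The synthetic generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs. Episodes: frequencies N(7.74, 1.01) Hz clipped to [6, 9],
durations N(3.53, 1.12) s truncated at 1 s, placed uniformly subject to
gap constraints by allocating the free time over the gap simplex with
sorted uniforms (equivalent to rejection sampling, but it terminates
deterministically and fails with an explicit message when the episodes
cannot fit). The minimum true gap is 2 s: a detector that merges episodes
closer than 1 s cannot be scored against ground truth whose gaps the merge
rule itself would erase. ECoG spike-and-wave morphology is a biphasic
kernel (6 ms-SD negative spike of 10 background SDs; 25 ms-SD positive
wave at 35% amplitude, 55 ms later) on 30 Hz-lowpass unit-SD noise — the
waveform is a plausible stand-in, parameterized so detection is
unambiguous at default settings.

Spike trains: SS are a gamma-renewal process (shape 4 by default — CV ≈
0.5, an irregularity between clock-like and Poisson) sampled by time
rescaling of the integrated rate, CS a Poisson process sampled by thinning
a ceiling rate; both are exact for the intended inhomogeneous rate
1 + m·cos(2πf(t − t₀) − φ) inside episodes (t₀ = the episode's first ECoG
spike, so φ = 0 peaks on the ECoG spike), optionally scaled by an ictal
gain. CS default phase (20°) places the CS peak just after the ECoG spike
— a modeling choice, since only the qualitative "after the start of the
falling phase" is constrained. After every CS, SS within the
climbing-fiber pause (10 ms) are removed. Ca²⁺ traces convolve the CS
train with a step-rise/exp-decay kernel (τ = 0.15 s) at 50 Hz and add
white noise (SD 0.125 → peak SNR 8).

What the generator does **not** emulate: recording drift and unit
isolation failures, spike-sorting errors (CS/SS labels are exact),
non-stationary background rates, waveform-level CS/SS interactions beyond
the pause, movement and imaging artifacts, and any real spatial structure
across cells. Passing benchmarks therefore demonstrate the correctness and
calibration of the *analysis* under the stated generative model, not
field-data performance.

## Benchmark sizes and determinism

The statistical benchmarks use 200 unmodulated cells (type-I calibration),
100 modulated cells (recovery), 50 recordings (detector fidelity), 200
independent pairs plus 10 six-pair cohorts (synchrony), and 100 cohorts of
46 ROIs (Ca²⁺ contrast), on 100–200 s recordings with 8–20 episodes —
sizes chosen to keep each inclusion rule satisfiable (≥ 2 s ictal data,
≥ 10 ictal CS, non-empty interictal tiling) while every check completes in
minutes. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` substreams: identical seed + config give
byte-identical outputs, and a run manifest (config + seed + version)
suffices to replay any pipeline run exactly.

## Known limitations

* The episode detector assumes the sharp deflection is negative and the
  6–9 Hz band; other discharge morphologies need re-parameterization.
* The burst index saturates at sustained high rates (above).
* Phase estimates inherit PSTH bin quantization (±½ bin worst case even
  with the sub-bin estimator) and need ~10+ episodes to stabilize for CS.
* The spike-sorting demo (threshold + 2-means on amplitude/width) is a
  demonstration for template-synthesized traces, not a production sorter.
* Cross-correlogram normalization makes amplitudes comparable across
  pairs, but rate differences between periods still affect bootstrap power;
  conclusions should rest on the Z-scores, not raw amplitudes.
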