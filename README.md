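# ictalock

Phase-locking and synchrony analysis of cerebellar Purkinje-cell activity
during absence seizures.

## The problem

During an absence seizure the cortex produces **generalized spike-and-wave
discharges (GSWDs)**: 6–9 Hz trains of sharp negative ECoG deflections, each
followed by a slow wave. Purkinje cells of the cerebellar cortex fire two
kinds of action potentials — low-rate **complex spikes** (CS, ~1 Hz, driven
by a climbing fiber from the inferior olive) and high-rate **simple spikes**
(SS, tens of Hz) — and a central question for cerebellar involvement in
absence epilepsy is whether, and how tightly, this firing locks to the
seizure rhythm and synchronizes across cells.

`ictalock` implements the complete analysis chain for that question, for
electrophysiologists working with simultaneous ECoG + single-unit (or
two-photon Ca²⁺) recordings:

1. **Episode detection** — negative ECoG peaks above a robust
   (MAD-scaled) threshold, grouped into runs whose inter-peak intervals lie
   in the 6–9 Hz band; runs shorter than 1 s are discarded and runs closer
   than 1 s merged. Interictal periods exclude a ±2 s guard band around
   every episode.
2. **Phase-locking classification** — ECoG-spike-triggered PSTHs (10 ms
   bins) summarized by modulation amplitude (peak − trough near *t* = 0),
   FFT dominant frequency, and mean 6–9 Hz power; chance levels from 500
   ISI-shuffle surrogates give *Z* = (X − μ)/σ. CS firing is phase-locked
   when *Z*₍amp₎ ≥ 1.96 and the dominant frequency lies in 6–9 Hz; SS
   additionally requires *Z*₍power₎ ≥ 1.96. The firing phase is
   360° · *t*₍first peak₎ / median GSWD interval.
3. **Firing-pattern statistics** — per period (ictal/interictal): CS and SS
   rates, CV (σ_ISI/μ_ISI), CV2 (mean of 2|ISIₙ₊₁ − ISIₙ|/(ISIₙ₊₁ + ISIₙ)),
   burst index (fraction of spikes in runs of ≥ 3 spikes within 100 ms),
   and the median climbing-fiber pause (CS → next SS; ≥ 10 ms median
   identifies a Purkinje cell).
4. **Pairwise synchrony** — 10 ms-binned cross-correlograms normalized so
   zero-lag autocorrelations equal 1, with per-lag *Z*-scores from 500
   bootstrap surrogates that ISI-shuffle both trains; a pair is synchronous
   when *Z* > 1.96 within one bin of zero lag. CS pairs require ≥ 10 ictal
   CS per train.
5. **Ca²⁺ events** — transient detection on per-ROI dF/F traces
   (percentile baseline + MAD threshold + decay check) feeding the same
   synchrony machinery, plus a paired ictal/interictal rate contrast.

A first-class **synthetic-data generator** (`ictalock.synth`) emulates the
recordings — episodes at N(7.74, 1.01) Hz lasting N(3.53, 1.12) s,
gamma-renewal SS, Poisson CS with configurable phase-locking depth/phase
and climbing-fiber pause, and kernel-convolved Ca²⁺ traces — with full
ground truth, so every stage is testable without any animal data.

## Worked example

```python
from ictalock.gswd import detect_gswds
from ictalock.modulation import analyze_modulation
from ictalock.synth import SynthConfig, generate_ecog, generate_purkinje_train

cfg = SynthConfig(total_duration=130.0, n_episodes=20, gswd_rate_mean=7.0,
                  gswd_rate_sd=0.0, mod_depth_cs=0.8, mod_depth_ss=0.8,
                  phase_cs_deg=20.0, phase_ss_deg=200.0, seed=3)
rec, truth = generate_ecog(cfg)
episodes = detect_gswds(rec)             # recovers all 20 episodes
train = generate_purkinje_train(cfg, truth, unit_id="PC00")
for label, times in (("CS", train.cs_times), ("SS", train.ss_times)):
    r = analyze_modulation(times, episodes, label, n_shuffles=500, seed=11)
    print(label, r.modulated, round(r.z_score, 2), round(r.phase_deg, 1))
```

prints

```
CS True 3.3 36.4
SS True 1019.47 213.2
```

i.e. both spike types are classified as phase-locked (Z ≥ 1.96 at a 6–9 Hz
dominant frequency), with the CS peak just after the ECoG spike (~20°
generated, 36° recovered at 10 ms bin resolution) and SS roughly antiphase
(~200° generated, 213° recovered) — the inverse CS/SS phase relation this
analysis is designed to expose. `examples/` contains one short script per
capability (simulation, detection, classification, firing statistics,
synchrony, calcium).

A thin CLI mirrors the stages:
`ictalock simulate|detect-gswd|firing-stats|modulate|synchrony|calcium|run`.

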