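"""Generate a synthetic recording session with ground truth.

Builds 120 s of ECoG with ten 6-9 Hz spike-and-wave episodes, one
phase-locked Purkinje cell, and prints what the generator embedded.
"""

import numpy as np

from ictalock.synth import SynthConfig, generate_ecog, generate_purkinje_train

cfg = SynthConfig(
    total_duration=120.0,
    n_episodes=10,
    mod_depth_ss=0.8,     # strong simple-spike phase locking inside episodes
    mod_depth_cs=0.8,
    seed=1,
)
rec, truth = generate_ecog(cfg)
train = generate_purkinje_train(cfg, truth, unit_id="PC00")

ict = sum(e - s for s, e in truth.episodes)
print(f"recording: {rec.duration:.0f} s at {rec.fs:.0f} Hz, channel {rec.channel_names[0]}")
print(f"episodes:  {len(truth.episodes)} covering {ict:.1f} s "
      f"({truth.ecog_spike_times.size} ECoG spikes)")
freqs = [1 / np.diff(sp).mean() for sp in truth.spikes_per_episode]
print(f"episode frequencies: {min(freqs):.2f}-{max(freqs):.2f} Hz "
      "(drawn from N(7.74, 1.01), clipped to 6-9 Hz)")
print(f"unit PC00: {train.cs_times.size} complex spikes (~1 Hz), "
      f"{train.ss_times.size} simple spikes (~{train.ss_times.size / rec.duration:.0f} Hz)")
# Every number above is ground truth: downstream examples must recover them.
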