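"""Detect spike-and-wave episodes in ECoG and derive interictal periods.

Episodes are runs of large negative peaks repeating at 6-9 Hz, at least
1 s long, merged when separated by less than 1 s; interictal time excludes
a 2 s guard band around every episode.
"""

from ictalock.gswd import detect_gswds, ictal_intervals, interictal_intervals
from ictalock.synth import SynthConfig, generate_ecog

cfg = SynthConfig(total_duration=120.0, n_episodes=10, seed=1)
rec, truth = generate_ecog(cfg)

episodes = detect_gswds(rec, channel="M1", mad_k=4.0)
print(f"detected {len(episodes)} episodes (ground truth: {len(truth.episodes)})")
for ep, (ts, te) in zip(episodes, truth.episodes):
    print(f"  [{ep.start:7.2f}, {ep.end:7.2f}] s  {ep.n_spikes:3d} spikes  "
          f"{1 / ep.median_interval:4.2f} Hz   boundary error "
          f"{1e3 * max(abs(ep.start - ts), abs(ep.end - te)):4.1f} ms")

span = (0.0, rec.duration)
ict = ictal_intervals(episodes)
inter = interictal_intervals(episodes, span, guard=2.0)
print(f"ictal time      {sum(e - s for s, e in ict):6.1f} s")
print(f"interictal time {sum(e - s for s, e in inter):6.1f} s "
      "(2 s guard bands around every episode excluded)")
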