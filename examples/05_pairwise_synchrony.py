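"""Pairwise synchrony via surrogate-calibrated cross-correlograms.

Two simple-spike trains share a cosine drive only inside episodes; their
10 ms-binned cross-correlogram is compared against 500 ISI-shuffle
bootstraps, separately for ictal and interictal periods.
"""

from ictalock.gswd import interictal_intervals
from ictalock.synchrony import bootstrap_z, cross_correlogram, is_synchronous
from ictalock.synth import SynthConfig, generate_ecog, generate_purkinje_train

cfg = SynthConfig(total_duration=200.0, n_episodes=12, gswd_rate_mean=7.0,
                  gswd_rate_sd=0.0, mod_depth_ss=0.8, ss_rate=50.0, seed=900)
rec, truth = generate_ecog(cfg)
a = generate_purkinje_train(cfg, truth, unit_id="PC00", unit_index=0)
b = generate_purkinje_train(cfg, truth, unit_id="PC01", unit_index=1)

ict = list(truth.episodes)
inter = interictal_intervals(ict, (0.0, cfg.total_duration))
for period, ivs in (("ictal", ict), ("interictal", inter)):
    ccg = cross_correlogram(a.ss_times, b.ss_times, ivs, period=period,
                            pair=("PC00", "PC01"))
    ccg = bootstrap_z(a.ss_times, b.ss_times, ivs, ccg, n_boot=500, seed=4)
    print(f"{period:>10}: peak lag {1e3 * ccg.peak_lag:6.1f} ms  "
          f"peak amp {ccg.peak_amp:.3f}  Z(~0 ms) {ccg.z_near_zero(0.010):6.2f}  "
          f"synchronous={is_synchronous(ccg)}")
print("Shared ictal-only modulation makes the pair synchronous (Z > 1.96")
print("within one bin of zero lag) during episodes but not between them.")
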