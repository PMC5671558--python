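"""Firing statistics: CV/CV2/burst oracles, Purkinje identification,
interval restriction, and the threshold-and-cluster sorting demo."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ictalock.synth import SynthConfig, generate_ecog, generate_purkinje_train, generate_voltage_trace
from ictalock.trains import (
    CS,
    SS,
    LabeledSpikeTrain,
    detect_and_sort,
    firing_stats,
    restrict,
    validate_purkinje,
)


def make_train(ss_times, cs_times=(), duration=None):
    times = np.concatenate([np.asarray(cs_times, float), np.asarray(ss_times, float)])
    labels = np.array([CS] * len(cs_times) + [SS] * len(ss_times), dtype=object)
    order = np.argsort(times)
    dur = duration if duration is not None else float(times.max()) + 1.0
    return LabeledSpikeTrain(times[order], labels[order], duration=dur)


class TestValidatePurkinje:
    def test_single_pair_pause_is_the_median(self):
        tr = make_train(ss_times=[1.015], cs_times=[1.000])
        v = validate_purkinje(tr)
        assert v.valid and v.median_pause == pytest.approx(0.015)

    def test_short_pauses_fail_identification(self):
        tr = make_train(ss_times=[1.005, 2.004, 3.006], cs_times=[1.0, 2.0, 3.0])
        v = validate_purkinje(tr)
        assert not v.valid and v.median_pause < 0.010

    def test_no_cs_is_not_validated_with_reason(self):
        tr = make_train(ss_times=[0.5, 1.0, 1.5])
        v = validate_purkinje(tr)
        assert not v.valid and v.reason == "no CS"


class TestRestrict:
    def test_full_span_is_identity(self):
        tr = make_train(ss_times=[1.0, 2.0, 3.0], duration=5.0)
        r = restrict(tr, [(0.0, 5.0)])
        assert np.array_equal(r.times, tr.times)
        assert r.analysis_time == 5.0

    def test_membership_and_analysis_time(self):
        tr = make_train(ss_times=[1.0, 2.0, 3.0, 11.0, 12.0], duration=20.0)
        r = restrict(tr, [(0.0, 5.0)])
        assert np.array_equal(r.times, [1.0, 2.0, 3.0])
        assert r.analysis_time == 5.0

    def test_interval_end_is_exclusive(self):
        tr = make_train(ss_times=[1.0, 5.0], duration=20.0)
        r = restrict(tr, [(0.0, 5.0)])
        assert np.array_equal(r.times, [1.0])

    def test_empty_interval_list(self):
        tr = make_train(ss_times=[1.0], duration=2.0)
        r = restrict(tr, [])
        assert r.times.size == 0 and r.analysis_time == 0.0


class TestFiringStats:
    def test_regular_train_has_zero_cv_and_cv2(self):
        tr = make_train(ss_times=np.arange(0.0, 10.0, 0.02), duration=10.0)
        fs = firing_stats(tr)
        assert fs.cv == pytest.approx(0.0, abs=1e-9)
        assert fs.cv2 == pytest.approx(0.0, abs=1e-9)

    def test_cv2_of_single_isi_pair(self):
        # ISIs 10 ms and 30 ms: CV2 = 2|30-10|/(30+10) = 1.0
        tr = make_train(ss_times=[0.0, 0.010, 0.040], duration=1.0)
        assert firing_stats(tr).cv2 == pytest.approx(1.0)

    def test_poisson_train_cv_and_cv2_near_one(self, rng):
        isis = rng.exponential(1 / 50.0, size=100_000)
        tr = make_train(ss_times=np.cumsum(isis), duration=float(isis.sum()) + 1)
        fs = firing_stats(tr)
        assert abs(fs.cv - 1.0) < 0.01
        assert abs(fs.cv2 - 1.0) < 0.02

    def test_burst_index_worked_example(self):
        # spikes at 0, 20, 40, 1000, 2000 ms: one 3-spike burst of 5 spikes
        tr = make_train(ss_times=[0.0, 0.020, 0.040, 1.0, 2.0], duration=3.0)
        assert firing_stats(tr).burst_index == pytest.approx(0.6)

    def test_zero_analysis_time_leaves_stats_undefined(self):
        tr = make_train(ss_times=[1.0], duration=2.0)
        fs = firing_stats(tr, [])
        assert fs.cs_rate is None and fs.ss_rate is None and fs.cv is None

    def test_rates_compose_across_disjoint_intervals(self):
        cfg = SynthConfig(total_duration=60.0, n_episodes=0, seed=2)
        _, truth = generate_ecog(cfg)
        tr = generate_purkinje_train(cfg, truth)
        iv1, iv2 = [(5.0, 20.0)], [(30.0, 50.0)]
        both = firing_stats(tr, iv1 + iv2)
        f1, f2 = firing_stats(tr, iv1), firing_stats(tr, iv2)
        t1, t2 = f1.analysis_time, f2.analysis_time
        assert both.ss_rate == pytest.approx((f1.ss_rate * t1 + f2.ss_rate * t2) / (t1 + t2))
        assert both.cs_rate == pytest.approx((f1.cs_rate * t1 + f2.cs_rate * t2) / (t1 + t2))

    def test_isis_never_span_interval_gaps(self):
        # two clusters; the 5 s gap between them must not enter the ISI stats
        tr = make_train(ss_times=[1.0, 1.1, 1.2, 6.0, 6.1, 6.2], duration=10.0)
        fs = firing_stats(tr, [(0.0, 2.0), (5.0, 7.0)])
        assert fs.cv == pytest.approx(0.0, abs=1e-9)  # all within-segment ISIs equal

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_statistic_bounds_on_random_trains(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 200))
        times = np.sort(r.uniform(0, 10, size=n))
        times = times[np.concatenate(([True], np.diff(times) > 0))]
        tr = make_train(ss_times=times, duration=11.0)
        fs = firing_stats(tr)
        if fs.cv2 is not None:
            assert 0.0 <= fs.cv2 <= 2.0
        assert 0.0 <= fs.burst_index <= 1.0


def test_ictal_cs_rate_increase_recovered_across_cells():
    """Cells generated with 2x ictal CS gain show positive rate change
    (paired t over cells, p < 0.01)."""
    from scipy import stats as sps
    from ictalock.gswd import interictal_intervals

    deltas = []
    for s in range(40):
        cfg = SynthConfig(total_duration=100.0, n_episodes=6, cs_rate=1.0,
                          ictal_cs_gain=2.0, ss_rate=30.0, seed=8200 + s)
        _, truth = generate_ecog(cfg)
        tr = generate_purkinje_train(cfg, truth)
        ict = list(truth.episodes)
        inter = interictal_intervals(ict, (0.0, 100.0))
        f_i = firing_stats(tr, ict)
        f_n = firing_stats(tr, inter)
        deltas.append(f_i.cs_rate - f_n.cs_rate)
    deltas = np.asarray(deltas)
    t, p = sps.ttest_1samp(deltas, 0.0)
    assert deltas.mean() > 0
    assert p < 0.01 and t > 0


class TestDetectAndSort:
    def test_two_template_trace_sorted_accurately(self):
        cfg = SynthConfig(total_duration=10.0, n_episodes=0, ss_rate=40.0,
                          cs_rate=1.0, seed=17)
        _, truth = generate_ecog(cfg)
        tr = generate_purkinje_train(cfg, truth, unit_id="u")
        v, fs = generate_voltage_trace(cfg, truth, "u", snr=10.0)
        sorted_tr = detect_and_sort(v, fs)
        # match detected events to ground truth by time, compare labels
        correct = total = 0
        for t, lab in zip(sorted_tr.times, sorted_tr.labels):
            d_cs = np.min(np.abs(truth.cs_times["u"] - t)) if truth.cs_times["u"].size else 1
            d_ss = np.min(np.abs(truth.ss_times["u"] - t)) if truth.ss_times["u"].size else 1
            if min(d_cs, d_ss) < 0.002:
                total += 1
                correct += (lab == CS) == (d_cs < d_ss)
        assert total >= 10
        assert correct / total >= 0.99

    def test_pure_noise_rejected(self):
        v = np.random.default_rng(0).standard_normal(50_000) * 0.1
        with pytest.raises(ValueError, match="insufficient events"):
            detect_and_sort(v, 10_000.0)

    def test_single_template_sets_warning_flag(self):
        cfg = SynthConfig(total_duration=10.0, n_episodes=0, ss_rate=40.0,
                          cs_rate=1.0, seed=18)
        _, truth = generate_ecog(cfg)
        generate_purkinje_train(cfg, truth, unit_id="u")
        v, fs = generate_voltage_trace(cfg, truth, "u", snr=10.0, single_template=True)
        with pytest.warns(UserWarning, match="clusters"):
            tr = detect_and_sort(v, fs)
        assert "sort_warning" in tr.meta
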