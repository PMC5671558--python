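"""PSTH construction, FFT measures, ISI-shuffle nulls, classification rules
and the phase formula."""

import numpy as np
import pytest

from ictalock.gswd import GswdEpisode
from ictalock.modulation import (
    ModulationMeasures,
    NullDistribution,
    Psth,
    ShuffleNull,
    analyze_modulation,
    build_psth,
    classify_modulation,
    fft_resolution,
    median_gswd_interval,
    modulation_measures,
    phase_difference,
    phase_from_peak_time,
    shuffle_isis,
    shuffle_null,
)
from ictalock.synth import SynthConfig, generate_ecog, generate_purkinje_train


def make_episode(start, end, f=8.0):
    spikes = np.arange(start + 0.5 / f, end - 0.4 / f, 1.0 / f)
    return GswdEpisode(start, end, spikes, float(np.median(np.diff(spikes))))


@pytest.fixture(scope="module")
def episodes():
    return [make_episode(5.0 + 6.0 * k, 9.0 + 6.0 * k) for k in range(5)]


class TestBuildPsth:
    def test_events_on_triggers_fill_only_the_zero_bin(self, episodes):
        triggers = np.concatenate([ep.ecog_spike_times for ep in episodes])
        psth = build_psth(np.unique(triggers), episodes)
        zero_bin = np.flatnonzero(psth.left_edges == 0.0)[0]
        assert psth.counts[zero_bin] == triggers.size
        # events in other bins come only from neighboring triggers' windows
        assert psth.counts[zero_bin] == psth.counts.max()

    def test_window_and_bin_width_give_100_bins(self, episodes):
        psth = build_psth(np.array([6.0, 7.0]), episodes, bin_width=0.010, window=0.5)
        assert psth.counts.size == 100

    def test_homogeneous_events_give_flat_psth(self, episodes, rng):
        events = np.sort(rng.uniform(0.0, 35.0, size=20_000))
        psth = build_psth(events, episodes)
        from scipy.stats import chisquare

        # central bins (fully covered windows) should be uniform
        sel = np.abs(psth.centers) <= 0.3
        stat, p = chisquare(psth.counts[sel])
        assert p > 0.01

    def test_insufficient_ictal_data_rejected(self):
        eps = [make_episode(2.0, 3.5)]
        with pytest.raises(ValueError, match="insufficient ictal"):
            build_psth(np.array([1.0, 2.0]), eps)


class TestMeasures:
    def _psth_from_counts(self, counts, cycle=0.129):
        n = counts.size
        edges = -0.5 + np.arange(n + 1) * 0.010
        return Psth(0.010, 0.5, edges, counts.astype(float), n_triggers=1, cycle=cycle)

    def test_pure_cosine_dominant_frequency(self):
        t = -0.495 + 0.010 * np.arange(100)
        counts = 10 + 5 * np.cos(2 * np.pi * 7.0 * t)
        m = modulation_measures(self._psth_from_counts(counts))
        assert abs(m.dominant_freq - 7.0) <= fft_resolution(100, 0.010)

    def test_flat_psth_has_zero_amplitude(self):
        m = modulation_measures(self._psth_from_counts(np.full(100, 7.0)))
        assert m.amplitude == 0.0

    def test_cosine_amplitude_is_twice_the_cosine_coefficient(self):
        t = -0.495 + 0.010 * np.arange(100)
        a = 4.0
        counts = 20 + a * np.cos(2 * np.pi * 7.75 * t)
        m = modulation_measures(self._psth_from_counts(counts))
        assert m.amplitude == pytest.approx(2 * a, rel=0.02)

    def test_all_zero_psth_undefined_frequency(self):
        m = modulation_measures(self._psth_from_counts(np.zeros(100)))
        assert m.amplitude == 0.0 and m.dominant_freq is None


class TestShuffle:
    def test_shuffle_preserves_isi_multiset_count_and_span(self, rng):
        times = np.sort(rng.uniform(0, 50, 200))
        for i in range(20):
            s = shuffle_isis(times, rng)
            assert s.size == times.size
            assert s[0] == times[0]
            assert np.allclose(np.sort(np.diff(s)), np.sort(np.diff(times)))
            assert s[-1] == pytest.approx(times[-1])

    def test_null_distributions_have_matching_sizes(self, episodes, rng):
        events = np.sort(rng.uniform(0, 35, 2000))
        null = shuffle_null(events, episodes, n_shuffles=50, seed=0)
        assert null.amplitude.values.size == 50
        assert null.power.values.size == 50
        assert null.amplitude.sigma >= 0

    def test_observed_percentile_uniform_under_null(self, episodes):
        """For unmodulated trains the observed amplitude percentile within
        its own shuffle null is uniform (calibration of the null)."""
        from scipy.stats import kstest

        pct = []
        master = np.random.default_rng(99)
        for _ in range(120):
            events = np.sort(master.uniform(0.0, 35.0, size=1500))
            psth = build_psth(events, episodes)
            m = modulation_measures(psth)
            null = shuffle_null(events, episodes, n_shuffles=150,
                                seed=int(master.integers(2**31)))
            pct.append(np.mean(null.amplitude.values < m.amplitude))
        stat, p = kstest(pct, "uniform")
        assert p > 0.01


def _null(mu_a=10.0, sd_a=2.0, mu_p=5.0, sd_p=1.0):
    return ShuffleNull(
        amplitude=NullDistribution("amplitude", np.array([]), mu_a, sd_a),
        power=NullDistribution("mean_power_6_9", np.array([]), mu_p, sd_p),
        bin_mu=np.zeros(100),
        bin_sigma=np.ones(100),
        n_shuffles=500,
    )


class TestClassify:
    def _measures(self, amp, freq, power=100.0):
        return ModulationMeasures(amp, freq, power, np.array([]), np.array([]))

    def test_significant_amplitude_in_band_is_modulated(self):
        r = classify_modulation(self._measures(15.0, 7.2), _null(), "CS")
        assert r.modulated and r.z_amplitude == pytest.approx(2.5)

    def test_out_of_band_frequency_is_not_modulated(self):
        r = classify_modulation(self._measures(15.0, 4.0), _null(), "CS")
        assert not r.modulated

    def test_observation_equal_to_null_mean_gives_z_zero(self):
        r = classify_modulation(self._measures(10.0, 7.0, power=5.0), _null(), "CS")
        assert r.z_amplitude == 0.0 and not r.modulated

    def test_ss_additionally_requires_power_z(self):
        weak_power = self._measures(15.0, 7.2, power=5.5)  # power z = 0.5
        assert not classify_modulation(weak_power, _null(), "SS").modulated
        strong = self._measures(15.0, 7.2, power=9.0)      # power z = 4
        r = classify_modulation(strong, _null(), "SS")
        assert r.modulated and r.z_score == pytest.approx(4.0)

    def test_degenerate_null_flags_cell(self):
        n = _null(sd_a=0.0)
        r = classify_modulation(self._measures(15.0, 7.2), n, "CS")
        assert not r.modulated and "degenerate" in r.reason


class TestPhase:
    def test_phase_formula_worked_example(self):
        # 64.5 ms peak on a 129 ms median interval is half a cycle: 180 deg
        assert phase_from_peak_time(0.0645, 0.129) == pytest.approx(180.0)

    def test_peak_on_trigger_gives_zero_phase(self):
        edges = -0.5 + np.arange(101) * 0.010
        counts = np.zeros(100)
        zero_bin = np.flatnonzero(edges[:-1] == 0.0)[0]
        counts[zero_bin] = 50
        psth = Psth(0.010, 0.5, edges, counts, 50, cycle=0.129,
                    rel_times=np.zeros(50))
        assert phase_difference(psth) == pytest.approx(0.0)

    def test_phase_wraps_at_full_cycle(self):
        assert phase_from_peak_time(0.129, 0.129) == pytest.approx(0.0)


class TestRecovery:
    def test_modulated_cell_recovered_with_frequency_and_phase(self, modulated_bundle):
        cfg, _, truth, episodes, train = modulated_bundle
        res = analyze_modulation(train.ss_times, episodes, "SS", "PC0",
                                 n_shuffles=500, seed=11)
        assert res.modulated
        assert abs(res.dominant_freq - 7.0) <= fft_resolution(100, 0.010)
        err = (res.phase_deg - cfg.phase_ss_deg + 180.0) % 360.0 - 180.0
        assert abs(err) <= 28.0

    def test_unmodulated_cell_not_flagged(self, quiet_bundle):
        _, _, _, episodes, train = quiet_bundle
        res = analyze_modulation(train.ss_times, episodes, "SS", n_shuffles=500, seed=5)
        assert not res.modulated

    def test_antiphase_cs_ss_relationship_recovered(self):
        """Generator with CS and SS 180 deg apart: recovered population
        phases differ by 180 +- 30 deg (CS peaks on the ECoG spike while SS
        pause, the inverse relation seen in phase-locked cells)."""
        cs_ph, ss_ph = [], []
        for u in range(6):
            cfg = SynthConfig(total_duration=260.0, n_episodes=40, gswd_rate_mean=7.0,
                              gswd_rate_sd=0.0, mod_depth_ss=0.8, mod_depth_cs=0.8,
                              phase_cs_deg=20.0, phase_ss_deg=200.0, seed=77 + u)
            rec, truth = generate_ecog(cfg)
            from ictalock.gswd import detect_gswds
            eps = detect_gswds(rec)
            tr = generate_purkinje_train(cfg, truth, unit_index=u)
            rss = analyze_modulation(tr.ss_times, eps, "SS", n_shuffles=500, seed=[1, u])
            rcs = analyze_modulation(tr.cs_times, eps, "CS", n_shuffles=500, seed=[2, u])
            if rss.phase_deg is not None:
                ss_ph.append(rss.phase_deg)
            if rcs.phase_deg is not None:
                cs_ph.append(rcs.phase_deg)
        assert len(cs_ph) >= 3 and len(ss_ph) >= 3

        def circ_mean(deg):
            a = np.deg2rad(deg)
            return np.rad2deg(np.angle(np.mean(np.exp(1j * a)))) % 360.0

        diff = abs(((circ_mean(cs_ph) - circ_mean(ss_ph)) + 180.0) % 360.0 - 180.0)
        assert abs(diff - 180.0) <= 30.0


def test_median_gswd_interval_matches_generator_frequency(modulated_bundle):
    _, _, _, episodes, _ = modulated_bundle
    assert median_gswd_interval(episodes) == pytest.approx(1.0 / 7.0, rel=0.02)
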