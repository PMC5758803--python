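"""Response windows, window measurement, spontaneous null and echo classification."""

import numpy as np
import pytest

from echotune.errors import InvalidArgumentError
from echotune.responses import (
    ResponseWindow,
    build_windows,
    classify_echo,
    empirical_bayes_rates,
    estimate_spont_rate,
    measure_window,
    summarize_neuron,
)
from echotune.signal import DffTrace, Transient, compute_dff, detect_transients
from echotune.stimulus import make_protocol
from echotune.synth import sample_population, synthesize_trace

FR = 40.0


def _flat_dff(duration_s=800.0, fr=FR):
    n = int(duration_s * fr) + 1
    return DffTrace(neuron_id="z", frame_rate_hz=fr, dff=np.zeros(n), f0=100.0)


def _transient(onset, amp=0.06):
    return Transient("z", onset, onset + 0.18, amp, 0.4, onset + 1.0)


class TestBuildWindows:
    def test_echo_window_centers_follow_the_isi(self, protocol11):
        windows = build_windows(protocol11, k_max=5)
        t_end = protocol11.train_end_s(0)
        centers = sorted(
            w.ref_time_s for w in windows if w.kind == "echo" and w.freq_hz == protocol11.frequencies_hz[0]
        )
        assert np.allclose(centers, t_end + 2.0 * np.arange(1, 6))

    def test_no_echo_windows_for_kmax_zero(self, protocol11):
        windows = build_windows(protocol11, k_max=0)
        assert not [w for w in windows if w.kind in ("echo", "baseline")]
        assert len([w for w in windows if w.kind == "sound"]) == 220

    def test_echo_windows_disjoint_brute_force(self, protocol11):
        windows = [
            w
            for w in build_windows(protocol11, echo_halfwidth_s=0.9 * protocol11.isi_s / 2)
            if w.kind == "echo"
        ]
        for a in windows:
            for b in windows:
                if a is not b:
                    assert a.end_s <= b.start_s or b.end_s <= a.start_s

    def test_overlap_rejected(self, protocol11):
        with pytest.raises(InvalidArgumentError):
            build_windows(protocol11, echo_halfwidth_s=1.0)

    def test_baseline_windows_tile_pretrain_silence(self, protocol11):
        windows = build_windows(protocol11)
        base0 = [w for w in windows if w.kind == "baseline" and w.freq_hz == protocol11.frequencies_hz[0]]
        assert len(base0) == 5
        assert max(w.end_s for w in base0) == pytest.approx(protocol11.train_onsets_s[0])
        assert all(w.width_s == pytest.approx(1.5) for w in base0)


class TestMeasureWindow:
    def test_zero_trace(self):
        dff = _flat_dff(100.0)
        w = ResponseWindow("sound", 10.0, 8000.0, 10.0, 10.5)
        amp, lat = measure_window(dff, [], w)
        assert amp == 0.0 and lat is None

    def test_integral_matches_closed_form(self):
        fr = 200.0  # fine grid keeps the trapezoid error below the 2% bound
        n = int(20 * fr) + 1
        t = np.arange(n) / fr
        onset = 5.1
        sig = np.where(t >= onset, np.exp(-(t - onset) / 0.7) - np.exp(-(t - onset) / 0.07), 0.0)
        tpk = 0.07 * 0.7 / 0.63 * np.log(10.0)
        peak = np.exp(-tpk / 0.7) - np.exp(-tpk / 0.07)
        dff = DffTrace("z", fr, sig / peak, 100.0)
        w = ResponseWindow("sound", 5.0, 8000.0, 5.0, 5.5)
        amp, _ = measure_window(dff, [], w, mode="integral")
        # closed-form integral of the unit-peak kernel over [0, 0.4]
        exact = (0.7 * (1 - np.exp(-0.4 / 0.7)) - 0.07 * (1 - np.exp(-0.4 / 0.07))) / peak
        assert amp == pytest.approx(exact, rel=0.02)

    def test_latency_from_generator_log(self, protocol11):
        gt = sample_population(1, echo_fraction=0.0, seed=8)[0]
        object.__setattr__(gt, "sound_latency_s", 0.083)
        tr, events = synthesize_trace(gt, protocol11, noise_sd=0.0, seed=8)
        dff = compute_dff(tr)
        transients = detect_transients(dff, noise_sd=0.004)
        fi = int(np.argmin(np.abs(np.asarray(protocol11.frequencies_hz) - gt.bf_hz)))
        onset0 = protocol11.tone_onsets_s(fi)[0]
        w = ResponseWindow("sound", float(onset0), protocol11.frequencies_hz[fi], float(onset0), float(onset0 + 0.5))
        _, lat = measure_window(dff, transients, w)
        ev = min(
            (e for e in events if e.category == "evoked" and abs(e.time_s - onset0) < 0.5),
            key=lambda e: e.time_s,
        )
        assert lat is not None
        assert lat == pytest.approx(ev.time_s - onset0, abs=0.075)

    def test_window_outside_trace_rejected(self):
        dff = _flat_dff(10.0)
        with pytest.raises(InvalidArgumentError):
            measure_window(dff, [], ResponseWindow("sound", 50.0, 1000.0, 50.0, 50.5))


class TestEstimateSpontRate:
    def test_no_transients_zero_rate(self, protocol11):
        assert estimate_spont_rate([], protocol11, (0.0, 800.0)) == 0.0

    def test_transients_only_inside_trains_excluded(self, protocol11):
        trs = [_transient(protocol11.train_onsets_s[i] + 5.0) for i in range(protocol11.n_freqs)]
        assert estimate_spont_rate(trs, protocol11, (0.0, 800.0)) == 0.0

    def test_poisson_rate_recovery_within_3se(self, protocol11):
        rate, dur = 0.05, 800.0
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, dur, rng.poisson(rate * dur)))
        trs = [_transient(t) for t in times]
        est, free = estimate_spont_rate(trs, protocol11, (0.0, dur), return_free_time=True)
        se = np.sqrt(rate / free)
        assert est == pytest.approx(rate, abs=3 * se)

    def test_insufficient_free_time_rejected(self, protocol11):
        start = protocol11.train_onsets_s[0]
        with pytest.raises(InvalidArgumentError):
            estimate_spont_rate([], protocol11, (start, start + 50.0))


class TestEmpiricalBayes:
    def test_homogeneous_counts_shrink_to_pooled(self):
        rng = np.random.default_rng(1)
        T = np.full(200, 250.0)
        k = rng.poisson(0.01 * 250.0, 200)
        rates = empirical_bayes_rates(k, T)
        pooled = k.sum() / T.sum()
        assert np.all(np.abs(rates - pooled) < 0.5 * pooled + 1e-4)

    def test_heterogeneous_counts_keep_ordering(self):
        T = np.full(100, 300.0)
        k = np.concatenate([np.zeros(50), np.full(50, 12.0)])
        rates = empirical_bayes_rates(k, T)
        assert rates[0] < rates[-1]

    def test_small_population_pseudo_count(self):
        rates = empirical_bayes_rates(np.array([0.0, 2.0]), np.array([100.0, 100.0]))
        assert rates[0] == pytest.approx(0.005)
        assert rates[1] == pytest.approx(0.025)


class TestClassifyEcho:
    def test_no_transients_is_not_echo(self, protocol11):
        cls = classify_echo([], build_windows(protocol11), 0.01)
        assert not cls.is_echo and cls.p_spont == 1.0

    def test_generator_echo_neuron_detected(self, protocol11):
        gt = sample_population(1, echo_fraction=1.0, seed=13)[0]
        object.__setattr__(gt, "n_echo_events", 5)
        tr, _ = synthesize_trace(gt, protocol11, noise_sd=0.0, seed=13)
        dff = compute_dff(tr)
        transients = detect_transients(dff, noise_sd=0.004)
        windows = build_windows(protocol11)
        cls = classify_echo(transients, windows, 0.0, neuron_id=gt.neuron_id)
        assert cls.is_echo
        assert 1 <= cls.n_echo_events_max <= 5
        assert gt.echo_freq_hz in cls.echo_freqs_hz

    def test_nonecho_neuron_without_spontaneous_is_negative(self, protocol11):
        gt = sample_population(1, echo_fraction=0.0, seed=14)[0]
        object.__setattr__(gt, "spont_rate_hz", 0.0)
        tr, _ = synthesize_trace(gt, protocol11, noise_sd=0.0, seed=14)
        transients = detect_transients(compute_dff(tr), noise_sd=0.004)
        cls = classify_echo(transients, build_windows(protocol11), 0.01)
        assert not cls.is_echo

    def test_false_positive_rate_near_alpha_under_null(self, protocol11):
        # pure-spontaneous neurons, known rate: FP rate must stay at ~alpha
        windows = build_windows(protocol11)
        dur = protocol11.end_of_stimulation_s + 15.0
        rate, n = 0.01, 1500
        rng = np.random.default_rng(5)
        fp = 0
        for _ in range(n):
            times = np.sort(rng.uniform(0, dur, rng.poisson(rate * dur)))
            fp += classify_echo([_transient(t) for t in times], windows, rate).is_echo
        # binomial 99% upper bound around alpha = 0.05
        assert fp / n <= 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / n)

    def test_events_lie_in_exactly_one_echo_window(self, protocol11):
        windows = build_windows(protocol11)
        echo_windows = [w for w in windows if w.kind == "echo"]
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, protocol11.end_of_stimulation_s + 12, 400))
        cls = classify_echo([_transient(t) for t in times], windows, 0.01)
        for ev in cls.events:
            hits = [w for w in echo_windows if w.contains(ev.onset_s)]
            assert len(hits) == 1

    def test_negative_rate_rejected(self, protocol11):
        with pytest.raises(InvalidArgumentError):
            classify_echo([], build_windows(protocol11), -0.1)


class TestSummarizeNeuron:
    def test_zero_trace_summary(self, protocol11):
        dff = _flat_dff(protocol11.end_of_stimulation_s + 15.0)
        windows = build_windows(protocol11)
        cls = classify_echo([], windows, 0.0)
        s = summarize_neuron(dff, [], windows, cls)
        assert s.sound_amp is None and s.echo_amp is None
        assert s.baseline_amp == 0.0
        assert s.sound_latency_s is None and s.echo_latency_s is None

    def test_noiseless_neuron_amplitudes_match_configuration(self, protocol11):
        gt = sample_population(1, echo_fraction=1.0, seed=21)[0]
        object.__setattr__(gt, "spont_rate_hz", 0.0)
        tr, _ = synthesize_trace(gt, protocol11, noise_sd=0.0, seed=21)
        dff = compute_dff(tr)
        transients = detect_transients(dff, noise_sd=0.004)
        windows = build_windows(protocol11)
        cls = classify_echo(transients, windows, 0.0, neuron_id=gt.neuron_id)
        s = summarize_neuron(dff, transients, windows, cls)
        # responsive-window mean is diluted by off-BF tones, but bounded by
        # the at-BF amplitude from above and the one-sigma amplitude from below
        assert 0.4 * gt.evoked_amp <= s.sound_amp <= 1.05 * gt.evoked_amp
        assert cls.is_echo
        # transient peaks track the configured kernel amplitude; the windowed
        # peak-minus-start measure sits slightly lower because the preceding
        # event's decay elevates the window-start value it subtracts
        peaks = np.mean([e.peak_amp for e in cls.events])
        assert peaks == pytest.approx(gt.echo_amp, rel=0.2)
        assert 0.5 * gt.echo_amp <= s.echo_amp <= 1.1 * gt.echo_amp
        assert s.echo_latency_s > s.sound_latency_s
        assert s.baseline_amp == pytest.approx(0.0, abs=1e-6)
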