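"""The synthetic forward model: population sampling, trace rendering, bookkeeping."""

import numpy as np
import pytest

from echotune.calibration import ANESTHETIZED, AWAKE
from echotune.errors import InvalidArgumentError
from echotune.stimulus import make_protocol
from echotune.synth import (
    kernel_peak_time,
    sample_population,
    synthesize_session,
    synthesize_trace,
    transient_kernel,
)


class TestKernel:
    def test_unit_peak_and_causality(self):
        t = np.linspace(-1, 5, 2401)
        k = transient_kernel(t)
        assert np.all(k[t < 0] == 0)
        assert k.max() == pytest.approx(1.0, abs=1e-3)  # grid does not hit the exact peak
        assert transient_kernel(np.array([kernel_peak_time()]))[0] == pytest.approx(1.0, abs=1e-12)
        assert t[np.argmax(k)] == pytest.approx(kernel_peak_time(), abs=0.01)

    def test_invalid_time_constants(self):
        with pytest.raises(InvalidArgumentError):
            transient_kernel(np.array([0.1]), rise_tau_s=0.8, decay_tau_s=0.7)


class TestSamplePopulation:
    def test_zero_echo_fraction(self):
        pop = sample_population(50, echo_fraction=0.0, seed=0)
        assert not any(g.is_echo for g in pop)

    def test_echo_count_is_rounded_product(self):
        pop = sample_population(777, seed=3)
        expected = round(ANESTHETIZED.echo_fraction * 777)
        assert sum(g.is_echo for g in pop) == expected

    def test_echo_fraction_out_of_range(self):
        with pytest.raises(InvalidArgumentError):
            sample_population(10, echo_fraction=1.5)

    def test_seed_determinism(self):
        a = sample_population(40, seed=9)
        b = sample_population(40, seed=9)
        assert a == b

    def test_amplitude_calibration_closure(self):
        # with n >= 500 the empirical means track the preset's (truncated
        # normal) distributions within 3 SEM
        from scipy.stats import truncnorm

        def tmean(mean, sd, lo):
            return truncnorm.mean((lo - mean) / sd, np.inf, loc=mean, scale=sd)

        c = ANESTHETIZED
        pop = sample_population(4000, echo_fraction=1.0, seed=11)
        for attr, target in [
            ("echo_amp", tmean(c.echo_amp_mean, c.echo_amp_sd, c.echo_amp_min)),
            ("evoked_amp", tmean(c.evoked_amp_mean, c.evoked_amp_sd, c.evoked_amp_min)),
            ("sound_latency_s", tmean(c.sound_latency_mean_s, c.sound_latency_neuron_sd_s, 0.01)),
            ("echo_latency_s", tmean(c.echo_latency_mean_s, c.echo_latency_neuron_sd_s, 0.02)),
        ]:
            vals = np.array([getattr(g, attr) for g in pop])
            sem = vals.std(ddof=1) / np.sqrt(vals.size)
            assert abs(vals.mean() - target) < 3 * sem + 1e-4, attr

    def test_echo_frequency_within_one_grid_step_of_bf(self, protocol11):
        logf = np.log2(np.asarray(protocol11.frequencies_hz))
        step = protocol11.log2_step_oct
        pop = sample_population(300, echo_fraction=1.0, seed=2, freqs_hz=protocol11.frequencies_hz)
        for g in pop:
            nearest = protocol11.frequencies_hz[int(np.argmin(np.abs(logf - np.log2(g.bf_hz))))]
            assert abs(np.log2(g.echo_freq_hz / nearest)) <= step + 1e-9

    def test_positions_inside_field(self):
        pop = sample_population(100, field_um=150.0, seed=4)
        xy = np.array([g.xy_um for g in pop])
        assert xy.min() >= 0 and xy.max() <= 150.0


class TestSynthesizeTrace:
    def _null_neuron(self, **over):
        base = dict(
            neuron_id="n0",
            bf_hz=8000.0,
            tuning_sigma_oct=1.0,
            evoked_amp=0.0,
            spont_rate_hz=0.0,
            is_echo=False,
            echo_freq_hz=8000.0,
            n_echo_events=0,
            echo_amp=0.0,
            echo_latency_s=0.0,
            sound_latency_s=0.06,
            xy_um=(0.0, 0.0),
        )
        base.update(over)
        from echotune.synth import NeuronGroundTruth

        return NeuronGroundTruth(**base)

    def test_null_signal_gives_constant_baseline(self, protocol11):
        gt = self._null_neuron()
        tr, events = synthesize_trace(gt, protocol11, noise_sd=0.0, baseline_f=55.0, seed=0)
        assert not events
        assert np.allclose(tr.f, 55.0)

    def test_evoked_event_bookkeeping_and_tuning(self, protocol11):
        gt = self._null_neuron(evoked_amp=0.1, bf_hz=protocol11.frequencies_hz[5])
        _, events = synthesize_trace(gt, protocol11, noise_sd=0.0, seed=0)
        evoked = [e for e in events if e.category == "evoked"]
        assert len(evoked) == protocol11.n_reps * protocol11.n_freqs
        # amplitude at BF equals evoked_amp; one sigma away it is evoked_amp * exp(-1/2)
        at_bf = [e for e in evoked if abs(e.amplitude - 0.1) < 1e-12]
        assert len(at_bf) == protocol11.n_reps
        sigma_gain = gt.tuning_gain(gt.bf_hz * 2.0**gt.tuning_sigma_oct)
        assert sigma_gain == pytest.approx(np.exp(-0.5))

    def test_echo_events_at_anticipated_times(self, protocol11):
        fi = 5
        gt = self._null_neuron(
            is_echo=True,
            n_echo_events=4,
            echo_amp=0.06,
            echo_freq_hz=protocol11.frequencies_hz[fi],
            echo_latency_s=0.2,
        )
        _, events = synthesize_trace(gt, protocol11, noise_sd=0.0, seed=0)
        echoes = sorted(e.time_s for e in events if e.category == "echo")
        assert len(echoes) == 4
        t_end = protocol11.train_end_s(fi)
        for k, ts in enumerate(echoes, start=1):
            lag = ts - (t_end + k * protocol11.isi_s)
            assert 0.0 <= lag < 0.2 + 5 * ANESTHETIZED.echo_jitter_sd_s

    def test_too_short_duration_rejected(self, protocol11):
        gt = self._null_neuron()
        with pytest.raises(InvalidArgumentError):
            synthesize_trace(gt, protocol11, duration_s=100.0)

    def test_event_counts_by_category_match_configuration(self, protocol11):
        gt = self._null_neuron(evoked_amp=0.1, is_echo=True, n_echo_events=2, echo_amp=0.05)
        _, events = synthesize_trace(gt, protocol11, noise_sd=0.0, seed=1)
        by_cat = {}
        for e in events:
            by_cat[e.category] = by_cat.get(e.category, 0) + 1
        assert by_cat == {"evoked": 220, "echo": 2}


class TestSynthesizeSession:
    def test_seed_determinism_byte_identical(self, tmp_path):
        proto = make_protocol(3, 2000.0, 8000.0, n_reps=3)
        for d in ("a", "b"):
            synthesize_session(proto, n_neurons=3, seed=7, out_dir=tmp_path / d)
        for name in ("traces.csv", "ground_truth.csv", "events.csv", "protocol.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_trace_table_shape(self, tmp_path):
        proto = make_protocol(2, 2000.0, 4000.0, n_reps=2)
        bundle = synthesize_session(proto, n_neurons=2, seed=0)
        df = bundle.traces_frame()
        assert list(df.columns) == ["time_s", "neuron_000", "neuron_001"]

    def test_ground_truth_echo_fraction_round_trips(self, small_bundle):
        gt = small_bundle.ground_truth_frame()
        assert gt.is_echo.sum() == round(ANESTHETIZED.echo_fraction * len(gt))

    def test_presets_differ_only_in_documented_fields(self):
        a = sample_population(60, calib=ANESTHETIZED, seed=5)
        w = sample_population(60, calib=AWAKE, seed=5)
        for ga, gw in zip(a, w):
            assert ga.spont_rate_hz != gw.spont_rate_hz
            assert gw == type(ga)(**{**ga.__dict__, "spont_rate_hz": gw.spont_rate_hz})

    def test_event_log_matches_trace_energy(self, protocol11):
        # noiseless bundle: every logged kernel appears in the trace
        bundle = synthesize_session(protocol11, n_neurons=4, seed=3)
        ev = bundle.events_frame()
        assert set(ev.category) <= {"spontaneous", "evoked", "echo"}
        assert (ev.amplitude >= 0).all()
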