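"""Synthetic forward model of ROI fluorescence during rhythmic tone trains.

The generator produces, per neuron, a raw fluorescence trace

    f(t) = baseline_f · (1 + s(t) + ε(t)),    ε ~ N(0, noise_sd) per frame,

where the Δf/f signal s(t) is a sum of unit-peak double-exponential transient
kernels placed at

* spontaneous Poisson event times,
* every tone onset of every train, scaled by Gaussian tuning in log2
  frequency distance from the neuron's best frequency (BF), and
* for echo neurons only, 1–5 "echo" times after the train at the neuron's
  echo frequency, at the anticipated continuation of the rhythm
  (t_end + k·ISI) plus a latency.

Every kernel placed is recorded in an event log, which downstream tests use
as ground truth for detection, classification and latency measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ANESTHETIZED, CalibrationPreset, get_preset
from .errors import InvalidArgumentError
from .signal import RoiTrace
from .stimulus import StimulusProtocol, make_protocol, write_protocol

__all__ = [
    "NeuronGroundTruth",
    "SimEvent",
    "SessionBundle",
    "transient_kernel",
    "kernel_peak_time",
    "sample_population",
    "synthesize_trace",
    "synthesize_session",
]

#: Kernel support, as a multiple of the decay time constant (tail < 0.1 % of peak).
_KERNEL_SUPPORT_TAUS = 7.0


@dataclass(frozen=True)
class NeuronGroundTruth:
    """Generator parameters of one synthetic neuron."""

    neuron_id: str
    bf_hz: float
    tuning_sigma_oct: float
    evoked_amp: float
    spont_rate_hz: float
    is_echo: bool
    echo_freq_hz: float
    n_echo_events: int
    echo_amp: float
    echo_latency_s: float
    sound_latency_s: float
    xy_um: tuple[float, float]

    def __post_init__(self) -> None:
        if self.evoked_amp < 0 or self.echo_amp < 0 or self.spont_rate_hz < 0:
            raise InvalidArgumentError("amplitudes and rates must be >= 0")
        if self.is_echo and not (1 <= self.n_echo_events <= 5):
            raise InvalidArgumentError("n_echo_events must be in [1, 5] for echo neurons")

    def tuning_gain(self, freq_hz: float) -> float:
        """Gaussian tuning factor in log2-frequency distance from BF (peak 1 at BF)."""
        d = np.log2(freq_hz / self.bf_hz)
        return float(np.exp(-0.5 * (d / self.tuning_sigma_oct) ** 2))


@dataclass(frozen=True)
class SimEvent:
    """One kernel placed by the generator (the ground-truth event log entry)."""

    neuron_id: str
    category: str  # 'spontaneous' | 'evoked' | 'echo'
    time_s: float  # kernel onset
    amplitude: float  # kernel peak, Δf/f


@dataclass
class SessionBundle:
    """One synthetic imaging session: protocol, traces, ground truth, event log."""

    protocol: StimulusProtocol
    traces: list[RoiTrace]
    ground_truth: list[NeuronGroundTruth]
    events: list[SimEvent]
    seed: int
    calib: CalibrationPreset = field(default=ANESTHETIZED)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.neuron_id, e.category, e.time_s, e.amplitude) for e in self.events],
            columns=["neuron_id", "category", "time_s", "amplitude"],
        )

    def ground_truth_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.ground_truth:
            rows.append(
                {
                    "neuron_id": g.neuron_id,
                    "bf_hz": g.bf_hz,
                    "tuning_sigma_oct": g.tuning_sigma_oct,
                    "evoked_amp": g.evoked_amp,
                    "spont_rate_hz": g.spont_rate_hz,
                    "is_echo": g.is_echo,
                    "echo_freq_hz": g.echo_freq_hz,
                    "n_echo_events": g.n_echo_events,
                    "echo_amp": g.echo_amp,
                    "echo_latency_s": g.echo_latency_s,
                    "sound_latency_s": g.sound_latency_s,
                    "x_um": g.xy_um[0],
                    "y_um": g.xy_um[1],
                }
            )
        return pd.DataFrame(rows)

    def traces_frame(self) -> pd.DataFrame:
        t = self.traces[0].times_s
        data = {"time_s": t}
        for tr in self.traces:
            data[f"neuron_{tr.neuron_id}"] = tr.f
        return pd.DataFrame(data)


def transient_kernel(t_s: np.ndarray, rise_tau_s: float = 0.07, decay_tau_s: float = 0.7) -> np.ndarray:
    """Unit-peak double-exponential Ca²⁺ transient kernel, zero for t < 0."""
    if not (0 < rise_tau_s < decay_tau_s):
        raise InvalidArgumentError("require 0 < rise_tau_s < decay_tau_s")
    t = np.asarray(t_s, dtype=float)
    raw = np.where(t >= 0, np.exp(-t / decay_tau_s) - np.exp(-t / rise_tau_s), 0.0)
    tpk = kernel_peak_time(rise_tau_s, decay_tau_s)
    peak = np.exp(-tpk / decay_tau_s) - np.exp(-tpk / rise_tau_s)
    return raw / peak


def kernel_peak_time(rise_tau_s: float = 0.07, decay_tau_s: float = 0.7) -> float:
    """Time to peak of the double-exponential kernel (closed form)."""
    return (
        rise_tau_s
        * decay_tau_s
        / (decay_tau_s - rise_tau_s)
        * np.log(decay_tau_s / rise_tau_s)
    )


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, size: int | None = None) -> np.ndarray | float:
    """Gaussian draw truncated below at ``lo`` (resampling; falls back to clip)."""
    n = 1 if size is None else size
    out = rng.normal(mean, sd, n)
    for _ in range(100):
        bad = out < lo
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    out = np.maximum(out, lo)
    return float(out[0]) if size is None else out


def sample_population(
    n_neurons: int,
    echo_fraction: float | None = None,
    field_um: float = 200.0,
    calib: CalibrationPreset | str = ANESTHETIZED,
    seed: int = 0,
    freqs_hz: tuple[float, ...] | None = None,
) -> list[NeuronGroundTruth]:
    """Draw ground-truth parameters for a population of neurons.

    Exactly ``round(echo_fraction · n_neurons)`` neurons are flagged as echo
    neurons (``echo_fraction`` defaults to the preset's value).  Best
    frequencies are log-uniform across the stimulus band; each echo neuron's
    echo frequency is the stimulus frequency nearest its BF, displaced by one
    grid step with probability ``calib.echo_step_jitter_p``.  ROI centroids
    are uniform on a ``field_um`` × ``field_um`` square.
    """
    if isinstance(calib, str):
        calib = get_preset(calib)
    if echo_fraction is None:
        echo_fraction = calib.echo_fraction
    if not (0.0 <= echo_fraction <= 1.0):
        raise InvalidArgumentError("echo_fraction must be in [0, 1]")
    if n_neurons < 1 or field_um <= 0:
        raise InvalidArgumentError("n_neurons and field_um must be positive")
    if freqs_hz is None:
        freqs_hz = make_protocol(11, 2000.0, 40000.0).frequencies_hz
    freqs = np.asarray(freqs_hz, dtype=float)
    logf = np.log2(freqs)

    rng = np.random.default_rng(seed)
    n_echo = int(round(echo_fraction * n_neurons))
    echo_ids = set(rng.choice(n_neurons, size=n_echo, replace=False).tolist())

    out: list[NeuronGroundTruth] = []
    for i in range(n_neurons):
        bf = float(2.0 ** rng.uniform(logf[0], logf[-1]))
        is_echo = i in echo_ids
        nearest = int(np.argmin(np.abs(logf - np.log2(bf))))
        step = 0
        if is_echo and len(freqs) > 1 and rng.random() < calib.echo_step_jitter_p:
            step = int(rng.choice([-1, 1]))
            step = int(np.clip(nearest + step, 0, len(freqs) - 1)) - nearest
        echo_freq = float(freqs[nearest + step])
        out.append(
            NeuronGroundTruth(
                neuron_id=f"{i:03d}",
                bf_hz=bf,
                tuning_sigma_oct=_trunc_normal(
                    rng, calib.tuning_sigma_mean_oct, calib.tuning_sigma_sd_oct, calib.tuning_sigma_min_oct
                ),
                evoked_amp=_trunc_normal(rng, calib.evoked_amp_mean, calib.evoked_amp_sd, calib.evoked_amp_min),
                spont_rate_hz=calib.spont_rate_hz,
                is_echo=is_echo,
                echo_freq_hz=echo_freq,
                n_echo_events=int(rng.integers(calib.n_echo_min, calib.n_echo_max + 1)) if is_echo else 0,
                echo_amp=_trunc_normal(rng, calib.echo_amp_mean, calib.echo_amp_sd, calib.echo_amp_min)
                if is_echo
                else 0.0,
                echo_latency_s=_trunc_normal(rng, calib.echo_latency_mean_s, calib.echo_latency_neuron_sd_s, 0.02)
                if is_echo
                else 0.0,
                sound_latency_s=_trunc_normal(rng, calib.sound_latency_mean_s, calib.sound_latency_neuron_sd_s, 0.01),
                xy_um=(float(rng.uniform(0, field_um)), float(rng.uniform(0, field_um))),
            )
        )
    return out


def synthesize_trace(
    gt: NeuronGroundTruth,
    protocol: StimulusProtocol,
    frame_rate_hz: float = 40.0,
    noise_sd: float | None = None,
    baseline_f: float = 100.0,
    duration_s: float | None = None,
    seed: int = 0,
    calib: CalibrationPreset = ANESTHETIZED,
) -> tuple[RoiTrace, list[SimEvent]]:
    """Render one neuron's raw fluorescence trace and its ground-truth event log.

    ``duration_s`` must cover the protocol with at least 30 s of pre-train
    silence and 6 ISIs of post-train silence (defaults to exactly that).
    ``noise_sd`` defaults to the preset's value; pass 0 for noiseless traces.
    """
    if noise_sd is None:
        noise_sd = calib.noise_sd
    min_dur = protocol.end_of_stimulation_s + 6.0 * protocol.isi_s
    if duration_s is None:
        duration_s = min_dur + 3.0 * protocol.isi_s
    if duration_s < min_dur or min(protocol.train_onsets_s) < 30.0:
        raise InvalidArgumentError(
            "duration must cover the protocol plus 6 ISIs of post-train and 30 s of pre-train silence"
        )
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate_hz)) + 1
    t = np.arange(n_frames) / frame_rate_hz

    events: list[SimEvent] = []
    # spontaneous Poisson events over the whole recording
    n_spont = rng.poisson(gt.spont_rate_hz * duration_s)
    for ts in np.sort(rng.uniform(0.0, duration_s, n_spont)):
        amp = _trunc_normal(rng, calib.spont_amp_mean, calib.spont_amp_sd, calib.spont_amp_min)
        events.append(SimEvent(gt.neuron_id, "spontaneous", float(ts), amp))
    # tone-evoked events: every tone of every train, tuning-scaled
    for fi, freq in enumerate(protocol.frequencies_hz):
        gain = gt.tuning_gain(freq)
        for onset in protocol.tone_onsets_s(fi):
            lag = _trunc_normal(rng, gt.sound_latency_s, calib.sound_jitter_sd_s, 0.0)
            if gt.evoked_amp * gain > 0:  # zero-amplitude kernels are never placed
                events.append(SimEvent(gt.neuron_id, "evoked", float(onset + lag), gt.evoked_amp * gain))
    # echo events: anticipated continuation of the rhythm after the echo train
    if gt.is_echo:
        fi = int(np.argmin(np.abs(np.asarray(protocol.frequencies_hz) - gt.echo_freq_hz)))
        t_end = protocol.train_end_s(fi)
        for k in range(1, gt.n_echo_events + 1):
            lag = _trunc_normal(rng, gt.echo_latency_s, calib.echo_jitter_sd_s, 0.0)
            events.append(SimEvent(gt.neuron_id, "echo", float(t_end + k * protocol.isi_s + lag), gt.echo_amp))

    signal = np.zeros(n_frames)
    support = int(np.ceil(_KERNEL_SUPPORT_TAUS * calib.decay_tau_s * frame_rate_hz))
    for ev in events:
        if ev.amplitude <= 0:
            continue
        i0 = int(np.ceil(ev.time_s * frame_rate_hz))
        if i0 >= n_frames:
            continue
        i1 = min(i0 + support, n_frames)
        signal[i0:i1] += ev.amplitude * transient_kernel(
            t[i0:i1] - ev.time_s, calib.rise_tau_s, calib.decay_tau_s
        )
    noise = rng.normal(0.0, noise_sd, n_frames) if noise_sd > 0 else 0.0
    f = baseline_f * (1.0 + signal + noise)
    trace = RoiTrace(neuron_id=gt.neuron_id, frame_rate_hz=frame_rate_hz, f=f)
    events.sort(key=lambda e: e.time_s)
    return trace, events


def synthesize_session(
    protocol: StimulusProtocol | None = None,
    n_neurons: int = 100,
    echo_fraction: float | None = None,
    calib: CalibrationPreset | str = ANESTHETIZED,
    frame_rate_hz: float = 40.0,
    baseline_f: float = 100.0,
    field_um: float = 200.0,
    post_s: float = 15.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SessionBundle:
    """Generate a full synthetic session, optionally writing it to disk.

    When ``out_dir`` is given, writes ``protocol.json``, ``traces.csv``
    (column ``time_s`` plus one ``neuron_<id>`` column each),
    ``ground_truth.csv`` and ``events.csv``; the files round-trip through
    :mod:`echotune.io`.  Identical seeds yield byte-identical outputs.
    """
    if isinstance(calib, str):
        calib = get_preset(calib)
    if protocol is None:
        protocol = make_protocol(11, 2000.0, 40000.0)
    post_s = max(post_s, 6.0 * protocol.isi_s + 0.5)
    duration_s = protocol.end_of_stimulation_s + post_s

    ss = np.random.SeedSequence(seed)
    pop_seed, *trace_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_neurons + 1)]
    gts = sample_population(
        n_neurons,
        echo_fraction=echo_fraction,
        field_um=field_um,
        calib=calib,
        seed=pop_seed,
        freqs_hz=protocol.frequencies_hz,
    )
    traces: list[RoiTrace] = []
    events: list[SimEvent] = []
    for gt, s in zip(gts, trace_seeds):
        tr, ev = synthesize_trace(
            gt,
            protocol,
            frame_rate_hz=frame_rate_hz,
            baseline_f=baseline_f,
            duration_s=duration_s,
            seed=s,
            calib=calib,
        )
        traces.append(tr)
        events.extend(ev)
    bundle = SessionBundle(
        protocol=protocol, traces=traces, ground_truth=gts, events=events, seed=seed, calib=calib
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_protocol(protocol, out / "protocol.json")
        bundle.traces_frame().to_csv(out / "traces.csv", index=False, float_format="%.5f")
        bundle.ground_truth_frame().to_csv(out / "ground_truth.csv", index=False, float_format="%.6f")
        bundle.events_frame().to_csv(out / "events.csv", index=False, float_format="%.6f")
    return bundle
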