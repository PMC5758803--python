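"""Sound, echo and baseline response windows; echo-neuron classification.

After a rhythmic tone train ends, an "echo" (omitted-stimulus) response is a
Ca²⁺ transient occurring at one of the anticipated continuation times
t_end + k·ISI (t_end = onset of the train's last tone).  A neuron is called
an echo neuron when the number of transient onsets falling inside its echo
windows, pooled over all trains, is improbable under a Poisson null whose
rate is the neuron's own spontaneous transient rate estimated from
stimulus-free epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError
from .signal import DffTrace, Transient
from .stimulus import StimulusProtocol

__all__ = [
    "ResponseWindow",
    "EchoEvent",
    "EchoClassification",
    "NeuronResponseSummary",
    "build_windows",
    "measure_window",
    "classify_echo",
    "estimate_spont_rate",
    "summarize_neuron",
]


@dataclass(frozen=True)
class ResponseWindow:
    """One measurement window tied to a stimulus train.

    ``kind`` is ``'sound'`` (per tone), ``'echo'`` (per anticipated post-train
    time, index ``k``) or ``'baseline'`` (matched-width pre-train windows).
    ``ref_time_s`` is the tone onset, the anticipated time, or the window
    start for baseline windows.
    """

    kind: str
    ref_time_s: float
    freq_hz: float
    start_s: float
    end_s: float
    k: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("sound", "echo", "baseline"):
            raise InvalidArgumentError(f"unknown window kind {self.kind!r}")
        if not (self.start_s <= self.ref_time_s <= self.end_s):
            raise InvalidArgumentError("ref_time_s must lie inside the window")

    @property
    def width_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t_s: float) -> bool:
        return self.start_s <= t_s < self.end_s


@dataclass(frozen=True)
class EchoEvent:
    """One transient attributed to an echo window."""

    freq_hz: float
    k: int
    onset_s: float
    peak_amp: float
    latency_s: float  # onset minus the window's anticipated time


@dataclass
class EchoClassification:
    neuron_id: str
    is_echo: bool
    p_spont: float
    events: list[EchoEvent] = field(default_factory=list)
    echo_freqs_hz: tuple[float, ...] = ()
    n_echo_events_max: int = 0
    spont_rate_hz: float = float("nan")


@dataclass
class NeuronResponseSummary:
    """Per-neuron amplitude/latency summary; ``None`` marks absent categories."""

    neuron_id: str
    sound_amp: float | None
    echo_amp: float | None
    baseline_amp: float | None
    sound_latency_s: float | None
    echo_latency_s: float | None
    is_echo: bool
    n_sound_windows_responsive: int
    n_echo_events: int


def build_windows(
    protocol: StimulusProtocol,
    sound_win_s: float = 0.5,
    echo_halfwidth_s: float = 0.75,
    k_max: int = 5,
) -> list[ResponseWindow]:
    """Construct sound, echo and baseline windows for every train.

    Per tone: a sound window [onset, onset + sound_win_s].  Per train: echo
    windows centred on t_end + k·ISI (k = 1..k_max) with half-width
    ``echo_halfwidth_s``, and k_max matched-width baseline windows tiling the
    silence immediately before the train onset.
    """
    if sound_win_s <= 0 or echo_halfwidth_s <= 0 or k_max < 0:
        raise InvalidArgumentError("window parameters must be positive")
    if k_max > 0 and echo_halfwidth_s >= protocol.isi_s / 2:
        raise InvalidArgumentError("echo windows overlap: echo_halfwidth_s >= isi/2")
    windows: list[ResponseWindow] = []
    w = 2.0 * echo_halfwidth_s
    for fi, freq in enumerate(protocol.frequencies_hz):
        onset0 = protocol.train_onsets_s[fi]
        if k_max > 0 and onset0 - k_max * w < 0:
            raise InvalidArgumentError("insufficient pre-train silence for baseline windows")
        for onset in protocol.tone_onsets_s(fi):
            windows.append(
                ResponseWindow("sound", float(onset), float(freq), float(onset), float(onset + sound_win_s))
            )
        t_end = protocol.train_end_s(fi)
        for k in range(1, k_max + 1):
            c = t_end + k * protocol.isi_s
            windows.append(
                ResponseWindow("echo", float(c), float(freq), float(c - echo_halfwidth_s), float(c + echo_halfwidth_s), k=k)
            )
        for j in range(1, k_max + 1):
            s = onset0 - j * w
            windows.append(ResponseWindow("baseline", float(s), float(freq), float(s), float(s + w), k=j))
    return windows


def measure_window(
    dff: DffTrace,
    transients: list[Transient],
    w: ResponseWindow,
    mode: str = "peak",
    integral_dur_s: float = 0.5,
) -> tuple[float, float | None]:
    """Amplitude and latency of the response inside one window.

    peak mode
        amplitude = max Δf/f in the window minus Δf/f at the window start,
        floored at 0 (removes the decaying tail of preceding transients).
    integral mode
        trapezoidal integral of Δf/f over [ref_time, ref_time + integral_dur_s].

    Latency is the first transient onset at or after ``ref_time_s`` within the
    window, minus ``ref_time_s``; ``None`` when no such transient exists.
    """
    t = dff.times_s
    if w.start_s < t[0] - 1e-9 or w.end_s > t[-1] + 1e-9:
        raise InvalidArgumentError("window lies outside the trace")
    if mode == "peak":
        i0 = int(np.searchsorted(t, w.start_s, side="left"))
        i1 = int(np.searchsorted(t, w.end_s, side="right"))
        seg = dff.dff[i0:i1]
        amp = float(max(np.max(seg) - dff.value_at(w.start_s), 0.0)) if seg.size else 0.0
    elif mode == "integral":
        hi = min(w.ref_time_s + integral_dur_s, float(t[-1]))
        i0 = int(np.searchsorted(t, w.ref_time_s, side="left"))
        i1 = int(np.searchsorted(t, hi, side="right"))
        seg_t, seg = t[i0:i1], dff.dff[i0:i1]
        amp = float(np.trapezoid(seg, seg_t)) if seg.size > 1 else 0.0
    else:
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    latency = None
    for tr in transients:
        if w.ref_time_s <= tr.onset_s < w.end_s:
            latency = float(tr.onset_s - w.ref_time_s)
            break
    return amp, latency


def estimate_spont_rate(
    transients: list[Transient],
    protocol: StimulusProtocol,
    trace_extent_s: tuple[float, float],
    windows: list[ResponseWindow] | None = None,
    echo_halfwidth_s: float = 0.75,
    k_max: int = 5,
    min_free_s: float = 30.0,
    return_free_time: bool = False,
) -> float | tuple[float, float]:
    """Spontaneous transient rate from stimulus-free time.

    Stimulus-free time excludes every train span (first tone onset through
    the last tone's response, i.e. up to the start of the first echo window)
    and every echo window; baseline epochs in the inter-train gaps remain.
    The rate is (onsets in free time) / (free duration).
    """
    lo, hi = trace_extent_s
    hw = echo_halfwidth_s
    if windows is not None:
        echo_hws = [w.width_s / 2 for w in windows if w.kind == "echo"]
        if echo_hws:
            hw = echo_hws[0]
    # last-tone responses onset up to ~isi - halfwidth after the train end;
    # excluding that tail keeps evoked onsets out of the "spontaneous" count
    tail = max(protocol.tone_dur_s, protocol.isi_s - hw)
    excluded: list[tuple[float, float]] = []
    for fi in range(protocol.n_freqs):
        onset = protocol.train_onsets_s[fi]
        excluded.append((onset, protocol.train_end_s(fi) + tail))
    if windows is not None:
        for w in windows:
            if w.kind == "echo":
                excluded.append((w.start_s, w.end_s))
    else:
        for fi in range(protocol.n_freqs):
            t_end = protocol.train_end_s(fi)
            for k in range(1, k_max + 1):
                c = t_end + k * protocol.isi_s
                excluded.append((c - echo_halfwidth_s, c + echo_halfwidth_s))
    excluded.sort()
    merged: list[list[float]] = []
    for a, b in excluded:
        a, b = max(a, lo), min(b, hi)
        if b <= a:
            continue
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    free = (hi - lo) - sum(b - a for a, b in merged)
    if free < min_free_s:
        raise InvalidArgumentError(f"only {free:.1f} s of stimulus-free time (< {min_free_s} s)")

    def in_excluded(ts: float) -> bool:
        return any(a <= ts < b for a, b in merged)

    n_free = sum(1 for tr in transients if lo <= tr.onset_s <= hi and not in_excluded(tr.onset_s))
    rate = n_free / free
    return (rate, free) if return_free_time else rate


def empirical_bayes_rates(
    counts: np.ndarray,
    free_times_s: np.ndarray,
    pseudo_count: float = 0.5,
) -> np.ndarray:
    """Per-neuron spontaneous-rate estimates with Gamma–Poisson partial pooling.

    Each neuron's stimulus-free event count ``k_i`` over ``T_i`` seconds is a
    noisy rate measurement; the population of counts constrains a Gamma prior
    (method of moments), and the returned rate is the posterior mean
    ``(k_i + a) / (T_i + b)``.  When the counts show no over-dispersion beyond
    Poisson (no evidence of rate heterogeneity) the prior collapses toward
    the pooled rate.  With fewer than 5 neurons, falls back to the
    per-neuron estimate with a Jeffreys-style ``pseudo_count``.
    """
    k = np.asarray(counts, dtype=float)
    T = np.asarray(free_times_s, dtype=float)
    if k.size != T.size or np.any(T <= 0):
        raise InvalidArgumentError("counts and free times must align, times > 0")
    if k.size < 5:
        return (k + pseudo_count) / T
    pooled = k.sum() / T.sum()
    m_k, v_k = float(k.mean()), float(k.var(ddof=1))
    excess = v_k - m_k
    t_bar = float(T.mean())
    if excess <= 0 or pooled <= 0:
        # no detectable heterogeneity: shrink hard toward the pooled rate
        b = 100.0 * t_bar
        a = pooled * b
    else:
        b = m_k * t_bar / excess
        a = m_k * b / t_bar
        # never weaker than the plain pseudo-count regularizer
        a = max(a, pseudo_count)
    return (k + a) / (T + b)


def classify_echo(
    transients: list[Transient],
    windows: list[ResponseWindow],
    spont_rate_hz: float,
    alpha: float = 0.05,
    neuron_id: str = "",
) -> EchoClassification:
    """Poisson-null test for echo responses.

    Counts transient onsets falling in echo windows across all trains;
    ``p_spont`` is the mid-P Poisson upper tail of the observed count given
    an expected count of ``spont_rate_hz × total echo-window time`` (mid-P:
    half the point probability is counted, the standard de-conservatization
    of discrete tail tests).  The neuron is an echo neuron iff the count is
    ≥ 1 and ``p_spont < alpha``.
    """
    if spont_rate_hz < 0:
        raise InvalidArgumentError("spont_rate_hz must be >= 0")
    echo_windows = [w for w in windows if w.kind == "echo"]
    total_time = sum(w.width_s for w in echo_windows)
    events: list[EchoEvent] = []
    for tr in transients:
        for w in echo_windows:
            if w.contains(tr.onset_s):
                events.append(
                    EchoEvent(
                        freq_hz=w.freq_hz,
                        k=w.k,
                        onset_s=tr.onset_s,
                        peak_amp=tr.peak_amp,
                        latency_s=tr.onset_s - w.ref_time_s,
                    )
                )
                break
    count = len(events)
    lam = spont_rate_hz * total_time
    if count > 0:
        p = float(stats.poisson.sf(count, lam) + 0.5 * stats.poisson.pmf(count, lam))
    else:
        p = 1.0
    is_echo = count >= 1 and p < alpha
    per_train: dict[float, int] = {}
    for ev in events:
        per_train[ev.freq_hz] = per_train.get(ev.freq_hz, 0) + 1
    return EchoClassification(
        neuron_id=neuron_id,
        is_echo=is_echo,
        p_spont=p,
        events=events,
        echo_freqs_hz=tuple(sorted(per_train)) if is_echo else (),
        n_echo_events_max=max(per_train.values()) if per_train else 0,
        spont_rate_hz=spont_rate_hz,
    )


def summarize_neuron(
    dff: DffTrace,
    transients: list[Transient],
    windows: list[ResponseWindow],
    cls: EchoClassification,
) -> NeuronResponseSummary:
    """Per-neuron amplitude and latency summary.

    * ``sound_amp`` / ``sound_latency_s``: mean over sound windows that
      contain a detected transient onset (windows without a transient are
      treated as response failures and do not dilute the amplitude).
    * ``echo_amp`` / ``echo_latency_s``: mean over the classified echo
      events, peak measured in the event's window.  Latencies are measured
      from the anticipated time; events preceding it are excluded from the
      latency average.
    * ``baseline_amp``: mean peak-mode amplitude over all baseline windows,
      with no transient requirement.
    """
    sound_amps: list[float] = []
    sound_lats: list[float] = []
    base_amps: list[float] = []
    echo_by_window: dict[tuple[float, int], ResponseWindow] = {}
    for w in windows:
        if w.kind == "sound":
            amp, lat = measure_window(dff, transients, w, mode="peak")
            if lat is not None:
                sound_amps.append(amp)
                sound_lats.append(lat)
        elif w.kind == "baseline":
            amp, _ = measure_window(dff, [], w, mode="peak")
            base_amps.append(amp)
        else:
            echo_by_window[(w.freq_hz, w.k)] = w
    echo_amps: list[float] = []
    echo_lats: list[float] = []
    if cls.is_echo:
        for ev in cls.events:
            w = echo_by_window.get((ev.freq_hz, ev.k))
            if w is None:
                continue
            amp, lat = measure_window(dff, transients, w, mode="peak")
            echo_amps.append(amp)
            if lat is not None:
                echo_lats.append(lat)
    mean = lambda xs: float(np.mean(xs)) if xs else None
    return NeuronResponseSummary(
        neuron_id=cls.neuron_id or dff.neuron_id,
        sound_amp=mean(sound_amps),
        echo_amp=mean(echo_amps),
        baseline_amp=mean(base_amps),
        sound_latency_s=mean(sound_lats),
        echo_latency_s=mean(echo_lats),
        is_echo=cls.is_echo,
        n_sound_windows_responsive=len(sound_amps),
        n_echo_events=len(cls.events) if cls.is_echo else 0,
    )
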