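"""Frequency tuning: response integrals, Gaussian fits, best frequency, ΔFrequency.

A neuron's tuning curve is the mean 500-ms trapezoidal integral of Δf/f after
each tone onset, per stimulus frequency, averaged over the train's
repetitions.  Curves are fitted with a Gaussian on a log2-frequency axis
(x = log2(f / 1 kHz)); the fitted centre, mapped back to Hz and clamped to
the stimulus band, is the best frequency (BF).  ΔFrequency is the octave
distance log2(echo_freq / BF) between the frequency whose train evoked a
neuron's echo responses and its tone-evoked BF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import InvalidArgumentError
from .responses import EchoClassification, ResponseWindow, measure_window
from .signal import DffTrace
from .stimulus import StimulusProtocol

__all__ = [
    "TuningCurve",
    "GaussianFit",
    "DeltaFrequencyRecord",
    "build_tuning_curve",
    "fit_gaussian",
    "best_frequency",
    "delta_frequency",
    "delta_histogram",
    "population_average_tuning",
]

_REF_HZ = 1000.0  # log2 frequency axis reference (1 kHz)


@dataclass(frozen=True)
class TuningCurve:
    neuron_id: str
    freqs_hz: np.ndarray
    mean_resp: np.ndarray  # Δf/f·s, 500-ms integrals averaged over repetitions
    sem_resp: np.ndarray
    norm_resp: np.ndarray  # mean_resp / max(mean_resp) when the max is > 0


@dataclass(frozen=True)
class GaussianFit:
    """amp·exp(−(x−mu)²/(2σ²)) + offset on x = log2(f / 1 kHz)."""

    amp: float
    mu_log2: float
    sigma_log2: float
    offset: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class DeltaFrequencyRecord:
    neuron_id: str
    bf_hz: float
    echo_freq_hz: float
    delta_oct: float


def build_tuning_curve(
    dff: DffTrace,
    protocol: StimulusProtocol,
    integral_dur_s: float = 0.5,
) -> TuningCurve:
    """Per-frequency mean ± SEM of the post-onset Δf/f integrals."""
    t_end = dff.times_s[-1]
    means, sems = [], []
    for fi, freq in enumerate(protocol.frequencies_hz):
        onsets = protocol.tone_onsets_s(fi)
        if onsets[-1] + integral_dur_s > t_end + 1e-9:
            raise InvalidArgumentError("train extends beyond the trace")
        vals = []
        for onset in onsets:
            w = ResponseWindow("sound", float(onset), float(freq), float(onset), float(onset + integral_dur_s))
            amp, _ = measure_window(dff, [], w, mode="integral", integral_dur_s=integral_dur_s)
            vals.append(amp)
        vals = np.asarray(vals)
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0)
    mean_resp = np.asarray(means)
    mx = mean_resp.max()
    norm = mean_resp / mx if mx > 0 else np.zeros_like(mean_resp)
    return TuningCurve(
        neuron_id=dff.neuron_id,
        freqs_hz=np.asarray(protocol.frequencies_hz, dtype=float),
        mean_resp=mean_resp,
        sem_resp=np.asarray(sems),
        norm_resp=norm,
    )


def _gauss(x: np.ndarray, amp: float, mu: float, sigma: float, offset: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + offset


def fit_gaussian(curve: TuningCurve) -> GaussianFit:
    """Least-squares Gaussian fit on the log2-frequency axis.

    Initialisation is multi-start (centre at the curve argmax and at the
    response-weighted centroid); the best residual wins.  When the optimiser
    fails, the curve is flat, or the fitted width exceeds the stimulus band,
    the fit is flagged ``converged=False`` with the argmax frequency as a
    fallback centre.
    """
    if curve.freqs_hz.size < 4:
        raise InvalidArgumentError("need >= 4 distinct frequencies to fit")
    x = np.log2(curve.freqs_hz / _REF_HZ)
    y = curve.mean_resp
    band = float(x[-1] - x[0])
    ymax, ymin = float(y.max()), float(y.min())
    fallback = GaussianFit(
        amp=max(ymax - ymin, 0.0),
        mu_log2=float(x[int(np.argmax(y))]),
        sigma_log2=band / 2 if band > 0 else 1.0,
        offset=ymin,
        rss=float(np.sum((y - y.mean()) ** 2)),
        converged=False,
    )
    if ymax - ymin <= 0:
        return fallback
    weights = np.clip(y - ymin, 0, None)
    centroid = float(np.sum(weights * x) / np.sum(weights)) if weights.sum() > 0 else float(np.mean(x))
    best: GaussianFit | None = None
    for mu0 in (float(x[int(np.argmax(y))]), centroid):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # singular covariance on tiny grids
                popt, _ = curve_fit(
                    _gauss,
                    x,
                    y,
                    p0=[ymax - ymin, mu0, band / 4 if band > 0 else 1.0, ymin],
                    bounds=(
                        [0.0, x[0] - band, 1e-3, -np.inf],
                        [np.inf, x[-1] + band, 10 * max(band, 1.0), np.inf],
                    ),
                    maxfev=5000,
                )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - _gauss(x, *popt)) ** 2))
        if best is None or rss < best.rss:
            best = GaussianFit(
                amp=float(popt[0]),
                mu_log2=float(popt[1]),
                sigma_log2=float(popt[2]),
                offset=float(popt[3]),
                rss=rss,
                converged=True,
            )
    if best is None or best.sigma_log2 > band or best.amp <= 0:
        return fallback
    return best


def best_frequency(curve: TuningCurve, fit: GaussianFit | None = None) -> float | None:
    """Best frequency in Hz: Gaussian-fit centre clamped to the stimulus band.

    Falls back to the argmax stimulus frequency for non-converged fits;
    returns ``None`` for an all-zero curve (no measurable preference).
    """
    if curve.freqs_hz.size == 0:
        raise InvalidArgumentError("empty tuning curve")
    if not np.any(curve.mean_resp > 0):
        return None
    if fit is None:
        fit = fit_gaussian(curve)
    if fit.converged:
        bf = _REF_HZ * 2.0**fit.mu_log2
        return float(np.clip(bf, curve.freqs_hz[0], curve.freqs_hz[-1]))
    return float(curve.freqs_hz[int(np.argmax(curve.mean_resp))])


def delta_frequency(bf_hz: float | None, cls: EchoClassification) -> list[DeltaFrequencyRecord]:
    """ΔFrequency records, one per distinct echo-evoking frequency.

    Returns an empty list (with no error) when the neuron is not an echo
    neuron or its BF is undefined.
    """
    if not cls.is_echo or bf_hz is None or not np.isfinite(bf_hz) or bf_hz <= 0:
        return []
    return [
        DeltaFrequencyRecord(
            neuron_id=cls.neuron_id,
            bf_hz=float(bf_hz),
            echo_freq_hz=float(f),
            delta_oct=float(np.log2(f / bf_hz)),
        )
        for f in cls.echo_freqs_hz
    ]


def delta_histogram(
    records: list[DeltaFrequencyRecord],
    bin_oct: float = float(np.log2(20.0) / 10.0),
) -> tuple[np.ndarray, np.ndarray, GaussianFit | None]:
    """Histogram of ΔFrequency (octaves) with a Gaussian fit to the counts.

    Bins are ``bin_oct`` wide (default: one stimulus step of the standard
    11-tone 2–40 kHz grid) and centred so one bin is centred on 0.  Returns
    (counts, bin_edges, fit); the fit is ``None`` with fewer than 5 records.
    """
    deltas = np.asarray([r.delta_oct for r in records], dtype=float)
    if deltas.size == 0:
        return np.array([]), np.array([]), None
    half = bin_oct / 2.0
    lo = np.floor((deltas.min() + half) / bin_oct) * bin_oct - half
    hi = np.ceil((deltas.max() - half) / bin_oct) * bin_oct + half
    edges = np.arange(lo, hi + bin_oct / 2, bin_oct)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_oct])
    counts, edges = np.histogram(deltas, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if deltas.size < 5:
        return counts, edges, None
    if np.count_nonzero(counts) < 2:
        mode = float(centers[int(np.argmax(counts))])
        return counts, edges, GaussianFit(float(counts.max()), mode, bin_oct, 0.0, 0.0, False)
    curve = TuningCurve(
        neuron_id="delta_hist",
        freqs_hz=_REF_HZ * 2.0**centers,  # reuse the log2-axis fitter
        mean_resp=counts.astype(float),
        sem_resp=np.zeros_like(counts, dtype=float),
        norm_resp=counts / counts.max() if counts.max() > 0 else counts.astype(float),
    )
    if centers.size < 4:
        mu = float(np.average(centers, weights=np.maximum(counts, 1e-12)))
        return counts, edges, GaussianFit(float(counts.max()), mu, bin_oct, 0.0, 0.0, False)
    return counts, edges, fit_gaussian(curve)


def population_average_tuning(
    curves: list[TuningCurve],
    bfs_hz: list[float | None],
    step_oct: float,
    n_steps: int = 4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BF-aligned average of normalized tuning curves.

    Each curve's frequency axis is re-expressed as octaves from its BF,
    snapped to the stimulus grid step, and the normalized responses are
    averaged per offset bin over neurons.  Returns (offsets_oct, mean, sem).
    """
    offsets = np.arange(-n_steps, n_steps + 1) * step_oct
    acc: list[list[float]] = [[] for _ in offsets]
    for curve, bf in zip(curves, bfs_hz):
        if bf is None or bf <= 0:
            continue
        rel = np.log2(curve.freqs_hz / bf)
        for r, v in zip(rel, curve.norm_resp):
            j = int(round(r / step_oct)) + n_steps
            if 0 <= j < len(offsets) and abs(r - (j - n_steps) * step_oct) < step_oct / 2:
                acc[j].append(float(v))
    mean = np.array([np.mean(a) if a else np.nan for a in acc])
    sem = np.array([np.std(a, ddof=1) / np.sqrt(len(a)) if len(a) > 1 else np.nan for a in acc])
    return offsets, mean, sem
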