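"""End-to-end per-session analysis: traces → transients → classification → tuning.

This module wires the stages together for a list of ROI traces sharing one
stimulus protocol.  It exists so the CLI, the validation suite and external
callers run the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .responses import (
    EchoClassification,
    NeuronResponseSummary,
    build_windows,
    classify_echo,
    empirical_bayes_rates,
    estimate_spont_rate,
    summarize_neuron,
)
from .signal import DffTrace, RoiTrace, Transient, compute_dff, detect_transients, estimate_noise_sd
from .stats import PopulationSummary, SpatialHeterogeneityResult, spatial_heterogeneity, summarize_population
from .stimulus import StimulusProtocol
from .tuning import (
    DeltaFrequencyRecord,
    GaussianFit,
    TuningCurve,
    best_frequency,
    build_tuning_curve,
    delta_frequency,
    fit_gaussian,
)

__all__ = ["AnalysisParams", "NeuronResult", "SessionResult", "analyze_session", "analyze_population"]


@dataclass(frozen=True)
class AnalysisParams:
    """All tunable analysis settings with their package defaults."""

    amp_thresh_sd: float = 3.0
    rise_thresh: float = 0.1  # Δf/f per second, onset-to-peak
    min_dur_s: float = 0.1
    min_separation_s: float = 0.2
    sound_win_s: float = 0.5
    echo_halfwidth_s: float = 0.75
    k_max: int = 5
    alpha: float = 0.05
    null_rate_pseudo_count: float = 0.5  # Jeffreys-style regularizer for the Poisson null
    integral_dur_s: float = 0.5
    baseline_percentile: float = 25.0


@dataclass
class NeuronResult:
    neuron_id: str
    dff: DffTrace
    noise_sd: float
    transients: list[Transient]
    spont_rate_hz: float
    classification: EchoClassification
    summary: NeuronResponseSummary
    tuning: TuningCurve
    fit: GaussianFit
    bf_hz: float | None
    delta_records: list[DeltaFrequencyRecord]


@dataclass
class SessionResult:
    protocol: StimulusProtocol
    params: AnalysisParams
    neurons: list[NeuronResult] = field(default_factory=list)

    @property
    def summaries(self) -> list[NeuronResponseSummary]:
        return [n.summary for n in self.neurons]

    @property
    def echo_fraction_pct(self) -> float:
        return 100.0 * sum(n.classification.is_echo for n in self.neurons) / len(self.neurons)

    @property
    def delta_records(self) -> list[DeltaFrequencyRecord]:
        return [r for n in self.neurons for r in n.delta_records]

    def transients_frame(self) -> pd.DataFrame:
        rows = [
            (tr.neuron_id, tr.onset_s, tr.peak_s, tr.peak_amp, tr.rise_rate, tr.offset_s)
            for n in self.neurons
            for tr in n.transients
        ]
        return pd.DataFrame(
            rows, columns=["neuron_id", "onset_s", "peak_s", "peak_amp", "rise_rate", "offset_s"]
        )

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for n in self.neurons:
            s, c = n.summary, n.classification
            rows.append(
                {
                    "neuron_id": s.neuron_id,
                    "is_echo": s.is_echo,
                    "p_spont": c.p_spont,
                    "spont_rate_hz": n.spont_rate_hz,
                    "n_echo_events": s.n_echo_events,
                    "n_echo_events_max": c.n_echo_events_max,
                    "echo_freqs_hz": ";".join(f"{f:.0f}" for f in c.echo_freqs_hz),
                    "sound_amp": s.sound_amp,
                    "echo_amp": s.echo_amp,
                    "baseline_amp": s.baseline_amp,
                    "sound_latency_s": s.sound_latency_s,
                    "echo_latency_s": s.echo_latency_s,
                    "bf_hz": n.bf_hz,
                    "fit_converged": n.fit.converged,
                }
            )
        return pd.DataFrame(rows)

    def tuning_frame(self) -> pd.DataFrame:
        rows = {}
        for n in self.neurons:
            rows[n.neuron_id] = n.tuning.mean_resp
        df = pd.DataFrame(rows).T
        df.columns = [f"{f:.0f}" for f in self.protocol.frequencies_hz]
        df.index.name = "neuron_id"
        return df

    def delta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.neuron_id, r.bf_hz, r.echo_freq_hz, r.delta_oct) for r in self.delta_records],
            columns=["neuron_id", "bf_hz", "echo_freq_hz", "delta_oct"],
        )


def analyze_session(
    traces: list[RoiTrace],
    protocol: StimulusProtocol,
    params: AnalysisParams = AnalysisParams(),
) -> SessionResult:
    """Run the full analysis for every ROI trace in one session.

    Classification uses an empirical-Bayes spontaneous-rate null: each
    neuron's stimulus-free event count is shrunk toward the session's pooled
    rate (Gamma–Poisson partial pooling), which keeps the Poisson null proper
    for neurons with few or no spontaneous events.
    """
    windows = build_windows(
        protocol,
        sound_win_s=params.sound_win_s,
        echo_halfwidth_s=params.echo_halfwidth_s,
        k_max=params.k_max,
    )
    # pass 1: normalisation, detection and per-neuron spontaneous statistics
    prep = []
    for trace in traces:
        dff = compute_dff(trace, percentile=params.baseline_percentile)
        noise_sd = estimate_noise_sd(dff)
        transients = detect_transients(
            dff,
            amp_thresh_sd=params.amp_thresh_sd,
            rise_thresh=params.rise_thresh,
            min_dur_s=params.min_dur_s,
            min_separation_s=params.min_separation_s,
            noise_sd=noise_sd,
        )
        extent = (float(dff.times_s[0]), float(dff.times_s[-1]))
        spont_rate, free_s = estimate_spont_rate(
            transients, protocol, extent, windows=windows, return_free_time=True
        )
        prep.append((trace, dff, noise_sd, transients, spont_rate, free_s))
    null_rates = empirical_bayes_rates(
        np.asarray([round(r * f) for _, _, _, _, r, f in prep]),
        np.asarray([f for *_, f in prep]),
        pseudo_count=params.null_rate_pseudo_count,
    )
    # pass 2: classification, summaries, tuning
    result = SessionResult(protocol=protocol, params=params)
    for (trace, dff, noise_sd, transients, spont_rate, free_s), null_rate in zip(prep, null_rates):
        cls = classify_echo(
            transients, windows, float(null_rate), alpha=params.alpha, neuron_id=trace.neuron_id
        )
        summary = summarize_neuron(dff, transients, windows, cls)
        tuning = build_tuning_curve(dff, protocol, integral_dur_s=params.integral_dur_s)
        if tuning.freqs_hz.size >= 4:
            fit = fit_gaussian(tuning)
        else:  # too few tones for a Gaussian fit; argmax fallback
            fit = GaussianFit(
                amp=float(tuning.mean_resp.max(initial=0.0)),
                mu_log2=float(np.log2(tuning.freqs_hz[int(np.argmax(tuning.mean_resp))] / 1000.0)),
                sigma_log2=1.0,
                offset=0.0,
                rss=float("nan"),
                converged=False,
            )
        bf = best_frequency(tuning, fit)
        deltas = delta_frequency(bf, cls)
        result.neurons.append(
            NeuronResult(
                neuron_id=trace.neuron_id,
                dff=dff,
                noise_sd=noise_sd,
                transients=transients,
                spont_rate_hz=spont_rate,
                classification=cls,
                summary=summary,
                tuning=tuning,
                fit=fit,
                bf_hz=bf,
                delta_records=deltas,
            )
        )
    return result


def analyze_population(
    sessions: list[SessionResult],
    xy_um: list[np.ndarray] | None = None,
    r_um: float = 50.0,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[PopulationSummary, SpatialHeterogeneityResult | None]:
    """Pool per-session results; spatial test uses the first session's map.

    ``xy_um`` supplies, per session, an (n_neurons, 2) array of ROI centroids
    aligned with that session's neuron order; the spatial test runs on the
    echo neurons of each session separately and the first available result is
    returned (maps from different imaging planes cannot share coordinates).
    """
    pop = summarize_population([s.summaries for s in sessions])
    spatial: SpatialHeterogeneityResult | None = None
    if xy_um is not None:
        for sess, xy in zip(sessions, xy_um):
            mask, freqs, pts = [], [], []
            for n, p in zip(sess.neurons, np.atleast_2d(xy)):
                c = n.classification
                if c.is_echo and c.echo_freqs_hz:
                    counts: dict[float, int] = {}
                    for ev in c.events:
                        counts[ev.freq_hz] = counts.get(ev.freq_hz, 0) + 1
                    freqs.append(max(counts, key=counts.get))
                    pts.append(p)
            if len(freqs) >= 5:
                res = spatial_heterogeneity(
                    np.asarray(pts), np.asarray(freqs), r_um=r_um, n_perm=n_perm, seed=seed
                )
                if res.available:
                    spatial = res
                    break
    return pop, spatial
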