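"""Population summaries, Wilcoxon tests and the spatial-heterogeneity test.

The echo fraction is averaged per session first (mean ± SEM across sessions,
i.e. across animals), while amplitudes and latencies are pooled across
neurons with SEM over neurons.  Three comparisons mirror the standard
presentation of omitted-stimulus data: echo vs baseline amplitude (paired
signed rank over neurons), sound vs echo amplitude and sound vs echo latency
(both unpaired rank sum).

Spatial heterogeneity of the echo-frequency map is quantified as the mean
pairwise octave distance between echo frequencies of nearby echo neurons; a
permutation null (shuffling frequencies across echo-neuron positions) gives
a one-sided p-value for the *tonotopic clustering* alternative, so a large
p means the local map is heterogeneous/mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InvalidArgumentError, UndefinedTestError
from .responses import NeuronResponseSummary

__all__ = [
    "PopulationSummary",
    "SpatialHeterogeneityResult",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "summarize_population",
    "spatial_heterogeneity",
]


@dataclass
class PopulationSummary:
    n_neurons: int
    n_sessions: int
    echo_fraction_mean: float  # per-session mean, percent
    echo_fraction_sem: float
    amp_echo_mean: float | None
    amp_echo_sem: float | None
    amp_baseline_mean: float | None
    amp_baseline_sem: float | None
    amp_sound_mean: float | None
    amp_sound_sem: float | None
    lat_sound_mean: float | None
    lat_sound_sem: float | None
    lat_echo_mean: float | None
    lat_echo_sem: float | None
    p_amp_echo_vs_baseline: float | None
    p_amp_sound_vs_echo: float | None
    p_lat_sound_vs_echo: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SpatialHeterogeneityResult:
    statistic: float  # mean pairwise |Δ octave| among nearby echo neurons
    null_mean: float
    null_sd: float
    p_perm: float  # small p = tonotopic clustering; large p = mixed map
    n_pairs: int
    n_neurons: int
    available: bool


def wilcoxon_signed_rank(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; the null distribution is exact for n ≤ 25
    (no tied ranks), otherwise a continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise UndefinedTestError("all paired differences are zero")
    if d.size < 5:
        raise InvalidArgumentError("need >= 5 nonzero differences")
    ranks = sps.rankdata(np.abs(d))
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return float(res.pvalue)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Mann–Whitney/Wilcoxon rank-sum p-value for unpaired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidArgumentError("both groups must be non-empty")
    if min(x.size, y.size) < 4:
        raise InvalidArgumentError("need >= 4 observations per group")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def _pool(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    v = np.asarray(values, dtype=float)
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), sem


def summarize_population(sessions: list[list[NeuronResponseSummary]]) -> PopulationSummary:
    """Aggregate per-neuron summaries from one or more sessions.

    Echo fraction is computed per session and averaged across sessions;
    every other quantity is pooled across all neurons.  Echo fields are
    ``None`` when no neuron in any session was classified as an echo neuron.
    """
    if not sessions:
        raise InvalidArgumentError("need at least one session")
    fractions = []
    for sess in sessions:
        if not sess:
            raise InvalidArgumentError("empty session")
        fractions.append(100.0 * sum(s.is_echo for s in sess) / len(sess))
    fractions = np.asarray(fractions)
    frac_sem = float(fractions.std(ddof=1) / np.sqrt(fractions.size)) if fractions.size > 1 else 0.0

    neurons = [s for sess in sessions for s in sess]
    echo_amps = [s.echo_amp for s in neurons if s.echo_amp is not None]
    base_amps = [s.baseline_amp for s in neurons if s.baseline_amp is not None]
    sound_amps = [s.sound_amp for s in neurons if s.sound_amp is not None]
    sound_lats = [s.sound_latency_s for s in neurons if s.sound_latency_s is not None]
    echo_lats = [s.echo_latency_s for s in neurons if s.echo_latency_s is not None]

    def safe(test, *args):
        try:
            return test(*args)
        except (InvalidArgumentError, UndefinedTestError):
            return None

    paired = [
        (s.echo_amp, s.baseline_amp)
        for s in neurons
        if s.echo_amp is not None and s.baseline_amp is not None
    ]
    p_eb = safe(wilcoxon_signed_rank, [a for a, _ in paired], [b for _, b in paired]) if paired else None
    p_se = safe(wilcoxon_rank_sum, sound_amps, echo_amps) if echo_amps else None
    p_lat = safe(wilcoxon_rank_sum, sound_lats, echo_lats) if echo_lats else None

    amp_echo = _pool(echo_amps)
    amp_base = _pool(base_amps)
    amp_sound = _pool(sound_amps)
    lat_sound = _pool(sound_lats)
    lat_echo = _pool(echo_lats)
    return PopulationSummary(
        n_neurons=len(neurons),
        n_sessions=len(sessions),
        echo_fraction_mean=float(fractions.mean()),
        echo_fraction_sem=frac_sem,
        amp_echo_mean=amp_echo[0],
        amp_echo_sem=amp_echo[1],
        amp_baseline_mean=amp_base[0],
        amp_baseline_sem=amp_base[1],
        amp_sound_mean=amp_sound[0],
        amp_sound_sem=amp_sound[1],
        lat_sound_mean=lat_sound[0],
        lat_sound_sem=lat_sound[1],
        lat_echo_mean=lat_echo[0],
        lat_echo_sem=lat_echo[1],
        p_amp_echo_vs_baseline=p_eb,
        p_amp_sound_vs_echo=p_se,
        p_lat_sound_vs_echo=p_lat,
    )


def spatial_heterogeneity(
    xy_um: np.ndarray,
    echo_freqs_hz: np.ndarray,
    r_um: float = 50.0,
    n_perm: int = 9999,
    seed: int = 0,
) -> SpatialHeterogeneityResult:
    """Permutation test for local tonotopic structure of the echo-frequency map.

    Parameters
    ----------
    xy_um
        (n, 2) echo-neuron centroids in µm.
    echo_freqs_hz
        One echo-evoking frequency per neuron (Hz).
    r_um
        Neighbourhood radius defining "adjacent" neurons.

    The statistic is the mean |log2(f_i/f_j)| over neuron pairs closer than
    ``r_um``; the null shuffles frequencies across positions.  The p-value
    ``(1 + #{null ≤ observed}) / (n_perm + 1)`` is one-sided for the
    clustering (locally similar) alternative.
    """
    xy = np.atleast_2d(np.asarray(xy_um, dtype=float))
    f = np.asarray(echo_freqs_hz, dtype=float)
    if n_perm < 999:
        raise InvalidArgumentError("n_perm must be >= 999")
    if xy.shape[0] != f.size:
        raise InvalidArgumentError("positions and frequencies must align")
    n = f.size
    if n < 5:
        return SpatialHeterogeneityResult(np.nan, np.nan, np.nan, np.nan, 0, n, available=False)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    ii, jj = np.where(np.triu(d <= r_um, k=1))
    if ii.size < 1:
        return SpatialHeterogeneityResult(np.nan, np.nan, np.nan, np.nan, 0, n, available=False)
    logf = np.log2(f)
    obs = float(np.abs(logf[ii] - logf[jj]).mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(logf)
        null[b] = np.abs(perm[ii] - perm[jj]).mean()
    p = float((1 + np.sum(null <= obs)) / (n_perm + 1))
    return SpatialHeterogeneityResult(
        statistic=obs,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        p_perm=p,
        n_pairs=int(ii.size),
        n_neurons=n,
        available=True,
    )
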