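"""Rhythmic pure-tone stimulation protocols.

A protocol is a set of tone *trains*: for each carrier frequency, ``n_reps``
identical tones presented at a fixed inter-stimulus interval (ISI, onset to
onset).  Frequencies are logarithmically spaced across the stimulation band,
the arrangement used to map frequency tuning in auditory cortex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["StimulusProtocol", "make_protocol", "read_protocol", "write_protocol"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing and frequency layout of a rhythmic tone-train session.

    Parameters
    ----------
    frequencies_hz
        Tone frequencies, strictly increasing (Hz).  One train per frequency.
    isi_s
        Inter-stimulus interval within a train, onset to onset (s).
    tone_dur_s
        Tone duration (s), including ramps.
    n_reps
        Number of tone repetitions per train.
    train_onsets_s
        Onset time of the first tone of each train (s); same length and order
        as ``frequencies_hz``.
    ramp_s
        Linear on/off ramp duration (s).  Metadata only; the analysis never
        uses it.
    """

    frequencies_hz: tuple[float, ...]
    isi_s: float
    tone_dur_s: float
    n_reps: int
    train_onsets_s: tuple[float, ...]
    ramp_s: float = 0.01

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        if f.size < 1 or np.any(np.diff(f) <= 0):
            raise InvalidArgumentError("frequencies must be strictly increasing")
        if not (self.isi_s > self.tone_dur_s > 0):
            raise InvalidArgumentError("require isi_s > tone_dur_s > 0")
        if self.n_reps < 1:
            raise InvalidArgumentError("n_reps must be >= 1")
        if len(self.train_onsets_s) != f.size:
            raise InvalidArgumentError("one train onset per frequency required")
        onsets = np.asarray(self.train_onsets_s, dtype=float)
        order = np.argsort(onsets)
        span = self.train_span_s
        for a, b in zip(order[:-1], order[1:]):
            if onsets[a] + span > onsets[b]:
                raise InvalidArgumentError("trains overlap")

    @property
    def n_freqs(self) -> int:
        return len(self.frequencies_hz)

    @property
    def train_span_s(self) -> float:
        """Duration of one train, first tone onset to last tone offset."""
        return (self.n_reps - 1) * self.isi_s + self.tone_dur_s

    @property
    def log2_step_oct(self) -> float:
        """Grid spacing in octaves (uniform for log-spaced protocols)."""
        f = np.log2(np.asarray(self.frequencies_hz))
        if f.size < 2:
            return 0.0
        return float(np.mean(np.diff(f)))

    def tone_onsets_s(self, freq_index: int) -> np.ndarray:
        """Onset times of every tone in the train for ``frequencies_hz[freq_index]``."""
        t0 = self.train_onsets_s[freq_index]
        return t0 + self.isi_s * np.arange(self.n_reps)

    def train_end_s(self, freq_index: int) -> float:
        """Onset time of the *last* tone of a train (the anticipated-time anchor)."""
        return self.train_onsets_s[freq_index] + (self.n_reps - 1) * self.isi_s

    @property
    def end_of_stimulation_s(self) -> float:
        return max(self.train_onsets_s) + self.train_span_s


def make_protocol(
    n_freqs: int,
    f_min_hz: float,
    f_max_hz: float,
    n_reps: int = 20,
    isi_s: float = 2.0,
    tone_dur_s: float = 0.1,
    gap_s: float = 30.0,
    first_onset_s: float = 30.0,
    ramp_s: float = 0.01,
) -> StimulusProtocol:
    """Build a log-spaced tone-train protocol.

    Frequencies are geometrically spaced from ``f_min_hz`` to ``f_max_hz``
    inclusive and presented lowest to highest, each train separated from the
    previous train's end by ``gap_s`` of silence.

    Raises
    ------
    InvalidArgumentError
        For non-positive counts/durations or ``f_min_hz > f_max_hz``.
    """
    if n_freqs < 1:
        raise InvalidArgumentError("n_freqs must be >= 1")
    if not (0 < f_min_hz <= f_max_hz):
        raise InvalidArgumentError("require 0 < f_min_hz <= f_max_hz")
    if n_reps < 1 or tone_dur_s <= 0 or isi_s <= tone_dur_s or gap_s < 0:
        raise InvalidArgumentError("invalid timing parameters")
    if n_freqs == 1:
        freqs = np.array([float(f_min_hz)])
    else:
        freqs = np.geomspace(f_min_hz, f_max_hz, n_freqs)
    span = (n_reps - 1) * isi_s + tone_dur_s
    onsets = first_onset_s + (span + gap_s) * np.arange(n_freqs)
    return StimulusProtocol(
        frequencies_hz=tuple(float(f) for f in freqs),
        isi_s=float(isi_s),
        tone_dur_s=float(tone_dur_s),
        n_reps=int(n_reps),
        train_onsets_s=tuple(float(t) for t in onsets),
        ramp_s=float(ramp_s),
    )


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    """Serialize a protocol to JSON (keys are the dataclass field names)."""
    payload = {
        "frequencies_hz": list(protocol.frequencies_hz),
        "isi_s": protocol.isi_s,
        "tone_dur_s": protocol.tone_dur_s,
        "n_reps": protocol.n_reps,
        "train_onsets_s": list(protocol.train_onsets_s),
        "ramp_s": protocol.ramp_s,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_protocol(path: str | Path) -> StimulusProtocol:
    payload = json.loads(Path(path).read_text())
    return StimulusProtocol(
        frequencies_hz=tuple(payload["frequencies_hz"]),
        isi_s=float(payload["isi_s"]),
        tone_dur_s=float(payload["tone_dur_s"]),
        n_reps=int(payload["n_reps"]),
        train_onsets_s=tuple(payload["train_onsets_s"]),
        ramp_s=float(payload.get("ramp_s", 0.01)),
    )
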