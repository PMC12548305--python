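"""Core domain containers shared across the pipeline.

Times are always seconds from recording start; peri-event quantities
(bin edges, windows, jitter bounds) are milliseconds relative to pulse
onset, matching how such analyses are conventionally reported.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("optofear")


class InvalidParameterError(ValueError):
    """A parameter violates an operation's preconditions."""


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class SpikeTrain:
    """One unit's sorted spike times (seconds) over a known recording span."""

    unit_id: str
    spike_times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.ascontiguousarray(np.asarray(self.spike_times, dtype=float))
        object.__setattr__(self, "spike_times", t)
        if t.ndim != 1:
            raise InvalidParameterError("spike_times must be one-dimensional")
        if self.duration <= 0:
            raise InvalidParameterError("duration must be positive")
        if t.size:
            if t[0] < 0:
                raise InvalidParameterError("spike times must be non-negative")
            d = np.diff(t)
            if np.any(d < 0):
                raise InvalidParameterError("spike times must be ascending")
            if np.any(d == 0):
                log.warning("unit %s: duplicate spike times present", self.unit_id)
            if t[-1] >= self.duration:
                raise InvalidParameterError(
                    f"unit {self.unit_id}: spike at {t[-1]:.6f}s >= duration {self.duration}s"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def isis(self) -> np.ndarray:
        """Inter-spike intervals in seconds."""
        return np.diff(self.spike_times)


@dataclass(frozen=True)
class StimProtocol:
    """Light-pulse onsets plus the train/pulse geometry that produced them."""

    pulse_onsets: np.ndarray          # seconds, strictly ascending
    pulse_width: float                # seconds
    pulse_rate: float                 # Hz within a train
    train_spec: tuple = ()            # ((duration_s, intensity_label), ...)
    inter_train_gap: float = 30.0     # seconds between trains
    baseline_s: float = 300.0         # pre-stimulation baseline
    total_duration: float = 0.0       # seconds
    train_ids: np.ndarray = field(default=None)  # int per pulse, or None

    def __post_init__(self) -> None:
        onsets = np.ascontiguousarray(np.asarray(self.pulse_onsets, dtype=float))
        object.__setattr__(self, "pulse_onsets", onsets)
        if self.pulse_rate <= 0:
            raise InvalidParameterError("pulse_rate must be positive")
        if not 0 < self.pulse_width < 1.0 / self.pulse_rate:
            raise InvalidParameterError("pulse_width must lie in (0, 1/pulse_rate)")
        if onsets.size:
            if np.any(np.diff(onsets) <= 0):
                raise InvalidParameterError("pulse onsets must be strictly ascending")
            if onsets[0] < self.baseline_s:
                raise InvalidParameterError("no pulse may precede the baseline period")
        if self.train_ids is not None:
            tid = np.asarray(self.train_ids, dtype=int)
            if tid.shape != onsets.shape:
                raise InvalidParameterError("train_ids must align with pulse_onsets")
            object.__setattr__(self, "train_ids", tid)
        if self.total_duration == 0.0 and onsets.size:
            object.__setattr__(
                self, "total_duration",
                float(onsets[-1] + 1.0 / self.pulse_rate + self.inter_train_gap),
            )

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_onsets.size)

    @property
    def pulse_period(self) -> float:
        """Seconds between consecutive pulses within a train."""
        return 1.0 / self.pulse_rate


@dataclass(frozen=True)
class Peth:
    """Peri-event time histogram pooled over pulses, one unit.

    ``counts[i]`` is the number of spikes falling in
    ``[bin_edges_ms[i], bin_edges_ms[i+1])`` relative to any pulse onset,
    summed over pulses.
    """

    unit_id: str
    bin_edges_ms: np.ndarray
    counts: np.ndarray
    n_pulses: int
    z: np.ndarray | None = None
    zero_baseline_sd: bool = False

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_ms, dtype=float)
        counts = np.asarray(self.counts)
        if counts.size != edges.size - 1:
            raise InvalidParameterError("counts must have len(bin_edges) - 1 entries")
        if np.any(counts < 0):
            raise InvalidParameterError("counts must be non-negative")
        object.__setattr__(self, "bin_edges_ms", edges)
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def bin_width_ms(self) -> float:
        return float(self.bin_edges_ms[1] - self.bin_edges_ms[0])

    @property
    def rate(self) -> np.ndarray:
        """Firing rate per bin in Hz: counts / (n_pulses * bin_width)."""
        return self.counts / (self.n_pulses * self.bin_width_ms / 1000.0)


@dataclass(frozen=True)
class JitterConfig:
    """Parameters of the jitter-surrogate responsiveness test.

    Defaults follow the published analysis: 100 surrogates, spike shifts of
    magnitude U(1, 10) ms, 1-ms bins, the 99th surrogate percentile as the
    per-bin threshold, and a 12-ms post-onset test window covering both the
    pulse onset (0 ms) and offset (10 ms) responses.
    """

    n_surrogates: int = 100
    jitter_low_ms: float = 1.0
    jitter_high_ms: float = 10.0
    bin_ms: float = 1.0
    percentile: float = 99.0
    test_window_ms: float = 12.0
    pulse_width_ms: float = 10.0
    jitter_sign: str = "symmetric"   # "symmetric" or "positive"
    baseline_window_ms: tuple = (-25.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surrogates < 2:
            raise InvalidParameterError("need at least 2 surrogates")
        if self.n_surrogates < 20:
            log.warning(
                "n_surrogates=%d: percentile threshold will be unstable",
                self.n_surrogates,
            )
        if not 0 < self.jitter_low_ms < self.jitter_high_ms:
            raise InvalidParameterError("require 0 < jitter_low < jitter_high")
        if not 50.0 < self.percentile < 100.0:
            raise InvalidParameterError("percentile must lie in (50, 100)")
        if self.test_window_ms < self.pulse_width_ms:
            raise InvalidParameterError("test window must cover the pulse width")
        if self.jitter_sign not in ("symmetric", "positive"):
            raise InvalidParameterError("jitter_sign must be 'symmetric' or 'positive'")
        n_bins = self.test_window_ms / self.bin_ms
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise InvalidParameterError("bin_ms must divide test_window_ms")

    @property
    def n_test_bins(self) -> int:
        return int(round(self.test_window_ms / self.bin_ms))

    @property
    def test_bin_edges_ms(self) -> np.ndarray:
        return np.arange(self.n_test_bins + 1) * self.bin_ms


@dataclass(frozen=True)
class ResponseCall:
    """Per-unit verdict of the jitter test."""

    unit_id: str
    responsive: bool
    significant_bins_ms: np.ndarray      # left edges of significant bins
    response_type: str                   # "excited" | "inhibited_rebound" | "none"
    thresholds: np.ndarray               # per-bin surrogate thresholds (counts)
    observed_counts: np.ndarray          # per-bin observed counts

    def __post_init__(self) -> None:
        sig = np.asarray(self.significant_bins_ms, dtype=float)
        object.__setattr__(self, "significant_bins_ms", sig)
        if self.responsive != (sig.size > 0):
            raise InvalidParameterError("responsive must mirror significant bins")
        if (self.response_type == "none") == self.responsive:
            raise InvalidParameterError("response_type 'none' iff not responsive")

    @property
    def first_significant_bin_ms(self) -> float | None:
        if not self.responsive:
            return None
        return float(self.significant_bins_ms.min())


@dataclass(frozen=True)
class RecordingSet:
    """Spike trains from one recording site plus acquisition metadata."""

    trains: tuple
    sampling_rate: float
    site_id: str = "site0"
    group_label: str = "ChR2"

    def __post_init__(self) -> None:
        ids = [t.unit_id for t in self.trains]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError("unit_ids must be unique within a recording set")
        object.__setattr__(self, "trains", tuple(self.trains))
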