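"""Peri-event time histograms around light-pulse onsets.

Counts are pooled over pulses with half-open bins; at 20 Hz stimulation the
display windows of consecutive pulses overlap, and a spike is counted
relative to every pulse whose window contains it (pooled-PETH convention).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import InvalidParameterError, Peth

#: Display window: one pre-onset margin plus one inter-pulse period at 20 Hz.
DEFAULT_WINDOW_MS = (-25.0, 50.0)
#: Pre-onset bins used as the z-scoring baseline.
DEFAULT_BASELINE_MS = (-25.0, 0.0)


def pooled_relative_times(spikes: np.ndarray, onsets: np.ndarray, lo_s: float, hi_s: float):
    """Spike times relative to every onset whose [lo, hi) window holds them.

    Returns (relative_times_s, pulse_index), each of length equal to the
    total number of (spike, pulse) pairings.
    """
    lo_idx = np.searchsorted(spikes, onsets + lo_s, side="left")
    hi_idx = np.searchsorted(spikes, onsets + hi_s, side="left")
    counts = hi_idx - lo_idx
    total = int(counts.sum())
    if total == 0:
        return np.empty(0), np.empty(0, dtype=int)
    pulse_idx = np.repeat(np.arange(onsets.size), counts)
    starts = np.repeat(lo_idx - np.concatenate(([0], np.cumsum(counts)[:-1])), counts)
    flat = spikes[starts + np.arange(total)]
    return flat - onsets[pulse_idx], pulse_idx


def compute_peth(train, pulse_onsets, window_ms=DEFAULT_WINDOW_MS, bin_ms: float = 1.0) -> Peth:
    """Bin spikes by time relative to pulse onsets, pooled over pulses.

    A spike at relative time t lands in the bin with left edge <= t < right
    edge; spikes outside the window are ignored.
    """
    onsets = np.asarray(pulse_onsets, dtype=float)
    if onsets.size == 0:
        raise InvalidParameterError("no pulses to align to")
    w0, w1 = float(window_ms[0]), float(window_ms[1])
    if w1 <= w0:
        raise InvalidParameterError("window must have positive span")
    n_bins = (w1 - w0) / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise InvalidParameterError("bin_ms must divide the window span")
    n_bins = int(round(n_bins))

    rel, _ = pooled_relative_times(train.spike_times, onsets, w0 / 1000.0, w1 / 1000.0)
    idx = np.floor((rel * 1000.0 - w0) / bin_ms).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]  # guard float edge effects
    counts = np.bincount(idx, minlength=n_bins)
    edges = w0 + np.arange(n_bins + 1) * bin_ms
    return Peth(
        unit_id=train.unit_id,
        bin_edges_ms=edges,
        counts=counts,
        n_pulses=int(onsets.size),
    )


def zscore_peth(
    peth: Peth,
    baseline_ms=DEFAULT_BASELINE_MS,
    test_window_ms=(0.0, 12.0),
) -> Peth:
    """z-score a PETH's per-bin rates against its pre-onset baseline bins.

    z = (rate - mean(baseline rates)) / SD(baseline rates) with sample SD.
    When the baseline SD is zero the z trace is set to 0 and the unit is
    flagged (``zero_baseline_sd``).
    """
    b0, b1 = float(baseline_ms[0]), float(baseline_ms[1])
    t0, t1 = float(test_window_ms[0]), float(test_window_ms[1])
    if max(b0, t0) < min(b1, t1):
        raise InvalidParameterError("baseline bins must be disjoint from the test window")
    left = peth.bin_edges_ms[:-1]
    mask = (left >= b0) & (left < b1)
    if not mask.any():
        raise InvalidParameterError("baseline window contains no bins")
    rate = peth.rate
    mu = rate[mask].mean()
    sd = rate[mask].std(ddof=1) if mask.sum() > 1 else 0.0
    if sd == 0.0:
        z = np.zeros_like(rate)
        flagged = True
    else:
        z = (rate - mu) / sd
        flagged = False
    return Peth(
        unit_id=peth.unit_id,
        bin_edges_ms=peth.bin_edges_ms,
        counts=peth.counts,
        n_pulses=peth.n_pulses,
        z=z,
        zero_baseline_sd=flagged,
    )


@dataclass(frozen=True)
class PopulationMatrix:
    """z-scored PETHs stacked over units, responders first.

    Rows 0..partition_index-1 are responsive units sorted by the latency of
    their first significant bin; the rest are non-responders by unit_id.
    """

    unit_order: tuple
    z: np.ndarray
    partition_index: int
    bin_edges_ms: np.ndarray


def population_matrix(peths, calls) -> PopulationMatrix:
    """Stack z-scored PETHs with the responder partition used for display."""
    peths = list(peths)
    calls = {c.unit_id: c for c in calls}
    if set(calls) != {p.unit_id for p in peths}:
        raise InvalidParameterError("PETH and ResponseCall unit sets differ")
    if len(peths) == 0:
        raise InvalidParameterError("no units")
    edges = peths[0].bin_edges_ms
    for p in peths:
        if p.z is None:
            raise InvalidParameterError(f"unit {p.unit_id}: z-score the PETH first")
        if not np.array_equal(p.bin_edges_ms, edges):
            raise InvalidParameterError("all PETHs must share bin edges")

    responders = [p for p in peths if calls[p.unit_id].responsive]
    responders.sort(key=lambda p: (calls[p.unit_id].first_significant_bin_ms, p.unit_id))
    others = sorted(
        (p for p in peths if not calls[p.unit_id].responsive), key=lambda p: p.unit_id
    )
    ordered = responders + others
    return PopulationMatrix(
        unit_order=tuple(p.unit_id for p in ordered),
        z=np.vstack([p.z for p in ordered]),
        partition_index=len(responders),
        bin_edges_ms=edges,
    )
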