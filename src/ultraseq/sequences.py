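"""Identification of individual sequences from the phase trace.

One sequence is one full turn of the population state around the ring:
the phase of the oscillation traverses 2 pi in an ascending manner. The
phase (computed from activity smoothed at the oscillation bin size T_osc)
is discretized into 10 bins. Because the PCA plane fixes the phase only
up to an arbitrary rotation, the absolute phase at which a sequence
begins carries no meaning; boundaries are therefore anchored in the data:
circular jumps of 3 or more phase bins between consecutive time points
(and over-long constant-phase dwells) cut the session into continuous
segments, and within each segment consecutive full turns are carved from
the cumulative phase advance measured from the segment's onset.
Fluctuations of up to 1 bin against the direction of ascent are allowed;
a larger decrement ends the segment. Trailing stretches advancing through
at least 5 of the 10 bins are kept separately as partial segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .session import EventMatrix
from .sorting import oscillation_phase


@dataclass
class SequenceSet:
    intervals: List[Tuple[int, int]]           # half-open [start, end) bins
    partial_segments: List[Tuple[int, int]]
    bin_size: float
    n_bins: int

    @property
    def durations(self) -> np.ndarray:
        return np.array([(e - s) * self.bin_size for s, e in self.intervals])

    @property
    def isis(self) -> np.ndarray:
        """Inter-sequence intervals in seconds (0 for back-to-back)."""
        if len(self.intervals) < 2:
            return np.array([])
        starts = np.array([s for s, _ in self.intervals[1:]])
        ends = np.array([e for _, e in self.intervals[:-1]])
        return (starts - ends) * self.bin_size

    @property
    def concat_index(self) -> np.ndarray:
        """Indices of all bins inside sequences, in temporal order."""
        if not self.intervals:
            return np.array([], dtype=int)
        return np.concatenate([np.arange(s, e) for s, e in self.intervals])

    @property
    def in_sequence(self) -> np.ndarray:
        mask = np.zeros(self.n_bins, dtype=bool)
        for s, e in self.intervals:
            mask[s:e] = True
        return mask


def _segment_cuts(bins: np.ndarray, valid: np.ndarray, n_phase_bins: int,
                  discontinuity_bins: int, limit_bins: int) -> np.ndarray:
    """Time points that terminate continuous segments.

    A cut happens at a circular phase-bin jump of ``discontinuity_bins``
    or more, around a constant-phase dwell longer than ``limit_bins``
    (sustained activity), and at every transition into or out of bins
    where the phase is undefined (projection too close to the origin).
    """
    half = n_phase_bins // 2
    diff = np.diff(bins.astype(int))
    cdiff = (diff + half) % n_phase_bins - half   # signed circular step
    cut_at = set((np.flatnonzero(np.abs(cdiff) >= discontinuity_bins) + 1).tolist())
    cut_at |= set((np.flatnonzero(np.diff(valid)) + 1).tolist())
    start = 0
    for i in range(1, bins.size + 1):
        if i == bins.size or bins[i] != bins[start]:
            if i - start > limit_bins:
                cut_at.add(start)
                cut_at.add(i)
            start = i
    return np.array(sorted(cut_at | {0, bins.size}), dtype=int)


def identify_sequences(events: EventMatrix, t_osc: float, *,
                       n_phase_bins: int = 10, discontinuity_bins: int = 3,
                       max_decrement: int = 1, partial_min_bins: int = 5,
                       sustained_factor: float = 2.0, edge_tolerance: int = 1,
                       radius_floor: float = 0.25,
                       min_duration_factor: float = 0.5,
                       phase_trace=None) -> SequenceSet:
    """Identify individual sequences (and partial segments) in a session.

    ``phase_trace`` may be supplied to skip the internal phase computation
    (it must then come from activity smoothed at T_osc). Bins whose
    projection radius falls below ``radius_floor`` times the session's
    95th-percentile radius have no meaningful phase (the population state
    is near the manifold centre) and act as segment breaks. A full turn
    must additionally last at least ``min_duration_factor`` times the
    period implied by T_osc (10 T_osc); faster windings are inconsistent
    with the session's oscillation and are discarded as chance excursions.
    """
    if phase_trace is None:
        phase_trace = oscillation_phase(events, smoothing_width=t_osc)
    phi = np.asarray(phase_trace.phi, dtype=float)
    if phase_trace.radius is not None and radius_floor > 0:
        floor = radius_floor * np.percentile(phase_trace.radius, 95)
        valid = phase_trace.radius >= floor
    else:
        valid = np.ones(phi.size, dtype=bool)
    width = 2 * np.pi / n_phase_bins
    bins = np.clip(((phi + np.pi) // width).astype(int), 0, n_phase_bins - 1)
    limit_bins = max(1, int(round(sustained_factor * t_osc / events.bin_size)))
    cuts = _segment_cuts(bins, valid, n_phase_bins, discontinuity_bins,
                         limit_bins)

    half = n_phase_bins // 2
    min_turn_bins = int(round(min_duration_factor * n_phase_bins * t_osc
                              / events.bin_size))
    intervals: List[Tuple[int, int]] = []
    partials: List[Tuple[int, int]] = []

    def close(turn_start: int, end: int, tail: float) -> None:
        # a closing turn is truncated by the segment edge; grant it the
        # same 1-bin tolerance as in-sequence fluctuations
        if (tail >= n_phase_bins - edge_tolerance
                and end - turn_start >= min_turn_bins):
            intervals.append((turn_start, end))
        elif tail >= partial_min_bins:
            partials.append((turn_start, end))

    for a, b in zip(cuts[:-1], cuts[1:]):
        if b - a < 2 or not valid[a]:
            continue
        seg = bins[a:b].astype(int)
        cdiff = (np.diff(seg) + half) % n_phase_bins - half
        advance = np.concatenate([[0.0], np.cumsum(cdiff)])
        turn_start, peak, peak_idx = 0, 0.0, 0
        for t in range(1, advance.size):
            if advance[t] > peak:
                peak, peak_idx = advance[t], t
            if advance[t] - advance[turn_start] >= n_phase_bins:
                if t - turn_start >= min_turn_bins:
                    intervals.append((int(a + turn_start), int(a + t)))
                turn_start, peak, peak_idx = t, advance[t], t
            elif advance[t] < peak - max_decrement:
                # cumulative drawdown beyond the allowed fluctuation:
                # the ascent is broken; close out at the last peak
                close(int(a + turn_start), int(a + peak_idx),
                      peak - advance[turn_start])
                turn_start, peak, peak_idx = t, advance[t], t
        close(int(a + turn_start), int(b), peak - advance[turn_start])
    return SequenceSet(intervals=intervals, partial_segments=partials,
                       bin_size=events.bin_size, n_bins=bins.size)


def sequence_stats(seqs: SequenceSet) -> dict:
    """Durations, inter-sequence intervals and sequence frequency.

    The frequency is the number of sequences divided by the total time the
    network spent inside sequences (the concatenated-sequence window).
    """
    durations = seqs.durations
    total_time = float(durations.sum())
    freq = len(seqs.intervals) / total_time if total_time > 0 else float("nan")
    return {
        "durations_s": durations,
        "isis_s": seqs.isis,
        "n_sequences": len(seqs.intervals),
        "sequence_frequency_hz": freq,
        "median_duration_s": float(np.median(durations)) if durations.size else float("nan"),
    }


def duration_variability(durations_per_session: List[np.ndarray],
                         n_shuffles: int = 500,
                         rng: np.random.Generator | None = None) -> dict:
    """Within- vs between-session variability of sequence durations.

    Approach 1: observed per-session SD against a null where all durations
    are pooled and randomly reassigned to sessions (counts preserved).
    Approach 2: mean shortest/longest duration ratio for within-session
    pairs vs pairs spanning different sessions, per session.
    """
    if len(durations_per_session) < 2:
        raise ValueError("need at least 2 sessions")
    if rng is None:
        rng = np.random.default_rng()
    durations_per_session = [np.asarray(d, dtype=float)
                             for d in durations_per_session]
    counts = [d.size for d in durations_per_session]
    pooled = np.concatenate(durations_per_session)

    observed_sd = np.array([d.std() for d in durations_per_session])
    null_sd = np.empty((n_shuffles, len(counts)))
    for it in range(n_shuffles):
        perm = rng.permutation(pooled)
        off = 0
        for k, c in enumerate(counts):
            null_sd[it, k] = perm[off:off + c].std()
            off += c

    def pair_ratio_mean(a: np.ndarray, b: np.ndarray | None = None) -> float:
        if b is None:  # within-group pairs
            if a.size < 2:
                return float("nan")
            iu = np.triu_indices(a.size, k=1)
            x, y = a[iu[0]], a[iu[1]]
        else:
            x = np.repeat(a, b.size)
            y = np.tile(b, a.size)
            if x.size == 0:
                return float("nan")
        return float(np.mean(np.minimum(x, y) / np.maximum(x, y)))

    within = np.array([pair_ratio_mean(d) for d in durations_per_session])
    between = np.empty(len(counts))
    for i, d in enumerate(durations_per_session):
        others = np.concatenate([durations_per_session[j]
                                 for j in range(len(counts)) if j != i])
        between[i] = pair_ratio_mean(d, others)
    return {
        "observed_sd": observed_sd,
        "null_sd": null_sd,
        "within_ratio": within,
        "between_ratio": between,
    }


def segment_event_rate(events: EventMatrix, seqs: SequenceSet,
                       n_segments: int = 10) -> dict:
    """Mean event rate across ten equal segments of each sequence.

    The rate in one segment is the total number of events across cells
    divided by the segment duration and the number of cells; rates are
    averaged over sequences. Also reports the percent change from the
    minimum-rate segment to the maximum-rate segment.
    """
    if not seqs.intervals:
        raise ValueError("no sequences")
    n_cells = events.n_cells
    rates = np.zeros((len(seqs.intervals), n_segments))
    for si, (a, b) in enumerate(seqs.intervals):
        edges = np.linspace(a, b, n_segments + 1)
        for k in range(n_segments):
            lo, hi = int(round(edges[k])), int(round(edges[k + 1]))
            dur = (hi - lo) * events.bin_size
            if dur <= 0:
                rates[si, k] = np.nan
                continue
            rates[si, k] = events.values[:, lo:hi].sum() / (dur * n_cells)
    mean_rates = np.nanmean(rates, axis=0)
    lo, hi = mean_rates.min(), mean_rates.max()
    pct_change = float((hi - lo) / lo * 100.0) if lo > 0 else float("inf")
    return {"segment_rates": mean_rates, "percent_change": pct_change}
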