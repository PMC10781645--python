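"""Single-cell tuning to the phase of the oscillation.

All operations here work on the concatenated-sequence window: the bins of
all identified sequences joined end to end, with the phase trace restricted
accordingly. The locking degree is the mean resultant vector length of the
phases at which a cell's events occur; its null resamples event bins from
the concatenated window. Mutual information between event counts (0.52-s
bins) and the 10-bin phase uses the plug-in estimator with a shuffle
estimate of the limited-sampling bias.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np


from .sequences import SequenceSet
from .sorting import _wrap


def resultant_length(phases: np.ndarray) -> float:
    """Mean resultant vector length of a sample of angles."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("no phases")
    return float(np.hypot(np.cos(phases).mean(), np.sin(phases).mean()))


def circular_mean(phases: np.ndarray) -> float:
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("no phases")
    return float(np.arctan2(np.sin(phases).mean(), np.cos(phases).mean()))


def locking_degree(event_trace: np.ndarray, phi_concat: np.ndarray,
                   n_shuffles: int = 1000, pct: float = 99.0,
                   rng: np.random.Generator | None = None) -> dict:
    """Locking of one cell to the oscillation phase.

    ``event_trace`` and ``phi_concat`` are restricted to the concatenated
    sequences. The null redraws the cell's event bins at random from the
    concatenated window, keeping the event count.
    """
    event_trace = np.asarray(event_trace)
    phi_concat = np.asarray(phi_concat, dtype=float)
    if event_trace.shape != phi_concat.shape:
        raise ValueError("trace and phase must have the same length")
    idx = np.flatnonzero(event_trace)
    if idx.size == 0:
        return {"r": float("nan"), "locked": False, "null_cutoff": float("nan"),
                "n_events": 0}
    r = resultant_length(phi_concat[idx])
    if rng is None:
        rng = np.random.default_rng()
    k, T = idx.size, phi_concat.size
    draws = rng.integers(0, T, size=(n_shuffles, k))
    ph = phi_concat[draws]
    null = np.hypot(np.cos(ph).mean(axis=1), np.sin(ph).mean(axis=1))
    cutoff = float(np.percentile(null, pct))
    return {"r": r, "locked": bool(r > cutoff), "null_cutoff": cutoff,
            "n_events": int(k)}


def _downsample_counts(trace: np.ndarray, factor: int) -> np.ndarray:
    n = (trace.size // factor) * factor
    return trace[:n].reshape(-1, factor).sum(axis=1)


def _downsample_phase(phi: np.ndarray, factor: int) -> np.ndarray:
    n = (phi.size // factor) * factor
    ph = phi[:n].reshape(-1, factor)
    return np.arctan2(np.sin(ph).mean(axis=1), np.cos(ph).mean(axis=1))


def _plugin_mi(joint: np.ndarray) -> float:
    """Plug-in Shannon mutual information (bits) from a joint count table."""
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / (px @ py)[mask])))


def phase_mutual_information(event_trace: np.ndarray, phi_concat: np.ndarray,
                             coarse_factor: int = 4, n_phase_bins: int = 10,
                             n_shuffles: int = 1000,
                             rng: np.random.Generator | None = None) -> dict:
    """Bias-corrected mutual information between event counts and phase.

    Counts and phase are re-binned to 0.52-s resolution; counts are
    discretized into s_max + 1 bins and the phase into 10 bins. The bias is
    the mean MI over temporal shuffles of the count trace; MI_c = MI - bias.
    """
    counts = _downsample_counts(np.asarray(event_trace), coarse_factor)
    phase = _downsample_phase(np.asarray(phi_concat, dtype=float), coarse_factor)
    if counts.size != phase.size:
        n = min(counts.size, phase.size)
        counts, phase = counts[:n], phase[:n]
    s_max = int(counts.max())
    width = 2 * np.pi / n_phase_bins
    pbins = np.clip(((phase + np.pi) // width).astype(int), 0, n_phase_bins - 1)
    n_s = s_max + 1

    def joint_from(c):
        flat = pbins * n_s + c
        return np.bincount(flat, minlength=n_phase_bins * n_s).reshape(
            n_phase_bins, n_s).astype(float)

    mi = _plugin_mi(joint_from(counts))
    if rng is None:
        rng = np.random.default_rng()
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        null[i] = _plugin_mi(joint_from(counts[rng.permutation(counts.size)]))
    bias = float(null.mean())
    return {"mi": mi, "bias": bias, "mi_c": mi - bias, "null_sd": float(null.std())}


def tuning_curve(event_trace: np.ndarray, phi_concat: np.ndarray,
                 n_bins: int = 40) -> np.ndarray:
    """Fraction of a cell's events per phase bin (sums to 1)."""
    idx = np.flatnonzero(np.asarray(event_trace))
    if idx.size == 0:
        raise ValueError("cell has no events")
    phases = np.asarray(phi_concat, dtype=float)[idx]
    width = 2 * np.pi / n_bins
    bins = np.clip(((phases + np.pi) // width).astype(int), 0, n_bins - 1)
    curve = np.bincount(bins, minlength=n_bins).astype(float)
    return curve / curve.sum()


def preferred_phase(event_trace: np.ndarray, phi: np.ndarray,
                    scope: str = "concatenated",
                    seqs: SequenceSet | None = None,
                    min_events: int = 5):
    """Circular mean of the phases at which a cell's events occur.

    ``concatenated`` scope expects ``event_trace``/``phi`` already
    restricted to the concatenated sequences and returns one angle.
    ``per_sequence`` scope expects full-session traces plus the sequence
    set, and returns one angle per sequence with at least ``min_events``
    events (NaN otherwise).
    """
    event_trace = np.asarray(event_trace)
    phi = np.asarray(phi, dtype=float)
    if scope == "concatenated":
        idx = np.flatnonzero(event_trace)
        if idx.size == 0:
            raise ValueError("cell has no events")
        return circular_mean(phi[idx])
    if scope != "per_sequence":
        raise ValueError(f"unknown scope {scope!r}")
    if seqs is None:
        raise ValueError("per_sequence scope requires the SequenceSet")
    out = np.full(len(seqs.intervals), np.nan)
    for k, (a, b) in enumerate(seqs.intervals):
        idx = np.flatnonzero(event_trace[a:b]) + a
        if idx.size >= min_events:
            out[k] = circular_mean(phi[idx])
    return out


def phase_entropy_ratio(preferred_phases: np.ndarray, n_bins: int = 10,
                        n_shuffles: int = 1000,
                        phi_concat: np.ndarray | None = None,
                        events_concat: np.ndarray | None = None,
                        rng: np.random.Generator | None = None) -> dict:
    """Uniformity of the preferred-phase distribution.

    H_ratio = H(Q) / H_flat where Q is the 10-bin histogram of preferred
    phases and H_flat = log2(10) ~ 3.32 bits. If the concatenated phase and
    event matrix are supplied, a shuffle mean is computed by recomputing
    the preferred phases after temporally shuffling the phase trace.
    """
    preferred_phases = np.asarray(preferred_phases, dtype=float)
    if preferred_phases.size < 10:
        raise ValueError("need at least 10 cells")

    def h_ratio(phases):
        width = 2 * np.pi / n_bins
        b = np.clip(((_wrap(phases) + np.pi) // width).astype(int), 0, n_bins - 1)
        q = np.bincount(b, minlength=n_bins).astype(float)
        q = q / q.sum()
        nz = q > 0
        h = -np.sum(q[nz] * np.log2(q[nz]))
        return h / np.log2(n_bins)

    out = {"h_ratio": float(h_ratio(preferred_phases)),
           "h_flat_bits": float(np.log2(n_bins))}
    if phi_concat is not None and events_concat is not None:
        if rng is None:
            rng = np.random.default_rng()
        phi_concat = np.asarray(phi_concat, dtype=float)
        events_concat = np.asarray(events_concat)
        vals = np.empty(n_shuffles)
        for i in range(n_shuffles):
            phi_sh = phi_concat[rng.permutation(phi_concat.size)]
            prefs = np.array([
                circular_mean(phi_sh[np.flatnonzero(row)])
                for row in events_concat if row.any()])
            vals[i] = h_ratio(prefs)
        out["shuffle_mean"] = float(vals.mean())
    return out


def participation_index(event_trace: np.ndarray, seqs: SequenceSet,
                        threshold: float = 0.9) -> float:
    """Fraction of sequences needed to account for 90% of a cell's events.

    Per-sequence event fractions are accumulated from the largest down;
    the index is the size of the smallest subset reaching the threshold,
    divided by the total number of sequences. Low values mean activity
    concentrated in few sequences; values near 1 mean reliable
    participation in most sequences.
    """
    event_trace = np.asarray(event_trace)
    if not seqs.intervals:
        raise ValueError("no sequences")
    per_seq = np.array([event_trace[a:b].sum() for a, b in seqs.intervals],
                       dtype=float)
    total = per_seq.sum()
    if total == 0:
        return float("nan")
    fractions = np.sort(per_seq / total)[::-1]
    csum = np.cumsum(fractions)
    k = int(np.searchsorted(csum, threshold)) + 1
    return k / len(seqs.intervals)


def relative_frequency_groups(primary_freqs: np.ndarray,
                              seq_frequency: float,
                              locking: np.ndarray,
                              participation: np.ndarray,
                              alpha: float = 0.25) -> dict:
    """Compare tuning between cells oscillating at vs away from the
    sequence frequency.

    Each cell's relative frequency is its primary frequency divided by the
    session's sequence frequency. The ``alpha`` fraction of cells with
    relative frequency closest to 1 forms the "near" group, the ``alpha``
    fraction farthest from 1 the "far" group; mean locking degree and
    participation index are reported per group.
    """
    if not 0.0 < alpha <= 0.5:
        raise ValueError("alpha must be in (0, 0.5]")
    primary_freqs = np.asarray(primary_freqs, dtype=float)
    n = primary_freqs.size
    size = int(np.floor(alpha * n))
    if size < 1:
        raise ValueError("alpha too small for the number of cells")
    dist = np.abs(primary_freqs / seq_frequency - 1.0)
    order = np.argsort(dist, kind="stable")
    near, far = order[:size], order[n - size:]
    locking = np.asarray(locking, dtype=float)
    participation = np.asarray(participation, dtype=float)
    return {
        "near_idx": near, "far_idx": far,
        "near_locking": float(np.nanmean(locking[near])),
        "far_locking": float(np.nanmean(locking[far])),
        "near_participation": float(np.nanmean(participation[near])),
        "far_participation": float(np.nanmean(participation[far])),
    }
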