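"""Wheel-running behavior and its relation to sequence occurrence.

The wheel position (cm, 40-50 Hz) is differentiated to speed, interpolated
to the imaging time base, smoothed with a 2-s boxcar and thresholded at
2 cm/s (sub-threshold values are set to zero, so immobility includes wheel
twitches). Running/immobility bouts are maximal constant-state runs, and
sequence occurrence is conditioned on the state labels.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .session import BehaviorTrace, EventMatrix
from .sequences import SequenceSet

LAP_LENGTH_CM = 2 * np.pi * 8.54   # wheel perimeter, ~53.66 cm


def derive_speed(behavior: BehaviorTrace, bin_size: float, n_bins: int,
                 speed_threshold: float = 2.0, kernel_s: float = 2.0) -> BehaviorTrace:
    """Speed, acceleration and running state on the event-bin time base.

    Speed is the position derivative, interpolated to the event bins,
    boxcar-smoothed over ``kernel_s`` and thresholded: values below
    ``speed_threshold`` cm/s are set to zero. State is running where the
    thresholded speed is nonzero. Acceleration is the derivative of the
    thresholded speed (no re-interpolation).
    """
    pos = behavior.position
    rate = behavior.native_rate
    t_native = np.arange(pos.size) / rate
    speed_native = np.gradient(pos, t_native) if pos.size > 1 else np.zeros(1)
    t_bins = (np.arange(n_bins) + 0.5) * bin_size
    speed = np.interp(t_bins, t_native, speed_native)
    k = max(1, int(round(kernel_s / bin_size)))
    kernel = np.ones(k) / k
    speed = np.convolve(speed, kernel, mode="same")
    speed = np.where(speed < speed_threshold, 0.0, speed)
    accel = np.gradient(speed, bin_size) if speed.size > 1 else np.zeros_like(speed)
    state = speed > 0
    return BehaviorTrace(position=pos, native_rate=rate, speed=speed,
                         acceleration=accel, state=state)


def bouts_from_state(state: np.ndarray) -> List[Tuple[int, int, bool]]:
    """Maximal constant-state runs as (start, end, running) half-open bins."""
    state = np.asarray(state, dtype=bool)
    if state.size == 0:
        return []
    edges = np.flatnonzero(np.diff(state)) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [state.size]])
    return [(int(a), int(b), bool(state[a])) for a, b in zip(starts, ends)]


def count_laps(behavior: BehaviorTrace, interval_s: Tuple[float, float],
               lap_length_cm: float = LAP_LENGTH_CM) -> float:
    """Completed laps in a time interval: distance run / wheel perimeter."""
    t0, t1 = interval_s
    if t1 < t0:
        raise ValueError("interval end before start")
    i0 = int(round(t0 * behavior.native_rate))
    i1 = min(int(round(t1 * behavior.native_rate)), behavior.position.size - 1)
    distance = float(behavior.position[i1] - behavior.position[i0])
    return distance / lap_length_cm


def sequence_probability_by_state(seqs: SequenceSet, state: np.ndarray) -> dict:
    """P(in-sequence | running) and P(in-sequence | immobile)."""
    state = np.asarray(state, dtype=bool)
    osc = seqs.in_sequence
    n = min(osc.size, state.size)
    osc, state = osc[:n], state[:n]
    p_run = float(osc[state].mean()) if state.any() else float("nan")
    p_imm = float(osc[~state].mean()) if (~state).any() else float("nan")
    return {"p_osc_given_running": p_run, "p_osc_given_immobile": p_imm}


def immobility_sequence_fraction(state: np.ndarray, seqs: SequenceSet,
                                 bin_size: float,
                                 length_bins=((0, 3), (3, 5), (5, 10),
                                              (10, 15), (15, 20), (25, float("inf"))),
                                 n_shuffles: int = 500,
                                 rng: np.random.Generator | None = None) -> dict:
    """Fraction of immobility bouts fully covered by sequences, per length.

    A bout counts as covered when every one of its bins lies inside an
    identified sequence (back-to-back sequences count as uninterrupted
    coverage). The null temporally shuffles the sequence-label bins.
    """
    if rng is None:
        rng = np.random.default_rng()
    state = np.asarray(state, dtype=bool)
    osc = seqs.in_sequence
    n = min(osc.size, state.size)
    osc, state = osc[:n], state[:n]
    bouts = [(a, b) for a, b, running in bouts_from_state(state) if not running]

    def fractions(mask):
        out = []
        for lo, hi in length_bins:
            members = [(a, b) for a, b in bouts
                       if lo <= (b - a) * bin_size < hi]
            if not members:
                out.append(float("nan"))
                continue
            covered = [mask[a:b].all() for a, b in members]
            out.append(float(np.mean(covered)))
        return np.array(out)

    observed = fractions(osc)
    null = np.empty((n_shuffles, len(length_bins)))
    for s in range(n_shuffles):
        null[s] = fractions(osc[rng.permutation(n)])
    return {"observed": observed,
            "null_mean": np.nanmean(null, axis=0),
            "null_p95": np.nanpercentile(null, 95, axis=0),
            "length_bins": list(length_bins),
            "n_bouts": len(bouts)}


def onset_speed_analysis(seqs: SequenceSet, speed: np.ndarray,
                         state: np.ndarray, bin_size: float,
                         window_s: float = 10.0, epoch_gap_s: float = 10.0,
                         bout_min_s: float = 20.0) -> dict:
    """Speed around sequence onsets and onset counts by behavioral state.

    Pre/post mean speeds are taken over ``window_s`` around every onset.
    Epoch onsets are sequences at least ``epoch_gap_s`` after the previous
    one (or the first); their counts inside long (>= ``bout_min_s``)
    running vs immobility bouts give the onset-rate ratio.
    """
    speed = np.asarray(speed, dtype=float)
    state = np.asarray(state, dtype=bool)
    w = max(1, int(round(window_s / bin_size)))
    pre, post = [], []
    onsets = [a for a, _ in seqs.intervals]
    for a in onsets:
        if a - w >= 0 and a + w <= speed.size:
            pre.append(speed[a - w:a].mean())
            post.append(speed[a:a + w].mean())
    # epoch onsets: first sequence, or gap from previous sequence end
    epoch_onsets = []
    prev_end = None
    for a, b in seqs.intervals:
        if prev_end is None or (a - prev_end) * bin_size >= epoch_gap_s:
            epoch_onsets.append(a)
        prev_end = b
    min_bins = int(round(bout_min_s / bin_size))
    long_bouts = [(a, b, run) for a, b, run in bouts_from_state(state)
                  if b - a >= min_bins]
    n_run = sum(1 for o in epoch_onsets
                for a, b, run in long_bouts if run and a <= o < b)
    n_imm = sum(1 for o in epoch_onsets
                for a, b, run in long_bouts if not run and a <= o < b)
    ratio = n_run / n_imm if n_imm > 0 else float("inf") if n_run > 0 else float("nan")
    return {
        "pre_speeds": np.array(pre), "post_speeds": np.array(post),
        "n_epoch_onsets": len(epoch_onsets),
        "onsets_in_running_bouts": int(n_run),
        "onsets_in_immobility_bouts": int(n_imm),
        "onset_ratio_running_vs_immobile": float(ratio),
    }


def coactivity_and_synchrony(events: EventMatrix) -> dict:
    """Pairwise |Pearson r| and per-bin active-cell fraction distributions."""
    values = events.values.astype(float)
    if events.n_cells < 2:
        raise ValueError("need at least 2 cells")
    sd = values.std(axis=1)
    keep = sd > 0
    C = np.corrcoef(values[keep])
    iu = np.triu_indices(C.shape[0], k=1)
    synchrony = np.abs(C[iu])
    coactivity = values.mean(axis=0)
    return {"synchrony": synchrony, "coactivity": coactivity}
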