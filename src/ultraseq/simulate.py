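"""Synthetic session generator with matched ground truth.

The generator emulates the statistical structure the analysis assumes: a
latent ring phase advancing 2 pi per period during sequence epochs
(undefined during gaps), per-cell preferred phases with von Mises tuning,
per-sequence Bernoulli participation, uniform background noise events,
gaps inserted at sequence boundaries (so zero inter-sequence intervals
predominate), cells placed uniformly in the field of view (optionally with
a planted phase-position gradient to simulate a travelling wave), and
running/immobility bouts optionally coupled to sequence epochs.

Defaults describe a realistic oscillatory recording: 400 cells over 30
minutes at 129-ms bins, a 150-s sequence period, and roughly three
quarters of the session spent inside sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import i0

from .session import BehaviorTrace, CellPositions, EventMatrix, Session
from .sorting import _wrap


@dataclass
class SimConfig:
    n_cells: int = 400
    duration: float = 1800.0          # s
    bin_size: float = 0.129           # s
    period: float = 150.0             # s per sequence
    tuning_concentration: float = 4.0  # von Mises kappa
    peak_event_prob: float = 0.2      # event probability at the preferred phase
    participation_prob: float = 0.9   # per-sequence Bernoulli participation
    noise_rate: float = 0.002         # background event probability per bin
    gap_rate_factor: float = 1.0      # gap firing rate relative to the
                                      # in-sequence mean (cells keep firing,
                                      # unorganized, outside sequences)
    gap_prob: float = 0.25            # probability of a gap after a sequence
    gap_mean: float = 220.0           # s, exponential mean gap length
    behavior_coupling: float = 0.8    # P(running) for bouts inside sequences
    bout_mean_running: float = 30.0   # s
    bout_mean_immobile: float = 20.0  # s
    run_speed_mean: float = 8.0       # cm/s
    run_speed_sd: float = 2.0
    native_rate: float = 40.0         # Hz, wheel tracking
    fov_size: float = 600.0           # um
    phase_position_gradient: float = 0.0  # rad/um
    pref_phase_jitter: float = 0.3    # rad, jitter around the planted gradient
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_cells <= 0 or self.duration <= 0:
            raise ValueError("need a positive number of cells and duration")
        if self.period <= 10 * self.bin_size:
            raise ValueError("period must exceed 10 bins")
        for name in ("peak_event_prob", "participation_prob", "noise_rate",
                     "gap_prob", "behavior_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_size))

    @property
    def period_bins(self) -> int:
        return int(round(self.period / self.bin_size))


@dataclass
class GroundTruth:
    true_phase: np.ndarray                    # per-bin rad, NaN in gaps
    true_preferred_phase: np.ndarray          # per-cell rad
    sequence_intervals: List[Tuple[int, int]]  # half-open bins
    participation: np.ndarray                 # (n_sequences, n_cells) bool
    positions: np.ndarray                     # (n_cells, 2) um


def tuning_gain_mean(kappa: float) -> float:
    """Mean of exp(kappa (cos d - 1)) over a uniform phase sweep.

    This is the average thinning factor a cell sees across one full
    sequence, used for closed-form event-rate expectations.
    """
    return float(np.exp(-kappa) * i0(kappa))


def expected_events_per_cell(cfg: SimConfig, n_sequences: int,
                             n_sequence_bins: int) -> float:
    """Closed-form expectation of a cell's event count.

    Tuned in-sequence events, matched-rate gap events and uniform
    background noise combine per bin by inclusion-exclusion (independent
    sources may coincide in a bin, which yields a single event).
    """
    rate_seq = (cfg.participation_prob * cfg.peak_event_prob
                * tuning_gain_mean(cfg.tuning_concentration))
    gap_rate = cfg.gap_rate_factor * rate_seq
    n_gap_bins = cfg.n_bins - n_sequence_bins
    p_seq = 1.0 - (1.0 - rate_seq) * (1.0 - cfg.noise_rate)
    p_gap = 1.0 - (1.0 - gap_rate) * (1.0 - cfg.noise_rate)
    return n_sequence_bins * p_seq + n_gap_bins * p_gap


def _build_timeline(cfg: SimConfig, rng: np.random.Generator):
    """Alternating sequence epochs and gaps; only full sequences placed."""
    intervals: List[Tuple[int, int]] = []
    pb, n = cfg.period_bins, cfg.n_bins
    t = 0
    while t + pb <= n:
        intervals.append((t, t + pb))
        t += pb
        if rng.random() < cfg.gap_prob:
            gap = int(round(rng.exponential(cfg.gap_mean) / cfg.bin_size))
            t += max(1, gap)
    return intervals


def generate_behavior(cfg: SimConfig, rng: np.random.Generator,
                      in_sequence: Optional[np.ndarray] = None) -> BehaviorTrace:
    """Alternating running/immobility bouts and the wheel position trace.

    Without ``in_sequence``, bout states are chosen uniformly at random.
    With it, a bout whose bins mostly fall inside sequences is running
    with probability ``behavior_coupling`` (and with probability
    1 - coupling otherwise), which couples locomotion to the sequences.
    """
    n = cfg.n_bins
    state = np.zeros(n, dtype=bool)
    t = 0
    while t < n:
        run_len = rng.exponential(cfg.bout_mean_running)
        imm_len = rng.exponential(cfg.bout_mean_immobile)
        for length, candidate in ((run_len, True), (imm_len, False)):
            nb = max(1, int(round(length / cfg.bin_size)))
            hi = min(t + nb, n)
            if in_sequence is None:
                running = candidate
            else:
                frac = in_sequence[t:hi].mean() if hi > t else 0.0
                p_run = (cfg.behavior_coupling * frac
                         + (1 - cfg.behavior_coupling) * (1 - frac))
                running = rng.random() < p_run
            state[t:hi] = running
            t = hi
            if t >= n:
                break
    # per-bout constant speed, then integrate to position at the native rate
    speed_bins = np.zeros(n)
    for a, b in _runs(state):
        if state[a]:
            v = max(3.0, rng.normal(cfg.run_speed_mean, cfg.run_speed_sd))
            speed_bins[a:b] = v
    n_native = int(round(cfg.duration * cfg.native_rate))
    t_native = np.arange(n_native) / cfg.native_rate
    t_bins = (np.arange(n) + 0.5) * cfg.bin_size
    speed_native = np.interp(t_native, t_bins, speed_bins)
    position = np.cumsum(speed_native) / cfg.native_rate
    return BehaviorTrace(position=position, native_rate=cfg.native_rate,
                         speed=speed_bins, state=state)


def _runs(mask: np.ndarray):
    edges = np.flatnonzero(np.diff(mask)) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [mask.size]])
    return zip(starts, ends)


def generate_session(cfg: SimConfig,
                     rng: Optional[np.random.Generator] = None,
                     with_behavior: bool = True) -> Tuple[Session, GroundTruth]:
    """Generate one synthetic session and its ground truth."""
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    n_bins, n_cells = cfg.n_bins, cfg.n_cells
    intervals = _build_timeline(cfg, rng)
    n_seq = len(intervals)

    phase = np.full(n_bins, np.nan)
    ramp = np.linspace(-np.pi, np.pi, cfg.period_bins, endpoint=False)
    for a, b in intervals:
        phase[a:b] = ramp[:b - a]

    positions = rng.uniform(0, cfg.fov_size, size=(n_cells, 2))
    if cfg.phase_position_gradient != 0.0:
        prefs = _wrap(cfg.phase_position_gradient * positions[:, 0]
                      + rng.normal(0, cfg.pref_phase_jitter, n_cells))
    else:
        prefs = rng.uniform(-np.pi, np.pi, n_cells)

    participation = rng.random((n_seq, n_cells)) < cfg.participation_prob
    events = rng.random((n_cells, n_bins)) < cfg.noise_rate

    # unorganized activity during gaps at the in-sequence mean rate: the
    # network disengages from the sequence, the cells do not fall silent
    gap_rate = (cfg.gap_rate_factor * cfg.participation_prob
                * cfg.peak_event_prob * tuning_gain_mean(cfg.tuning_concentration))
    gap_mask = np.isnan(phase)
    if gap_mask.any() and gap_rate > 0:
        events[:, gap_mask] |= (rng.random((n_cells, int(gap_mask.sum())))
                                < gap_rate)

    kappa = cfg.tuning_concentration
    for s, (a, b) in enumerate(intervals):
        delta = phase[a:b][None, :] - prefs[:, None]
        if np.isinf(kappa):
            # limit case: one event per sequence, at the closest-phase bin
            closest = np.argmin(np.abs(_wrap(delta)), axis=1)
            hit = rng.random(n_cells) < cfg.peak_event_prob
            active = participation[s] & hit
            events[np.flatnonzero(active), a + closest[active]] = True
        else:
            p = cfg.peak_event_prob * np.exp(kappa * (np.cos(delta) - 1.0))
            p = p * participation[s][:, None]
            events[:, a:b] |= rng.random((n_cells, b - a)) < p

    event_matrix = EventMatrix(events.astype(np.uint8), cfg.bin_size)
    in_sequence = np.zeros(n_bins, dtype=bool)
    for a, b in intervals:
        in_sequence[a:b] = True
    behavior = (generate_behavior(cfg, rng, in_sequence)
                if with_behavior else None)
    session = Session(
        events=event_matrix,
        positions=CellPositions(positions, cfg.fov_size),
        behavior=behavior,
        meta={"modality": "imaging", "synthetic": True,
              "period_s": cfg.period, "rng_seed": cfg.rng_seed},
    )
    truth = GroundTruth(true_phase=phase, true_preferred_phase=prefs,
                        sequence_intervals=intervals,
                        participation=participation, positions=positions)
    return session, truth


def generate_fluorescence(events: EventMatrix, decay_tau: float = 1.0,
                          noise_sd: float = 0.0,
                          rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Causal exponential-kernel trace from events plus white noise.

    The inverse of event deconvolution: each event contributes a kernel
    exp(-t / tau) from its bin onward. Used to exercise SNR estimation and
    binarization, not as a biophysical indicator model.
    """
    if decay_tau <= 0:
        raise ValueError("decay_tau must be positive")
    if rng is None:
        rng = np.random.default_rng()
    values = events.values.astype(float)
    n_k = max(1, int(np.ceil(5 * decay_tau / events.bin_size)))
    kernel = np.exp(-np.arange(n_k) * events.bin_size / decay_tau)
    out = np.empty_like(values)
    for i, row in enumerate(values):
        out[i] = np.convolve(row, kernel)[:row.size]
    if noise_sd > 0:
        out = out + rng.normal(0, noise_sd, out.shape)
    return out
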