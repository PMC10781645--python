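"""Stage orchestration: run the full analysis on one session.

Stages build on each other in a fixed order — the oscillation score fixes
f_max and the oscillation bin size T_osc; sequences are identified from
the T_osc-smoothed phase; tuning, spatial and ensemble statistics all work
on the concatenated-sequence window. Each stage writes one sub-record of
the report and can be enabled independently (dependencies are recomputed
as needed).
"""

from __future__ import annotations

import logging
import time
from typing import Iterable, Optional

import numpy as np

from . import behavior as beh
from . import ensembles as ens
from . import spatial as spa
from . import spectral as spe
from . import tuning as tun
from .config import AnalysisConfig
from .oscillation import oscillation_score
from .sequences import identify_sequences, sequence_stats, segment_event_rate
from .session import EventMatrix, Session
from .sorting import oscillation_phase, pca_sort, sorting_stability

logger = logging.getLogger("ultraseq")

ALL_STAGES = ("score", "sequences", "tuning", "spatial", "ensembles",
              "behavior", "spectral", "stability")


def analyze_session(session: Session, config: Optional[AnalysisConfig] = None,
                    stages: Iterable[str] = ("score", "sequences", "tuning",
                                             "ensembles", "behavior"),
                    rng: Optional[np.random.Generator] = None) -> dict:
    cfg = config or AnalysisConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    stages = list(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    events = session.events
    report: dict = {"n_cells": events.n_cells, "n_bins": events.n_bins,
                    "bin_size_s": events.bin_size}

    t0 = time.time()
    est = oscillation_score(
        events, welch_window_bins=cfg.welch_window_bins,
        n_tau_bins=cfg.n_tau_bins_score, max_lag_s=cfg.max_lag_s,
        n_d_bins=cfg.n_distance_bins,
        cond_window_bins=cfg.cond_welch_window_bins,
        factors_phase=(cfg.peak_factor_tail_phase, cfg.peak_factor_min_phase),
        factors_cond=(cfg.peak_factor_tail_cond, cfg.peak_factor_min_cond),
        score_threshold=cfg.score_threshold, fallback_t_osc=cfg.fallback_t_osc)
    logger.info("score stage: %.1f s", time.time() - t0)
    if "score" in stages:
        report["score"] = {
            "oscillation_score": est.score, "is_oscillatory": est.is_oscillatory,
            "f_max_hz": est.f_max, "p_osc_s": est.p_osc, "t_osc_s": est.t_osc,
        }

    seqs = identify_sequences(
        events, est.t_osc, n_phase_bins=cfg.n_phase_bins,
        discontinuity_bins=cfg.discontinuity_bins,
        max_decrement=cfg.max_decrement_bins,
        partial_min_bins=cfg.partial_min_bins,
        sustained_factor=cfg.sustained_factor)
    if "sequences" in stages:
        stats = sequence_stats(seqs)
        report["sequences"] = {
            "n_sequences": stats["n_sequences"],
            "n_partial_segments": len(seqs.partial_segments),
            "median_duration_s": stats["median_duration_s"],
            "sequence_frequency_hz": stats["sequence_frequency_hz"],
            "durations_s": stats["durations_s"],
            "isis_s": stats["isis_s"],
        }
        if seqs.intervals:
            report["sequences"]["segment_rates"] = segment_event_rate(
                events, seqs)["segment_rates"]

    concat = seqs.concat_index
    phi_seq = oscillation_phase(events, smoothing_width=est.t_osc).phi
    phi_concat = phi_seq[concat] if concat.size else np.array([])
    ev_concat = events.values[:, concat] if concat.size else None

    if "tuning" in stages and concat.size:
        rvals, locked, prefs, pi_vals = [], [], [], []
        for i, row in enumerate(ev_concat):
            if row.any():
                res = tun.locking_degree(row, phi_concat,
                                         n_shuffles=cfg.n_shuffles_locking,
                                         pct=cfg.locking_percentile, rng=rng)
                rvals.append(res["r"])
                locked.append(res["locked"])
                prefs.append(tun.preferred_phase(row, phi_concat))
            else:
                rvals.append(np.nan)
                prefs.append(np.nan)
            try:
                pi_vals.append(tun.participation_index(events.values[i], seqs,
                                                       cfg.pi_threshold))
            except ValueError:
                pi_vals.append(np.nan)
        finite_prefs = np.array([p for p in prefs if np.isfinite(p)])
        entropy = (tun.phase_entropy_ratio(finite_prefs, cfg.n_phase_bins)
                   if finite_prefs.size >= 10 else {"h_ratio": float("nan")})
        report["tuning"] = {
            "locked_fraction": float(np.mean(locked)) if locked else float("nan"),
            "mean_locking": float(np.nanmean(rvals)),
            "preferred_phases": prefs,
            "participation_index": pi_vals,
            "h_ratio": entropy["h_ratio"],
        }

    if "spatial" in stages and session.positions is not None and concat.size:
        prefs_arr = np.array([
            tun.preferred_phase(row, phi_concat) if row.any() else np.nan
            for row in ev_concat])
        report["spatial"] = {
            "phase_distance": spa.phase_distance_correlation(
                prefs_arr, session.positions, variant="signed",
                n_shuffles=cfg.n_shuffles_phase_distance, rng=rng),
            "neighborhood": spa.neighborhood_phase_diffs(
                prefs_arr, session.positions,
                radius_um=cfg.neighborhood_radii_um[1],
                n_shuffles=cfg.n_shuffles_spatial, rng=rng),
        }

    if "ensembles" in stages:
        order = pca_sort(events).order
        membership = ens.assign_ensembles(order, cfg.n_ensembles)
        if est.is_oscillatory and concat.size:
            matrix, t_osc = ev_concat.astype(float), est.t_osc
        else:
            matrix, t_osc = events.values.astype(float), cfg.fallback_t_osc
        dyn = ens.ensemble_dynamics(
            matrix, membership, t_osc, events.bin_size, cfg.n_ensembles,
            n_shuffles=cfg.n_shuffles_ensembles,
            transition_pct=cfg.transition_percentile,
            score_pct=cfg.sequence_score_percentile, rng=rng)
        report["ensembles"] = {
            "sequence_score": dyn["sequence_score"],
            "score_cutoff": dyn["score_cutoff"],
            "score_significant": dyn["score_significant"],
            "P_k": dyn["P_k"],
            "transition_matrix": dyn["transition_matrix"],
        }

    if "behavior" in stages and session.behavior is not None:
        derived = beh.derive_speed(session.behavior, events.bin_size,
                                   events.n_bins, cfg.speed_threshold,
                                   cfg.speed_kernel_s)
        probs = beh.sequence_probability_by_state(seqs, derived.state)
        onset = beh.onset_speed_analysis(seqs, derived.speed, derived.state,
                                         events.bin_size)
        report["behavior"] = {**probs,
                              "onset_ratio": onset["onset_ratio_running_vs_immobile"],
                              "n_epoch_onsets": onset["n_epoch_onsets"]}

    if "spectral" in stages:
        fs_rows = []
        for i, row in enumerate(events.values):
            if row.sum() == 0:
                continue
            spec = spe.cell_spectrum(row, fs=1.0 / events.bin_size,
                                     window_bins=cfg.welch_window_bins)
            fs_rows.append({"cell": i, "f_cell": spec.primary_frequency,
                            "max_power": spec.max_power})
        report["spectral"] = {"cells": fs_rows}

    if "stability" in stages:
        report["stability"] = sorting_stability(
            events, n_shuffles=cfg.n_shuffles_stability, rng=rng)

    return report
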