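"""Session-level oscillation score.

The score asks two things of a session: (1) the phase of the oscillation
must itself be periodic — the PSD of sin(phi(t)) must carry a prominent
peak at some f_max > 0; and (2) for cell pairs at a fixed angular distance
in the ring sorting, the time lags that maximize their cross-correlations
must recur at integer multiples of a common lag. The latter is probed by
building the joint distribution of peak cross-correlation lag (tau) and
angular loading distance (d), and testing each of the 11 d-bins'
conditional tau-distributions for a prominent spectral peak. The score is
the fraction of d-bins with such a peak; sessions scoring >= 0.72 are
classified as oscillatory.

Peak prominence follows two strict-inequality rules: amplitude > k_tail
times the mean of the PSD beyond the peak and > k_min times the PSD
minimum between 0 and the peak (9/9 for the population phase, 10/4.5 for
the conditional lag distributions).
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
from scipy import fft as sfft

from .session import EventMatrix
from .sorting import _pca_basis, _wrap
from .spectral import welch_psd


@dataclass
class LagDistanceHistogram:
    joint: np.ndarray          # (n_tau_bins, n_d_bins), sums to 1
    tau_edges: np.ndarray      # s
    d_edges: np.ndarray        # rad


@dataclass
class OscillationEstimate:
    f_max: float               # Hz; nan when non-oscillatory
    p_osc: float               # s; nan when non-oscillatory
    t_osc: float               # s; fallback value when non-oscillatory
    score: float               # in {0, 1/11, ..., 1}
    is_oscillatory: bool
    details: dict = field(default_factory=dict)


def angular_distance(theta_i, theta_j):
    """Signed difference of two angles wrapped into [-pi, pi)."""
    return _wrap(np.asarray(theta_i) - np.asarray(theta_j))


def pairwise_peak_lags(values: np.ndarray, max_lag_bins: int,
                       chunk: int = 256) -> np.ndarray:
    """Peak cross-correlation lag (in bins) for every unordered cell pair.

    Cross-correlations are raw lagged sums computed by FFT; for pair
    (i, j) with i < j a positive lag means cell i's activity follows cell
    j's. Flat cross-correlations tie-break to lag 0.
    """
    values = np.asarray(values, dtype=np.float32)
    n, T = values.shape
    L = int(max_lag_bins)
    nfft = sfft.next_fast_len(T + L + 1)
    spectra = sfft.rfft(values, nfft, axis=1)
    iu = np.triu_indices(n, k=1)
    n_pairs = iu[0].size
    taus = np.empty(n_pairs, dtype=np.int64)
    for start in range(0, n_pairs, chunk):
        sl = slice(start, min(start + chunk, n_pairs))
        prod = spectra[iu[0][sl]] * np.conj(spectra[iu[1][sl]])
        cc = sfft.irfft(prod, nfft, axis=1)
        window = np.concatenate([cc[:, nfft - L:], cc[:, :L + 1]], axis=1)
        best = np.argmax(window, axis=1) - L
        flat = np.ptp(window, axis=1) <= 1e-6 * np.maximum(
            np.abs(window).max(axis=1), 1.0)
        best[flat] = 0
        taus[sl] = best
    return taus


def lag_distance_joint(events: EventMatrix, theta: np.ndarray,
                       n_tau_bins: int = 96, max_lag_s: float = 248.0,
                       n_d_bins: int = 11) -> LagDistanceHistogram:
    """Joint histogram of peak cross-correlation lag and angular distance."""
    if events.n_cells < 10:
        raise ValueError("need at least 10 cells")
    theta = np.asarray(theta, dtype=float)
    max_lag_bins = int(round(max_lag_s / events.bin_size))
    taus = pairwise_peak_lags(events.values, max_lag_bins) * events.bin_size
    iu = np.triu_indices(events.n_cells, k=1)
    d = angular_distance(theta[iu[0]], theta[iu[1]])
    tau_edges = np.linspace(-max_lag_s, max_lag_s, n_tau_bins + 1)
    d_edges = np.linspace(-np.pi, np.pi, n_d_bins + 1)
    joint, _, _ = np.histogram2d(np.clip(taus, -max_lag_s, max_lag_s),
                                 np.clip(d, -np.pi, np.nextafter(np.pi, 0)),
                                 bins=[tau_edges, d_edges])
    joint = joint / joint.sum()
    return LagDistanceHistogram(joint=joint, tau_edges=tau_edges, d_edges=d_edges)


def prominent_peak(freqs: np.ndarray, psd: np.ndarray,
                   factor_tail: float, factor_min: float):
    """Locate a prominent spectral peak at f > 0.

    The candidate is the global maximum over positive frequencies. It
    counts as a peak only if its amplitude strictly exceeds ``factor_tail``
    times the mean of the PSD beyond it and ``factor_min`` times the PSD
    minimum between 0 (inclusive) and the peak. A peak landing on the last
    frequency bin has no tail and is rejected.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    pos = freqs > 0
    if not pos.any():
        return False, float("nan")
    k = np.flatnonzero(pos)[int(np.argmax(psd[pos]))]
    f_peak = freqs[k]
    amp = psd[k]
    tail = psd[freqs > f_peak]
    if tail.size == 0:
        return False, float("nan")
    head = psd[(freqs >= 0) & (freqs < f_peak)]
    if amp > factor_tail * tail.mean() and amp > factor_min * head.min():
        return True, float(f_peak)
    return False, float("nan")


def oscillation_bin_size(f_max: float, fallback: float = 8.5) -> float:
    """Characteristic temporal bin: a tenth of the sequence period.

    Non-oscillatory sessions (f_max NaN or <= 0) fall back to the mean
    oscillation bin size across oscillatory sessions (8.5 s by default).
    """
    if f_max is None or not np.isfinite(f_max) or f_max <= 0:
        return float(fallback)
    return 1.0 / (10.0 * f_max)


def oscillation_score(events: EventMatrix, *, welch_window_bins: int = 8192,
                      n_tau_bins: int = 240, max_lag_s: float = 248.0,
                      n_d_bins: int = 11, cond_window_bins: int = 128,
                      factors_phase=(9.0, 9.0), factors_cond=(10.0, 4.5),
                      score_threshold: float = 0.72,
                      fallback_t_osc: float = 8.5) -> OscillationEstimate:
    """Compute the oscillation score of a session.

    The PCA basis is shared between the phase trace and the loading angles
    so the phase and the ring coordinates refer to the same plane.
    """
    matrix = events.values.astype(float)
    loadings, proj = _pca_basis(matrix)
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    theta = np.arctan2(loadings[:, 1], loadings[:, 0])

    fs = 1.0 / events.bin_size
    freqs, psd = welch_psd(np.sin(phi), fs=fs, window_bins=welch_window_bins)
    found, f_max = prominent_peak(freqs, psd, *factors_phase)
    if not found:
        return OscillationEstimate(
            f_max=float("nan"), p_osc=float("nan"),
            t_osc=fallback_t_osc, score=0.0, is_oscillatory=False,
            details={"reason": "no prominent peak in PSD of sin(phase)"})

    p_osc = 1.0 / f_max
    t_osc = oscillation_bin_size(f_max)
    hist = lag_distance_joint(events, theta, n_tau_bins=n_tau_bins,
                              max_lag_s=max_lag_s, n_d_bins=n_d_bins)
    flags = []
    for i in range(n_d_bins):
        cond = hist.joint[:, i]
        cfreqs, cpsd = welch_psd(cond, fs=1.0, window_bins=cond_window_bins)
        ok, _ = prominent_peak(cfreqs, cpsd, *factors_cond)
        flags.append(bool(ok))
    score = sum(flags) / n_d_bins
    return OscillationEstimate(
        f_max=float(f_max), p_osc=float(p_osc), t_osc=float(t_osc),
        score=float(score), is_oscillatory=bool(score >= score_threshold),
        details={"d_bin_peak_flags": flags, "theta": theta, "phi": phi})
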