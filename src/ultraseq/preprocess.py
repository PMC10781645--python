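"""Binarization, SNR estimation, smoothing and shuffle constructors.

The three shuffles used as null models throughout the pipeline live here:

``temporal``
    independent permutation of time bins per cell; destroys all temporal
    structure while preserving per-cell event counts.
``circular``
    independent rigid circular shift per cell; preserves each cell's
    autocorrelation (and hence its spectrum) but destroys cross-cell timing.
``epoch``
    per cell, the trace is cut into epochs of length W seconds whose order
    is permuted; inter-event intervals within epochs survive while
    periodicity at time scales beyond W is destroyed. With W equal to the
    bin size this approaches the temporal shuffle; with a single epoch it
    is the identity.

SD convention: population SD (ddof=0) everywhere, pinned by tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import convolve1d

from .session import EventMatrix


@dataclass
class ShuffleSpec:
    kind: str                      # temporal | circular | epoch
    epoch_length: Optional[float] = None  # s, epoch kind only
    n_iterations: int = 1

    def __post_init__(self):
        if self.kind not in ("temporal", "circular", "epoch"):
            raise ValueError(f"unknown shuffle kind {self.kind!r}")
        if self.kind == "epoch" and (self.epoch_length is None or self.epoch_length <= 0):
            raise ValueError("epoch shuffle requires a positive epoch_length")


def _downsample_mean(matrix: np.ndarray, factor: int) -> np.ndarray:
    """Mean-downsample each row by an integer factor, dropping the remainder."""
    n = (matrix.shape[1] // factor) * factor
    return matrix[:, :n].reshape(matrix.shape[0], -1, factor).mean(axis=2)


def binarize_activity(deconvolved: np.ndarray, bin_size: float,
                      downsample_factor: int = 4, k_sd: float = 1.5) -> EventMatrix:
    """Binarize deconvolved calcium activity.

    Per cell: mean-downsample by ``downsample_factor``, then threshold at
    mean + ``k_sd`` * SD of the downsampled trace. Values strictly above
    threshold become 1. A constant trace yields an all-zero row.
    """
    deconvolved = np.atleast_2d(np.asarray(deconvolved, dtype=float))
    if np.any(deconvolved < 0):
        raise ValueError("deconvolved activity must be non-negative")
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    down = _downsample_mean(deconvolved, downsample_factor)
    thresh = down.mean(axis=1, keepdims=True) + k_sd * down.std(axis=1, keepdims=True)
    return EventMatrix((down > thresh).astype(np.uint8), bin_size * downsample_factor)


def compute_snr(f_corr: np.ndarray, deconvolved: np.ndarray, bin_size: float,
                pre_s: float = 1.0, post_s: float = 10.0) -> float:
    """Signal-to-noise ratio of one cell.

    Activity bins are those where the deconvolved trace exceeds its mean
    plus one SD. Noise bins must be at least ``pre_s`` seconds before and
    ``post_s`` seconds after every activity bin. SNR is the mean of
    ``f_corr`` over activity bins divided by the SD of ``f_corr`` over
    noise bins; 0 if no activity bins survive, +inf if no noise bins remain.
    """
    f_corr = np.asarray(f_corr, dtype=float)
    deconvolved = np.asarray(deconvolved, dtype=float)
    if f_corr.shape != deconvolved.shape:
        raise ValueError("traces must have the same length")
    thresh = deconvolved.mean() + deconvolved.std()
    active = deconvolved > thresh
    if not active.any():
        return 0.0
    pre = int(np.ceil(pre_s / bin_size))
    post = int(np.ceil(post_s / bin_size))
    excluded = active.copy()
    idx = np.flatnonzero(active)
    for i in idx:
        excluded[max(0, i - pre):min(active.size, i + post + 1)] = True
    noise = ~excluded
    if not noise.any():
        import warnings
        warnings.warn("no noise bins remain; SNR undefined", stacklevel=2)
        return float("inf")
    sd = f_corr[noise].std()
    if sd == 0:
        return float("inf")
    return float(f_corr[active].mean() / sd)


def gaussian_kernel(width_s: float, bin_size: float) -> np.ndarray:
    """Unit-mass Gaussian kernel.

    ``width_s`` is the full window length (the convention of Matlab-style
    gaussian smoothing windows), so the SD is width / 5 and the kernel is
    truncated at the window edges (+-2.5 SD).
    """
    if width_s <= 0:
        raise ValueError("kernel width must be positive")
    sd = width_s / bin_size / 5.0
    half = max(1, int(np.ceil(2.5 * sd)))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sd) ** 2)
    return k / k.sum()


def gaussian_smooth(matrix: np.ndarray, width_s: float, bin_size: float) -> np.ndarray:
    """Per-row Gaussian convolution, same length, mass-preserving edges."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    kernel = gaussian_kernel(width_s, bin_size)
    return convolve1d(matrix, kernel, axis=1, mode="constant", cval=0.0)


def make_shuffle(events: EventMatrix, spec: ShuffleSpec,
                 rng: np.random.Generator) -> EventMatrix:
    """One shuffled realization of an event matrix (per-cell independent)."""
    values = events.values
    n_cells, n_bins = values.shape
    if spec.kind == "temporal":
        out = np.empty_like(values)
        for i in range(n_cells):
            out[i] = values[i, rng.permutation(n_bins)]
    elif spec.kind == "circular":
        shifts = rng.integers(0, n_bins, size=n_cells)
        out = np.empty_like(values)
        for i in range(n_cells):
            out[i] = np.roll(values[i], shifts[i])
    else:  # epoch
        w_bins = int(round(spec.epoch_length / events.bin_size))
        if w_bins < 1:
            raise ValueError("epoch shorter than one bin")
        if w_bins > n_bins:
            raise ValueError("epoch longer than the session")
        edges = list(range(0, n_bins, w_bins)) + [n_bins]
        n_epochs = len(edges) - 1
        out = np.empty_like(values)
        for i in range(n_cells):
            order = rng.permutation(n_epochs)
            out[i] = np.concatenate([values[i, edges[j]:edges[j + 1]] for j in order])
    return EventMatrix(out, events.bin_size)


def shuffle_trace(trace: np.ndarray, spec: ShuffleSpec,
                  rng: np.random.Generator, bin_size: float) -> np.ndarray:
    """Shuffle a single binary trace (convenience wrapper)."""
    em = EventMatrix(np.atleast_2d(trace), bin_size)
    return make_shuffle(em, spec, rng).values[0]


def binarize_spike_trains(counts: np.ndarray, bin_size: float = 0.120,
                          smooth_width: Optional[float] = 5.0,
                          discard_s: float = 300.0) -> EventMatrix:
    """Binarize spike-count matrices (electrophysiology variant).

    Optionally Gaussian-smooth each train (width 5 s), then threshold at
    mean + k*SD with k = 1 for smoothed and 1.5 for raw matrices. The first
    ``discard_s`` seconds are dropped to remove the arousal transient that
    imaging sessions do not contain.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n_discard = int(round(discard_s / bin_size))
    if counts.shape[1] <= n_discard:
        raise ValueError("session shorter than the discarded initial segment")
    counts = counts[:, n_discard:]
    if smooth_width is not None:
        mat = gaussian_smooth(counts, smooth_width, bin_size)
        k = 1.0
    else:
        mat = counts
        k = 1.5
    thresh = mat.mean(axis=1, keepdims=True) + k * mat.std(axis=1, keepdims=True)
    return EventMatrix((mat > thresh).astype(np.uint8), bin_size)
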