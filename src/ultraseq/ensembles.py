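"""Ensemble coarse-graining and sequential-dynamics statistics.

Cells are ordered along the ring (PCA sorting) and either iteratively
merged in adjacent pairs (coarse-graining; participation index tracked per
step) or split into 10 contiguous blocks ("ensembles"). Ensemble activity,
downsampled at the oscillation bin size, is summarized by the index of the
most active ensemble per bin; that integer trace feeds the transition
matrix, the probabilities of strictly increasing ensemble runs, and the
sequence score (probability of runs of three or more ensembles), each with
temporal-shuffle nulls that re-run the ensemble construction on shuffled
activity.
"""

from __future__ import annotations

from math import comb


import numpy as np


def merge_step(variables: np.ndarray) -> np.ndarray:
    """One coarse-graining step: average adjacent pairs of variables.

    Variables must already be ordered by ring coordinate. An odd trailing
    variable is dropped (mirrors dropping the last cell in the sorting).
    """
    variables = np.atleast_2d(np.asarray(variables, dtype=float))
    n = variables.shape[0]
    if n < 2:
        raise ValueError("need at least 2 variables to merge")
    n_even = (n // 2) * 2
    v = variables[:n_even]
    return (v[0::2] + v[1::2]) / 2.0


def assign_ensembles(sort_order: np.ndarray, n_ens: int = 10) -> np.ndarray:
    """Contiguous-block ensemble membership along the sorted order.

    Returns an array mapping cell index -> ensemble id in 1..n_ens.
    Ensembles 1..n_ens-1 hold floor(N/n_ens) cells; the last takes the
    remainder.
    """
    sort_order = np.asarray(sort_order)
    n = sort_order.size
    if n < n_ens:
        raise ValueError("fewer cells than ensembles")
    block = n // n_ens
    membership = np.empty(n, dtype=int)
    for e in range(n_ens):
        lo = e * block
        hi = (e + 1) * block if e < n_ens - 1 else n
        membership[sort_order[lo:hi]] = e + 1
    return membership


def ensemble_activity(matrix: np.ndarray, membership: np.ndarray,
                      n_ens: int = 10) -> np.ndarray:
    """Mean activity per ensemble per time bin -> (n_ens, n_bins)."""
    matrix = np.asarray(matrix, dtype=float)
    out = np.empty((n_ens, matrix.shape[1]))
    for e in range(1, n_ens + 1):
        out[e - 1] = matrix[membership == e].mean(axis=0)
    return out


def argmax_ensemble_trace(matrix: np.ndarray, membership: np.ndarray,
                          t_osc: float, bin_size: float,
                          n_ens: int = 10) -> np.ndarray:
    """Most-active ensemble per T_osc-sized bin (1-based ids).

    Ensemble activity is averaged in bins of the oscillation bin size;
    ties (including all-zero bins) break to the lowest ensemble index.
    """
    act = ensemble_activity(matrix, membership, n_ens)
    per = max(1, int(round(t_osc / bin_size)))
    n_coarse = act.shape[1] // per
    if n_coarse < 1:
        raise ValueError("trace shorter than one oscillation bin")
    coarse = act[:, :n_coarse * per].reshape(n_ens, n_coarse, per).mean(axis=2)
    return np.argmax(coarse, axis=0) + 1


def transition_matrix(trace: np.ndarray, n_ens: int = 10) -> np.ndarray:
    """Non-self transition probabilities between consecutive bins.

    Entry (i, j) is the probability of observing the transition i -> j
    among all transitions to a different ensemble; the matrix sums to 1.
    """
    trace = np.asarray(trace)
    if trace.size < 2:
        raise ValueError("trace too short")
    a, b = trace[:-1], trace[1:]
    keep = a != b
    T = np.zeros((n_ens, n_ens))
    np.add.at(T, (a[keep] - 1, b[keep] - 1), 1.0)
    total = T.sum()
    return T / total if total > 0 else T


def _collapse_repeats(trace: np.ndarray) -> np.ndarray:
    trace = np.asarray(trace)
    if trace.size == 0:
        return trace
    keep = np.concatenate([[True], np.diff(trace) != 0])
    return trace[keep]


def sequential_activation(trace: np.ndarray, n_ens: int = 10) -> np.ndarray:
    """Probability of strictly increasing ensemble runs of each length.

    The argmax trace is first collapsed over sustained activity (repeats).
    Every maximal strictly increasing run of length m contributes all its
    C(m, k) increasing subsequences of length k (skips allowed). Returns
    P(k) for k = 2..n_ens, normalized by the total subsequence count.
    """
    collapsed = _collapse_repeats(trace)
    counts = np.zeros(n_ens + 1)
    i = 0
    while i < collapsed.size:
        j = i
        while j + 1 < collapsed.size and collapsed[j + 1] > collapsed[j]:
            j += 1
        m = j - i + 1
        if m >= 2:
            for k in range(2, min(m, n_ens) + 1):
                counts[k] += comb(m, k)
        i = j + 1 if j > i else i + 1
    total = counts.sum()
    P = counts[2:] / total if total > 0 else counts[2:]
    return P


def sequence_score(P: np.ndarray) -> float:
    """Probability of sequential activation of three or more ensembles."""
    P = np.asarray(P, dtype=float)
    return float(P[1:].sum())   # P[0] is k=2


def ensemble_dynamics(matrix: np.ndarray, membership: np.ndarray,
                      t_osc: float, bin_size: float, n_ens: int = 10,
                      n_shuffles: int = 500,
                      transition_pct: float = 95.0, score_pct: float = 99.0,
                      rng: np.random.Generator | None = None) -> dict:
    """Transition matrix, P(k) and sequence score with shuffle nulls.

    Each shuffle permutes every cell's activity in time (membership held
    fixed) and re-runs the ensemble-matrix construction, giving per-entry
    transition cutoffs and the sequence-score null distribution.
    """
    if rng is None:
        rng = np.random.default_rng()
    matrix = np.asarray(matrix)
    trace = argmax_ensemble_trace(matrix, membership, t_osc, bin_size, n_ens)
    T = transition_matrix(trace, n_ens)
    P = sequential_activation(trace, n_ens)
    score = sequence_score(P)

    null_T = np.empty((n_shuffles, n_ens, n_ens))
    null_score = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuffled = rng.permuted(matrix, axis=1)
        tr = argmax_ensemble_trace(shuffled, membership, t_osc, bin_size, n_ens)
        null_T[s] = transition_matrix(tr, n_ens)
        null_score[s] = sequence_score(sequential_activation(tr, n_ens))
    return {
        "trace": trace,
        "transition_matrix": T,
        "transition_cutoffs": np.percentile(null_T, transition_pct, axis=0),
        "P_k": P,
        "sequence_score": score,
        "score_cutoff": float(np.percentile(null_score, score_pct)),
        "score_significant": bool(score > np.percentile(null_score, score_pct)),
        "null_scores": null_score,
    }
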