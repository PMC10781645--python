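"""Travelling-wave tests on anatomical cell positions.

A travelling wave would make nearby cells prefer nearby oscillation
phases. Three complementary tests probe this: (1) Pearson correlation
between pairwise anatomical distance and pairwise preferred-phase
difference, against a position-shuffle null; (2) the mean vector length
of preferred phases within spatial bins of the field of view (high MVL =
locally similar phases); and (3) absolute phase differences among cell
pairs within small circular neighbourhoods, compared with the 5th
percentile of a phase-shuffle null (waves give smaller-than-chance
differences). All three are invariant under rigid motions of the
positions.
"""

from __future__ import annotations

import numpy as np

from .session import CellPositions, EventMatrix
from .sorting import _wrap
from .tuning import resultant_length


def _pair_arrays(pref_phases: np.ndarray, xy: np.ndarray, variant: str):
    n = pref_phases.size
    iu = np.triu_indices(n, k=1)
    dist = np.hypot(xy[iu[0], 0] - xy[iu[1], 0], xy[iu[0], 1] - xy[iu[1], 1])
    dphi = _wrap(pref_phases[iu[0]] - pref_phases[iu[1]])
    if variant == "absolute":
        dphi = np.abs(dphi)
    elif variant != "signed":
        raise ValueError(f"unknown variant {variant!r}")
    return dist, dphi


def phase_distance_correlation(pref_phases: np.ndarray,
                               positions: CellPositions,
                               variant: str = "signed",
                               n_shuffles: int = 100, pct: float = 95.0,
                               rng: np.random.Generator | None = None) -> dict:
    """|Pearson r| between pairwise anatomical distance and phase difference.

    NaN preferred phases (cells below the per-sequence event minimum) are
    excluded. Significance: 95th percentile of |r| over shuffles of the
    phase-to-position assignment.
    """
    pref_phases = np.asarray(pref_phases, dtype=float)
    keep = np.isfinite(pref_phases)
    phases, xy = pref_phases[keep], positions.xy[keep]
    if phases.size < 10:
        raise ValueError("need at least 10 cells with preferred phases")
    if rng is None:
        rng = np.random.default_rng()
    dist, dphi = _pair_arrays(phases, xy, variant)
    r = float(np.abs(np.corrcoef(dist, dphi)[0, 1]))
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        _, dphi_s = _pair_arrays(phases[rng.permutation(phases.size)], xy, variant)
        null[s] = np.abs(np.corrcoef(dist, dphi_s)[0, 1])
    cutoff = float(np.percentile(null, pct))
    return {"r": r, "null_cutoff": cutoff, "significant": bool(r > cutoff),
            "n_pairs": int(dist.size)}


def binned_phase_mvl(pref_phases: np.ndarray, positions: CellPositions,
                     bin_size_um: float = 100.0, min_cells: int = 10,
                     n_shuffles: int = 200, pct: float = 95.0,
                     rng: np.random.Generator | None = None) -> dict:
    """MVL of preferred phases within square spatial bins of the FOV."""
    pref_phases = np.asarray(pref_phases, dtype=float)
    keep = np.isfinite(pref_phases)
    phases, xy = pref_phases[keep], positions.xy[keep]
    if rng is None:
        rng = np.random.default_rng()
    n_side = max(1, int(round(positions.fov_size / bin_size_um)))
    ix = np.clip((xy[:, 0] // bin_size_um).astype(int), 0, n_side - 1)
    iy = np.clip((xy[:, 1] // bin_size_um).astype(int), 0, n_side - 1)
    cell_bin = ix * n_side + iy
    bins = [b for b in np.unique(cell_bin)
            if np.count_nonzero(cell_bin == b) >= min_cells]
    if not bins:
        return {"mvl": {}, "significant_fraction": float("nan"), "n_bins": 0}
    mvl, sig = {}, {}
    for b in bins:
        members = cell_bin == b
        observed = resultant_length(phases[members])
        null = np.empty(n_shuffles)
        for s in range(n_shuffles):
            null[s] = resultant_length(
                phases[rng.permutation(phases.size)][:members.sum()])
        mvl[int(b)] = observed
        sig[int(b)] = bool(observed > np.percentile(null, pct))
    frac = sum(sig.values()) / len(sig)
    return {"mvl": mvl, "significant": sig,
            "significant_fraction": float(frac), "n_bins": len(bins)}


def neighborhood_phase_diffs(pref_phases: np.ndarray, positions: CellPositions,
                             radius_um: float = 100.0, n_shuffles: int = 200,
                             pct: float = 5.0,
                             rng: np.random.Generator | None = None) -> dict:
    """Absolute phase differences among cell pairs closer than a radius.

    Observed mean and median are compared with the 5th percentile of the
    phase-shuffle null; values below the cutoff indicate locally similar
    phases, as a travelling wave would produce.
    """
    pref_phases = np.asarray(pref_phases, dtype=float)
    keep = np.isfinite(pref_phases)
    phases, xy = pref_phases[keep], positions.xy[keep]
    if phases.size < 2:
        raise ValueError("need at least 2 cells with preferred phases")
    if rng is None:
        rng = np.random.default_rng()
    iu = np.triu_indices(phases.size, k=1)
    dist = np.hypot(xy[iu[0], 0] - xy[iu[1], 0], xy[iu[0], 1] - xy[iu[1], 1])
    close = dist <= radius_um
    if not close.any():
        raise ValueError("no cell pairs within the radius")
    i_close, j_close = iu[0][close], iu[1][close]

    def pooled_diffs(ph):
        return np.abs(_wrap(ph[i_close] - ph[j_close]))

    obs = pooled_diffs(phases)
    null_mean = np.empty(n_shuffles)
    null_median = np.empty(n_shuffles)
    for s in range(n_shuffles):
        d = pooled_diffs(phases[rng.permutation(phases.size)])
        null_mean[s] = d.mean()
        null_median[s] = np.median(d)
    mean_cut = float(np.percentile(null_mean, pct))
    med_cut = float(np.percentile(null_median, pct))
    return {
        "mean": float(obs.mean()), "median": float(np.median(obs)),
        "mean_cutoff": mean_cut, "median_cutoff": med_cut,
        "mean_below_cutoff": bool(obs.mean() < mean_cut),
        "median_below_cutoff": bool(np.median(obs) < med_cut),
        "n_pairs": int(close.sum()),
    }


def com_trajectory(events: EventMatrix, positions: CellPositions,
                   seqs, bin_s: float = 5.0, n_shuffles: int = 500,
                   rng: np.random.Generator | None = None) -> dict:
    """Centre of mass of the population activity along each sequence.

    For each sequence, activity is summed in ``bin_s`` windows and the
    event-count-weighted mean cell position is tracked; the cumulative
    distance travelled by the COM is compared with the 5th/95th percentile
    band from shuffling the positions of the cells in the FOV.
    """
    if rng is None:
        rng = np.random.default_rng()
    bins_per = max(1, int(round(bin_s / events.bin_size)))
    xy = positions.xy

    def one_traj(xy_used, a, b):
        coms = []
        for lo in range(a, b, bins_per):
            hi = min(lo + bins_per, b)
            m = events.values[:, lo:hi].sum(axis=1).astype(float)
            if m.sum() == 0:
                continue
            coms.append((m @ xy_used) / m.sum())
        coms = np.asarray(coms)
        if len(coms) < 2:
            return coms, 0.0
        steps = np.hypot(np.diff(coms[:, 0]), np.diff(coms[:, 1]))
        return coms, float(steps.sum())

    out = []
    for a, b in seqs.intervals:
        coms, cumdist = one_traj(xy, a, b)
        null = np.empty(n_shuffles)
        for s in range(n_shuffles):
            _, null[s] = one_traj(xy[rng.permutation(xy.shape[0])], a, b)
        out.append({
            "com": coms, "cumulative_distance": cumdist,
            "null_p5": float(np.percentile(null, 5)),
            "null_p95": float(np.percentile(null, 95)),
            "within_band": bool(np.percentile(null, 5) <= cumdist
                                <= np.percentile(null, 95)),
        })
    return {"per_sequence": out,
            "fraction_within_band": float(np.mean([o["within_band"] for o in out]))
            if out else float("nan")}
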