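"""Pipeline configuration.

``AnalysisConfig`` gathers every tunable constant of the analysis in one
place, with defaults set to the values used throughout the study design:
129-ms event bins (7.73 Hz), 1.5-SD binarization, 8192-bin Hamming Welch
windows, 9x/9x and 10x/4.5x peak-prominence factors, an oscillation-score
cutoff of 0.72, 10 ensembles, a 2 cm/s running threshold, and an 8.5-s
fallback oscillation bin size for non-oscillatory sessions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class AnalysisConfig:
    # -- temporal resolution
    bin_size: float = 0.129           # s, event-matrix bin (imaging-like)
    coarse_factor: int = 4            # 129 ms -> 0.52 s downsampling

    # -- binarization
    binarize_k_sd: float = 1.5        # threshold = mean + k*SD
    snr_min: float = 4.0              # inclusion cutoff on cell SNR

    # -- spectral analysis
    welch_window_bins: int = 8192     # 17.6 min of 129-ms bins
    welch_overlap: float = 0.5
    epoch_shuffle_w: float = 20.0     # s, epoch length for the oscillatory-cell null
    n_shuffles_cell: int = 200
    cell_test_percentile: float = 95.0

    # -- oscillation score
    max_lag_s: float = 248.0
    n_tau_bins_score: int = 240
    n_tau_bins_display: int = 96
    n_distance_bins: int = 11
    peak_factor_tail_phase: float = 9.0
    peak_factor_min_phase: float = 9.0
    peak_factor_tail_cond: float = 10.0
    peak_factor_min_cond: float = 4.5
    cond_welch_window_bins: int = 128
    score_threshold: float = 0.72
    fallback_t_osc: float = 8.5       # s, mean oscillation bin size fallback

    # -- sequences
    n_phase_bins: int = 10
    discontinuity_bins: int = 3
    max_decrement_bins: int = 1
    partial_min_bins: int = 5
    sustained_factor: float = 2.0     # constant-phase runs > factor*T_osc collapsed

    # -- tuning
    n_tuning_bins: int = 40
    n_shuffles_locking: int = 1000
    locking_percentile: float = 99.0
    n_shuffles_mi: int = 1000
    pi_threshold: float = 0.9
    min_events_per_sequence: int = 5

    # -- spatial wave tests
    n_shuffles_phase_distance: int = 100
    n_shuffles_spatial: int = 200
    n_shuffles_com: int = 500
    spatial_bin_um: float = 100.0
    spatial_min_cells: int = 10
    neighborhood_radii_um: tuple = (50.0, 100.0, 200.0)
    com_bin_s: float = 5.0

    # -- ensembles
    n_ensembles: int = 10
    n_shuffles_ensembles: int = 500
    transition_percentile: float = 95.0
    sequence_score_percentile: float = 99.0

    # -- behavior
    speed_threshold: float = 2.0      # cm/s
    speed_kernel_s: float = 2.0       # boxcar width
    wheel_radius_cm: float = 8.54
    immobility_length_bins: tuple = ((0, 3), (3, 5), (5, 10), (10, 15), (15, 20), (25, float("inf")))

    # -- misc
    n_shuffles_stability: int = 100
    n_shuffles_durations: int = 500
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("coarse_factor", "welch_window_bins", "n_shuffles_cell",
                     "n_tau_bins_score", "n_distance_bins", "n_phase_bins",
                     "n_tuning_bins", "n_ensembles"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cell_test_percentile", "locking_percentile",
                     "transition_percentile", "sequence_score_percentile"):
            p = getattr(self, name)
            if not 0.0 < p < 100.0:
                raise ValueError(f"{name} must be in (0, 100)")

    @property
    def sampling_frequency(self) -> float:
        return 1.0 / self.bin_size

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["neighborhood_radii_um"] = list(d["neighborhood_radii_um"])
        d["immobility_length_bins"] = [list(b) for b in d["immobility_length_bins"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "neighborhood_radii_um" in d:
            d["neighborhood_radii_um"] = tuple(d["neighborhood_radii_um"])
        if "immobility_length_bins" in d:
            d["immobility_length_bins"] = tuple(
                (b[0], float(b[1])) for b in d["immobility_length_bins"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
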