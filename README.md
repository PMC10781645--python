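# ultraseq

Detection and analysis of **minute-scale oscillatory sequences** in neural
population event data.

Large populations of cortical neurons can activate in stereotyped sequences
that repeat with periods of tens of seconds to minutes — far below the
frequency range of classical brain rhythms. In a session where this happens,
the population state travels around a ring-shaped manifold, each cell fires
at a preferred angle of the ring, and a raster sorted by that angle shows
repeating diagonal sweeps. `ultraseq` implements the complete analysis chain
for finding and quantifying these dynamics in binarized event matrices
(calcium-imaging events at 129-ms bins, or spike matrices at 120-ms bins),
together with a synthetic-session generator that provides ground truth for
every stage. It is aimed at systems neuroscientists working with
head-fixed population recordings.

## The core statistics

* **Ring coordinates and phase.** PCA on the cells × time event matrix
  yields per-cell loadings on PC1/PC2 and per-bin projections. Each cell's
  ring coordinate is θᵢ = atan2(l²ᵢ, l¹ᵢ) and the population phase is
  φ(t) = atan2(PC2(t), PC1(t)), both in [−π, π). One sequence = one full
  2π traversal of φ.
* **Oscillation score.** The session-level statistic: the PSD of sin φ(t)
  (Welch, 8192-bin Hamming windows, 50% overlap) must carry a prominent
  peak at f_max > 0 (amplitude > 9× the tail mean and > 9× the minimum
  below the peak); then, in the joint distribution of pairwise peak
  cross-correlation lags τ (240 bins, |τ| ≤ 248 s) and angular distances
  d (11 bins), each d-bin's conditional τ-distribution is tested for a
  prominent spectral peak (10×/4.5× rule). The score is the fraction of
  the 11 d-bins with a peak; sessions scoring ≥ 0.72 are oscillatory,
  with period P_osc = 1/f_max and oscillation bin size T_osc = P_osc/10.
* **Sequence identification.** The phase of the T_osc-smoothed activity is
  discretized into 10 bins; discontinuities cut the session into segments
  and consecutive full 2π turns are carved from each segment's cumulative
  phase advance.
* **Single-cell tuning.** Locking degree r (mean resultant vector length
  of event phases, shuffle null at the 99th percentile), bias-corrected
  mutual information between event counts and phase, 40-bin tuning curves,
  preferred phases, the entropy ratio H(Q)/log₂10 of the preferred-phase
  distribution, and the participation index (fraction of sequences holding
  90% of a cell's events).
* **Travelling-wave tests.** Three tests of whether phase maps onto
  anatomy: pairwise phase-difference vs distance correlation, per-bin mean
  vector length of preferred phases in the field of view, and phase
  differences within small neighbourhoods — each against position- or
  phase-shuffle nulls.
* **Ensemble dynamics.** Ring-sorted cells are split into 10 contiguous
  ensembles; the most-active-ensemble trace at T_osc resolution gives
  transition matrices, probabilities P(k) of strictly increasing runs of
  k ensembles, and the sequence score Σ_{k≥3} P(k) with a 500-shuffle null.
* **Template model.** A 500-input perceptron trained toward a 100-s ramp
  or an Ornstein–Uhlenbeck trace shows that a linear readout of periodic
  sequence inputs can only express targets at the sequence's own time
  scale or faster inputs fail — the functional argument for slow sequences.

## Worked example

Simulate a 120-cell, 700-s session with a 70-s sequence period and analyze
it:

```bash
cat > sim.yaml <<EOF
n_cells: 120
duration: 700.0
period: 70.0
gap_prob: 0.0
rng_seed: 9
EOF
ultraseq simulate -c sim.yaml -o session.h5 --truth truth.json
# wrote session.h5 (120 cells, 5426 bins, 9 sequences)
ultraseq analyze session.h5 -o report.json --stages score,sequences,tuning
```

The report contains, among other entries:

```
score.oscillation_score   1.0        # 11 of 11 angular-distance bins peak
score.p_osc_s             69.9954    # recovered period (true: 70 s)
score.t_osc_s             6.9995     # oscillation bin size = P_osc / 10
sequences.n_sequences     9          # matches the 9 simulated sequences
sequences.median_duration_s  69.789
tuning.locked_fraction    1.0        # all cells phase-locked at the 99th pct
tuning.h_ratio            0.975      # preferred phases nearly uniform
```

Every number is recovered from the event matrix alone; the generator's
ground truth (`truth.json`) is only used to verify them. The same
`analyze` command accepts recorded sessions in the documented HDF5/CSV
layout (see `ultraseq.session.read_session`).

The library surface mirrors the CLI: `generate_session`,
`oscillation_score`, `identify_sequences`, `analyze_session`, and the
per-module functions in `ultraseq.tuning`, `ultraseq.spatial`,
`ultraseq.ensembles`, `ultraseq.behavior` and `ultraseq.model`.

## Documentation

`docs/methods.md` describes the model assumptions, the synthetic-data
generator, all numerical choices and known limitations.
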