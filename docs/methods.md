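# Methods

## Scope and model

`ultraseq` analyzes binary event matrices — cells × time bins, 129-ms bins
for imaging-derived events (sampling frequency 7.73 Hz), 120-ms bins for
spike matrices — for ultraslow oscillatory sequences: repeated, ordered
activations of the whole population with periods of tens of seconds to
minutes. The underlying picture is a one-dimensional ring attractor read
out through noisy, sparse events: at any moment the population state has a
ring coordinate (the phase), each cell fires preferentially at its own
phase, and one sequence corresponds to one full turn of the phase.

The pipeline assumes stationarity of the ring geometry within a session
(the same PCA plane describes the whole recording), events that are sparse
relative to the bin size, and enough cells (hundreds) that the
two-dimensional projection averages over single-cell noise.

## Ring coordinates, phase, and gauge conventions

PCA is applied to the event matrix with cells as variables and bins as
observations. Per-cell loading angles θᵢ and the per-bin phase
φ(t) = atan2(PC2(t), PC1(t)) share one basis. Because each principal
component is defined only up to sign, the basis carries a reflection and a
rotation gauge. The package canonicalizes the reflection so that the
median wrapped increment of φ is positive (phase ascends in time); cells
are then ordered by ascending θ, which makes a cell's rank equal its
activation order, makes identified sequences ascend through the sorting
and through the ensemble numbering, and keeps θ positively aligned with
each cell's preferred phase. The rotation gauge (a common offset of all
angles) is left wherever the decomposition puts it: every downstream
statistic is rotation-invariant, and sequence boundaries are anchored in
the data rather than at a fixed phase (below).

Bins where the projection radius is (near) zero have no meaningful phase;
they carry the previous phase forward and are flagged.

## Oscillation score

1. The PSD of sin φ(t) is estimated by Welch's method (Hamming windows of
   8192 bins ≈ 17.6 min, 50% overlap; the window shrinks with a warning on
   shorter sessions). A peak at f_max > 0 is *prominent* if its amplitude
   strictly exceeds 9× the mean of the PSD above the peak and 9× the PSD
   minimum between 0 (inclusive) and the peak. No prominent peak → score 0.
2. For every unordered cell pair, the lag τ maximizing the raw (FFT-based,
   unnormalized) cross-correlation within ±248 s and the wrapped angular
   distance d = θᵢ − θⱼ enter a joint histogram (240 τ-bins × 11 d-bins,
   normalized to 1). Flat cross-correlations tie-break to τ = 0.
3. Each d-bin's conditional τ-distribution is treated as a signal over the
   τ axis; its Welch PSD (128-bin Hamming, 50% overlap) is tested with the
   10× tail / 4.5× minimum prominence rule. The score is the fraction of
   the 11 d-bins with a peak; ≥ 0.72 (8 of 11, leaving room for the
   near-zero-distance bins where co-activity is instantaneous rather than
   lagged) classifies the session as oscillatory.

The period is P_osc = 1/f_max and the oscillation bin size T_osc =
P_osc/10, so one sequence spans ~10 analysis bins. Non-oscillatory
sessions use the fallback T_osc = 8.5 s for ensemble analyses.

Strict inequalities are used at all prominence boundaries so edge cases
are reproducible.

## Sequence identification

The phase is recomputed from activity smoothed with a Gaussian of width
T_osc and discretized into 10 bins. *Smoothing-width convention:* a
"width" W means the full smoothing window, with SD = W/5 and truncation at
the window edges — the convention of Matlab-style Gaussian smoothing
windows. (Interpreting W as the SD over-smooths: the measured phase then
loses about one phase bin of winding at every epoch edge and the last
sequence of each continuous epoch is systematically missed.)

Segments are cut at: circular jumps of ≥ 3 phase bins between consecutive
points; constant-phase dwells longer than 2 T_osc (sustained activity);
transitions into or out of bins whose projection radius falls below 0.25×
the session's 95th-percentile radius (no meaningful phase — this also
prevents chance phase-winding during non-oscillatory stretches); and
cumulative drawdowns of more than 1 bin below the running peak of the
phase advance (the allowed fluctuation is ~0.6 rad).

Within each segment, consecutive full turns (cumulative advance of 10
bins) are carved starting at the segment onset; anchoring at the onset
makes boundaries independent of the rotation gauge and aligned with where
the oscillation actually (re)started. A closing turn truncated by the
segment edge is granted a 1-bin tolerance, mirroring the in-sequence
fluctuation allowance. A full turn must additionally last at least
0.5 × 10 T_osc: faster windings are inconsistent with the session's own
period and are discarded as chance excursions (without this rule,
temporally shuffled sessions produce a few spurious 13–40-s "turns").
Trailing stretches advancing through ≥ 5 bins are recorded as partial
segments. Intervals are half-open in bins; durations, inter-sequence
intervals (0 for back-to-back sequences) and the sequence frequency
(count / total in-sequence time) follow from them.

## Single-cell tuning

All tuning statistics are computed on the concatenated-sequence window.
The locking degree is the mean resultant vector length of the phases at
which a cell's events occur; the null redraws the cell's event bins at
random (with replacement) from the concatenated window 1000 times —
for event counts far below the window length this is indistinguishable
from the permutation null, at a fraction of the cost — and a cell is
locked above the null's 99th percentile. Mutual information uses 0.52-s
count bins (s_max + 1 count states) × 10 phase bins with the plug-in
estimator; the limited-sampling bias is the mean MI over 1000 count-trace
permutations and MI_c = MI − bias. Tuning curves use 40 phase bins;
preferred phases are circular means (per session, or per sequence with a
5-event minimum). The entropy ratio H(Q)/log₂10 ∈ [0, 1] quantifies the
uniformity of the 10-bin preferred-phase distribution (flat entropy
3.32 bits).

The participation index is the smallest fraction of sequences that
accounts for ≥ 90% of a cell's events, accumulating sequences from the
largest contribution down: concentrated cells score near 1/n_seq, reliable
participants near 1. (Accumulating from the smallest contribution up, as a
literal reading of the procedure might suggest, would assign concentrated
cells an index of 1 and contradict the statistic's meaning.)

## Travelling-wave tests

Three complementary tests ask whether the phase maps onto anatomical
space; all are invariant under rigid motions of the positions.
(1) |Pearson r| between pairwise anatomical distance and preferred-phase
difference over all N(N−1)/2 pairs, against 100 position shuffles at the
95th percentile; both the signed wrapped difference and its absolute value
are available — the signed variant cancels for symmetric wave directions,
so the absolute variant is the sensitive detector. (2) The mean vector
length of preferred phases within square spatial bins (100 or 200 µm,
bins with ≥ 10 cells), against 200 phase shuffles. (3) Absolute phase
differences among cell pairs within circular neighbourhoods (radius
50/100/200 µm), compared with the 5th percentile of phase-shuffle nulls —
a wave makes local differences smaller than chance. The centre of mass of
population activity, tracked in 5-s bins along each sequence, gives a
cumulative travel distance compared against a 500-fold position-shuffle
band.

## Ensembles and sequential dynamics

Adjacent cells in the ring order are merged pairwise (averaging; an odd
trailing cell is dropped) to coarse-grain the population; the
participation index is tracked per merge step. For the standard analyses,
cells are split into 10 contiguous blocks along the order (blocks of
⌊N/10⌋, remainder in the last), ensemble activity is the mean over member
cells, and the most active ensemble per T_osc bin (ties to the lowest
index) yields an integer trace. From that trace: non-self transition
probabilities (10 × 10, normalized to 1); the probabilities P(k) of
strictly increasing runs of k ensembles, counting every increasing
subsequence of every maximal run (a run 1,2,3 yields one triple and the
three pairs 1-2, 2-3, 1-3; sustained repeats are collapsed first; runs do
not wrap 10 → 1); and the sequence score Σ_{k≥3} P(k). Nulls re-run the
ensemble construction on 500 per-cell temporal shuffles of the activity
matrix with membership held fixed; transitions use per-entry 95th
percentiles and the score its 99th percentile.

## Behavior

Wheel position (40–50 Hz) is differentiated, interpolated to the event
bins, smoothed with a 2-s boxcar, and thresholded at 2 cm/s (sub-threshold
speeds set to 0, so wheel twitches count as immobility). Running and
immobility bouts are maximal constant-state runs. Laps divide distance by
the wheel perimeter 2π·8.54 ≈ 53.66 cm. Conditioned statistics include
P(in-sequence | running/immobile), the fraction of immobility bouts per
length bin fully covered by sequences (with a label-shuffle null; the
printed length bins 0–3, 3–5, 5–10, 10–15, 15–20, > 25 s are kept as
stated, including the 20–25-s hole), pre/post-onset mean speeds (10-s
windows; epoch onsets are sequences ≥ 10 s after the previous one), and
onset counts within ≥ 20-s running vs immobility bouts. Synchrony
(pairwise |Pearson r|) and co-activity (per-bin active fraction) describe
non-oscillatory sessions.

## Synthetic sessions

`generate_session` emulates exactly the structure the analysis assumes —
it is a test scaffold, not a biophysical claim. A latent phase ramps
2π per period during sequence epochs and is undefined during gaps
(inserted after a sequence with probability `gap_prob`, exponential mean
`gap_mean`; defaults 0.25/220 s put ~73% of the session inside sequences).
Cells get uniform preferred phases (or a planted anatomical gradient with
jitter, to simulate a travelling wave), fire by von Mises thinning
(κ = 4, peak event probability 0.2) in sequences they participate in
(Bernoulli 0.9 per sequence), and emit unorganized events during gaps at
their in-sequence mean rate — real populations do not fall silent between
oscillatory epochs, and near-silent gaps would let the leading principal
component capture the on/off envelope instead of the ring. Uniform
background noise (0.002/bin) is added everywhere. Behavior alternates
exponential running/immobility bouts whose state is coupled to the
sequence epochs through `behavior_coupling`. Defaults describe the
reference condition: 400 cells, 30 min, 150-s period.

What the generator does **not** emulate: indicator dynamics beyond an
exponential kernel (`generate_fluorescence` exists only to exercise SNR
estimation and binarization), burstiness and refractoriness, slow drifts
of the ring geometry, heterogeneous per-cell rates, multi-region
structure, and sequence-to-sequence variability in speed profiles.
Passing tests therefore demonstrate correctness of the analysis under its
own assumptions, not performance on every real recording.

## Single-cell spectra

Autocorrelations are biased (divide-by-T) estimates of the mean-subtracted
trace, normalized to 1 at lag 0; the PSD of the positive-lag half is
estimated with the same Welch settings as the population analysis, and the
primary frequency is its peak. Significance uses epoch shuffles: the trace
is cut into epochs of length W (default 20 s; a trailing shorter epoch
participates as-is) whose order is permuted, preserving inter-event
structure within epochs while destroying longer periodicity. The observed
peak is compared against the 95th percentile of the *peak heights* (max
over positive frequencies) of 200 shuffled spectra. Comparing the
max-picked observed peak against a pointwise null at the same frequency
would classify essentially any flat-spectrum trace as oscillatory; the
peak-height null is the selection-matched form of the same test. The
fraction of oscillatory cells decreases as W grows past the sequence
duration, as expected.

## Template model

500 input units carry Gaussian bumps (σ = 7.6 s at template scale) with
equally spaced means tiling a sequence template of 240 s; compressing the
template to lengths 120/60/40/30 s scales means and widths together and
tiles the pattern periodically over the 120-s simulation window
(3588 steps of 33.44 ms). Targets are a ramp t/100 (clipped at 1 after
100 s) and an Ornstein–Uhlenbeck process (μ = 1, σ = 0.005, τ = 25.6 s,
Euler–Maruyama at the simulation step). A single linear readout R = WX is
trained for 1000 iterations with a momentum-accelerated batch delta rule:
the update direction is X(T − R), the step is η/λ_max(XXᵀ) (η = 1), and a
heavy-ball momentum of 0.95 accelerates the Gram's slow directions. The
plain delta rule at η = 1 diverges on these strongly overlapping inputs
(λ_max ≈ 6× the step count), and without momentum 1000 iterations stall
well short of the pseudo-inverse optimum along small-eigenvalue
directions; the literal scalar-error variant is retained behind
`rule="scalar"` for comparison. Reported errors are the means over the
last 100 iterations of Σ_t |T − R| and of the summed squared error; the
closed-form least-squares solution provides the floor. The absolute-error
metric is intrinsically non-monotone across the stated input lengths (the
40-s input tiles the window in three even tiles and fits the ramp
marginally better than the 60-s input — a property of the least-squares
floor itself), while the squared-error metric is monotone; monotonicity
statements use the latter. The structural result is forced by linearity:
for periodic X, R = WX is periodic with the input's period for every W, so
fast periodic inputs cannot express the non-periodic 100-s targets while
the slowest input reproduces them essentially perfectly (ramp NRMSE
≈ 0.002).

## Numerical conventions

* Population SD (ddof = 0) everywhere.
* Binarization thresholds are strict (`>` mean + k·SD).
* All shuffles preserve per-cell event counts exactly.
* One seeded `numpy.random.Generator` is passed explicitly to every
  stochastic operation; CLI runs log the resolved configuration and seed.
* NaN serializes to JSON null with a logged warning.
* Analysis problem sizes in the test and acceptance suites (session
  durations of 12–30 min, 120–400 cells, 20–1000 shuffle iterations per
  null) were chosen as the smallest sizes at which the statistics of
  interest are stable.

## Known limitations

* The period estimate 1/f_max degrades when sequences are frequently
  interrupted (the Welch peak mixes sequence and gap statistics); the
  session-length/sequence-count estimator is then preferable.
* The conditional-lag prominence test needs several sequence periods
  within the ±248-s lag range; sessions of a few hundred seconds or a few
  dozen cells can score below 0.72 despite visible sequences.
* The signed phase-difference vs distance correlation is blind to waves by
  direction symmetry; use the absolute variant for detection.
* Pearson correlation on wrapped phase differences under-detects waves
  whose phase advances a full turn across the field of view; the local
  (MVL and neighbourhood) tests do not share this limitation.
* The locking null resamples event bins with replacement; for cells whose
  events fill a substantial fraction of the window the permutation null
  would be slightly tighter.
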