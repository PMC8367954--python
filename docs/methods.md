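# Methods

This note records the model assumptions, the parameter choices that
matter, what the synthetic generator does and does not emulate, and the
numerical decisions taken where the design was genuinely open.

## Preprocessing

Recordings are band-pass filtered 1–40 Hz with a 4th-order Butterworth
plus a 2nd-order Butterworth band-stop notch (default 50 ± 2 Hz), both
applied forward–backward (zero-phase). Zero-phase filtering is a choice:
it avoids group-delay displacement of microstate boundaries at the cost of
non-causality, which is irrelevant for offline analysis. Down-sampling
(default target 125 Hz) uses polyphase anti-aliased resampling; the
artifact mask is OR-pooled over each source window so artifacts can only
grow, never shrink, under resampling. Artifact handling is mask-based
throughout — samples are never deleted — so run-length logic downstream
sees one coherent timeline; transitions across masked stretches are
treated as unobserved rather than as evidence.

GFP is the population (ddof = 0) spatial standard deviation per time
point, defined only for average-referenced data; the API enforces
re-referencing first. GFP peaks are strict interior local maxima
(`v[i−1] < v[i] > v[i+1]`); equal-valued plateaus yield no peak, a
deterministic reading that almost never triggers on floating-point data.
Peaks on, or adjacent to, masked samples are discarded.

## Clustering

The modified k-means treats a map and its sign-flip as the same state:
assignment maximizes `|corr|`, and the centroid update is the dominant
eigenvector of the assigned maps' outer-product sum (computed on
row-normalized maps, so each GFP peak carries one vote). The eigenvector
centroid is preferred to a sign-aligned mean because it is the exact
polarity-invariant analogue of the mean and is basis-stable. GEV is
GFP²-weighted; this split (unweighted votes for clustering, GFP² weights
for explained variance) mirrors standard practice of clustering only at
peaks while scoring variance on the signal. Emptied clusters are re-seeded
from the worst-fit map. Restart seeds derive from one master seed; the
best-of-n-restarts rule (default 50) makes results reproducible given
(seed, restarts).

The cluster-number meta-criterion is an ensemble of five validity
criteria — Krzanowski–Lai on the GFP²-weighted unexplained variance, a
predictive-residual cross-validation criterion with a `((C−1)/(C−1−k))²`
dof penalty, silhouette on the `1 − |corr|` distance (subsampled to 1000
maps for tractability), a polarity-invariant Davies–Bouldin index, and a
GEV elbow — aggregated as the median of per-criterion optima with ties
broken downward. The ensemble approximates published multi-criterion
selection schemes whose exact composition varies across tools; its
members and the aggregation are configurable.

Group templates come from re-clustering the pooled subject-level template
maps (each subject contributes k maps, one vote each; subject maps are
unit-norm by construction, so pooling is implicitly GFP-normalized).
Template letters A–E are assigned by optimal matching against five
idealized canonical topographies (two diagonal gradients, an
anterior–posterior gradient, fronto-central and occipito-central foci on
the spherical layout); the letters are purely cosmetic and never affect a
numeric result — analyses that compare against generator ground truth
must align labels through `match_templates`, not through the letters.

## Back-fitting and temporal parameters

The labeling floor is read strictly: `corr > 0.5` labels a sample,
`corr = 0.5` exactly stays unlabeled. Argmax ties break toward the lower
template index. No temporal smoothing or minimum-duration rejection is
applied by default (`min_duration_ms` exists as an opt-in knob). The GEV
denominator includes all unmasked samples, labeled or not, keeping GEV a
fraction of total signal variance; coverage likewise uses total unmasked
time as its denominator. Runs truncated by a mask boundary still count
toward duration and occurrence — excluding them would bias durations
downward in artifact-rich recordings.

## Transition syntax

Transitions are counted only between directly adjacent labeled runs
(configurable bridge, default 0 samples). The expected matrix renormalizes
coverage proportions without the source state, `E_ij = c_j/Σ_{m≠i}c_m`,
which makes the observed/expected ratio exactly 1 under memorylessness
(tested against i.i.d. sequences) and exactly 1 for any two-state
sequence (only one destination exists). Coverage is the base measure;
occurrence frequency can be passed instead by the caller. Edge-wise group
comparison always uses the Welch t-test with BH-FDR over the K(K−1)
edges, unlike the normality-gated choice used for temporal parameters.

## Group statistics

"Unpaired t-test" is implemented as Welch (unequal variances) throughout;
pooled-variance is not the default anywhere. The normality gate is the
D'Agostino–Pearson omnibus test at α = 0.05 per sample, with a validity
floor of n = 8 below which the rank test is used with a warning. FDR
blocks: one block of 20 (5 maps × 4 parameters) for temporal parameters;
per-instrument blocks (ADOS/MSEL/CBCL, unknown scores in their own block)
for clinical correlations; one block of K(K−1) for transitions. The
male-only sensitivity analysis is a row filter (`subset="sex == 'M'"`),
not a separate code path. Bootstrap subsampling draws with replacement
within each group (so n may exceed the group size), default 500 resamples
per n over n = 3..47, two-tailed t-test at α = 0.05.

## Synthetic cohort generator

The generator emulates the structure the microstate model assumes and the
study conditions it is tested under: 110 channels on a spherical
(Fibonacci) sensor cap, 125 Hz, 300 s per subject, five template maps,
group sizes 66/47, contiguous artifact blocks (10% of time in ~5 s
blocks), and per-group per-map mean-duration and coverage targets equal
to the reference cohort's printed group means — so the map-B group effect
(duration ×1.053, coverage ×1.22, occurrence ×1.15) is injected by
construction. `effect_scale` interpolates the ASD targets toward the TD
values (0 gives a null cohort).

State sequences are semi-Markov: explicit gamma-distributed durations
(shape 2, chosen for positivity and realistic right skew) make duration
and occurrence independently controllable, which a first-order chain
cannot do. The embedded chain has `P_ij = u_j/(1−u_i)`; its stationary
distribution is ∝ `u(1−u)`, so the weights that realize the target run
frequencies are obtained by solving `u_j(1−u_j) ∝ cov_j/dur_j` by
bisection. EEG is rendered as `template[L(t)] × A sin(2πft+φ_run)` (10 Hz
carrier, random phase per run — the sign alternation is what exercises
polarity invariance) plus spatially structured dipolar noise with a 30%
white component, scaled to a template-to-noise amplitude ratio (SNR) of
10, a realism choice reflecting the high SNR of cleaned resting EEG at
GFP peaks. Subjects get jittered copies of the cohort templates
(jitter SD 0.15 of a unit-norm map). Clinical columns are drawn from the
reference cohort's printed per-group moments with its missingness rates;
configured couplings replace a score's noise with a correlated mixture of
the subject's true parameter (default: CBCL affective problems vs true
map-B coverage, ρ = 0.4).

What the generator does **not** emulate: biophysical forward modeling
(no head geometry, no 1/f background spectrum), ocular/muscle artifact
waveforms (the mask stands in for artifact handling), inter-electrode
noise correlation structure of a real net, and label-free transitions
between non-adjacent topographies. Passing recovery tests therefore show
the pipeline is correct under its own model assumptions, not that a real
cohort would yield these effect sizes.

Two quantitative consequences of the generative model are worth knowing.
First, estimated mean durations are attenuated (~30% at SNR 10) relative
to ground truth because the sinusoidal carrier passes through zero within
a state, and near those crossings the topography is noise-dominated and
the run breaks; the attenuation is common to both groups, so group
*ratios* survive within a few percent and across-subject correlation with
truth stays high. Real recordings do not null the topography at GFP
troughs, so this is a worst case of the generator, not of the method.
Second, the reference cohort's printed occurrence (~2.4–2.5/s) is
arithmetically inconsistent with its printed coverage/duration
(coverage/duration ≈ 2.9/s) under exhaustive labeling; the generator
follows duration and coverage, so absolute occurrences come out near
coverage/duration while between-group occurrence ratios match.

## Problem sizes used in the test suite

The suite exercises the full pipeline on reduced cohorts chosen as the
package's own verification scale: 5+5 subjects × 60 s for the pipeline
property tests and 6+6 subjects × 300 s (the study's record length) for
the recovery checks, with 8 k-means restarts; the generator's defaults
remain at the study scale (66/47 × 300 s, 50 restarts). Monte-Carlo
checks use 2000–4000 replicates where a ±7-point tolerance is asserted
and seeded RNGs everywhere; hypothesis-based property tests run
derandomized.

## Known limitations

* The meta-criterion ensemble approximates, but is not identical to, the
  seven-criterion scheme used by some commercial tools; on well-separated
  synthetic data all five members agree.
* EDF output is 16-bit quantized (error ≤ range/2¹⁶); CSV output
  round-trips bit-exactly.
* `select_optimal_k` fits every k in the scan range serially; for
  ~10⁴ peak maps and k ≤ 10 this is minutes, not seconds.
* The normalized transition ratio is undefined for states with no
  outgoing transitions (NaN rows are excluded from group statistics with
  a warning).
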