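# Methods

`natisc` implements the statistical machinery of a two-belief naturalistic
fMRI experiment: every subject watches the same film four times — twice
believing the two protagonists (sisters facing an organ-donation dilemma)
are genetically related, twice believing the younger one was adopted — and
the question is whether that belief changes how viewers' brains, eyes and
bodies synchronize. This note records the models, the defaults, and the
design choices that were genuinely open.

## Inter-subject correlation (ISC)

For voxel v and a pair of runs from different subjects, ISC is the Pearson
correlation of the two BOLD time courses over the run's TRs. Correlations
are variance-stabilized with the Fisher transform z = atanh(r), averaged on
the z scale, and back-transformed with tanh for reporting. Correlations are
clamped to |r| <= 1 − 1e-7 before atanh so degenerate (duplicated) runs
remain finite; zero-variance voxels produce missing values, never zeros,
and missing entries are excluded from all means.

Within one belief condition each subject has `S` viewings (study: S = 2),
and all S² cross-subject combinations are pooled: `S²·N(N−1)/2` pairs, i.e.
1740 at N = 30. Pairs are enumerated in a fixed deterministic order, so the
k-th genetic pair and the k-th non-genetic pair involve the same subjects
and session slots — that matched structure is what the condition contrast
differences.

### Run cleaning

`clean_bold` residualizes each run on [intercept | user-supplied confounds
| discrete-cosine drift basis] in a single joint least-squares projection,
so residuals are exactly orthogonal to every regressor (sequential
filtering would not guarantee this). The motion confound set is the
24-regressor expansion (6 rigid-body parameters, their backward
differences, and both squared); tissue-signal regressors are accepted as
extra columns rather than computed from atlases. The drift basis contains
every discrete-cosine component below the cutoff (ISC path default 0.01 Hz)
plus one guard component at/just above it — without the guard, drift whose
phase the cosine terms represent poorly leaks through (a half-cutoff
sinusoid retains ~1% of its power; with the guard, ~0.5%).

### Condition contrast and its permutation null

Observed statistic: per voxel, the one-sample t of the matched-pair
differences Δz_k = z_A,k − z_B,k. Pair values are not independent (pairs
share subjects), so pair-level permutation would be invalid; the
exchangeable unit under "belief does not matter" is the subject. Each
permutation swaps the genetic/non-genetic session sets of a random subset
of subjects and rebuilds the pooled statistic. A swap affecting exactly one
member of a pair turns both of the pair's entries into mixed-condition
correlations, so the design precomputes four tensors per pair — AA, BB, AB,
BA — and every permutation reduces to signed indexing (two matrix products
per batch of permutations; no correlation is recomputed). Two-sided p with
the (1 + k)/(1 + n_perm) floor, then Benjamini–Hochberg FDR at q = 0.05
within the analysis mask. The FDR t-threshold is data-dependent and
reported from the map itself, not treated as a constant.

A subtlety the synthetic experiments exposed: the generator draws an
independent stimulus course per condition, which models a *real* belief
effect on processing. Under that generative model, equal couplings in the
two conditions is **not** a null for subject-level exchange — swapping one
subject manufactures mixed pairs with zero expected correlation, and the
measured voxelwise type-I rate was ~0.09. Physically, all four viewings
show the same film, so the correct belief-null carries one
belief-independent shared course common to all viewings
(`EffectRegion(condition="both")`). With that null the test is calibrated
(measured type-I 0.047–0.053 across seeds at nominal 0.05; permutation
p-values pass Kolmogorov–Smirnov uniformity).

### One-group ISC significance

The one-group test (is ISC > 0 at all?) uses a circular-time-shift
surrogate null: each permutation rotates every run by an independent random
offset of at least 10 TRs, preserving autocorrelation while destroying
stimulus locking. One-sided p on the mean-z statistic, then BH-FDR. This
operates on runs, not on a precomputed correlation tensor — time shifts
cannot be applied to correlations after the fact.

### Cluster filter and conjunction

Significant-voxel masks can be cleaned by removing connected components
smaller than a minimum extent (default 64 voxels = 4×4×4) with 6-neighbour
connectivity by default (26 available); the filter is idempotent. The
conjunction with the GLM localizer is the intersection–union test: the
voxelwise maximum of the two p-maps, BH-FDR corrected at q = 0.05.

## GLM localizer

The moral-dilemma decision task is modelled with a boxcar spanning each
trial from identity revelation to button press, convolved with the
canonical double-gamma HRF (gamma-density difference; peak delay 6 s,
undershoot delay 16 s, ratio 1:6, unit dispersion — the convention of the
mainstream analysis suites, since only "canonical" is specified). The
boxcar is built on a TR/16 grid and sampled at TR onsets. Drift columns are
the discrete cosines with periods above 128 s (plus the guard component);
baseline is implicit (all non-decision time, including the narrative
lead-in), as no explicit baseline regressor is specified. First level is
per-voxel OLS; rank-deficient designs are an error naming the most
collinear column pair.

Second level: one-sample t over subjects' contrast maps, enhanced with TFCE
(E = 0.5, H = 2, 26-connectivity, dh = max/100 by default), sign-flip
permutations, family-wise correction by the max-TFCE null distribution,
significance at corrected p < 0.05. The TFCE threshold sweep uses the
midpoint quadrature rule, whose O(dh²) bias keeps the default 100-step
sweep within 1% of a fine-step sweep (an endpoint rule does not); the
single-voxel analytic value h³/3 and the uniform-block value e^0.5·h³/3 are
reproduced to the quadrature tolerance.

## Eye-gaze ISC

Saccades are samples whose speed exceeds 30°/s or whose acceleration
exceeds 4000°/s²; maximal runs of the remaining valid samples are fixations
at their centroid, with invalid (blink) samples splitting fixations.
Recordings failing quality control — blinks above 10% of the duration, or
a majority of interruptions of 1 s or longer — can be dropped with
`qc_gaze`. Session drift is removed retrospectively by rigidly shifting
each recording's fixation cloud so its mean coincides with the grand mean
across recordings (exact by construction).

Heatmaps: each fixation is a Gaussian of σ = 1° truncated at 3σ, rendered
on a 0.25°/cell grid (σ is the binding spatial scale; the grid just
needs to resolve it), accumulated in 2 s windows matching the TR; a
fixation contributes to every window it overlaps, with unit mass by default
(duration weighting by flag). The kernel is normalized over its truncated
discrete support, so mass conservation is exact away from screen edges;
normalizing over an infinite support would lose the 2-D tail mass
exp(−4.5) ≈ 0.011 per fixation. A 23 min 44 s recording yields
ceil(1424/2) = 712 windows.

Pairwise eyeISC is the Pearson correlation of flattened heatmaps per window
and recording pair, Fisher-transformed; windows missing or constant in
either member are missing. The group statistic compares the mean pairwise
eyeISC (z-averaged, back-transformed) of both-genetic pairs against
both-adopted pairs; mixed pairs are computed but excluded. The null
permutes recording group labels (two-sided exceedance with the permutation
floor; default 100 000 permutations).

Because the group statistic measures *within-group* agreement, a gaze
perturbation shared by every member of a group is invisible to it. The
generator therefore plants group effects stochastically: each recording of
the affected group independently follows a displaced attractor sequence
with probability 0.5 per dwell, which degrades that group's internal
agreement. Measured on synthetic cohorts: null false-positive rate 2–5%
over 100 simulations; a 5° displacement at 20 recordings/group is detected
at p ≈ 5e-4.

## Ancillary statistics

- **Framewise displacement**: FD_t = Σ|Δtrans| + 50 mm·Σ|Δrot| (rotations
  in radians on a 50 mm sphere, the motion-QC convention; configurable).
  QC: ≥90% of TRs under 0.5 mm.
- **Similarity permutation test** (motion, physiology): pair similarity is
  the negative absolute difference of scalar summaries, or the Fisher-z
  trace correlation; a two-sample t contrasts same-condition-A vs
  same-condition-B pair similarities, with recording-label permutation.
  Raw (unranked) distances are used.
- **TOST equivalence** on the standardized scale: t∓ = (d ∓ Δ)·√n, df =
  n − 1, equivalence iff both one-sided p < α. This reproduces the study's
  worked values: d = 0.33, Δ = 0.68, n = 30 gives t(29) = −1.92,
  p = 0.033; and t = 2.77 at df 29 maps to one-sided p = 0.005. Raw-score
  entry converts via d = mean/SD, Δ_raw = Δ·SD.
- **Mantel test**: Pearson correlation of strict upper triangles under
  joint row/column permutation of one matrix; 5000 permutations by
  default, permutation-floor p.
- **Time-point rating tests**: 5 Hz valence/arousal traces are
  block-averaged to the 2 s TR grid (the resampling is unspecified
  upstream; block means are the least-assumption choice), then a
  two-sample permutation t per time point with BH-FDR across time (the
  correction method across time is likewise a documented choice).

## Synthetic cohorts and what they do not show

`simulate_bold_cohort` plants, per condition, a shared low-pass-filtered
Gaussian stimulus course (cutoff 0.1 Hz, mimicking the slow autocorrelated
component of naturalistic BOLD) in configurable voxel boxes of a phantom
grid (default 16×16×8 so experiments run in seconds). A voxel with
coupling w carries w·s(t) + noise; with unit-variance s the true pairwise
ISC is c = w²/(w² + σ_noise²), inverted by `weight_for_isc`. The two
same-condition viewings of a subject share s but not noise — exactly what
makes same-condition cross-subject pairs correlate. Ancillary streams:
motion as smooth random walks (step 0.01 mm / 2e-4 rad per TR, optional
spikes), heart ~62 ± 4 bpm and breathing ~15 ± 2 min⁻¹ as slow positive
traces, ratings at 5 Hz bounded to [−1, 1] and [0, 1]. Gaze: fixation
dwells ~ Gamma(2, mean 0.35 s), 30 ms linear saccades, 0.01° sample
jitter, per-recording constant drift. All generators are bit-reproducible
given a seed.

The phantom has no spatial autocorrelation, no scanner drift or spike
artefacts, no hemodynamic coupling between the ISC signal and the task
regressors, and isotropic noise; passing tests therefore demonstrate the
correctness and calibration of the *statistics* under the stated model,
not robustness to real-scanner artefact structure. Effect sizes for the
belief contrast are calibration choices (no empirical estimate exists to
emulate), fixed once: couplings are expressed as target ISC values with
noise SD 0.8.

## Problem sizes

The calibration and recovery experiments in `natisc.validation` (also run
by `scripts/acceptance.py`) use: type-I calibration — 200 null cohorts,
N = 8, T = 150, 200 permutations, 4×4×2 phantom; recovery — one cohort,
N = 12, T = 300, 1000 permutations, 8×8×4 phantom with a 4×4×4 planted
box; eye-gaze null — 100 cohorts of 6 recordings/group, 12 s each, 2000
permutations; planted gaze effect — 20 recordings/group, 20 s, 2000
permutations. The grid and duration choices are the package's own: the
statistics are per-voxel/per-window, so modest grids measure the same
operating characteristics as large ones.

## Known limitations

Registration, smoothing and slice-timing are out of scope (inputs are
assumed spatially normalized); ISC inference is permutation-only (no
parametric or mixed-effects variants); cluster extent filtering is
descriptive, not a corrected cluster-level inference; gaze input must
already be in degrees of visual angle (pixel conversion is the caller's
responsibility); physiological rates are taken as given, not estimated
from raw recordings.
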