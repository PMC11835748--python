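# Methods

## Model and pipeline

The pipeline treats multi-subject ROI fMRI during naturalistic viewing as
realisations of a shared K-state Gaussian-observation hidden Markov model:
each volume belongs to a latent state k with region-wise mean `mu_k` and
covariance `Sigma_k`, and states switch according to a row-stochastic
transition matrix `A`. All subjects share one parameter set (the
group-level model), so states are directly comparable across subjects; the
forward–backward and Viterbi recursions restart at every subject boundary
with the shared initial distribution, so concatenation never manufactures
a transition between two different subjects.

Inference is expectation–maximisation (Baum–Welch) in the log domain
rather than variational Bayes. EM is deterministic given its
initialisation, dependency-free, and its maximised log-likelihood plays
the same model-order role in AIC that a variational free energy plays in
free-energy-based selection; we consider this a faithful substitution for
the scientific question (how many states, and where is each subject at
each time), not an approximation of the original tool's posterior.

Model order K is chosen by AIC = 2p − 2 log L with
p = (K−1) + K(K−1) + KR + K·R(R+1)/2 for full covariances. AIC selection
is exposed (`select_k`) and verified on synthetic cohorts; the real
study's per-K criterion values are not public, so no particular K is
treated as a reproducible target.

### Inter-subject consistency and its nulls

The core statistic is windowed consistency: the percentage of a group's
subjects whose decoded path contains state k at least once in the window
[v−w, v+w] (w = 3 volumes, a 7-TR window; edge windows truncated).
"Expressed the state in the window" is read as presence at ≥ 1 volume,
which is what anchors the score at 0% (nobody) and 100% (everybody).

Two nulls, both thresholded at their 95th percentile:

* **Between-group**: the cohort is re-split at random (without
  replacement) into pseudo-groups of the two original sizes, `n_iter`
  times, giving a state × volume percentile surface per group size. This
  null preserves everything about the cohort except the clinical labels.
* **Within-group**: surrogate paths are simulated from the group's
  empirical transition matrix — pooled transition counts over the group's
  decoded paths — one surrogate per member, uniform random initial state,
  same length, same window truncation. Surrogates keep each subject's
  marginal dynamics but destroy cross-subject temporal alignment. The
  consistency of each surrogate set is averaged over volumes, giving one
  scalar per state per iteration (matching the single horizontal
  reference line usually drawn per group); a per-volume variant and a
  pooled-across-states variant are available behind flags, and the
  surrogate generator can equally be driven by the joint HMM's transition
  matrix via the `transmat` argument. A state row with no observed exits
  falls back to a self-transition convention and is flagged.

A volume is reported only when the observed curve exceeds **both**
thresholds and lies inside the positive-scene mask; contiguous runs become
events ranked by duration.

### Scene masks and timing conventions

Volume indices are 0-based; scene intervals are half-open
`[onset, onset + duration)` in absolute movie seconds. The movie starts at
the first retained volume, so a post-trim volume v maps to time
`(v + trim_start)·TR`, and a volume belongs to a scene iff its acquisition
onset falls inside the interval. Half-open intervals make adjacent scenes
partition time without double counting. Dwell times and transition counts
are restricted to contiguous masked segments: a run or a transition pair
that crosses a mask gap is truncated, never bridged.

### Group statistics

Occupancy and dwell features use two-tailed pooled-variance t-tests with
max-statistic permutation FWE (the FWE mechanism is a design choice; the
max-|t| null is the standard nonparametric one). Transition matrices use
an NBS-style test: edge-wise t threshold (a required analysis parameter,
deliberately not defaulted), weakly connected components of the
supra-threshold directed graph, extent (edge count) as the component
statistic, maximal-component-size permutation null. On exchangeable
synthetic groups these tests flag nothing above chance, reproducing the
negative dynamics finding qualitatively.

### Facial analysis

Sixteen emotion-relevant AUs enter the analysis; AU45 (blink) is parsed
but excluded. Means are taken over valid frames only (tracking failures
are missing, not zero). Group comparison is pooled-variance t by default —
this choice reproduces the printed cohort-table t values from their
printed summaries — with Welch as an option; BH-FDR is applied across the
16-AU family. The t statistic is signed as non-melancholic minus
melancholic, matching the reporting convention of the cohort table. PCA
pools all subjects' frames group-blind (so PC-score group comparisons are
not circular) and fixes the axis sign so the six smile AUs (06, 07, 09,
12, 14, 25) load positively. Both per-subject mean PC scores and full
score series are returned, since either could be the compared quantity.

### Brain–behaviour coupling

The epoch coefficient is an OLS fit of each trace on an intercept plus
unconvolved boxcar; it equals the scene-minus-rest mean difference exactly
(asserted as an algebraic identity in the tests). The interaction analysis
fits `beta ~ 1 + group + facial + group:facial` and tests the interaction
by extra sum of squares, F(1, n−4). Voxelwise discovery of the cerebellar
cluster is out of scope (it requires voxel data); the pipeline operates on
supplied region traces, with identical interaction machinery. Points
beyond 2.5 SD of their group mean are reported but never removed. No
covariate adjustment (medication, motion) is applied at the group level.

## Synthetic cohorts: what they emulate, and what they do not

`synthcohort` generates the study conditions: two groups of 30 and 40
subjects, ~1400 retained volumes at TR 0.81 s, 25 regions, latent state
paths from a sticky Markov chain (diagonal ≈ 0.85, the empirical regime of
fMRI state sequences), Gaussian emissions with pairwise mean separation
≥ 5 (spherical unit covariance by default). Planted synchrony acts on the
*latent paths* — each volume of the window forces the planted state with
probability `adherence` — so the HMM stage genuinely has to recover the
epoch from signal; emissions always follow the final path. AU series are
stationary AR(1) noise (coefficient 0.3, SD 0.3 at 10 fps) plus
gamma-shaped event-locked bumps whose amplitude on the six smile AUs is
0.4 in group A versus 1.0 in group B (melancholic blunting); the epoch-
behaviour generator uses group slopes (−0.1, −1.0) with noise SD 0.25 as
the blunted-coupling fixture.

Not emulated: haemodynamic convolution, realistic fMRI noise spectra,
head-motion artefacts, inter-regional background correlation, or
individual anatomy. Passing tests therefore demonstrate that the
*statistics behave as designed* (calibrated nulls, recoverable planted
effects, correct oracles) — not that real acquisitions satisfy the
generative assumptions.

## Numerical choices

* EM: relative log-likelihood tolerance 1e-4, up to 500 iterations, 5
  seeded k-means-initialised restarts by default (best final likelihood
  kept, ties by restart order). Covariance updates receive a ridge of
  1e-6 × mean variance, escalated tenfold while a Cholesky factorisation
  fails, then a degenerate-fit error.
* Viterbi ties break toward the lexicographically smallest path: the DP
  stores best-completion scores per (volume, state) and the forward walk
  takes the lowest-index argmax.
* Permutation p-values use the add-one convention
  `(1 + #{null ≥ obs}) / (n_perm + 1)` for random permutations and the
  exact fraction under full enumeration.
* Degenerate inputs are errors where silence would corrupt results
  (constant traces, empty masks, all-missing AU series, collinear boxcar
  designs) and flagged conventions where a value is still well-defined
  (absorbing transition rows, never-visited states as NaN dwell).

## Problem sizes used in the verification suite

The acceptance computations run the full study scale for HMM recovery
(70 subjects × 1400 volumes × 25 regions, K = 12, 2 restarts) and a
reduced synchrony scale chosen for tight Monte-Carlo error at desk time:
6 states, 8 regions, 22 subjects, 250 volumes, 200 null iterations, 100
cohorts for calibration and 20 seeds for planted recovery; ANCOVA
calibration and power use 500–1000 replicates. These sizes are the
package's verification conditions, stated here so they can be scaled up
by anyone wanting tighter estimates.

## Known limitations

* EM log-likelihood is not the variational free energy; AIC values are
  comparable within this package only.
* The between-group null shares subjects with the observed curves, so a
  very strong event expressed by much of the cohort raises its own
  threshold; this is inherent to the design, which asks whether one
  *labelled* group exceeds what any same-sized group would show.
* Consistency treats decoded paths as data, ignoring decoding
  uncertainty.
* The NBS edge threshold is analysis-defining and left to the user.
* Ragged AU recordings (different frame counts per subject) are supported
  by the statistics but the generator emits equal-length series.
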