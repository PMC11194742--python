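# Methods

## The design being modelled

A two-arm randomized controlled trial: preschool children assigned to a
Letter (treatment) or Language (control) curriculum, measured with MEG
before and after the two-week intervention while viewing Words, Faces and
Cars (30 trials per category per session).  The scientific questions map
onto four statistical objects: a group × condition × time interaction in a
word-selective ROI (differential tuning change), temporal clusters of
group differences in change scores (window-free localization),
condition-by-group models at each time point (selectivity before/after),
and correlations between per-subject category change scores (competition
vs shared gain).

## Synthetic data generator

Each trial of each channel is

    scale_type × ( gain_subject × A[group, condition, session] × k(t) + ε(t) )

where `k(t)` is a unit-peak Gaussian kernel (latency 0.180 s, width
σ = 0.040 s), `A` the group × condition × session amplitude matrix
(arbitrary units, default 5.0 everywhere = the pre-intervention
"no selectivity" state), `gain_subject ~ N(1, 0.15)` a multiplicative
per-subject gain shared across all of a subject's cells (inducing the
random-intercept structure and a shared-gain coupling between categories),
and `ε` stationary AR(1) noise with marginal SD 3.0 and lag-1
autocorrelation ρ = 0.234.

Parameter rationale (all fixed once, with units):

- **sfreq = 100 Hz** — decimated sampling of a 40-Hz low-passed signal;
  it also places the 180 ms peak exactly on the sampling grid.  The
  analysis window then spans W = 11 samples.
- **peak latency 0.180 s** — within the 175–185 ms range a first evoked
  peak occupies in this ROI in this age group.
- **ρ = 0.234** — the theoretical lag-1 autocorrelation of ideal 40-Hz
  low-passed white noise sampled at 100 Hz, sinc(2·f_c·Δt).  Colored noise
  matters specifically for the cluster stage: with white noise the
  supra-threshold t course fragments into single-sample runs, which real
  low-passed recordings do not do.  Set `noise_ar1 = 0` for white noise.
- **channel_type_scales (1, 20)** — stands in for the gradiometer vs
  magnetometer scale disparity, so per-type rejection thresholds are
  separately exercised.
- **artifacts** — with probability 0.05 per trial, a 50 ms square
  transient of amplitude 250 (≫ any clean peak-to-peak) lands on 10% of
  the channels of one randomly chosen type.  Config validation enforces
  the separation `artifact_amplitude > max(A) + 7·noise SD`.
- **2 × 24 subjects, 30 trials/condition, epochs −0.1 to 1.0 s** — the
  trial's design constants.

**Effect-size convention.**  Planted interventions are expressed in units
of the *within-subject SD*: the trial-to-trial SD of the window-averaged
ROI response, `σ·sqrt(f / (C·W))` with C = 6 ROI channels and f the AR(1)
inflation of a W-sample mean (f ≈ 2.4 at ρ = 0.234, giving ≈ 0.458 units
by default).  Under this convention a 1-SD planted effect yields a
subject-level change-contrast effect size of d ≈ 2.2 at the window level
and ≈ 0.7–0.9 per sample near the peak — strong but not trivial for both
the mixed-model and cluster stages at n = 24/group.

What the generator does **not** emulate: realistic sensor geometry and
forward physics, spatially correlated noise across channels, heteroscedastic
or non-Gaussian trial noise, eye/cardiac artifact morphology, or
session-specific gain drift.  Tests passing on this generator therefore
demonstrate the correctness and calibration of the *statistics*, not
robustness to every failure mode of real recordings.

## Rejection tuning

Peak-to-peak amplitude = max − min over the epoch, per channel and trial;
a trial is rejected iff any channel exceeds its type's threshold.  The grid
search scores each threshold pair by the mean across subjects of the
Pearson correlation between pre- and post-session grand-average evoked
courses (all conditions pooled over retained trials, post-stimulus samples
only) in the tuning ROI; cells that empty any subject × session ×
condition cell are untenable.  Choices made where the procedure is
underdetermined:

- tuning-ROI aggregation is a weighted channel mean; the pipeline uses
  scale-equalized weights (1 / per-type median peak-to-peak) so artifacts
  on either sensor type degrade the objective;
- the correlation uses the full post-stimulus epoch (baseline excluded);
- ties among optimal cells resolve to the most permissive pair (largest
  retained-trial count, then larger thresholds in channel-type order);
- candidate grids are log-spaced between the 50th and 100th percentile of
  the observed peak-to-peak distribution per type;
- zero-variance evoked courses are excluded from the objective mean with a
  logged warning rather than propagating NaN.

## ROI aggregation and the analysis window

With `data = U S Vᵗ` (singular values decreasing), the ROI course is
`sign × (‖S‖₂/√n_vertices) × Vt[0]`, sign = sign⟨U[:,0], flip vector⟩; the
scale matches mean per-vertex power and the flip vector carries the
dominant dipole orientations.  All-zero input returns all zeros.

The analysis window is the first local maximum of the grand-average
waveform within 50–500 ms whose prominence exceeds 10% of the waveform's
range ("first peak" is ill-defined under noise without a prominence floor),
± 50 ms, closed on both ends, snapped to the sampling grid.  The grand
average pools **pre-intervention data only** by default: pooling post data
would let a post-only effect move the window that the post statistics are
then computed in.  Window means use every sample with start ≤ t ≤ end.

## Mixed models

Fixed effects are dummy-coded (references: Language, Words, pre).  The
three-way model's random structure is per-subject intercept plus slopes for
condition, time and condition × time (correlated).  Estimation is REML —
via a fast profiled criterion specialized to balanced designs (all subjects
sharing one within-subject design matrix), falling back to statsmodels
MixedLM in the general case.  Denominator degrees of freedom use the
Satterthwaite approximation: for contrast L,
`df = 2 (L C L')² / (gᵗ A g)` with `C(θ)` the fixed-effect covariance,
`g = ∂(L C L')/∂θ` and `A` the inverse expected REML information
`I_jk = ½ tr(P V_j P V_k)` over the variance parameters θ = (vech G, σ²).
Multi-df F tests use the eigenvector-averaged df.  A dedicated test checks
F, t, SE and df against R lmerTest on a well-posed fixture (agreement to
≤ 0.1% on statistics, ≤ 2% on df).

Two structural caveats, both visible in `convergence_report`:

- With one observation per subject × condition × time cell, the maximal
  structure is saturated (6 observations, 6 random effects): the variance
  split between G and σ² is unidentified, though the fixed effects, their
  covariance and the Satterthwaite df (≈ n_subjects − 2) are.  Wald
  statistics can wobble ~1% with the optimizer path along this ridge.
- The convergence ladder only ever simplifies the random structure
  (full slopes → additive slopes → time slope → intercept → OLS), never
  the fixed-effect coding; in the exactly-noise-free limit the ladder ends
  at OLS, which reproduces generating coefficients exactly.

Main-effect F's in single-time models are Type-III style: marginal-mean
contrasts averaged over the other factor, built directly on the dummy
coefficients.  No multiple-testing correction is applied beyond the a
priori window and the cluster-level correction — deliberately mirroring
the trial's inferential structure.

Cohen's d uses the equal-n pooled SD `sqrt((s₁² + s₂²)/2)`; two-sample
power comes from the noncentral t with noncentrality `d·√(n/2)` and
df = 2n − 2.

## Cluster permutation

Pointwise two-sample pooled-variance t on 0–500 ms; cluster-forming
threshold = two-sided p < 0.05 t quantile at df = n_A + n_B − 2; clusters
are maximal same-sign supra-threshold runs with mass = Σt; the null is the
maximum |mass| over clusters per permutation (subject labels permuted,
group sizes preserved); p = (1 + #{null ≥ |mass|})/(1 + n_permutations),
never zero.  Exhaustive enumeration replaces Monte Carlo on request (or in
tests at 4+4 subjects).  Zero-pooled-variance timepoints get t = 0 with a
warning — they cannot seed clusters.  Note that MNE's two-sided
permutation H0 records the maximum *signed* cluster sum; this package
follows the max-|mass| convention, so cluster p-values are not expected to
coincide with MNE's for signed statistics (the observed clustering and the
null distribution of max signed mass do coincide, which is what the
cross-check test asserts).

## Competition correlations

Per-subject change scores Δ_condition = window mean(post) − window
mean(pre); Pearson r between Δ_words and Δ_faces or Δ_cars, two-sided p
from the exact t transform of r (no permutation — n = 24–48 with
approximately Gaussian window means).  Reported subsets: full sample and
Letter-only, the trial's two inferentially relevant strata.

## Problem sizes and numerical conventions

Calibration checks use 500 simulations (null cluster FWER at 24/group,
100 timepoints, 512 permutations; null three-way interaction at 24/group)
and 100 end-to-end studies at the default study size — sizes chosen so the
binomial noise on a 5% rate (SE ≈ 1%) is well inside the asserted [3%, 8%]
band while the whole suite stays fast on a single CPU.  Times are seconds
internally and milliseconds only in reports; stimulus onset is t = 0.
JSON output is serialized with sorted keys and repr-exact floats, so equal
seeds give byte-identical reports.  All randomness flows through
`numpy.random.default_rng` seeds recorded in every output together with a
configuration hash.

## Known limitations

- Sensor-space stand-in: ROI membership arrives as channel weights; no
  source localization, atlases or morphing.
- Temporal-only clustering; no spatial or spatiotemporal adjacency, no TFCE.
- The Satterthwaite layer uses the expected (not observed) REML
  information; at variance-boundary fits the df is approximate in the same
  way lmerTest's is.
- The generator's artifact model (square transient on one sensor type) is
  deliberately simple; it exercises the threshold logic, not artifact
  taxonomy.
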