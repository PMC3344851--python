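# Methods

## Signal model and phantom generator

A phantom run is a noisy linear mixture on a 24×24×24 grid of nominal 3 mm
isotropic voxels, 300 volumes at TR = 2 s (desk-sized, but with the temporal
structure of a 10-minute resting-state acquisition):

```
Y(v, t) = Σ_l  a_l · c_l(t) · M_l(v)  +  ε(v, t),   ε ~ N(0, 1/snr²)
```

with six latent sources `l`:

| source       | spatial map M_l                               | time course c_l                 | amplitude a_l |
|--------------|-----------------------------------------------|---------------------------------|---------------|
| network      | 14 positive blobs (7 mirrored bilateral pairs, radius 2 vox) **and** 6 anti-correlated blobs at weight −0.7 | band-limited Gaussian noise, 0.01–0.05 Hz | 1.0 |
| anti_network | 6 separate blobs (disjoint from all others)   | independent 0.01–0.05 Hz noise  | 0.6 |
| global       | strictly positive everywhere (1 ± 0.3 smooth field) | band-limited 0.005–0.05 Hz | 0.7 |
| drift        | gradient along z (0.3–1)                      | monotone linear ramp            | 1.5 |
| spike        | 2-voxel rim of the grid                       | 3-volume block (motion-like)    | 1.2 |
| physio       | inferior slab                                 | 0.2 Hz sinusoid                 | 0.8 |

All courses are unit-variance, so `snr` is the ratio of the network blob
amplitude to the voxel noise SD; the study condition is `snr = 2`
(σ = 0.5).  Blob centers live on a lattice with 5-voxel spacing and 4-voxel
margin, so every pair of radius-2 spheres is disjoint by construction — the
ground-truth masks are exact, which the test oracles rely on.

The anti-correlated regions are negative-weight blobs *of the network
source itself*.  This is deliberate: spatial ICA recovers rotations that
maximize spatial independence, so any region given its own independent
time course will be split into its own component.  Anti-correlation with
the network course survives the decomposition only if the anti blobs carry
no independent degrees of freedom.  The separately-labelled `anti_network`
source (an independent second "network") therefore sits on its own blob
set and acts as a further confound the selector must reject.

**Patient condition.** Patients receive the network course injected into
`n_extra_regions = 2` extra blobs with gain 0.6 relative to the network
amplitude — a pure connectivity increase with no amplitude change in the
core network.  The gain is a calibration choice (no empirical effect size
exists for it); 0.6 at n = 15/13 produces a contrast that survives
cluster-level correction without being trivial.

**Subject variability.** Each cohort subject gets a fresh noise/course
realization and one shared integer translation of all blob centers, uniform
in {−1, 0, 1} per axis, emulating residual normalization error.  A single
shared translation (rather than independent per-blob jitter) preserves blob
disjointness; ±1 voxel (3 mm) was chosen because misalignment on the order
of the blob radius itself (±2 voxels) destroys voxelwise correspondence
across subjects — the group effect in a radius-2 blob is then carried by a
minority of subjects at any given voxel, which no group statistic can
recover and which no real study design would accept for 6 mm structures.

Determinism: every public entry point takes a seed; cohort subject seeds
are derived from the master seed via `numpy` seed sequences, and identical
seeds give bit-identical outputs.

## Preprocessing

High-pass filtering projects each in-mask voxel course onto the orthogonal
complement of [intercept, linear trend, DCT-II cosines with frequency
≤ 0.005 Hz] — a projection, hence idempotent, with none of the wraparound
artifacts of Fourier masking.  Smoothing convolves each volume with an
isotropic Gaussian (default FWHM 8 mm; σ per axis = FWHM/√(8 ln 2) divided
by that axis's voxel size) with nearest-edge replication.  The order is
filter → smooth.  Motion correction, slice-timing and spatial normalization
are out of scope: phantoms are generated in a common grid with no motion.

## Decomposition and ROI derivation

Spatial ICA: voxels are samples, time points are channels.  After PCA
reduction to `n_components` (default 30) dimensions, FastICA (logcosh
contrast, tolerance 1e−4) maximizes the spatial non-Gaussianity of the
maps.  The iteration cap is 200: on phantom mixtures, recovery of the
structured sources is flat between 200 and 1000 iterations — the
directions that fail to converge are near-Gaussian noise rotations that
never converge at any cap — while runtime grows linearly.  Non-convergence
is reported on the result (`converged=False`), which remains usable.
Maps are z-scored in-mask with the scale folded into the paired course;
courses are centered.

Cross-subject clustering is a constrained average-linkage agglomeration on
|spatial correlation|: repeatedly merge the most similar pair of clusters
whose subject sets are disjoint (≤ 1 component per subject per cluster)
until `n_components` clusters remain.  Member maps are sign-aligned to the
member most similar to the rest before averaging.  The network cluster is
identified by best |correlation| with a caller-supplied hint map (phantoms:
the ground-truth network map; real data: an explicit cluster index) —
replacing selection by visual inspection.  Because the cluster's global
sign is ICA-arbitrary, the mean map is re-oriented (hint correlation, or
positive skewness as fallback) before ROI carving.

ROIs: each of 14 target + 6 anti centers (mm) yields the voxels whose
centers fall in a 10 mm cube around it (half-open on the positive side)
*and* pass the map threshold (mean map ≥ +1 z for targets, ≤ −1 z for
anti).  Empty intersections are hard errors naming the offending ROI.

## Fingerprints

Eleven features per component (feature-set version `rsnselect-fp-1`):
map skewness, kurtosis, 64-bin histogram entropy, clusterness (fraction of
|z| > 2 voxels in 26-connected clusters of ≥ 10), course one-lag
autocorrelation, 64-bin course entropy, and periodogram band-power
fractions for 0–0.008 / 0.008–0.02 / 0.02–0.05 / 0.05–0.1 / 0.1–Nyquist Hz.
The reference fingerprint stores the per-feature mean and a robust spread
(1.4826 × MAD, floored at 1e−6) over known network components.  The weight
is `w_F = exp(−d/11)` with `d` the Euclidean norm of the scale-standardized
deviation; skewness enters in absolute value so the weight is invariant to
the ICA sign indeterminacy.  The exponential form is the simplest smooth
function satisfying the behavioral contract (≈1 for network-like, →0 for
artifact components); the feature list itself is this package's fixed,
versioned choice.

## Selection

ROI mean courses are regressed (OLS) on [intercept + all component
courses]; `dof = n_volumes − n_components − 1` comes from the actual
design (269 for 300 volumes and 30 components) rather than any hard-coded
constant.  The edge threshold is the upper t-quantile at `1 − α/(n(n−1)/2)`
(α = 0.05, 91 pairs for 14 targets).  Graphs use the clique rule — an edge
joins every pair of suprathreshold targets — because each ROI carries
exactly one t-value per component, so thresholding node expression is the
only well-defined edge criterion.  Ties in the score are broken by higher
E, then lower graph index; if *every* score is zero the result is flagged
`no_network` rather than picking arbitrarily.

For group analysis the winning course is sign-corrected (negative-graph
winners are flipped so targets are positively expressed), residualized
against the 29 nuisance courses (making the two-step beta exactly the
full-model partial coefficient, by Frisch–Waugh–Lovell), and normalized to
unit variance so betas are in per-course-SD units comparable across
subjects — without this, per-subject ICA scale differences leak into the
group contrast as a systematic offset.

## Group statistics

One-sample (dof n−1) and pooled two-sample (dof n₁+n₂−2) t maps; zero
variance voxels get t = 0 and a flag.  Voxel inference: Benjamini–Hochberg
over in-mask two-sided p-values at q = 0.05.  Cluster inference: the
minimum cluster size k* such that ≤ 5 % of 1000 simulated null maps —
white Gaussian fields smoothed to the estimated FWHM, thresholded
two-sided at the voxel threshold (applied as the equivalent normal
quantile; identical suprathreshold sets at ~100× less cost than
quantile-transforming to t marginals), 26-connectivity — contain a cluster
of ≥ k* voxels.  The voxel threshold is parameterized by p (default 0.01
two-sided) with t from the actual dof; t = 2.772 appears only as a
regression constant in tests.  Smoothness is estimated from the lag-1
autocorrelation of the statistical map being thresholded
(ρ(d) = exp(−d²/4σ²) for Gaussian smoothing): measured on pure-null
cohorts, residual-based estimates under-represent the blob-scale
between-subject variability and let through too many false-positive
clusters, while the t-map estimate absorbs it.

## Test and calibration problem sizes

The acceptance suite uses: 50 single-subject phantoms at the full study
conditions (300 volumes, 30 components, snr 2) for selection accuracy; one
full 15 + 13 cohort for contrast recovery; and 20 pure-null cohorts of 28
control subjects (split 14/14, so dof stays at 26) at 120 volumes /
12 components for the cluster false-positive check.  The null cohorts are
lighter because the quantity under test — the cluster-wise FPR — depends on
the contrast dof and the beta-map smoothness, not on the run length; dof
was *not* reduced because the Gaussian-field null approximation underlying
the cluster estimator degrades sharply for low-dof t fields (measured:
4/20 false-positive cohorts at dof 8 vs ~1/20 at dof 26).

## Known limitations

* The phantom's sources are not perfectly spatially independent (the
  global, drift and rim maps overlap), so — as in real data — ICA
  separation is imperfect: component courses share variance (notably with
  the motion spike), betas are attenuated relative to the generative
  amplitudes, and the patient-vs-control contrast can show significant
  clusters over artifact-source regions reflecting group-systematic
  differences in variance attribution, not seeded effects.  The selection
  score is designed to survive this (and does, ≥ 90 % on phantoms), but
  contrast cluster tables should be read with the usual ICA caveats.
* The Monte-Carlo cluster threshold assumes a stationary Gaussian random
  field.  The null contrast field on ICA beta maps violates this in a
  specific, quantifiable way: when the selected course carries a
  contamination coefficient ε_i from another source (varying by subject),
  that source's *entire* spatial map enters the beta map scaled by ε_i, and
  the two-sample t over the map is spatially constant —
  t = Δε̄/(σ_ε·√(2/n)), one Student-t draw spread over the whole map.  Each
  latent source contributes one such rank-one "mode" per cohort, and
  between-subject anatomical jitter adds blob-scale modes, so a nominal 1 %
  voxel event can arrive as a several-hundred-voxel cluster that no
  smoothness-matched threshold absorbs.  Measured on pure-null phantom
  cohorts (28 controls split 14/14), ~10–15 % of cohorts show at least one
  surviving cluster despite the estimator itself being correctly calibrated
  (3–4 % held-out cluster-wise FPR on stationary fields).  This mirrors the
  documented behaviour of cluster-extent thresholds on real fMRI data;
  contrast cluster tables from ICA pipelines should be read accordingly,
  and permutation-based cluster inference would be the remedy where exact
  cohort-level control is required.
* Gaussian i.i.d. noise, hard-edged spherical sources, no motion fields,
  no slice timing, no EPI distortion, no Rician bias: passing phantom tests
  demonstrates the statistical machinery, not robustness to every real
  acquisition artifact.
* Real-data use requires the caller to supply ROI centers (mm) and either
  a network hint map or an explicit cluster index for the reference stage.
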