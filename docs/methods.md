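# Methods

This note documents the models, defaults and numerical choices behind
`taskrel`, and what the synthetic validation does and does not establish.

## Task model

Each task variant is 100 back-to-back 3 s trials (20 per condition:
auditory, visual, motor, cognitive, null) plus a 10 s buffer — 310 s,
covered by 155 volumes at TR = 2 s. The original stimulus-delivery
pseudo-random order is not public, so the package ships one canonical
permutation drawn from a fixed seed (1861) under the constraint that no
condition repeats more than three times consecutively; the "reversed"
order is its exact reversal. This sequence is a documented stand-in, not
the original: any analysis depending on the *specific* order (e.g. design
efficiency to the third decimal) should treat it as one realization. On
this sequence the four HRF-convolved condition regressors have maximum
pairwise |r| ≈ 0.39.

Stimulus parameters (tone frequencies, grating spatial/temporal frequency,
cue counts, eye-target geometry, working-memory string length) are carried
as immutable metadata only; no audiovisual rendering or behavioural
simulation is performed.

## BOLD simulator

Per subject s and region r the response amplitude has a trait component
a_{s,r} ~ N(μ_r, σ_b²) drawn once, and each session j adds
e_{s,j,r} ~ N(0, σ_w²). The voxel time-series is the sum of
amplitude × HRF-convolved condition regressor over regions containing the
voxel, plus per-voxel Legendre polynomial drift (orders 1–2, coefficient
SD `drift_amp`) and stationary AR(1) noise (per-volume SD σ_n, lag-1
correlation ρ). The population consistency ICC of the amplitudes is then
σ_b²/(σ_b² + σ_w²) by construction, which is what the ICC(3,1) estimators
target. Head motion is a seeded Gaussian random walk written in FSL `.par`
convention; it enters the analysis only as confound regressors — images
are never actually displaced.

Defaults (units are arbitrary signal units; the study they emulate reports
no per-condition effect sizes, so μ_r is arbitrary and documented as such):
μ_r = 1.0, σ_b = 0.5, σ_w = 0.2 (amplitude ICC ≈ 0.862), σ_n = 1.0,
ρ = 0.3, drift_amp = 1.0, motion step SD 0.01. These give single-session
voxel t-statistics around 3–4 in active regions before smoothing —
a realistic regime for a five-minute event-related run — and group maps
that survive Z = 3.1 cluster correction at n = 15.

The default grid is a 20×24×20 volume of 3 mm isotropic voxels with the mm
origin at the grid centre, mimicking MNI-style coordinates so mm-specified
sphere ROIs work unchanged; it is not the MNI152 brain. The five shipped
region/ROI centres (auditory, visual, motor, FEF, DLPFC) are synthetic
placeholders inside this grid — the study's Neurosynth-derived MNI
coordinates are unpublished — and are user-replaceable via TSV/JSON.

What the simulator does **not** emulate: physiological (cardiac/
respiratory) noise, susceptibility dropout, true head-motion image
transformations, spatial heterogeneity of the HRF, non-Gaussian amplitude
distributions, and registration error. Passing tests therefore show that
the estimators are correct and calibrated under the stated generative
model, not that real acquisitions meet that model.

## First-level GLM

Design per run: 4 condition regressors (boxcars on a 0.1 s grid convolved
with a peak-normalized canonical double-gamma HRF — delays 6/16 s,
dispersions 1, undershoot ratio 1/6 — scaled by the 0.1 s step and sampled
at volume times), their backward-difference temporal derivatives, a
24-column extended motion set {p, Δp, p², Δp²}, and a discrete-cosine
drift basis at a 100 s cutoff (constant + floor(2·T/cutoff) cosines;
7 columns for a 310 s run), 39 columns total. Data are smoothed with a
6 mm-FWHM Gaussian (zero-padded boundary) first. Estimation is plain OLS;
no prewhitening is applied (the simulated AR(1) is mild, and session- and
group-level inferences consume effect estimates, not single-run p-values).
Contrasts are each condition's canonical beta against the implicit
null-trial baseline; t maps become Z maps by equal-tail-mass normal
quantile mapping, capped at |Z| = 38 against quantile overflow
(zero-variance voxels get ±38, or 0 when the effect is also 0).

Sessions are combined per subject by inverse-variance-weighted fixed
effects. Group inference is a one-sample OLS t across subjects (not a
Bayesian mixed-effects model): deterministic, desk-scale, and sufficient
because the reliability analyses consume first-level outputs. Group
inference is one-sided (activation > baseline) by default.

## Cluster-extent correction

Supra-threshold voxels (Z > 3.1 by default) form 26-connected clusters.
Under `method="permutation"` the max-cluster-extent null comes from
one-sample sign flips of the subject maps (vectorized; squared data are
sign-invariant, so each flip costs one matrix product), or from
user-supplied null Z maps; a cluster of extent s survives if
(1 + #{null max ≥ s})/(n_perm + 1) ≤ α. `method="fixed_extent"` keeps
clusters of at least k voxels. The extent statistic is discrete, so the
randomization test is valid but conservative when supra-threshold sets are
sparse; calibration is demonstrated at a cluster-forming threshold of
Z = 2.3 on smooth noise, where the extent distribution is rich (measured
familywise error ≈ 3.5–5% at α = 0.05).

## Reliability statistics

`icc31` computes the two-way mean squares vectorially
(BMS, JMS, EMS from the row/column/grand means) and returns
(BMS − EMS)/(BMS + (k − 1)·EMS). Zero subject-plus-residual variance is
signalled as an error (scalar) or NaN (maps), never silently 0. Negative
estimates are reported as computed; flooring at zero would bias the
medians. An exact F-based confidence interval
(F = BMS/EMS, df = (n−1, (n−1)(k−1))) supports coverage checks.

Standardization uses the Fisher variance-stabilizing transform
z = atanh(ICC)·√(n − 3) with ICC clipped to ±(1 − 1e−7); this is
approximately standard normal under the null and monotone in ICC, and is
an approximation adopted because the exact published transform behind the
original maps is not recoverable. For cluster correction of ICC Z maps the
permutation null shuffles the subject pairing of session-2 maps, which
destroys within-subject consistency while preserving marginals. This null
needs a non-trivial permutation space: with fewer than ~8 subjects
(8! ≈ 4·10⁴ pairings) the test is badly underpowered.

Summary measures per condition: median ICC over the voxels surviving
correction (the mask retains original ICC values); the activation-mask
sweep takes plain voxel thresholds (no cluster step) on the cross-session
group activation Z map at 2.3/3.1/3.7/4.3 and reports the median of the
*unthresholded* ICC map inside each mask, with empty masks flagged rather
than dropped; overlap is 100·|ICC mask ∩ activation mask|/|ICC mask|.
Qualitative bands: excellent > 0.75, good 0.6–0.75, fair 0.4–0.59,
poor < 0.4.

## ROI analysis

ROIs are spheres (default radius 5 mm) with affine-aware voxel-centre
distances and inclusive boundary; an empty sphere falls back to the single
nearest voxel. Per matched (condition, ROI) pair the ROI-mean contrast
estimates form the n×2 ICC table; sessions are compared with two-sided
paired t-tests at a Bonferroni-corrected alpha (0.05/8 = 0.00625 for the
two-variant, four-condition family). Two-sided tests are the conservative
default.

## Pipeline

`run_pipeline` chains events → simulate → GLM → reliability → ROI →
report; stages communicate through the output directory (NIfTI-1 maps,
TSV tables, JSON manifest with config hash and versions), so the CLI can
run them individually and every summary cell is recomputable from the
emitted images. All random streams spawn from the single config seed;
reruns are byte-identical.

## Problem sizes and numerical choices

The default study is 15 subjects × 2 sessions × 2 variants on the
20×24×20 grid with 1000 permutations (≈ 45 s on one core). Validation
simulations use deliberately small grids: parameter recovery uses a
200-subject cohort on a 12³ grid with eight independent cubic regions and
near-zero scan noise (recovered mean ICC 0.698 vs true 0.7); familywise
error uses 500 pure-noise group datasets of 12 subjects on a 16³ grid
with 500 sign-flip permutations each. Medians use standard even-count
interpolation; mean-square subtractions clip tiny negative residual sums
at zero; the QR diagonal identifies collinear columns when a design is
rank-deficient.

## Known limitations

Only the two-session, single-measure consistency ICC is implemented
(no ICC(1,1)/ICC(2,1), no >2 sessions). No slice-timing correction,
prewhitening, registration or brain extraction — inputs are assumed
aligned, which is true for the simulator but a real-data user must
preprocess upstream. The group model ignores between-subject variance
heterogeneity (OLS, not FLAME). Cluster inference is extent-based and
discrete; mass- or TFCE-style statistics would calibrate better at high
cluster-forming thresholds.
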