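# Methods

This note documents the models and procedures implemented in `crpconn`, the
parameters that matter, the synthetic-data generator's assumptions, and the
numerical choices made where the design was genuinely open.

## Parcellation and canonical order

All vectors and matrices follow one fixed region order, bundled as
`data/parcellation.tsv`: 180 cortical regions per hemisphere (left block
first), grouped by resting-state module (VIS, MOT, DA, VA, LIM, FP, DMN),
followed by 8 bilateral subcortical structures (thalamus, caudate, putamen,
pallidum, hippocampus, amygdala, accumbens, ventral diencephalon), all
affiliated to module SUB. Regions addressed by name in analyses (POS1, v23ab,
d23ab, 31pv, RSC, a32pr, 10r, 7Pm, FOP1, …) carry HCP-MMP-style labels with
an `L_`/`R_` hemisphere prefix; the remaining cortical labels are synthetic
module-coded placeholders (e.g. `L_FP01`). Since every statistic in the
package is permutation-invariant over region labels, any consistent order is
equivalent; fixing one in the bundled table prevents silent misalignment
between panels, PD vectors and matrices.

## Preprocessing

**Framewise displacement.** FD_t = Σ|Δd| + r·Σ|Δθ| over the six rigid-body
parameters (translations mm, rotations rad), with head radius r = 50 mm
(the field-standard convention; the source analysis names FD without a
formula). FD_0 = 0. A subject is excluded when the FD statistic (mean by
default; RMS available and reported alongside) strictly exceeds 0.3 mm, when
any frame exceeds 1.3 mm, or when the mean inter-regional correlation of the
panel exceeds 0.7 (a systemic-artefact signature). The global-correlation
check runs on the filtered panel by default (the ordering is unstated in the
source design; a flag switches it).

**Volume dropping.** The first 6 of 250 volumes are discarded for
magnetization equilibration, leaving the canonical T = 244.

**Wavelet band-pass.** The MODWT with circular boundary handling is
implemented in `modwt.py` (PyWavelets supplies only filter coefficients; its
undecimated transform requires divisibility by 2^level and cannot handle
T = 244). The default wavelet is the 8-tap least-asymmetric Daubechies
filter, LA(8) ('sym4'). Detail level j has nominal passband
(1/2^(j+1), 1/2^j) cycles/sample; summing the additive MRA details at levels
2–4 at TR = 2.57 s gives 0.012–0.097 Hz, the conventional resting-state BOLD
band. The MRA is exactly additive (Σ_j D_j + S_J = x to round-off), linear,
and zero-phase; FFT checks show a 0.05 Hz sinusoid retains ≈ 99% amplitude
while 0.005 Hz retains ≈ 5%.

**PD normalization.** Regional proton density is divided by the subject mean
(removing global scanner-sensitivity differences), so PD is dimensionless
with unit subject mean.

## Connectome summaries

Functional connectivity is the Pearson correlation of band-limited regional
time series: a symmetric 376 × 376 matrix with unit diagonal. Weighted degree
is the signed mean of a node's 375 off-diagonal correlations (divide by
n−1 = 375; the diagonal is identically 1 and uninformative — the divisor
choice only rescales by ≈ 1.003 and cannot affect inference). No
thresholding or binarization is used anywhere. Modular degree is the mean
degree over one module's member nodes. Group-mean matrices average on the r
scale by default (Fisher-z averaging available). Seed profiles restrict a
node's row to all 375 targets or the 187 same-hemisphere targets.

## Statistics

**Global gate.** Two-sample KS tests compare whole-brain distributions of a
modality between groups; by default the units are group-mean values over
regions/edges (pooled per-subject values optional). Because units are not
independent, these p-values are descriptive; they serve as a gate
(p < 0.05 for any contrast opens the nodal/edge level for that modality,
gating can be disabled). The KS p uses scipy's automatic switch: exact
small-sample null distribution (identical to full permutation enumeration
for continuous data), asymptotic at scale.

**Mass-univariate regressions.** Each unit (region or edge) is fit by OLS
with the MRI measure as response and CRP as predictor plus covariates
(default age + scanning centre, dummy-coded; sex/BMI available). The
regression orientation generalizes correctly under covariate adjustment and
gives the identical slope t-statistic as the reversed simple regression.
PD~CRP uses all participants; connectivity~CRP uses depressed cases only;
case–control contrasts use a covariate-adjusted group indicator. Edge
responses are Fisher-z transformed by default (variance stabilization; raw-r
flag exists). Constant-response units are flagged and assigned p = 1.

**FDR.** Benjamini–Hochberg step-up, implemented directly; q-values are the
monotone-adjusted p·m/rank and significance is the strict q < 0.05. Each
analysis family (nodal PD, nodal degree, 70,500 whole-connectome edges, each
per-seed family of 375/187) is corrected separately. Edge tables also report
the lenient q < 0.1 mask.

**Mediation.** Product-of-coefficients linear SEM: fit m ~ x + covariates
(slope a) and y ~ m + x + covariates (slopes b, c′); ACME = a·b, ADE = c′,
total = a·b + c′ (an exact identity for the point estimates, asserted to
1e-10). Uncertainty by case-resampling bootstrap (default n_boot = 5000)
with percentile CIs; the bootstrap is vectorized over resamples and
deterministic given its seed. When two mediator regions are named (the
d23ab/31pv configuration) their PD is averaged into a composite mediator by
default, with a per-region option. Proportion mediated is reported only when
|total| exceeds a small floor (1e-8) to avoid ratio blow-up. Mediation
defaults to cases only, matching the connectivity~CRP convention; this is
flag-switchable. Percentile-bootstrap CIs show their well-known mild
undercoverage at extreme signal-to-noise; at effect sizes in the range the
analysis is designed for (path t ≈ 4–5), 95% CI coverage is ≈ 94%.

## Synthetic-cohort generator

The generator produces cohorts with the statistical structure the analysis
assumes, with known ground truth. Defaults reproduce the study design:
46 controls, 50 low-CRP cases, 33 high-CRP cases.

**Subject table.** CRP per group is drawn from a truncated normal: truncated
at the 3 mg/L stratification threshold (above for cases with high CRP, below
otherwise, and at zero always), with the parent (μ, σ) moment-matched so the
*post-truncation* mean and sd equal the configured values — HC 0.9 (0.7),
loCRP 1.0 (0.7), hiCRP 5.8 (2.6) mg/L. (Parameterizing the parent directly
with the target moments would inflate the truncated hiCRP mean to ≈ 6.5.)
Age, BMI and sex fractions follow the per-group marginals of the study
summary table; three scanning centres are assigned uniformly. A lognormal
CRP was rejected in favour of the moment-faithful truncated normal because
the downstream analysis uses CRP strictly linearly.

**BOLD panels.** Per subject, a zero-mean stationary Gaussian series
(T = 244, TR = 2.57 s) is drawn from a block-modular covariance: r = 0.3
within modules, 0.05 between. For depressed cases the DMN↔VA/DA blocks are
set to −0.05 (the case-specific anticorrelation pattern) and all entries
involving a DMN node are shifted by −0.03, reducing DMN hubness. CRP-scaled
edge effects (and the embedded mediation outcome) are applied on the
Fisher-z scale and back-transformed, keeping correlations in (−1, 1). If a
modified matrix loses positive definiteness it is projected by eigenvalue
clipping at 1e-8 followed by diagonal renormalization (deterministic);
the default construction is PD without projection.

**PD vectors.** pd_i = 1 + slope_i·CRP + N(0, 0.02), then subject-mean
normalized. The default effect map has 22 positive regions (posterior
cingulate/precuneus, inferior-orbital-polar frontal, medial prefrontal, and
four scattered singles) and 7 negative prefrontal/premotor regions.

**Effect magnitudes are synthetic choices, not estimates** — the source
findings report effect *locations*, not slopes. The PD slope (±0.003
normalized-PD units per mg/L) comes from a power calculation: with noise sd
0.02, pooled CRP sd ≈ 2.6 and n = 129, it gives ≈ 80% per-region power at
the BH-effective nodal threshold (0.05·22/376). Edge slopes are ±0.02
z/mg/L (the two "lenient-threshold" negative edges ±0.012). The canonical
mediation ground truths are sized the same way from the cases-only design
(n = 83): the exposure→mediator path at t ≈ 5 (r_xm ≈ 0.5, a study-like
association strength), and each path meant to be detected at ≥ 99% power
*after* accounting for the variance inflation from mediator–exposure
correlation — so the direct-only preset (a=0.004, b=0, c′=0.015) yields
ADE-significant/ACME-null and the mediated preset (a=0.01, b=1.5, c′=0)
yields ACME-significant, each in well over 90% of cohorts.

**Motion.** AR-style drift-plus-jitter traces whose FD comfortably passes
QC; a configurable fraction of subjects (default 3/132, emulating the
study's motion exclusions) receive a 2 mm translation spike that violates
the max-FD rule.

**Determinism.** One global seed fans out via `numpy.random.SeedSequence`
spawning to per-subject substreams, so outputs are independent of iteration
order and bitwise reproducible.

**What the generator does *not* emulate** — and hence what passing tests do
not show about real data: hemodynamics and autocorrelated BOLD noise (draws
are temporally white, so connectivity sampling error is mildly optimistic
relative to real fMRI), scanner- and site-specific artefacts, spatial
autocorrelation of PD noise, non-Gaussian CRP tails, covariate–outcome
confounding beyond what is injected, and any voxel-level structure. Tests on
these cohorts verify the *statistical machinery* (calibration, error
control, recovery at designed power), not the biological claims.

## Problem sizes used in the test suite

Statistical acceptance checks run at the full study geometry (376 regions,
T = 244, n = 129) with 100 simulated cohorts for recovery rates, 200
replicates for null FDR calibration, and 500 datasets for bootstrap-coverage
calibration; bootstrap sizes in tests are 400–1000 resamples (the library
default is 5000). These sizes put Monte-Carlo error well below the margins
being asserted.

## Known limitations

- The hierarchical gate uses descriptive KS p-values over non-independent
  units; it is a screening device, not a calibrated test.
- BH-FDR assumes positive regression dependence; the generator's modular
  covariance satisfies this in practice, but adversarial dependence could
  inflate FDR.
- The mediation model is linear with no exposure–mediator interaction and no
  sensitivity analysis for sequential ignorability.
- Real-data loaders validate shape and consistency but the package contains
  no image-level processing (no NIfTI, realignment, denoising or atlas
  registration); inputs must already be parcellated.
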