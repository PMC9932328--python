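# Methods

This note documents the models and numerical procedures in `cfqct`, the
defaults and why they were chosen, what the synthetic data do and do not
emulate, and the package's known limitations.

## Phantom generation

**Airway phantoms.** Branches are straight cylindrical tubes (air lumen at
−1000 HU, wall annulus at 0 HU, parenchyma background at −850 HU) embedded
in an HU lattice. Each voxel's value is the volume-weighted mix of the
three materials obtained by 3×3×3 subsampling of the voxel cube — a
binary-edged tube would make any half-maximum edge detector degenerate,
while the subsampled mix reproduces the ramped partial-volume edges of
reconstructed CT. Optional Gaussian noise is added from an explicit seed;
there is no global random state anywhere in the package. The standard
six-lobe builder produces a trachea (G1), two mains (G2) and one chain per
lobe (G3 up to G6 by default), lumens tapering geometrically
(child = 0.8 × parent) with wall thickness tracking the lumen; dilation
factors can be planted at named (lobe, generation) sites to create
tapering violations of exactly known size.

**Paired lung phantoms.** Six disjoint ellipsoidal "lobes" are filled with
Gaussian attenuation: inspiration N(−850, 50) HU, expiration N(−650, 50)
HU — lungs densify on expiration — with defect blobs drawn from
N(−880, 30) HU. Blobs are quasi-spherical, placed by rejection sampling
strictly inside their lobe, topped up by voxel-wise contiguous growth so
the planted voxel count hits the target fraction exactly; the recorded
fraction therefore equals what voxel counting recovers. These phantoms
emulate the attenuation *histograms* the trapping metrics consume; they do
not emulate lung anatomy, respiratory motion, reconstruction kernels, or
spatially correlated noise — conclusions from passing tests concern the
metric implementations, not scanner physics.

**Cohort simulator.** Balanced subject × visit × region tables from the
same generative family the mixed models assume: endpoint = fixed linear
predictor + patient intercept + region-within-patient intercept + residual,
all Gaussian. Baseline age ~ Uniform(8, 16) years (median ≈ 12, the
school-age range of interest) advancing 0/0.25/1/2 years over the
0/3/12/24-month visit schedule. Default fixed-effect scales follow the
fitted lobar models of the motivating analysis (age→BEI 0.046 per year,
A3→WP 0.004 per percentage point on the logit scale, age→LA 0.598 mm² per
year), with intercepts placed so endpoint levels land at the cohort's
medians (BEI ≈ 0.4, LA ≈ 10 mm², WP ≈ 49%). The severe-trapping covariate
A3 is log-normal(meanlog 0.8, sdlog 0.9) — positive, right-skewed, median
≈ 2.2% — and is configurable because no distributional form is claimed for
real cohorts, only medians/IQRs being known. Random-intercept SDs default
to (0.15, 0.10, 0.10) for BEI and WP-logit and (1.2, 0.8, 0.8) for LA;
these give intra-individual visit-to-visit variability of the order
observed in serial QCT. The WP endpoint is simulated on the latent logit
scale and mapped through 100·sigmoid, keeping it in (0, 100) and matching
the beta analysis model.

## Airway measurement

At each centerline position (sampled every 1 mm, skipping 2 mm at either
end where bifurcation geometry corrupts sections), the volume is resampled
along 64 radial spokes in the orthogonal plane (cubic-spline interpolation
with per-volume coefficient caching — trilinear is configurable but adds
enough blur to push the lumen area of a 4 mm airway ~5% low; 0.25 mm
radial step, 12 mm reach). Per spoke, the wall is the first peak
with ≥ 75 HU prominence; the inner border is the half-rise between the
lumen level (median over the innermost 0.3 mm) and the peak, the outer
border the half-fall between the peak and the outer plateau (median over a
1.5 mm window starting 2 mm past the peak), both with linear sub-sample
interpolation. Spokes without a peak or plateau are discarded; a section
is invalid when more than 25% fail. LA and the outer area are shoelace
areas of the polygons through the retained border points; TD/WT/WP follow
exactly from (LA, WA) by the equivalent-circle identities, which makes
them pure functions of the two areas (asserted to machine precision in the
tests).

**Thin-wall refinement.** Plain FWHM is biased once the wall is thinner
than the effective blur (voxel partial volume plus interpolation): the
measured bump widens, dragging the inner border into the lumen and
inflating WT by up to ~0.5 mm for a 0.5 mm wall at 0.6 mm voxels. Blur is
symmetric, so two quantities survive it: the midpoint of the two
half-crossings (the wall centre) and the profile integral across the wall.
With the wall attenuation W calibrated (`MeasureParams.wall_hu`; soft
tissue ≈ 0 HU, known exactly for phantoms), the true width follows in
closed form from the window integral I over [r0, r3]:

    w = [I − (L − B)(rc − r0)] / [W − (L + B)/2]

with L the lumen level, B the plateau, rc the crossing midpoint; corrected
borders are rc ∓ w/2. This drops the worst-case sweep error (lumen 2–8 mm,
wall 0.5–1.5 mm, spacing 0.5–0.6 mm) from ~0.6 mm to 0.23 mm. When no
calibration is supplied the measurement falls back to plain FWHM, and the
correction also falls back per-spoke when its integration window does not
fit or the calibration is inconsistent (denominator ≤ 0).

**Aggregation.** Branch geometry is the median over valid interior
sections; regional G5–10 aggregates are medians over all pooled sections
of the selected branches, so branches weigh in proportion to their section
counts (medians match how such endpoints are reported; the
pooled-vs-per-branch distinction is regression-tested against brute-force
pooling). Empty selections report missing values, never zeros.

**BEI.** For every measured parent→child pair with child generation ≥ 3,
the error max(0, (LD_c − κ·LD_p)/(κ·LD_p)) with κ = 1 (no tapering
reserve; configurable) is summed over the child's lobe or the whole lung.
Only the qualitative contract of the published index is reproducible —
zero under strict tapering, lobar summability, monotonicity in any single
dilation — since the reference algorithm's exact error formula is not
public; this implementation is a declared stand-in satisfying that
contract exactly.

## Air trapping

All metrics are histogram statistics over given lobe masks — no
inspiratory–expiratory registration is performed or needed. The RVC band
[−950, −856] HU has inclusive edges (bit-reproducible voxel counts); the
emphysema exclusion removes voxels at or below −950 HU on each scan
independently. The A1–A3 thresholds interpolate the patient's own MLA pair,
T_k = MLA_I + f_k·(MLA_E − MLA_I) with defaults f = (0.75, 0.50, 0.25),
computed once from the total lung and applied per lobe; this preserves the
defining properties of the pediatric scheme it stands in for —
patient-specific, three nested severities, defect area as % of analysed
parenchyma — while the original's exact construction is not recoverable
from public sources. Fractions are configurable and nesting A1 ≥ A2 ≥ A3
holds by construction.

## Statistics

Descriptives are median/IQR (linear-interpolation quantiles) and
counts/percentages. The Friedman statistic uses average-rank ties with the
standard tie correction; P comes from exact enumeration of all (k!)^n
within-subject orderings whenever that count is ≤ 10⁵, else from the χ²
reference. The Wilcoxon–Mann–Whitney test enumerates all group assignments
exactly when both groups have ≤ 8 observations (ties included), else uses
the tie-corrected normal approximation. McNemar uses the
continuity-corrected χ². Correlation maps pool observations across visits
and lobes, attach Fisher-z 95% CIs and verbal bands (<0.2 very weak, <0.4
weak, <0.6 moderate, <0.8 strong), and adjust all defined cells by
Benjamini–Hochberg. All P-values are descriptive; no further multiplicity
control is applied inside model reports.

**Linear mixed models.** Random intercepts for patient and
region-within-patient — regions are nested measurements of a patient, not
a crossed factor. REML, profiled over the three log-SDs by Nelder–Mead
simplex (derivative-free; the objective is cheap because equal-sized
patient blocks are factorized in one batched Cholesky), fixed effects by
GLS, Wald normal SEs/CIs/P-values. "Robust" means iterated Huber weights
(c = 1.345) on marginally standardized residuals entering the residual
variance as σ²/w, refit until the weights stabilize; it is switchable to
plain REML and the two coincide on clean data. Variance components within
1e-4 of the data scale are flagged as boundary rather than silently
truncated; with an exactly deterministic response the residual SD hits the
search floor and between-subject fixed effects become unidentifiable — the
fit reports the flag instead of pretending otherwise.

**Beta mixed models.** WP lives in (0, 100)%; it is mapped to (0,1) with
the boundary shrinkage (y·(n−1)+0.5)/n and modelled as
Beta(μφ, (1−μ)φ) with logit link. Random intercepts are integrated by a
Laplace approximation; the inner penalized likelihood is maximized jointly
over fixed effects and random-effect modes by Fisher-scoring Newton steps
(each patient contributes an independent (1+q)×(1+q) information block, so
steps and the Laplace determinant use a per-patient Schur complement,
batched), and the outer profile over (log φ, log σ_p, log σ_r) by simplex
search. Wald covariance of the fixed effects is the inverse fixed-effect
Schur complement at the optimum, i.e. conditional on the variance
parameters, the convention generalized mixed-model software uses. In the
small-dispersion limit the coefficients agree with a logit-scale linear
mixed fit (tested within 5%). The robust variant Huber-weights each
observation's log-likelihood by its Pearson residual. Reported WP
coefficients are on the logit scale; every report states this.

**Longitudinal models** regress the endpoint at t1 on age, A3 and the
endpoint at t0 over subject × region rows with the same random intercepts.
With one observation per region cell the region variance is weakly
identified and may sit at the boundary; it is kept (and flagged) for
structural consistency with the cross-sectional model. For WP the baseline
covariate enters on the logit scale, matching the response link.

## Recovery harnesses and problem sizes

The simulation harnesses in `cfqct.evaluation` run at the study design
size, 36 subjects × 4 visits × 6 regions, with 100 replicates for coverage
and pattern rates; successive replicates warm-start the variance search
from the previous optimum (the optimum is re-verified each time, only the
starting point is shared). Recovery harnesses use the non-robust fits:
robustness is a contamination device, and on the clean Gaussian/beta
simulations the two estimators coincide while the plain fit is several
times faster. The carry-over harness simulates the longitudinal generative
form directly with an A3→BEI effect of 0.017 at 3 months and 0 at 24
months (coefficient scales from the fitted longitudinal models) and counts
replicates where the 3-month CI excludes 0 from below while the 24-month
CI covers 0. The pipeline-determinism check in the acceptance script runs
a 4-subject, 4-visit cohort — determinism does not depend on cohort size —
while the bundled demo config (8 subjects) is exercised in the test suite.

## Numerical choices and degenerate inputs

- Polygon areas of a 64-gon underestimate a disc by ~0.16%; this is far
  below the geometric tolerances and left uncorrected.
- Section validity demands ≥ 75% usable spokes, LA > 0 and WA > 0; invalid
  sections carry a reason string and are excluded from medians.
- The Friedman denominator being zero (all ranks tied) returns statistic 0
  and P = 1 by convention.
- Threshold fractions must be non-increasing; MLA_E ≤ MLA_I (expiration
  not denser than inspiration) is rejected as non-physiological rather
  than silently producing inverted thresholds.
- Volume files are reoriented on read to the identity-direction (LPS)
  frame so phantom and mask lattices compare voxelwise; masks are
  validated against their volume's shape and spacing before any metric
  runs.
- All CSV outputs are written with fixed float formats and the manifest
  excludes timestamps, making pipeline runs byte-for-byte reproducible
  under a fixed seed.

## Limitations

- Airway segmentation of raw volumes is a phantom-grade HU-threshold
  region grow with a gross leak check; clinical-grade segmentation is out
  of scope, as are DICOM reading, deformable insp/exp registration,
  airway-artery ratios and mucus-plug detection.
- The BEI error term and the A1–A3 threshold construction are declared
  stand-ins for unpublished reference algorithms (see above); absolute
  values are not comparable to those tools, only the contractual
  properties are.
- Phantoms share one blur model (partial volume + interpolation); scanner
  kernels differ, so absolute geometry accuracies measured here bound the
  method on this blur model, not on any particular scanner.
- The beta mixed model uses a Laplace approximation; with very small
  region variances its σ_r estimate is shrunk toward the boundary, which
  is flagged but not corrected by adaptive quadrature.
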