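# Methods

This note documents the models, numerical choices and limitations of
`pskel`. It is written from the package's point of view: everything stated
here is computed by the code and exercised by the test suite.

## Scope and data model

The pipeline starts either from 4-D diffusion-weighted volumes with
gradient tables, or from precomputed 3-D scalar maps, all assumed to live
on one shared voxel grid. Registration, template construction, denoising
and distortion correction are deliberately out of scope: `pskel` never
resamples an image. Diffusivities are reported in 1e-3 mm²/s (neonatal
white-matter MD ≈ 1.2), FA/NDI/ODI are dimensionless in [0, 1], and
b-values in s/mm². Volumes with b ≤ 50 s/mm² are treated as b = 0
baselines, since scanners report small nonzero values there.

## Diffusion tensor fit

`fit_tensor` solves the log-linear model ln S = ln S0 − b gᵀDg by ordinary
least squares followed by one weighted pass with weights equal to the
squared predicted signal — the standard variance-stabilizing choice for
log-transformed magnitude data. Only volumes with b ≤ `max_bval`
(default 1000 s/mm²) enter the fit: the mono-exponential tensor
representation degrades at strong diffusion weighting, so the b = 2500
shell is excluded by default; the cutoff is a configuration knob, since no
universally agreed choice exists. Voxels with a nonpositive signal in any
used volume are re-fit on their positive subset when at least 7 usable
volumes remain, otherwise flagged invalid (NaN in the output maps).
Eigenvalues are clamped at zero after decomposition rather than re-fit
under constraint — simple, standard and easy to verify. FA is defined as 0
when all eigenvalues vanish.

## NODDI fit

The forward model is the three-compartment Watson formulation:

    S/S0 = (1 − v_iso)·[v_ic·A_ic + (1 − v_ic)·A_ec] + v_iso·exp(−b·d_iso)

with the Watson-dispersed stick integral A_ic, the dispersed zeppelin
A_ec = exp(−b gᵀ⟨D⟩g) under the tortuosity constraint
d_perp = d_par(1 − v_ic), and fixed diffusivities d_par = 1.7e-3 mm²/s,
d_iso = 3.0e-3 mm²/s (both overridable; neonatal tissue may warrant a
lower d_par, which is why the constant is exposed). Dispersion is
described by a single Watson concentration κ, reported as
ODI = (2/π)·arctan(1/κ); a Bingham (anisotropic-dispersion) variant with
primary/secondary dispersion indices is intentionally not implemented —
the downstream biomarker consumes one scalar dispersion index.

A_ic is evaluated by a product quadrature in the frame of the dominant
orientation μ: 48 Gauss–Legendre nodes in cos θ × 48 uniform azimuths.
Because the integrand depends on the gradient only through cos β = g·μ,
the signal is exactly rotation invariant. Watson weights are computed as
exp(κ(u² − 1)) for numerical stability; κ beyond the quadrature's
resolving power (≈ 1.3e4 at this order) is clamped, which only affects
ODI below ~1e-4. The unit tests compare this quadrature against a
200×200-node evaluation of the same integral (agreement better than 1e-4
relative).

Fitting holds μ fixed at the principal eigenvector of a tensor fit over
all shells and estimates (v_ic, κ, v_iso) per voxel by a coarse grid
search followed by a bounded compass (pattern) search on the residual sum
of squares, halving the step until 2e-4. For speed, the fit interpolates
A_ic from a per-shell lookup table over (cos β, κ) — 97 uniform cos β
nodes × 64 log-spaced κ nodes — precomputed with the exact quadrature;
the bilinear interpolation error (~1e-5) is negligible against the
fitting tolerances (noiseless recovery of NDI/ODI/v_iso is better than
0.02 across a broad parameter grid, see the acceptance tests). The fit
is fully deterministic given its inputs. NODDI requires at least two
nonzero shells and refuses single-shell data.

## Skeletonization and projection

The skeleton is the one-voxel-thick centre surface of the template FA
ridges. Per candidate voxel (FA ≥ threshold, default 0.15) the
across-tract direction is estimated from the centre of gravity of FA in
the 3×3×3 neighbourhood when its offset is informative (≥ 0.1 voxel),
otherwise as the axis of most negative second derivative among the 13
axis/diagonal lines, normalized per squared length, with ties broken in a
fixed order (axes, face diagonals, body diagonals). A voxel joins the
skeleton when its FA is ≥ both neighbours along that direction and
strictly greater than at least one — so uniform plateaus yield no
skeleton, and a template whose FA never reaches the threshold yields an
empty skeleton with a warning.

Projection searches subject FA along ± the stored direction up to
`search_radius` voxels (default 4) and samples *all* metrics at the
FA-maximizing location, so the six metrics of one subject share a single
voxel support by construction. Ties resolve to the nearest offset
(0, +1, −1, …). The distance-map constraint of the full TBSS projection
is omitted: on the tube-like geometry of the phantoms the plain
perpendicular search is exact, but on convoluted real anatomy the
constraint map prevents cross-tract capture — a known fidelity limitation
of this implementation.

The curated analysis mask is applied as *set restriction*, not value
multiplication: literal multiplication would inject zeros into the
histogram and corrupt the 5th percentile. Masks must be binary.

## Peak width

PS-X = p95 − p5 of the masked skeletonized values of metric X, computed on
the raw value set (no histogram binning, hence no bandwidth parameter)
with linear interpolation under the (n−1)-spacing rule — the default
convention of the major numerical libraries, stated so results are
bit-reproducible. At least 20 finite values are required; for large
Gaussian value sets the width converges to 2·z₀.₉₅·σ ≈ 3.2897 σ.

## Cohort statistics

Metrics are adjusted for age at scan by OLS on GA at scan over the whole
pooled sample (not within group — with group-dependent maturation the
pooled fit can absorb part of a group effect; the choice follows the
whole-sample convention of the analysis this package implements and is
isolated in one function). Residualized metrics are correlated with GA at
birth (Pearson, two-sided). Group comparison gates on the
D'Agostino–Pearson omnibus test of the pooled residuals at α = 0.05 per
metric: normal-looking metrics use the equal-variance two-sample t-test,
the rest the two-sided Mann–Whitney U; with fewer than 8 subjects in a
group the normality test is unreliable and the Mann–Whitney branch is
taken with a warning. P-values are Benjamini–Hochberg adjusted across the
six metrics.

Classification uses unregularized logistic regression with an intercept.
Accuracy is estimated by repeated stratified k-fold cross-validation
(defaults 30 × 10); each repeat draws a fresh stratified partition from a
seed derived from the master seed, and features are standardized by the
training fold's mean/sd only, so nothing leaks from the held-out fold.
The reported ± is the standard deviation across all fold-level accuracies
(300 by default).

## Synthetic phantoms and cohorts

The DWI phantom embeds axis-aligned tubes in free-water background. The
tissue fraction tapers as a Gaussian of distance to the centerline
(σ = radius/2), so ground-truth FA forms a ridge peaking exactly on the
centerline — the geometry the skeleton stage is designed around — and the
taper doubles as a CSF partial-volume rim. Two forward models are
available: the exact tensor signal (used to validate the tensor fitter to
1e-6) and the Watson NODDI signal, which is linear in the free-water
fraction and therefore needs only one exact quadrature evaluation per
tract. Noise is Rician by default (magnitude MRI), |S + ε₁ + iε₂| with
ε ~ N(0, S0/snr); Gaussian noise is available for fitter unit tests.
Gradient schemes are generated by seeded electrostatic repulsion with a
fixed iteration budget; the default scheme mirrors a two-acquisition
neonatal protocol (16 b0; 3 × b200, 6 × b500, 64 × b750, 64 × b2500,
2 mm isotropic voxels). Everything is bit-reproducible given the seed.

The demo cohort gives preterm-analog subjects stronger sinusoidal CSF
partial-volume modulation along their tracts, widening their MD/RD/AD
value histograms the way diffuse dysmaturation widens them in vivo.

The cohort generator draws each subject's six PS metrics as
group location + slope·(GA_scan − mean) + Gaussian noise. Locations are
the published term/preterm medians (e.g. PSMD 0.50/0.60) and scales the
published IQRs/1.349 (normal approximation) — the only printed
distributional anchors; GA at birth is uniform on the published group
ranges (term 36.42–42, preterm 23.42–32 weeks) and GA at scan uniform on
38–44.56 weeks, truncated below at birth age. Per-metric age-at-scan
slopes default to 0 (no published values exist). Metrics are drawn
independently across the six PS measures, unlike the strongly correlated
real metrics — which is why the synthetic all-metric classifier outgains
the best single metric more than a real cohort would. Passing tests on
these cohorts therefore demonstrate the correctness of the statistical
machinery and the attainable effect sizes at the published scale, not the
covariance structure of real data.

## Problem sizes

The test suite and acceptance script run phantoms of ~16×12×12–20×20×12
voxels, NODDI fits restricted to the voxels the projection can actually
sample (skeleton ± search rays), a 12-subject demo cohort, and 20–100
replicate synthetic cohorts of n = 135 for the statistical checks — sizes
chosen so the whole validation completes in minutes on one CPU while
leaving every code path and tolerance identical to a full-scale run.

## Known limitations

- No distance-map-constrained projection (see above); no de-projection.
- Watson (single-ODI) dispersion only; no Bingham split.
- The curated exclusion mask of a real study is manual; the package ships
  only phantom-derived masks and accepts any user-supplied binary mask.
- The tensor fit has no robust outlier rejection (RESTORE-style); the
  salvage path only drops nonpositive signals.
- Phantom geometry is axis-aligned tubes; no crossing-fiber ground truth
  beyond perpendicular tube intersections, no motion or eddy artifacts.
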