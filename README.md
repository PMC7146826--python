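# pskel

Peak width of skeletonized diffusion MRI metrics for the neonatal brain.

Preterm birth is associated with diffuse, generalized alterations of white
matter microstructure rather than focal lesions. A compact way to quantify
such diffuse change is the *peak width of skeletonized mean diffusivity*
(PSMD): project each subject's mean-diffusivity map onto the core
white-matter skeleton, restrict to a curated mask that excludes
CSF/GM-contaminated and infratentorial regions, and report the width of the
resulting value histogram,

```
PS-X = P95(X_skeleton) - P5(X_skeleton)
```

`pskel` computes this family of biomarkers for six diffusion metrics — the
tensor-derived MD, FA, AD, RD and the NODDI-derived NDI (neurite density
index, the intracellular volume fraction v_ic) and ODI (orientation
dispersion index, (2/π)·arctan(1/κ) for Watson concentration κ) — and runs
the accompanying two-group analysis: age-at-scan residualization, Pearson
correlation with gestational age at birth, normality-gated group tests with
Benjamini–Hochberg FDR correction, and logistic-regression classification
under 30-repeated 10-fold stratified cross-validation.

The package assumes all maps are already co-registered on a shared voxel
grid (template construction and registration are upstream concerns). It
ships a synthetic phantom and cohort generator so that the whole pipeline
is testable without any imaging data.

## What is inside

| module | role |
| --- | --- |
| `pskel.io` | NIfTI, FSL bval/bvec and cohort CSV readers/writers |
| `pskel.phantom` | multi-shell DWI phantoms with analytic ground truth; synthetic two-group cohorts |
| `pskel.dti` | weighted-least-squares tensor fit; MD/FA/AD/RD maps |
| `pskel.noddi` | Watson-model NODDI forward signal and fit; NDI/ODI maps |
| `pskel.skeleton` | FA-ridge skeletonization, perpendicular projection, custom mask |
| `pskel.peakwidth` | p95 − p5 histogram widths per subject |
| `pskel.stats` | residualization, correlations, FDR group tests, repeated stratified CV |
| `pskel.pipeline` / `pskel.cli` | orchestration, YAML config, `pskel` command |

## Worked example

Run the self-contained phantom demo: a 12-subject two-group cohort of
simulated multi-shell acquisitions (16 b0 plus b = 200/500/750/2500 s/mm²
shells, Rician noise at SNR 30) is fitted, skeletonized, masked and
analysed:

```sh
pskel demo --out-dir demo --seed 7
```

prints (abridged):

```
subject_id     PSMD    PSNDI
       T01 0.169896 0.138133
       T02 0.294752 0.157880
       ...
       P11 0.509055 0.151544
       P12 0.520351 0.149900
PSMD: mann-whitney p_fdr=0.00649
PSFA: mann-whitney p_fdr=0.269
...
```

Each row is one subject's histogram widths over the 28 masked skeleton
voxels (MD widths in 1e-3 mm²/s). The preterm-analog subjects (P…) carry
stronger CSF partial-volume heterogeneity along their tracts, so their MD
histograms are wider — PSMD separates the groups (FDR-adjusted
Mann–Whitney p ≈ 0.006 at n = 6+6) while the unmodulated PSFA does not.

The same stages are available as library calls:

```python
from pskel import (fit_tensor, tensor_scalars, fit_noddi, build_skeleton,
                   project_onto_skeleton, apply_custom_mask, compute_ps_all)
```

and as granular subcommands (`simulate-phantom`, `fit-dti`, `fit-noddi`,
`skeletonize`, `peakwidth`, `stats`, `run`); `pskel run --config cfg.yaml`
drives the map-based pipeline on precomputed, co-registered scalar maps.

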