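"""Readers and writers for the formats the pipeline touches.

NIfTI-1 volumes (via nibabel), FSL-style ``bval``/``bvec`` gradient text
files, and the cohort CSV (``subject_id,group,ga_birth,ga_scan`` plus
optional peak-width metric columns).  All maps are assumed to live on a
shared voxel grid already: the pipeline never resamples or registers.

Units: diffusivity maps (MD/AD/RD) are stored in 1e-3 mm^2/s, so typical
neonatal white-matter MD reads as ~1.2; FA/NDI/ODI are dimensionless in
[0, 1]; b-values are in s/mm^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: b-values at or below this (s/mm^2) count as unweighted baselines (b0).
#: Scanners commonly report small nonzero values on baseline volumes.
B0_THRESHOLD = 50.0

#: The six scalar map kinds the pipeline produces, plus the binary mask kind.
MAP_KINDS = ("MD", "FA", "AD", "RD", "NDI", "ODI")
_ALL_KINDS = MAP_KINDS + ("MASK",)
#: Map kinds constrained to [0, 1].
BOUNDED_KINDS = ("FA", "NDI", "ODI")
#: Peak-width metric names, in the fixed reporting order.
PS_METRICS = ("PSMD", "PSFA", "PSAD", "PSRD", "PSNDI", "PSODI")
#: Map kind feeding each peak-width metric.
PS_TO_KIND = dict(zip(PS_METRICS, MAP_KINDS))

GA_RANGE = (22.0, 46.0)  # plausible gestational ages, weeks
GROUPS = ("term", "preterm")


class PipelineError(Exception):
    """Base class for user-facing pipeline errors."""


class FormatError(PipelineError):
    """Malformed or mutually inconsistent input files."""


class ValidationError(PipelineError):
    """Inputs that parse but violate a domain invariant."""


# ---------------------------------------------------------------------------
# gradient tables and DWI volumes
# ---------------------------------------------------------------------------


@dataclass
class GradientTable:
    """Per-volume b-values (s/mm^2) and unit gradient directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (n, 3), got {self.bvecs.shape}")
        if len(self.bvals) != len(self.bvecs):
            raise FormatError(
                f"gradient table length mismatch: {len(self.bvals)} b-values "
                f"vs {len(self.bvecs)} directions"
            )
        if np.any(self.bvals < 0):
            raise ValidationError("negative b-values")
        dw = self.bvals > B0_THRESHOLD
        if not np.any(~dw):
            raise ValidationError(
                "gradient table has no b=0 baseline volume (needed for S0)"
            )
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and np.any(np.abs(norms - 1.0) > 1e-3):
            raise ValidationError(
                "non-unit gradient direction at b > 0 "
                f"(worst |norm - 1| = {np.abs(norms - 1.0).max():.4g})"
            )

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def shells(self) -> np.ndarray:
        """Unique nonzero b-values (rounded to the nearest 1 s/mm^2)."""
        dw = self.bvals > B0_THRESHOLD
        return np.unique(np.round(self.bvals[dw]))


@dataclass
class DWIVolume:
    """A 4-D diffusion-weighted acquisition on a voxel grid."""

    data: np.ndarray                  # (x, y, z, n_volumes), signal >= 0
    grid: tuple                       # voxel dimensions, mm
    gradients: GradientTable
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.grid = tuple(float(g) for g in self.grid)
        if self.data.ndim != 4:
            raise FormatError(f"DWI data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[3] != len(self.gradients):
            raise FormatError(
                f"volume count mismatch: image has {self.data.shape[3]} volumes, "
                f"gradient table has {len(self.gradients)}"
            )
        if any(g <= 0 for g in self.grid) or len(self.grid) != 3:
            raise ValidationError(f"voxel dimensions must be positive 3-vector, got {self.grid}")
        if np.nanmin(self.data) < 0:
            raise ValidationError("negative signal values in DWI data")

    @property
    def shape(self):
        return self.data.shape[:3]


@dataclass
class ScalarMap:
    """One 3-D scalar map (MD/FA/AD/RD/NDI/ODI or a binary MASK)."""

    kind: str
    data: np.ndarray
    grid: tuple
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        if self.kind not in _ALL_KINDS:
            raise ValidationError(f"unknown map kind {self.kind!r}; expected one of {_ALL_KINDS}")
        self.data = np.asarray(self.data, dtype=float)
        self.grid = tuple(float(g) for g in self.grid)
        if self.data.ndim != 3:
            raise FormatError(f"scalar map must be 3-D, got shape {self.data.shape}")
        if any(g <= 0 for g in self.grid) or len(self.grid) != 3:
            raise ValidationError(f"voxel dimensions must be positive 3-vector, got {self.grid}")
        finite = self.data[np.isfinite(self.data)]
        if finite.size:
            if self.kind in BOUNDED_KINDS and (
                finite.min() < -1e-6 or finite.max() > 1 + 1e-6
            ):
                raise ValidationError(f"{self.kind} values outside [0, 1]")
            if self.kind in ("MD", "AD", "RD") and finite.min() < -1e-9:
                raise ValidationError(f"{self.kind} has negative diffusivities")

    @property
    def shape(self):
        return self.data.shape


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------


@dataclass
class CohortRecord:
    subject_id: str
    group: str                        # "term" or "preterm"
    ga_birth: float                   # weeks
    ga_scan: float                    # weeks
    metrics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.group = str(self.group).strip().lower()
        if self.group not in GROUPS:
            raise ValidationError(
                f"subject {self.subject_id}: group must be one of {GROUPS}, got {self.group!r}"
            )
        for name, value in (("ga_birth", self.ga_birth), ("ga_scan", self.ga_scan)):
            if not (GA_RANGE[0] <= value <= GA_RANGE[1]):
                raise ValidationError(
                    f"subject {self.subject_id}: {name}={value} outside plausible "
                    f"range {GA_RANGE} weeks"
                )
        if self.ga_birth > self.ga_scan:
            raise ValidationError(
                f"subject {self.subject_id}: ga_birth {self.ga_birth} exceeds "
                f"ga_scan {self.ga_scan}"
            )


@dataclass
class CohortTable:
    records: list

    def __post_init__(self):
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "subject_id": r.subject_id,
                "group": r.group,
                "ga_birth": r.ga_birth,
                "ga_scan": r.ga_scan,
            }
            row.update(r.metrics)
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def groups(self) -> np.ndarray:
        return np.array([r.group for r in self.records])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _load_bvecs(bvec_path) -> np.ndarray:
    arr = np.atleast_2d(np.loadtxt(bvec_path))
    # FSL canonical layout is 3 rows x n columns; a 3-column layout is
    # auto-detected by shape (a 3x3 file is read as FSL rows).
    if arr.shape[0] == 3 and arr.shape[1] != 3:
        arr = arr.T
    elif arr.shape[1] == 3:
        pass
    elif arr.shape[0] == 3:
        arr = arr.T
    else:
        raise FormatError(f"bvec file has shape {arr.shape}; expected 3 rows or 3 columns")
    return arr


def read_dwi(image_path, bval_path, bvec_path) -> DWIVolume:
    """Read a 4-D NIfTI plus FSL bval/bvec files into a :class:`DWIVolume`.

    Gradient directions at b > 0 that are within 5% of unit length are
    renormalized with a warning; larger deviations are an error.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected 4-D image, got {data.ndim}-D")
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = _load_bvecs(bvec_path)
    n_img, n_bval, n_bvec = data.shape[3], len(bvals), len(bvecs)
    if not (n_img == n_bval == n_bvec):
        raise FormatError(
            f"per-volume counts disagree: image {n_img}, bvals {n_bval}, bvecs {n_bvec}"
        )
    dw = bvals > B0_THRESHOLD
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if norms.size and np.any(np.abs(norms - 1.0) > 0.05):
        raise FormatError(
            "gradient directions deviate from unit length by more than 5% "
            f"(worst norm {norms[np.abs(norms - 1.0).argmax()]:.4f})"
        )
    if norms.size and np.any(np.abs(norms - 1.0) > 1e-3):
        warnings.warn("renormalizing near-unit gradient directions", stacklevel=2)
        bvecs = bvecs.copy()
        bvecs[dw] = bvecs[dw] / norms[:, None]
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DWIVolume(
        data=data,
        grid=zooms,
        gradients=GradientTable(bvals=bvals, bvecs=bvecs),
        affine=np.asarray(img.affine),
    )


def write_scalar_map(smap: ScalarMap, path) -> None:
    """Write a scalar map as float32 NIfTI-1; round-trips within 1e-6."""
    img = nib.Nifti1Image(smap.data.astype(np.float32), smap.affine)
    img.header.set_zooms(smap.grid)
    nib.save(img, str(path))


def read_scalar_map(path, kind: str) -> ScalarMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScalarMap(kind=kind, data=data, grid=zooms, affine=np.asarray(img.affine))


def write_gradients(gtab: GradientTable, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, gtab.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, gtab.bvecs.T, fmt="%.8f")  # FSL 3-row layout


def read_cohort(csv_path) -> CohortTable:
    """Read and validate the cohort CSV.

    Required columns: subject_id, group, ga_birth, ga_scan.  Any of the six
    peak-width metric columns (PSMD, ..., PSODI) may be present; missing
    metrics are filled later by the pipeline.
    """
    df = pd.read_csv(csv_path)
    required = ["subject_id", "group", "ga_birth", "ga_scan"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{csv_path}: missing required columns {missing}")
    metric_cols = [c for c in df.columns if c.upper() in PS_METRICS]
    records = []
    for i, row in df.iterrows():
        try:
            metrics = {
                c.upper(): float(row[c]) for c in metric_cols if pd.notna(row[c])
            }
            records.append(
                CohortRecord(
                    subject_id=str(row["subject_id"]),
                    group=row["group"],
                    ga_birth=float(row["ga_birth"]),
                    ga_scan=float(row["ga_scan"]),
                    metrics=metrics,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{csv_path} row {i}: {exc}") from exc
    return CohortTable(records=records)


def write_cohort(cohort: CohortTable, csv_path) -> None:
    cohort.to_dataframe().to_csv(csv_path, index=False)
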