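"""Histogram peak-width of skeletonized diffusion metrics.

The peak width of one subject's skeletonized, masked metric is the
difference between the 95th and 5th percentiles of the raw voxel values.
Percentiles use linear interpolation with the (n-1)-spacing rule
(position = q*(n-1), interpolated between flanking order statistics) —
the dominant numerical-computing convention, stated here so results are
bit-reproducible.  No histogram binning is performed: percentiles act on
the raw value set, which avoids any bandwidth parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MAP_KINDS, PS_METRICS, PS_TO_KIND, ValidationError

MIN_VOXELS = 20   # below this the tail percentiles are too unstable to report


def peak_width(values) -> tuple:
    """(p5, p95, width) of a flat value set.

    Requires at least ``MIN_VOXELS`` values, all finite — masking upstream
    must already have removed off-support voxels.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < MIN_VOXELS:
        raise ValidationError(
            f"peak width needs >= {MIN_VOXELS} values, got {values.size}"
        )
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite values in skeletonized value set")
    p5, p95 = np.percentile(values, [5.0, 95.0])  # linear (n-1)-spacing rule
    return float(p5), float(p95), float(p95 - p5)


@dataclass
class PSResult:
    """The six peak-width values for one subject.

    Widths of MD/AD/RD are in 1e-3 mm^2/s; FA/NDI/ODI widths are
    dimensionless.
    """

    subject_id: str
    widths: dict          # PS metric name -> width
    p5: dict              # PS metric name -> 5th percentile
    p95: dict             # PS metric name -> 95th percentile
    n_voxels: int

    def __getattr__(self, name):
        if name.lower().startswith("ps") and name.upper() in PS_METRICS:
            return self.widths[name.upper()]
        raise AttributeError(name)

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id, "n_voxels": self.n_voxels}
        for m in PS_METRICS:
            row[m] = self.widths[m]
            row[f"{m}_p5"] = self.p5[m]
            row[f"{m}_p95"] = self.p95[m]
        return row


def compute_ps_all(skel_maps: dict) -> PSResult:
    """Compute all six peak widths from one subject's skeletonized maps.

    ``skel_maps`` maps kind (MD/FA/AD/RD/NDI/ODI) to a masked
    :class:`~pskel.skeleton.SkeletonizedMap`.  All six maps must carry the
    applied mask flag and identical voxel support (the FA-driven
    projection guarantees this when used as intended).
    """
    missing = [k for k in MAP_KINDS if k not in skel_maps]
    if missing:
        raise ValidationError(f"missing skeletonized maps for kinds {missing}")
    ref = skel_maps[MAP_KINDS[0]]
    subject_ids = {skel_maps[k].subject_id for k in MAP_KINDS}
    if len(subject_ids) > 1:
        raise ValidationError(f"maps from multiple subjects: {sorted(subject_ids)}")
    for k in MAP_KINDS:
        sm = skel_maps[k]
        if not sm.mask_applied:
            raise ValidationError(f"{k} map has not had the custom mask applied")
        if sm.voxel_indices.shape != ref.voxel_indices.shape or not np.array_equal(
            sm.voxel_indices, ref.voxel_indices
        ):
            raise ValidationError(
                f"{k} map voxel support differs from {MAP_KINDS[0]}; all six "
                "metrics must be sampled on one shared support"
            )
    widths, p5s, p95s = {}, {}, {}
    for ps_name in PS_METRICS:
        kind = PS_TO_KIND[ps_name]
        p5, p95, width = peak_width(skel_maps[kind].values)
        widths[ps_name], p5s[ps_name], p95s[ps_name] = width, p5, p95
    return PSResult(
        subject_id=ref.subject_id,
        widths=widths,
        p5=p5s,
        p95=p95s,
        n_voxels=int(ref.values.size),
    )
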