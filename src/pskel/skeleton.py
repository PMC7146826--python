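"""White-matter skeletonization and perpendicular projection.

The skeleton is the one-voxel-thick centre surface of the template FA
ridges: a voxel joins the skeleton when its FA is at or above the
threshold and is a local maximum of FA along the direction perpendicular
to the local tract.  The perpendicular direction is estimated per voxel
from the FA surface geometry — the centre-of-gravity offset of FA in the
3x3x3 neighbourhood when it is informative, otherwise the axis (of the 13
axis/diagonal lines) of most negative second derivative.

Subject maps are then projected onto the skeleton: for each skeleton
voxel, the subject's FA is searched along +/- the stored perpendicular
direction and the maximizing voxel supplies the skeletonized FA value;
every other metric is sampled at that same location ("driven by the FA"),
so all six metrics share one voxel support per subject.

The full distance-map-constrained search of the original TBSS projection
is deliberately omitted (a fidelity limitation documented in the methods
note); on tube-like geometry the plain perpendicular line search is
exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import FormatError, ScalarMap, ValidationError

DEFAULT_FA_THRESHOLD = 0.15
DEFAULT_SEARCH_RADIUS = 4

#: the 13 distinct axis/diagonal line directions of a 3x3x3 neighbourhood,
#: in the fixed tie-break order: axes, face diagonals, body diagonals
LINE_DIRECTIONS = np.array([
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
], dtype=int)

_COG_NORM_MIN = 0.1   # CoG offsets shorter than this (voxels) are uninformative


@dataclass
class Skeleton:
    """Binary skeleton plus per-voxel perpendicular search directions."""

    mask: np.ndarray                     # (x, y, z) bool
    directions: np.ndarray               # (x, y, z, 3) int8, valid on mask
    fa_threshold: float
    grid: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def indices(self) -> np.ndarray:
        """Skeleton voxel coordinates, (m, 3), in fixed row-major order."""
        return np.argwhere(self.mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def search_support(self, search_radius: int = DEFAULT_SEARCH_RADIUS) -> np.ndarray:
        """Boolean mask of every voxel the projection search can visit."""
        out = np.zeros_like(self.mask)
        shape = self.mask.shape
        for v in self.indices:
            u = self.directions[tuple(v)]
            for k in range(-search_radius, search_radius + 1):
                p = v + k * u
                if np.all(p >= 0) and np.all(p < shape):
                    out[tuple(p)] = True
        return out


@dataclass
class SkeletonizedMap:
    """One metric's values on the skeleton voxels of one subject."""

    kind: str
    subject_id: str
    values: np.ndarray                  # (m,)
    voxel_indices: np.ndarray           # (m, 3) skeleton voxels
    source_indices: np.ndarray          # (m, 3) where each value was sampled
    mask_applied: bool = False


def _fa_at(fa: np.ndarray, p) -> float:
    """FA with out-of-bounds and NaN treated as 0."""
    if np.any(np.asarray(p) < 0) or np.any(np.asarray(p) >= fa.shape):
        return 0.0
    v = fa[tuple(p)]
    return float(v) if np.isfinite(v) else 0.0


def _perpendicular_direction(fa: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Estimate the across-tract direction at voxel v as an integer offset."""
    # centre of gravity of FA over the 3x3x3 neighbourhood
    w_sum = 0.0
    cog = np.zeros(3)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                w = _fa_at(fa, v + (dx, dy, dz))
                w_sum += w
                cog += w * np.array([dx, dy, dz], dtype=float)
    if w_sum > 0:
        cog /= w_sum
    if np.linalg.norm(cog) >= _COG_NORM_MIN:
        u = np.rint(cog / np.abs(cog).max()).astype(int)
        if np.any(u != 0):
            return u
    # fall back: line of most negative second derivative (sharpest ridge
    # crossing), normalized per unit squared distance; first wins on ties
    f0 = _fa_at(fa, v)
    best, best_d2 = LINE_DIRECTIONS[0], np.inf
    for d in LINE_DIRECTIONS:
        d2 = (_fa_at(fa, v + d) + _fa_at(fa, v - d) - 2.0 * f0) / float(d @ d)
        if d2 < best_d2 - 1e-15:
            best_d2, best = d2, d
    return best.copy()


def build_skeleton(template_fa: ScalarMap, fa_threshold: float = DEFAULT_FA_THRESHOLD) -> Skeleton:
    """Extract the centre-surface skeleton of a template FA map.

    A voxel is kept when FA >= ``fa_threshold`` and its FA is >= both
    neighbours along the perpendicular direction (strictly greater than at
    least one, so uniform plateaus produce no skeleton).
    """
    fa = np.nan_to_num(template_fa.data, nan=0.0)
    mask = np.zeros(fa.shape, dtype=bool)
    directions = np.zeros(fa.shape + (3,), dtype=np.int8)
    if np.nanmax(fa) < fa_threshold:
        warnings.warn(
            f"template FA peaks below the threshold {fa_threshold}; skeleton is empty",
            stacklevel=2,
        )
        return Skeleton(mask=mask, directions=directions, fa_threshold=fa_threshold,
                        grid=template_fa.grid, affine=template_fa.affine)

    for v in np.argwhere(fa >= fa_threshold):
        u = _perpendicular_direction(fa, v)
        f0 = fa[tuple(v)]
        f_plus = _fa_at(fa, v + u)
        f_minus = _fa_at(fa, v - u)
        if f0 >= f_plus and f0 >= f_minus and (f0 > f_plus or f0 > f_minus):
            mask[tuple(v)] = True
            directions[tuple(v)] = u
    return Skeleton(mask=mask, directions=directions, fa_threshold=fa_threshold,
                    grid=template_fa.grid, affine=template_fa.affine)


_SEARCH_ORDER_CACHE: dict = {}


def _search_offsets(radius: int) -> list:
    """Offsets 0, +1, -1, +2, -2, ... so ties resolve to the nearest voxel."""
    if radius not in _SEARCH_ORDER_CACHE:
        order = [0]
        for k in range(1, radius + 1):
            order += [k, -k]
        _SEARCH_ORDER_CACHE[radius] = order
    return _SEARCH_ORDER_CACHE[radius]


def project_onto_skeleton(
    subject_fa: ScalarMap,
    other_maps,
    skel: Skeleton,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    subject_id: str = "subject",
):
    """Project a subject's maps onto the skeleton, driven by the FA.

    Returns one :class:`SkeletonizedMap` per input map, FA first; all
    returned maps share identical voxel support and source locations.
    """
    shape = skel.mask.shape
    for m in [subject_fa, *other_maps]:
        if m.shape != shape:
            raise FormatError(
                f"map {m.kind} shape {m.shape} does not match skeleton grid {shape}"
            )
    fa = subject_fa.data
    idx = skel.indices
    m = len(idx)
    located = np.empty((m, 3), dtype=int)
    offsets = _search_offsets(search_radius)
    for row, v in enumerate(idx):
        u = skel.directions[tuple(v)]
        best_val, best_p = -np.inf, v
        for k in offsets:
            p = v + k * u
            if np.any(p < 0) or np.any(p >= shape):
                continue
            val = fa[tuple(p)]
            if np.isfinite(val) and val > best_val:
                best_val, best_p = val, p
        located[row] = best_p

    out = []
    for smap in [subject_fa, *other_maps]:
        values = smap.data[located[:, 0], located[:, 1], located[:, 2]]
        out.append(
            SkeletonizedMap(
                kind=smap.kind,
                subject_id=subject_id,
                values=np.asarray(values, dtype=float),
                voxel_indices=idx.copy(),
                source_indices=located.copy(),
                mask_applied=False,
            )
        )
    return out


def apply_custom_mask(skel_map: SkeletonizedMap, custom_mask: ScalarMap) -> SkeletonizedMap:
    """Restrict a skeletonized map to the custom analysis mask.

    Removed voxels are dropped from the value set rather than zeroed:
    injecting zeros would corrupt the histogram percentiles downstream.
    """
    data = custom_mask.data
    finite = data[np.isfinite(data)]
    if not np.all((np.abs(finite) < 1e-9) | (np.abs(finite - 1.0) < 1e-9)):
        raise ValidationError("custom mask must be binary (0/1)")
    keep = np.array(
        [bool(data[tuple(v)] > 0.5) for v in skel_map.voxel_indices], dtype=bool
    )
    if not keep.any():
        warnings.warn("custom mask removes every skeleton voxel", stacklevel=2)
    return replace(
        skel_map,
        values=skel_map.values[keep],
        voxel_indices=skel_map.voxel_indices[keep],
        source_indices=skel_map.source_indices[keep],
        mask_applied=True,
    )
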