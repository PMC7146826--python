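"""Per-voxel diffusion tensor fitting and the four tensor scalar maps.

The tensor is estimated from the log-linear model ln S = ln S0 - b g'Dg by
a two-pass weighted least squares: an ordinary least-squares pass on the
log-signal, followed by a weighted pass with weights equal to the squared
predicted signal (the standard variance-stabilizing choice for log-
transformed Rician data).  Eigenvalues are clamped at zero after
decomposition.  Tensor coefficients and eigenvalues are stored in
1e-3 mm^2/s, matching the scalar-map unit convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    B0_THRESHOLD,
    DWIVolume,
    ScalarMap,
    ValidationError,
)

#: Volumes with b above this (s/mm^2) are excluded from the tensor fit by
#: default: the mono-exponential tensor model breaks down at strong
#: weighting, so only the low-b shell(s) plus baselines are used.
DEFAULT_MAX_BVAL = 1000.0

_COND_LIMIT = 1e8


@dataclass
class TensorField:
    """Per-voxel symmetric tensor (1e-3 mm^2/s) with S0 and validity mask."""

    coeffs: np.ndarray        # (..., 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    s0: np.ndarray            # (...,)
    valid: np.ndarray         # (...,) bool
    evals: np.ndarray         # (..., 3) descending, clamped >= 0
    evecs: np.ndarray         # (..., 3) principal eigenvector
    grid: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows [-b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz, 1]."""
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    X = np.empty((len(b), 7))
    X[:, 0] = -b * g[:, 0] ** 2
    X[:, 1] = -b * g[:, 1] ** 2
    X[:, 2] = -b * g[:, 2] ** 2
    X[:, 3] = -2 * b * g[:, 0] * g[:, 1]
    X[:, 4] = -2 * b * g[:, 0] * g[:, 2]
    X[:, 5] = -2 * b * g[:, 1] * g[:, 2]
    X[:, 6] = 1.0
    return X


def _tensor_matrices(coeffs: np.ndarray) -> np.ndarray:
    """(..., 6) unique coefficients -> (..., 3, 3) symmetric matrices."""
    D = np.zeros(coeffs.shape[:-1] + (3, 3))
    D[..., 0, 0] = coeffs[..., 0]
    D[..., 1, 1] = coeffs[..., 1]
    D[..., 2, 2] = coeffs[..., 2]
    D[..., 0, 1] = D[..., 1, 0] = coeffs[..., 3]
    D[..., 0, 2] = D[..., 2, 0] = coeffs[..., 4]
    D[..., 1, 2] = D[..., 2, 1] = coeffs[..., 5]
    return D


def _wls(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Two-pass WLS for each row of Y = log signals, shape (V, N)."""
    beta_ols = Y @ np.linalg.pinv(X).T                       # (V, 7)
    w = np.exp(2.0 * (beta_ols @ X.T))                       # squared predicted signal
    A = np.einsum("ni,vn,nj->vij", X, w, X)
    rhs = np.einsum("ni,vn,vn->vi", X, w, Y)
    return np.linalg.solve(A, rhs[..., None])[..., 0]


def fit_tensor(dwi: DWIVolume, mask: ScalarMap | None = None,
               max_bval: float = DEFAULT_MAX_BVAL) -> TensorField:
    """Fit the diffusion tensor on volumes with b <= ``max_bval``.

    Voxels with a nonpositive signal in any used volume are re-fit on their
    positive subset when at least 7 usable volumes remain, else flagged
    invalid.
    """
    gtab = dwi.gradients
    sel = gtab.bvals <= max_bval
    bvals, bvecs = gtab.bvals[sel], gtab.bvecs[sel]
    dw = bvals > B0_THRESHOLD
    if not np.any(~dw):
        raise ValidationError("no b=0 volume at or below max_bval")
    if dw.sum() < 6:
        raise ValidationError(
            f"tensor fit needs >= 6 diffusion-weighted directions, got {int(dw.sum())}"
        )
    X = design_matrix(bvals, bvecs)
    if np.linalg.cond(X) > _COND_LIMIT:
        raise ValidationError(
            "degenerate gradient design: condition number exceeds 1e8 "
            "(directions are (nearly) collinear/coplanar)"
        )

    shape = dwi.shape
    S = dwi.data[..., sel].reshape(-1, sel.sum())
    in_mask = np.ones(S.shape[0], dtype=bool)
    if mask is not None:
        if mask.shape != shape:
            raise ValidationError(f"mask shape {mask.shape} != data shape {shape}")
        in_mask = np.nan_to_num(mask.data).ravel() > 0.5

    V = S.shape[0]
    coeffs = np.zeros((V, 6))
    s0 = np.zeros(V)
    valid = np.zeros(V, dtype=bool)

    pos_all = np.all(S > 0, axis=1)
    main = in_mask & pos_all
    if np.any(main):
        beta = _wls(X, np.log(S[main]))
        coeffs[main] = beta[:, :6] * 1e3          # mm^2/s -> 1e-3 mm^2/s
        s0[main] = np.exp(beta[:, 6])
        valid[main] = True

    # salvage voxels with scattered nonpositive signals
    for v in np.flatnonzero(in_mask & ~pos_all):
        keep = S[v] > 0
        if keep.sum() < 7 or (bvals[keep] > B0_THRESHOLD).sum() < 6 or not np.any(
            bvals[keep] <= B0_THRESHOLD
        ):
            continue
        Xv = X[keep]
        if np.linalg.cond(Xv) > _COND_LIMIT:
            continue
        beta = _wls(Xv, np.log(S[v, keep])[None, :])[0]
        coeffs[v] = beta[:6] * 1e3
        s0[v] = np.exp(beta[6])
        valid[v] = True

    coeffs = coeffs.reshape(shape + (6,))
    s0 = s0.reshape(shape)
    valid = valid.reshape(shape)

    D = _tensor_matrices(coeffs)
    evals, evecs = np.linalg.eigh(D)              # ascending
    evals = np.clip(evals[..., ::-1], 0.0, None)  # descending, clamped
    principal = evecs[..., :, 2]                  # eigenvector of largest eigenvalue
    return TensorField(
        coeffs=coeffs, s0=s0, valid=valid, evals=evals, evecs=principal,
        grid=dwi.grid, affine=dwi.affine,
    )


def eigenvalue_scalars(evals: np.ndarray):
    """MD/FA/AD/RD from eigenvalue triples (..., 3), eigenvalues >= 0."""
    lam = np.asarray(evals, dtype=float)
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = 0.5 * (lam[..., 1] + lam[..., 2])
    dev = lam - md[..., None]
    num = np.sqrt((dev**2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return md, np.clip(fa, 0.0, 1.0), ad, rd


def tensor_scalars(field: TensorField):
    """Derive the four scalar maps; invalid voxels are NaN.

    Returns (MD, FA, AD, RD) :class:`~pskel.io.ScalarMap` objects in
    1e-3 mm^2/s (MD/AD/RD) and dimensionless FA.
    """
    md, fa, ad, rd = eigenvalue_scalars(field.evals)
    out = []
    for kind, data in (("MD", md), ("FA", fa), ("AD", ad), ("RD", rd)):
        arr = np.where(field.valid, data, np.nan)
        out.append(ScalarMap(kind=kind, data=arr, grid=field.grid, affine=field.affine))
    return tuple(out)
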