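r"""NODDI: the three-compartment Watson model, forward signal and fitting.

The normalized signal is

    S/S0 = (1 - v_iso) * [v_ic * A_ic + (1 - v_ic) * A_ec] + v_iso * exp(-b d_iso)

where A_ic is the Watson-dispersed stick integral

    A_ic = \int_{S^2} W(n; mu, kappa) exp(-b d_par (g.n)^2) dn,

A_ec = exp(-b g' <D> g) is the Watson-dispersed zeppelin with the
tortuosity constraint d_perp = d_par (1 - v_ic), and the Watson density is
W(n) proportional to exp(kappa (mu.n)^2).  The orientation dispersion
index is ODI = (2/pi) arctan(1/kappa).

``noddi_signal`` evaluates A_ic by a fixed-order spherical product
quadrature (Gauss-Legendre in cos(theta) x uniform azimuth) in the frame
of the dominant orientation mu; the signal therefore depends on g only
through cos(beta) = g.mu, which makes it exactly rotation invariant.

``fit_noddi`` estimates (v_ic, kappa, v_iso) per voxel by a coarse grid
search followed by bounded local refinement, with mu taken from the
principal eigenvector of a tensor fit.  For speed the fit interpolates
A_ic from a dense (cos beta, kappa) table precomputed per b-shell with the
same quadrature; the interpolation error (~1e-5) is negligible against
the fit tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .io import B0_THRESHOLD, DWIVolume, GradientTable, ScalarMap, ValidationError
from .dti import fit_tensor

D_PAR_DEFAULT = 1.7e-3   # intrinsic parallel diffusivity, mm^2/s
D_ISO_DEFAULT = 3.0e-3   # free-water diffusivity, mm^2/s
KAPPA_MAX = 64.0
N_POLAR = 48             # Gauss-Legendre nodes in cos(theta)
N_AZIMUTH = 48           # uniform azimuthal nodes


def odi_from_kappa(kappa):
    """ODI = (2/pi) arctan(1/kappa); ODI(0) = 1 by continuity."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValidationError("Watson concentration kappa must be >= 0")
    with np.errstate(divide="ignore"):
        out = (2.0 / np.pi) * np.arctan2(1.0, kappa)
    return out if out.ndim else float(out)


def kappa_from_odi(odi):
    """Inverse of :func:`odi_from_kappa`, clamped to [0, KAPPA_MAX]."""
    odi = np.asarray(odi, dtype=float)
    if np.any((odi < 0) | (odi > 1)):
        raise ValidationError("ODI must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        kappa = 1.0 / np.tan(np.pi * odi / 2.0)
    kappa = np.clip(np.where(odi <= 0, KAPPA_MAX, kappa), 0.0, KAPPA_MAX)
    return kappa if kappa.ndim else float(kappa)


@lru_cache(maxsize=8)
def _sphere_quadrature(n_polar: int, n_azimuth: int):
    """Product quadrature nodes (Q, 3) and weights (Q,) on the sphere.

    The polar axis is the Watson mean direction mu.
    """
    u, wu = np.polynomial.legendre.leggauss(n_polar)
    phi = 2.0 * np.pi * np.arange(n_azimuth) / n_azimuth
    su = np.sqrt(1.0 - u**2)
    nodes = np.stack(
        [
            np.outer(su, np.cos(phi)).ravel(),
            np.outer(su, np.sin(phi)).ravel(),
            np.repeat(u, n_azimuth),
        ],
        axis=1,
    )
    weights = np.repeat(wu, n_azimuth) * (2.0 * np.pi / n_azimuth)
    return nodes, weights


def _watson_weights(kappa, nodes, weights):
    """Normalized Watson quadrature weights for concentration(s) kappa."""
    u2 = nodes[:, 2] ** 2
    k = np.atleast_1d(np.asarray(kappa, dtype=float))
    # beyond the quadrature's resolving power the density is numerically a
    # point mass at the most polar node; clamp kappa to that limit so the
    # weights never underflow to all-zero
    k = np.minimum(k, 30.0 / (1.0 - u2.max()))
    # exp(kappa (u^2 - 1)) is the density up to normalization and stays
    # bounded for arbitrarily large kappa
    w = weights[:, None] * np.exp(np.outer(u2 - 1.0, k))
    return w / w.sum(axis=0, keepdims=True)          # (Q, K)


def _mu_frame(mu: np.ndarray) -> np.ndarray:
    """Orthonormal basis (e1, e2, mu) as rows; mu is the polar axis."""
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(mu[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    return np.stack([e1, e2, mu])


def watson_tau1(kappa, n_polar: int = N_POLAR, n_azimuth: int = N_AZIMUTH):
    """<(mu.n)^2> under the Watson density, by the same quadrature."""
    nodes, weights = _sphere_quadrature(n_polar, n_azimuth)
    wn = _watson_weights(kappa, nodes, weights)
    tau = (nodes[:, 2] ** 2) @ wn
    return tau if np.ndim(kappa) else float(tau[0])


def extracellular_signal(bvals, cos_beta, v_ic, tau1, d_par, d_iso=None):
    """Watson-dispersed zeppelin with the tortuosity constraint."""
    d_perp = d_par * (1.0 - v_ic)
    c2 = np.asarray(cos_beta) ** 2
    dapp = d_perp + (d_par - d_perp) * (tau1 * c2 + 0.5 * (1.0 - tau1) * (1.0 - c2))
    return np.exp(-np.asarray(bvals) * dapp)


def noddi_signal(
    v_ic: float,
    kappa: float,
    v_iso: float,
    mu,
    gradients: GradientTable,
    d_par: float = D_PAR_DEFAULT,
    d_iso: float = D_ISO_DEFAULT,
    s0: float = 1.0,
    n_polar: int = N_POLAR,
    n_azimuth: int = N_AZIMUTH,
) -> np.ndarray:
    """Forward NODDI signal for one voxel over a gradient scheme.

    Parameters are the intracellular fraction ``v_ic`` (NDI), Watson
    concentration ``kappa``, free-water fraction ``v_iso`` and dominant
    orientation ``mu`` (need not be normalized).  Returns a vector with
    one entry per volume; b=0 entries equal ``s0`` exactly.
    """
    for name, v in (("v_ic", v_ic), ("v_iso", v_iso)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1], got {v}")
    if kappa < 0:
        raise ValidationError("kappa must be >= 0")
    nodes, weights = _sphere_quadrature(n_polar, n_azimuth)
    wn = _watson_weights(kappa, nodes, weights)[:, 0]
    R = _mu_frame(mu)
    g = gradients.bvecs @ R.T                        # gradients in mu-frame
    b = gradients.bvals
    dots2 = (g @ nodes.T) ** 2                       # (N, Q)
    a_ic = np.exp(-np.outer(b * d_par, np.ones(nodes.shape[0])) * dots2) @ wn
    tau1 = float((nodes[:, 2] ** 2) @ wn)
    cos_beta = g[:, 2]
    a_ec = extracellular_signal(b, cos_beta, v_ic, tau1, d_par)
    a_iso = np.exp(-b * d_iso)
    signal = s0 * ((1.0 - v_iso) * (v_ic * a_ic + (1.0 - v_ic) * a_ec) + v_iso * a_iso)
    # b=0 rows are analytically s0; enforce exactly
    signal[b <= B0_THRESHOLD] = s0
    return signal


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_KAPPA_GRID = np.concatenate([[0.0], np.geomspace(0.05, KAPPA_MAX, 63)])
_COS_GRID = np.linspace(0.0, 1.0, 97)


class _AicTables:
    """A_ic(b, cos beta, kappa) tabulated per b-shell from the quadrature."""

    def __init__(self, shell_bvals, d_par, n_polar=N_POLAR, n_azimuth=N_AZIMUTH):
        nodes, weights = _sphere_quadrature(n_polar, n_azimuth)
        wn = _watson_weights(_KAPPA_GRID, nodes, weights)       # (Q, K)
        self.tau1 = (nodes[:, 2] ** 2) @ wn                     # (K,)
        sin_b = np.sqrt(1.0 - _COS_GRID**2)
        # dot of g(beta) = (sin beta, 0, cos beta) with each node
        dots2 = (
            np.outer(sin_b, nodes[:, 0]) + np.outer(_COS_GRID, nodes[:, 2])
        ) ** 2                                                   # (C, Q)
        self.tables = {
            float(b): np.exp(-b * d_par * dots2) @ wn            # (C, K)
            for b in shell_bvals
        }

    def _kappa_bracket(self, kappa):
        k = float(np.clip(kappa, 0.0, KAPPA_MAX))
        j = int(np.searchsorted(_KAPPA_GRID, k))
        if j == 0:
            return 0, 0, 0.0
        if j >= len(_KAPPA_GRID):
            j = len(_KAPPA_GRID) - 1
        lo, hi = j - 1, j
        t = (k - _KAPPA_GRID[lo]) / (_KAPPA_GRID[hi] - _KAPPA_GRID[lo])
        return lo, hi, t

    def a_ic(self, b, cos_beta, kappa):
        """Bilinear interpolation at one (shell, kappa) for cos_beta array."""
        lo, hi, t = self._kappa_bracket(kappa)
        tab = self.tables[float(b)]
        c = np.abs(np.asarray(cos_beta))
        a_lo = np.interp(c, _COS_GRID, tab[:, lo])
        if hi == lo:
            return a_lo
        a_hi = np.interp(c, _COS_GRID, tab[:, hi])
        return (1.0 - t) * a_lo + t * a_hi

    def a_ic_batch(self, b, cos_beta, kappa):
        """Bilinear lookup for cos_beta (n, V) with per-voxel kappa (V,)."""
        T = self.tables[float(b)]
        nc = len(_COS_GRID) - 1
        c = np.clip(np.abs(cos_beta), 0.0, 1.0) * nc
        ic = np.minimum(c.astype(int), nc - 1)
        tc = c - ic
        k = np.clip(kappa, 0.0, KAPPA_MAX)
        jk = np.clip(np.searchsorted(_KAPPA_GRID, k), 1, len(_KAPPA_GRID) - 1)
        tk = (k - _KAPPA_GRID[jk - 1]) / (_KAPPA_GRID[jk] - _KAPPA_GRID[jk - 1])
        jk = np.broadcast_to(jk, ic.shape)
        tk = np.broadcast_to(tk, ic.shape)
        a_lo = T[ic, jk - 1] * (1 - tc) + T[ic + 1, jk - 1] * tc
        a_hi = T[ic, jk] * (1 - tc) + T[ic + 1, jk] * tc
        return (1 - tk) * a_lo + tk * a_hi

    def tau1_at(self, kappa):
        lo, hi, t = self._kappa_bracket(kappa)
        return (1.0 - t) * self.tau1[lo] + t * self.tau1[hi]

    def tau1_batch(self, kappa):
        return np.interp(np.clip(kappa, 0.0, KAPPA_MAX), _KAPPA_GRID, self.tau1)


@dataclass
class NoddiParams:
    """Per-voxel NODDI estimates plus the fixed model constants."""

    v_ic: np.ndarray
    v_iso: np.ndarray
    kappa: np.ndarray
    mu: np.ndarray               # (..., 3) unit dominant orientation
    valid: np.ndarray
    d_par: float = D_PAR_DEFAULT
    d_iso: float = D_ISO_DEFAULT
    grid: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def ndi_map(self) -> ScalarMap:
        data = np.where(self.valid, np.clip(self.v_ic, 0, 1), np.nan)
        return ScalarMap(kind="NDI", data=data, grid=self.grid, affine=self.affine)

    def odi_map(self) -> ScalarMap:
        odi = (2.0 / np.pi) * np.arctan2(1.0, self.kappa)
        data = np.where(self.valid, odi, np.nan)
        return ScalarMap(kind="ODI", data=data, grid=self.grid, affine=self.affine)


# grid-search nodes: indices into _KAPPA_GRID so the table needs no kappa
# interpolation during the coarse pass
_KAPPA_SEARCH_IDX = np.array([0, 10, 20, 28, 36, 42, 48, 54, 60, 63])
_VIC_SEARCH = np.linspace(0.05, 0.95, 10)
_VISO_SEARCH = np.array([0.0, 0.1, 0.25, 0.45, 0.7, 1.0])


def fit_noddi(
    dwi: DWIVolume,
    mask: ScalarMap | None = None,
    d_par: float = D_PAR_DEFAULT,
    d_iso: float = D_ISO_DEFAULT,
) -> NoddiParams:
    """Fit (v_ic, kappa, v_iso) per voxel on multi-shell data.

    mu is initialized from the principal eigenvector of a tensor fit over
    all shells and held fixed; the three scalar parameters are found by a
    coarse grid search refined with bounded L-BFGS-B on the residual sum
    of squares.  Deterministic given the inputs (no randomness).
    """
    gtab = dwi.gradients
    shells = gtab.shells
    if len(shells) < 2:
        raise ValidationError(
            f"NODDI requires multi-shell data; found shells {shells.tolist()}"
        )
    shape = dwi.shape
    b0 = gtab.b0_mask
    s0 = dwi.data[..., b0].mean(axis=-1)

    in_mask = np.ones(shape, dtype=bool)
    if mask is not None:
        if mask.shape != shape:
            raise ValidationError(f"mask shape {mask.shape} != data shape {shape}")
        in_mask = np.nan_to_num(mask.data) > 0.5
    valid = in_mask & (s0 > 0)

    tensor = fit_tensor(dwi, mask=mask, max_bval=float(gtab.bvals.max()) + 1)
    mu = tensor.evecs

    # round b-values to their shell for table lookup
    b_shell = np.zeros(len(gtab))
    bv = gtab.bvals.copy()
    for s in shells:
        close = np.abs(bv - s) <= max(50.0, 0.02 * s)
        b_shell = np.where(close & ~b0, s, b_shell)
    tables = _AicTables(shells, d_par)
    a_iso = np.exp(-b_shell * d_iso)

    idx = np.argwhere(valid)
    V = len(idx)
    N = len(gtab)
    if V == 0:
        empty = np.zeros(shape)
        return NoddiParams(v_ic=empty, v_iso=empty.copy(), kappa=empty.copy(),
                           mu=mu, valid=valid, d_par=d_par, d_iso=d_iso,
                           grid=dwi.grid, affine=dwi.affine)

    sig = dwi.data[valid] / s0[valid][:, None]            # (V, N)
    mus = mu[valid]                                        # (V, 3)
    cosb = np.abs(gtab.bvecs @ mus.T)                      # (N, V)
    cosb = np.clip(cosb, 0.0, 1.0)
    y = sig.T                                              # (N, V)

    # ---- coarse grid search, vectorized across voxels --------------------
    best_sse = np.full(V, np.inf)
    best = np.zeros((V, 3))                                # v_ic, kappa, v_iso
    dw_rows = ~b0
    for ki in _KAPPA_SEARCH_IDX:
        kappa = _KAPPA_GRID[ki]
        tau1 = tables.tau1[ki]
        a_ic = np.ones((N, V))
        for b in shells:
            rows = b_shell == b
            tab_col = tables.tables[float(b)][:, ki]
            a_ic[rows] = np.interp(cosb[rows], _COS_GRID, tab_col)
        for vic in _VIC_SEARCH:
            a_ec = extracellular_signal(
                b_shell[dw_rows, None], cosb[dw_rows], vic, tau1, d_par
            )
            tissue = vic * a_ic[dw_rows] + (1.0 - vic) * a_ec
            for viso in _VISO_SEARCH:
                model = (1.0 - viso) * tissue + viso * a_iso[dw_rows, None]
                sse = ((model - y[dw_rows]) ** 2).sum(axis=0)
                upd = sse < best_sse
                if np.any(upd):
                    best_sse[upd] = sse[upd]
                    best[upd] = (vic, kappa, viso)

    # ---- vectorized bounded refinement (compass search over all voxels) --
    bshell_dw = b_shell[dw_rows]
    aiso_dw = a_iso[dw_rows]
    cb_dw = cosb[dw_rows]                                  # (Nd, V)
    y_dw = y[dw_rows]
    rows_by_shell = [bshell_dw == b for b in shells]

    def sse(x):
        """x: (V, 3) columns (v_ic, odi, v_iso); returns (V,) residual SSQ."""
        vic, odi, viso = x[:, 0], x[:, 1], x[:, 2]
        kappa = kappa_from_odi(odi)
        tau1 = tables.tau1_batch(kappa)
        a_ic = np.empty_like(cb_dw)
        for b, rows in zip(shells, rows_by_shell):
            a_ic[rows] = tables.a_ic_batch(b, cb_dw[rows], kappa)
        d_perp = d_par * (1.0 - vic)
        c2 = cb_dw**2
        dapp = d_perp + (d_par - d_perp) * (tau1 * c2 + 0.5 * (1 - tau1) * (1 - c2))
        a_ec = np.exp(-bshell_dw[:, None] * dapp)
        model = (1 - viso) * (vic * a_ic + (1 - vic) * a_ec) + viso * aiso_dw[:, None]
        return ((model - y_dw) ** 2).sum(axis=0)

    lb = np.array([0.0, 1e-3, 0.0])
    ub = np.array([1.0, 1.0, 1.0])
    x = np.column_stack([best[:, 0], odi_from_kappa(best[:, 1]), best[:, 2]])
    x = np.clip(x, lb, ub)
    f = sse(x)
    step = np.full(V, 0.08)
    for _ in range(40):
        improved = np.zeros(V, dtype=bool)
        for j in range(3):
            for sign in (1.0, -1.0):
                xt = x.copy()
                xt[:, j] = np.clip(x[:, j] + sign * step, lb[j], ub[j])
                ft = sse(xt)
                upd = ft < f - 1e-16
                x[upd] = xt[upd]
                f[upd] = ft[upd]
                improved |= upd
        step[~improved] *= 0.5
        if step.max() < 2e-4:
            break

    v_ic = np.zeros(shape)
    v_iso = np.zeros(shape)
    kap = np.zeros(shape)
    v_ic[valid] = x[:, 0]
    v_iso[valid] = x[:, 2]
    kap[valid] = kappa_from_odi(x[:, 1])

    return NoddiParams(
        v_ic=v_ic, v_iso=v_iso, kappa=kap, mu=mu, valid=valid,
        d_par=d_par, d_iso=d_iso, grid=dwi.grid, affine=dwi.affine,
    )
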