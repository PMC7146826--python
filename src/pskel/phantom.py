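"""Synthetic multi-shell DWI phantoms and synthetic two-group cohorts.

The phantom is a voxel grid containing axis-aligned "tract" tubes embedded
in free-water background.  Each tube carries ground-truth tensor
eigenvalues (for the DTI forward model) and NODDI parameters (NDI, ODI).
The tissue fraction tapers as a Gaussian of the distance to the tube
centerline, so the ground-truth FA has a ridge peaking exactly on the
centerline — the geometry the skeletonization stage is built around — and
the taper doubles as a CSF partial-volume rim.

Everything is deterministic given the spec's seed.  Cohort simulation
draws per-subject peak-width metrics around group locations taken from
the published term/preterm summary statistics (medians, with spreads from
IQR/1.349), so downstream statistics can be exercised at realistic scale
without any real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import (
    CohortRecord,
    CohortTable,
    DWIVolume,
    GradientTable,
    ScalarMap,
    ValidationError,
)
from .dti import eigenvalue_scalars
from .noddi import D_ISO_DEFAULT, D_PAR_DEFAULT, kappa_from_odi, noddi_signal

#: diffusivities below are in 1e-3 mm^2/s (so water ~ 3.0)
_UNIT = 1e-3


# ---------------------------------------------------------------------------
# gradient schemes
# ---------------------------------------------------------------------------


def _repulsion_directions(n: int, rng: np.random.Generator,
                          n_iter: int = 200) -> np.ndarray:
    """Near-uniform antipodally-symmetric directions by electrostatic
    repulsion with a fixed iteration budget (deterministic given rng)."""
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.1
    for it in range(n_iter):
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            diff = x[:, None, :] - sign * x[None, :, :]      # (n, n, 3)
            dist2 = (diff**2).sum(-1)
            np.fill_diagonal(dist2, np.inf)
            if sign < 0:
                dist2[dist2 < 1e-12] = np.inf                # own antipode
            force += (diff / (dist2[..., None] ** 1.5 + 1e-12)).sum(axis=1)
        # tangential component only
        force -= (force * x).sum(axis=1, keepdims=True) * x
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        x = x + step * force / norm
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        step *= 0.97
    return x


def make_gradient_scheme(n_b0: int, shells, seed: int = 0) -> GradientTable:
    """Build a multi-shell scheme: ``n_b0`` baselines plus, for each
    ``(bval, n_dirs)`` pair, ``n_dirs`` repulsion-spread directions."""
    if n_b0 < 1:
        raise ValidationError("scheme needs at least one b=0 volume")
    rng = np.random.default_rng(seed)
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for bval, n_dirs in shells:
        if n_dirs < 1:
            raise ValidationError(f"shell b={bval} has n_dirs={n_dirs} < 1")
        dirs = _repulsion_directions(int(n_dirs), rng)
        bvals.extend([float(bval)] * int(n_dirs))
        bvecs.extend(dirs)
    return GradientTable(bvals=np.array(bvals), bvecs=np.array(bvecs))


def default_scheme(seed: int = 0) -> GradientTable:
    """The study's two-acquisition scheme: 8+8 b0, 3 @ b=200, 6 @ b=500,
    64 @ b=750 and 64 @ b=2500 s/mm^2."""
    return make_gradient_scheme(
        16, [(200, 3), (500, 6), (750, 64), (2500, 64)], seed=seed
    )


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------


@dataclass
class Tract:
    """An axis-aligned tube with ground-truth microstructure.

    ``axis`` is the tube direction (0/1/2); ``center`` gives the centerline
    position in the two perpendicular grid axes (in voxel units, ascending
    axis order); ``radius`` is in voxels.  ``eigvals`` are the centerline
    tensor eigenvalues in 1e-3 mm^2/s (descending).  ``v_iso_amplitude``
    adds a sinusoidal CSF partial-volume modulation along the tube, a crude
    stand-in for heterogeneous tissue water content.
    """

    axis: int
    center: tuple
    radius: float
    eigvals: tuple = (1.7, 0.3, 0.3)
    ndi: float = 0.6
    odi: float = 0.2
    excluded: bool = False            # cerebellum/brainstem analog
    margin: int = 2                   # gap to the grid boundary along axis
    v_iso_amplitude: float = 0.0
    v_iso_period: float = 8.0         # voxels
    name: str = "tract"

    def __post_init__(self):
        lam = tuple(float(v) for v in self.eigvals)
        if not (lam[0] >= lam[1] >= lam[2] >= 0):
            raise ValidationError(f"eigenvalues must be descending >= 0, got {lam}")
        if self.radius < 1:
            raise ValidationError("tract radius must be >= 1 voxel")
        for nm, v in (("ndi", self.ndi), ("odi", self.odi)):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{nm} must lie in [0, 1]")
        if not (0.0 <= self.v_iso_amplitude <= 1.0):
            raise ValidationError("v_iso_amplitude must lie in [0, 1]")


@dataclass
class PhantomSpec:
    grid_shape: tuple = (20, 20, 12)
    tracts: list = field(default_factory=list)
    background_diffusivity: float = 3.0     # 1e-3 mm^2/s, CSF-like
    snr: float = np.inf                     # S0-relative
    noise_model: str = "none"               # none | gaussian | rician
    signal_model: str = "noddi"             # noddi | tensor forward model
    voxel_size: float = 2.0                 # mm, isotropic
    s0: float = 1.0
    d_par: float = D_PAR_DEFAULT            # mm^2/s, NODDI intrinsic
    seed: int = 0

    def __post_init__(self):
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.signal_model not in ("noddi", "tensor"):
            raise ValidationError(f"unknown signal model {self.signal_model!r}")
        if not self.snr > 0:
            raise ValidationError("snr must be positive (np.inf for noiseless)")

    @property
    def grid(self):
        return (self.voxel_size,) * 3


@dataclass
class _Fields:
    """Voxelwise ground-truth fields derived from a PhantomSpec."""

    lam: np.ndarray          # (..., 3) eigenvalues, 1e-3 mm^2/s, descending
    diag: np.ndarray         # (..., 3) tensor diagonal along grid axes
    axis: np.ndarray         # (...,) int, tract axis or -1 for background
    tract_id: np.ndarray     # (...,) int, -1 background
    tissue: np.ndarray       # (...,) tissue fraction in [0, 1]
    v_ic: np.ndarray
    odi: np.ndarray


def _phantom_fields(spec: PhantomSpec) -> _Fields:
    shape = tuple(spec.grid_shape)
    coords = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    bg = spec.background_diffusivity
    lam = np.full(shape + (3,), bg)
    diag = np.full(shape + (3,), bg)
    axis = np.full(shape, -1, dtype=int)
    tract_id = np.full(shape, -1, dtype=int)
    tissue = np.zeros(shape)
    v_ic = np.zeros(shape)
    odi = np.zeros(shape)
    rng = np.random.default_rng(spec.seed + 104729)   # phases independent of noise

    for t_idx, tract in enumerate(spec.tracts):
        perp = [a for a in range(3) if a != tract.axis]
        d2 = (coords[perp[0]] - tract.center[0]) ** 2 + (
            coords[perp[1]] - tract.center[1]
        ) ** 2
        sigma = tract.radius / 2.0
        g = np.exp(-d2 / (2.0 * sigma**2))
        along = coords[tract.axis]
        lo, hi = tract.margin, shape[tract.axis] - 1 - tract.margin
        g = np.where((along >= lo) & (along <= hi), g, 0.0)
        if tract.v_iso_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            wave = 0.5 + 0.5 * np.sin(2 * np.pi * along / tract.v_iso_period + phase)
            g = g * (1.0 - tract.v_iso_amplitude * wave)
        takeover = g > tissue
        tissue = np.where(takeover, g, tissue)
        axis[takeover] = tract.axis
        tract_id[takeover] = t_idx
        # eigenvalues blend toward the isotropic background; the ordering
        # lam1 >= lam2 >= lam3 is preserved by the affine blend
        grid_axis_for_eval = {tract.axis: 0, perp[0]: 1, perp[1]: 2}
        for i in range(3):
            lam_i = (tract.eigvals[i] - bg) * g + bg
            lam[..., i] = np.where(takeover, lam_i, lam[..., i])
        for grid_ax, eig_idx in grid_axis_for_eval.items():
            d_i = (tract.eigvals[eig_idx] - bg) * g + bg
            diag[..., grid_ax] = np.where(takeover, d_i, diag[..., grid_ax])
        v_ic[takeover] = tract.ndi
        odi[takeover] = tract.odi
    return _Fields(lam=lam, diag=diag, axis=axis, tract_id=tract_id,
                   tissue=tissue, v_ic=v_ic, odi=odi)


def ground_truth_maps(spec: PhantomSpec) -> dict:
    """Analytic MD/FA/AD/RD/NDI/ODI maps implied by the spec.

    Tensor scalars come from the tissue-blended eigenvalues; NDI and ODI
    equal the tract parameters wherever tissue is present (fraction >
    0.05) and 0 in free water, where they are undefined.
    """
    f = _phantom_fields(spec)
    md, fa, ad, rd = eigenvalue_scalars(f.lam)
    present = f.tissue > 0.05
    ndi = np.where(present, f.v_ic, 0.0)
    odi = np.where(present, f.odi, 0.0)
    grid = spec.grid
    return {
        "MD": ScalarMap(kind="MD", data=md, grid=grid),
        "FA": ScalarMap(kind="FA", data=fa, grid=grid),
        "AD": ScalarMap(kind="AD", data=ad, grid=grid),
        "RD": ScalarMap(kind="RD", data=rd, grid=grid),
        "NDI": ScalarMap(kind="NDI", data=ndi, grid=grid),
        "ODI": ScalarMap(kind="ODI", data=odi, grid=grid),
    }


def _tensor_forward(f: _Fields, gtab: GradientTable, s0: float) -> np.ndarray:
    """exp(-b g'Dg) for the (everywhere diagonal) tensor field."""
    bg2 = gtab.bvals[:, None] * gtab.bvecs**2          # (N, 3)
    q = np.einsum("na,...a->...n", bg2, f.diag)         # g'Dg * b per volume
    return s0 * np.exp(-q * _UNIT)


def _noddi_forward(spec: PhantomSpec, f: _Fields, gtab: GradientTable) -> np.ndarray:
    """Blend of per-tract Watson-model signals and free water.

    The signal is linear in the free-water fraction, so one exact forward
    evaluation per tract suffices; each voxel mixes its tract's tissue
    signal with CSF by its tissue fraction.
    """
    shape = f.lam.shape[:-1]
    N = len(gtab)
    d_iso = spec.background_diffusivity * _UNIT
    s_csf = spec.s0 * np.exp(-gtab.bvals * d_iso)
    signal = np.broadcast_to(s_csf, shape + (N,)).copy()
    axes_mu = np.eye(3)
    for t_idx, tract in enumerate(spec.tracts):
        region = f.tract_id == t_idx
        if not region.any():
            continue
        s_tissue = noddi_signal(
            v_ic=tract.ndi,
            kappa=kappa_from_odi(tract.odi),
            v_iso=0.0,
            mu=axes_mu[tract.axis],
            gradients=gtab,
            d_par=spec.d_par,
            d_iso=d_iso,
            s0=spec.s0,
        )
        w = f.tissue[region][:, None]
        signal[region] = w * s_tissue[None, :] + (1.0 - w) * s_csf[None, :]
    return signal


def simulate_dwi(spec: PhantomSpec, gradients: GradientTable):
    """Simulate the 4-D DWI plus analytic ground-truth maps.

    Rician noise replaces the signal by ||(S + e1, e2)|| with e ~
    N(0, S0/snr), the magnitude-MRI noise floor; Gaussian noise adds e1
    only (clipped at zero).
    """
    f = _phantom_fields(spec)
    if spec.signal_model == "tensor":
        signal = _tensor_forward(f, gradients, spec.s0)
    else:
        signal = _noddi_forward(spec, f, gradients)

    if spec.noise_model != "none" and np.isfinite(spec.snr):
        rng = np.random.default_rng(spec.seed)
        sigma = spec.s0 / spec.snr
        e1 = rng.normal(0.0, sigma, signal.shape)
        if spec.noise_model == "rician":
            e2 = rng.normal(0.0, sigma, signal.shape)
            signal = np.sqrt((signal + e1) ** 2 + e2**2)
        else:
            signal = np.clip(signal + e1, 0.0, None)

    dwi = DWIVolume(data=signal, grid=spec.grid, gradients=gradients)
    return dwi, ground_truth_maps(spec)


def make_template_and_mask(spec: PhantomSpec, rim: int = 1,
                           fa_threshold: float = 0.15):
    """Noiseless FA template plus the custom analysis mask.

    The mask is 1 on the above-threshold support of each non-excluded
    tract, eroded by ``rim`` voxels as a CSF/GM-contamination margin, and
    0 elsewhere (and on every tract flagged ``excluded``, the
    cerebellum/brainstem analog).
    """
    if not spec.tracts:
        raise ValidationError("phantom needs at least one tract for a template")
    f = _phantom_fields(spec)
    gt = ground_truth_maps(spec)
    template_fa = gt["FA"]
    mask = np.zeros(spec.grid_shape, dtype=bool)
    for t_idx, tract in enumerate(spec.tracts):
        if tract.excluded:
            continue
        support = (f.tract_id == t_idx) & (template_fa.data > fa_threshold)
        if rim > 0:
            support = ndimage.binary_erosion(support, iterations=rim)
        mask |= support
    return template_fa, ScalarMap(kind="MASK", data=mask.astype(float), grid=spec.grid)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: Group medians of the six peak-width metrics (term, preterm) — the
#: published summary statistics that anchor the generator's scale.
DEFAULT_LOCATIONS = {
    "PSMD": (0.50, 0.60),
    "PSFA": (0.32, 0.32),
    "PSAD": (0.70, 0.75),
    "PSRD": (0.62, 0.72),
    "PSNDI": (0.22, 0.24),
    "PSODI": (0.26, 0.27),
}

#: Group spreads: IQR / 1.349 (normal approximation from the published
#: 25th/75th percentiles).
DEFAULT_SCALES = {
    "PSMD": (0.06 / 1.349, 0.09 / 1.349),
    "PSFA": (0.02 / 1.349, 0.02 / 1.349),
    "PSAD": (0.04 / 1.349, 0.06 / 1.349),
    "PSRD": (0.09 / 1.349, 0.09 / 1.349),
    "PSNDI": (0.02 / 1.349, 0.02 / 1.349),
    "PSODI": (0.02 / 1.349, 0.01 / 1.349),
}

DEFAULT_GA_BIRTH = {"term": (36.42, 42.0), "preterm": (23.42, 32.0)}
DEFAULT_GA_SCAN = (38.0, 44.56)


@dataclass
class CohortSpec:
    n_term: int = 59
    n_preterm: int = 76
    locations: dict = field(default_factory=lambda: dict(DEFAULT_LOCATIONS))
    scales: dict = field(default_factory=lambda: dict(DEFAULT_SCALES))
    ga_birth_range: dict = field(default_factory=lambda: dict(DEFAULT_GA_BIRTH))
    ga_scan_range: tuple = DEFAULT_GA_SCAN
    age_slope: dict = field(default_factory=dict)   # per-metric, per week of GA at scan
    seed: int = 0

    def __post_init__(self):
        if self.n_term <= 0 or self.n_preterm <= 0:
            raise ValidationError("group counts must be positive")
        for m, (a, b) in self.scales.items():
            if a < 0 or b < 0:
                raise ValidationError(f"negative scale for {m}")
        for g, (lo, hi) in self.ga_birth_range.items():
            if not (22.0 <= lo <= hi <= 46.0):
                raise ValidationError(f"ga_birth range for {g} outside [22, 46]")


def simulate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a two-group cohort with peak-width metrics.

    Each metric is group location + age_slope * (GA at scan - sample mean
    GA at scan) + Gaussian noise of the group scale.  Deterministic given
    the seed.
    """
    rng = np.random.default_rng(spec.seed)
    groups = ["term"] * spec.n_term + ["preterm"] * spec.n_preterm
    n = len(groups)
    ga_birth = np.empty(n)
    ga_scan = np.empty(n)
    for i, g in enumerate(groups):
        lo, hi = spec.ga_birth_range[g]
        ga_birth[i] = rng.uniform(lo, hi)
        slo, shi = spec.ga_scan_range
        ga_scan[i] = rng.uniform(max(slo, ga_birth[i]), shi)
    ga_scan_centered = ga_scan - ga_scan.mean()

    records = []
    width = len(str(n))
    for i, g in enumerate(groups):
        col = 0 if g == "term" else 1
        metrics = {}
        for m in spec.locations:
            loc = spec.locations[m][col]
            scale = spec.scales.get(m, (0.0, 0.0))[col]
            slope = spec.age_slope.get(m, 0.0)
            noise = rng.normal(0.0, scale) if scale > 0 else 0.0
            metrics[m] = loc + slope * ga_scan_centered[i] + noise
        records.append(
            CohortRecord(
                subject_id=f"S{i + 1:0{width}d}",
                group=g,
                ga_birth=float(ga_birth[i]),
                ga_scan=float(ga_scan[i]),
                metrics=metrics,
            )
        )
    return CohortTable(records=records)


def two_tube_spec(**overrides) -> PhantomSpec:
    """The standard two-tube test phantom: one tube along x, one along y,
    vertically separated so their skeletons are disjoint."""
    defaults = dict(
        grid_shape=(20, 20, 12),
        tracts=[
            Tract(axis=0, center=(7.0, 4.0), radius=3.0, name="tube_x"),
            Tract(axis=1, center=(13.0, 8.0), radius=3.0, name="tube_y",
                  eigvals=(1.5, 0.35, 0.35), ndi=0.5, odi=0.3),
        ],
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)
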