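import numpy as np
import pytest
from scipy import ndimage

from pskel.dti import design_matrix, fit_tensor
from pskel.io import ValidationError
from pskel.phantom import (
    CohortSpec,
    PhantomSpec,
    Tract,
    ground_truth_maps,
    make_gradient_scheme,
    make_template_and_mask,
    simulate_cohort,
    simulate_dwi,
    _phantom_fields,
)


class TestGradientScheme:
    def test_study_shell_layout(self):
        gtab = make_gradient_scheme(8, [(750, 64)], seed=1)
        assert len(gtab) == 72
        assert int(gtab.b0_mask.sum()) == 8
        assert gtab.shells.tolist() == [750.0]

    def test_minimal_tensor_design_is_well_posed(self):
        gtab = make_gradient_scheme(1, [(1000, 6)], seed=2)
        assert len(gtab) == 7
        X = design_matrix(gtab.bvals, gtab.bvecs)
        assert np.linalg.matrix_rank(X) == 7
        assert np.isfinite(np.linalg.cond(X))

    def test_no_b0_rejected(self):
        with pytest.raises(ValidationError, match="b=0"):
            make_gradient_scheme(0, [(750, 6)])

    def test_empty_shell_rejected(self):
        with pytest.raises(ValidationError, match="n_dirs"):
            make_gradient_scheme(1, [(750, 0)])

    def test_directions_near_uniform(self):
        gtab = make_gradient_scheme(1, [(750, 32)], seed=3)
        dirs = gtab.bvecs[gtab.bvals > 0]
        # repulsion keeps the closest (antipodally identified) pair apart
        dots = np.abs(dirs @ dirs.T)
        np.fill_diagonal(dots, 0.0)
        assert dots.max() < 0.995

    def test_deterministic_given_seed(self):
        a = make_gradient_scheme(2, [(750, 12)], seed=9)
        b = make_gradient_scheme(2, [(750, 12)], seed=9)
        assert np.array_equal(a.bvecs, b.bvecs)


class TestTensorForwardModel:
    def _one_voxel_spec(self):
        return PhantomSpec(
            grid_shape=(1, 1, 1),
            tracts=[Tract(axis=0, center=(0.0, 0.0), radius=1.0,
                          eigvals=(1.7, 0.3, 0.3), margin=0)],
            signal_model="tensor",
        )

    def test_single_voxel_closed_form(self):
        from pskel.io import GradientTable

        gtab = GradientTable(bvals=[0.0, 1000.0], bvecs=[[0, 0, 0], [1, 0, 0]])
        dwi, _ = simulate_dwi(self._one_voxel_spec(), gtab)
        assert dwi.data[0, 0, 0, 1] == pytest.approx(np.exp(-1.7), rel=1e-12)
        assert dwi.data[0, 0, 0, 0] == pytest.approx(1.0)

    def test_isotropic_background_direction_independent(self, dti_scheme):
        spec = PhantomSpec(grid_shape=(2, 2, 2), tracts=[],
                           background_diffusivity=3.0, signal_model="tensor")
        dwi, _ = simulate_dwi(spec, dti_scheme)
        dw = dti_scheme.bvals > 50
        sig = dwi.data[0, 0, 0, dw]
        assert np.ptp(sig) < 1e-12

    def test_noiseless_signals_recover_eigenvalues(self, single_tube, dti_scheme):
        dwi, _ = simulate_dwi(single_tube, dti_scheme)
        field = fit_tensor(dwi)
        lam_true = _phantom_fields(single_tube).lam
        rel = np.abs(field.evals - lam_true) / lam_true
        assert rel.max() < 1e-6


class TestRicianNoise:
    def test_tract_b0_mean_matches_rician_mean(self, single_tube, dti_scheme):
        snr = 30.0
        spec = PhantomSpec(
            grid_shape=single_tube.grid_shape,
            tracts=[Tract(axis=0, center=(6.0, 6.0), radius=3.0, ndi=0.6, odi=0.2)],
            snr=snr, noise_model="rician", signal_model="noddi", seed=5,
        )
        dwi, _ = simulate_dwi(spec, dti_scheme)
        f = _phantom_fields(spec)
        core = f.tissue > 0.9            # voxels where S(b0) = s0 = 1
        b0_vals = dwi.data[core][:, dti_scheme.b0_mask].ravel()

        # Monte-Carlo oracle for the Rician mean at this snr
        rng = np.random.default_rng(12345)
        sigma = 1.0 / snr
        mc = np.sqrt((1.0 + rng.normal(0, sigma, 200_000)) ** 2
                     + rng.normal(0, sigma, 200_000) ** 2)
        se = np.sqrt(mc.var() / b0_vals.size + mc.var() / mc.size)
        assert abs(b0_vals.mean() - mc.mean()) < 3 * se

    def test_identical_seeds_bit_identical(self, single_tube, dti_scheme):
        spec_kw = dict(grid_shape=(8, 8, 8),
                       tracts=[Tract(axis=0, center=(4.0, 4.0), radius=2.0)],
                       snr=20.0, noise_model="rician", seed=77)
        a, _ = simulate_dwi(PhantomSpec(**spec_kw), dti_scheme)
        b, _ = simulate_dwi(PhantomSpec(**spec_kw), dti_scheme)
        assert np.array_equal(a.data, b.data)


class TestGroundTruth:
    def test_tensor_scalar_identities(self, parallel_tubes):
        gt = ground_truth_maps(parallel_tubes)
        f = _phantom_fields(parallel_tubes)
        lam = f.lam
        assert np.allclose(gt["MD"].data, lam.mean(-1))
        assert np.allclose(gt["AD"].data, lam[..., 0])
        assert np.allclose(gt["RD"].data, 0.5 * (lam[..., 1] + lam[..., 2]))
        iso = np.isclose(np.ptp(lam, axis=-1), 0.0)
        assert np.all(gt["FA"].data[iso] == 0.0)


class TestTemplateAndMask:
    def test_rim_matches_erosion_oracle(self, single_tube):
        template_fa, mask = make_template_and_mask(single_tube, rim=1)
        support = (_phantom_fields(single_tube).tract_id == 0) & (
            template_fa.data > 0.15
        )
        expected = ndimage.binary_erosion(support, iterations=1)
        assert np.array_equal(mask.data.astype(bool), expected)

    def test_excluded_tract_masked_out(self):
        spec = PhantomSpec(
            grid_shape=(16, 20, 12),
            tracts=[
                Tract(axis=0, center=(5.0, 6.0), radius=3.0),
                Tract(axis=0, center=(13.0, 6.0), radius=3.0, excluded=True,
                      name="brainstem_analog"),
            ],
        )
        _, mask = make_template_and_mask(spec, rim=0)
        tid = _phantom_fields(spec).tract_id
        assert mask.data[tid == 1].sum() == 0
        assert mask.data[tid == 0].sum() > 0

    def test_zero_rim_equals_fa_support(self, single_tube):
        template_fa, mask = make_template_and_mask(single_tube, rim=0)
        support = (_phantom_fields(single_tube).tract_id == 0) & (
            template_fa.data > 0.15
        )
        assert np.array_equal(mask.data.astype(bool), support)


class TestCohortSimulation:
    def test_zero_noise_zero_slope_is_exact_location(self):
        spec = CohortSpec(
            n_term=5, n_preterm=5,
            scales={m: (0.0, 0.0) for m in ("PSMD", "PSFA")},
            locations={"PSMD": (0.50, 0.60), "PSFA": (0.32, 0.32)},
            seed=1,
        )
        cohort = simulate_cohort(spec)
        for r in cohort.records:
            expected = 0.50 if r.group == "term" else 0.60
            assert r.metrics["PSMD"] == expected

    def test_linear_age_effect_recovered_exactly(self):
        spec = CohortSpec(
            n_term=20, n_preterm=20,
            locations={"PSMD": (0.5, 0.5)},
            scales={"PSMD": (0.0, 0.0)},
            age_slope={"PSMD": 0.01},
            seed=2,
        )
        cohort = simulate_cohort(spec)
        df = cohort.to_dataframe()
        X = np.column_stack([np.ones(len(df)), df["ga_scan"]])
        beta, *_ = np.linalg.lstsq(X, df["PSMD"], rcond=None)
        assert beta[1] == pytest.approx(0.01, abs=1e-10)

    def test_group_medians_match_published_scale(self):
        # medians over 30 seeds: term PSMD near 0.50, preterm near 0.60
        term_meds, pre_meds = [], []
        for seed in range(30):
            df = simulate_cohort(CohortSpec(seed=seed)).to_dataframe()
            term_meds.append(df.loc[df.group == "term", "PSMD"].median())
            pre_meds.append(df.loc[df.group == "preterm", "PSMD"].median())
        assert 0.45 <= np.mean(term_meds) <= 0.55
        assert 0.55 <= np.mean(pre_meds) <= 0.65

    def test_deterministic_given_seed(self):
        a = simulate_cohort(CohortSpec(seed=3)).to_dataframe()
        b = simulate_cohort(CohortSpec(seed=3)).to_dataframe()
        assert a.equals(b)
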