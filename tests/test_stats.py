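import numpy as np
import pandas as pd
import pytest

from pskel.io import CohortRecord, CohortTable, ValidationError
from pskel.phantom import CohortSpec, simulate_cohort
from pskel.stats import (
    ResidualizedMetrics,
    compute_stat_report,
    correlate_with_ga,
    cv_classify,
    group_compare,
    residualize,
)


def _cohort_from_arrays(metrics, groups, ga_birth, ga_scan):
    records = []
    for i in range(len(groups)):
        records.append(
            CohortRecord(
                subject_id=f"s{i:03d}",
                group=groups[i],
                ga_birth=float(ga_birth[i]),
                ga_scan=float(ga_scan[i]),
                metrics={m: float(v[i]) for m, v in metrics.items()},
            )
        )
    return CohortTable(records=records)


def _basic_cohort(n=40, seed=0, metric_fn=None):
    rng = np.random.default_rng(seed)
    groups = ["term"] * (n // 2) + ["preterm"] * (n - n // 2)
    ga_birth = np.where([g == "term" for g in groups],
                        rng.uniform(37, 42, n), rng.uniform(24, 32, n))
    ga_scan = np.maximum(ga_birth + 0.5, rng.uniform(38, 44, n))
    if metric_fn is None:
        metric_fn = lambda: rng.normal(0.5, 0.05, n)
    metrics = {"PSMD": metric_fn() if callable(metric_fn) else metric_fn}
    return _cohort_from_arrays(metrics, groups, ga_birth, ga_scan), ga_scan, ga_birth


class TestResidualize:
    def test_exact_linear_metric_leaves_zero_residuals(self):
        cohort, ga_scan, _ = _basic_cohort()
        for r, gs in zip(cohort.records, ga_scan):
            r.metrics["PSMD"] = 2.0 * gs + 1.0
        resid = residualize(cohort)
        assert np.abs(resid.residuals["PSMD"]).max() < 1e-10
        assert resid.coefficients["PSMD"][1] == pytest.approx(2.0)

    def test_independent_metric_residuals_are_centered_values(self):
        rng = np.random.default_rng(1)
        cohort, ga_scan, _ = _basic_cohort(seed=1)
        vals = rng.normal(0.5, 0.05, len(cohort))
        # orthogonalize against ga_scan so the true slope is exactly 0
        gs_c = ga_scan - ga_scan.mean()
        vals = vals - gs_c * (vals @ gs_c) / (gs_c @ gs_c)
        for r, v in zip(cohort.records, vals):
            r.metrics["PSMD"] = v
        resid = residualize(cohort)
        assert np.allclose(resid.residuals["PSMD"], vals - vals.mean(), atol=1e-12)

    def test_residual_invariants(self):
        cohort, ga_scan, _ = _basic_cohort(seed=2)
        resid = residualize(cohort)
        r = resid.residuals["PSMD"].to_numpy()
        assert abs(r.sum()) < 1e-10
        assert abs(np.corrcoef(r, ga_scan)[0, 1]) < 1e-10

    def test_known_slope_recovered_within_3_se(self):
        cohort = simulate_cohort(
            CohortSpec(age_slope={m: 0.01 for m in ("PSMD",)}, seed=3)
        )
        resid = residualize(cohort)
        slope = resid.coefficients["PSMD"][1]
        # standard error of the OLS slope
        x = resid.ga_scan
        r = resid.residuals["PSMD"].to_numpy()
        se = np.sqrt((r @ r) / (len(x) - 2) / ((x - x.mean()) ** 2).sum())
        assert abs(slope - 0.01) < 3 * se

    def test_constant_ga_scan_rejected(self):
        cohort, _, _ = _basic_cohort()
        for r in cohort.records:
            r.ga_scan = 41.0
            r.ga_birth = min(r.ga_birth, 41.0)
        with pytest.raises(ValidationError, match="constant"):
            residualize(cohort)


class TestCorrelateWithGa:
    def _resid(self, values, ga_birth):
        n = len(values)
        return ResidualizedMetrics(
            residuals=pd.DataFrame({"PSMD": values}),
            coefficients={"PSMD": (0.0, 0.0)},
            ga_scan=np.linspace(38, 44, n),
            ga_birth=np.asarray(ga_birth, dtype=float),
            group=np.array(["term"] * (n // 2) + ["preterm"] * (n - n // 2)),
        )

    def test_identity_gives_r_one(self):
        ga = np.linspace(25, 42, 30)
        r, p = correlate_with_ga(self._resid(ga.copy(), ga))["PSMD"]
        assert r == pytest.approx(1.0)

    def test_negative_limit(self):
        rng = np.random.default_rng(4)
        ga = np.linspace(25, 42, 30)
        vals = -ga + rng.normal(0, 1e-9, 30)
        r, _ = correlate_with_ga(self._resid(vals, ga))["PSMD"]
        assert r == pytest.approx(-1.0, abs=1e-6)

    def test_moderate_negative_correlation_recovered(self):
        # population r = -0.5 at n = 135: sample r within the Fisher-z band
        rng = np.random.default_rng(5)
        n = 135
        ga = rng.uniform(23, 42, n)
        z = (ga - ga.mean()) / ga.std()
        vals = -0.5 * z + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        r, p = correlate_with_ga(self._resid(vals, ga))["PSMD"]
        assert -0.65 <= r <= -0.35
        assert p < 0.01

    def test_zero_variance_rejected(self):
        ga = np.linspace(25, 42, 30)
        with pytest.raises(ValidationError, match="variance"):
            correlate_with_ga(self._resid(np.ones(30), ga))


def _resid_two_group(term_vals, pre_vals, metrics=("PSMD",)):
    n_t, n_p = len(term_vals[metrics[0]]), len(pre_vals[metrics[0]])
    data = {m: np.concatenate([term_vals[m], pre_vals[m]]) for m in metrics}
    return ResidualizedMetrics(
        residuals=pd.DataFrame(data),
        coefficients={m: (0.0, 0.0) for m in metrics},
        ga_scan=np.linspace(38, 44, n_t + n_p),
        ga_birth=np.concatenate([np.full(n_t, 39.5), np.full(n_p, 29.5)]),
        group=np.array(["term"] * n_t + ["preterm"] * n_p),
    )


class TestGroupCompare:
    def test_mirrored_groups_give_p_one_on_t_branch(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0.0, 1.0, 40)
        resid = _resid_two_group({"PSMD": vals}, {"PSMD": vals.copy()})
        res = group_compare(resid)["PSMD"]
        assert res.test == "t"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)

    def test_bh_adjustment_matches_step_up_oracle(self):
        def bh_oracle(p):
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(7)
        # large separations for 5 metrics, none for the last
        n = 30
        metrics = [f"PSM{i}" for i in range(6)]
        term = {m: rng.normal(i * 0.2, 1.0, n) for i, m in enumerate(metrics)}
        pre = {m: rng.normal(i * 0.2 + (0 if i == 5 else 1.0), 1.0, n)
               for i, m in enumerate(metrics)}
        resid = _resid_two_group(term, pre, metrics=metrics)
        res = group_compare(resid)
        raw = np.array([res[m].p_raw for m in metrics])
        adj = np.array([res[m].p_fdr for m in metrics])
        assert np.allclose(adj, bh_oracle(raw))
        assert np.all(adj >= raw - 1e-15)

    def test_small_group_falls_back_to_mannwhitney(self):
        rng = np.random.default_rng(8)
        resid = _resid_two_group(
            {"PSMD": rng.normal(0, 1, 5)}, {"PSMD": rng.normal(0, 1, 20)}
        )
        with pytest.warns(UserWarning, match="Mann-Whitney"):
            res = group_compare(resid)["PSMD"]
        assert res.test == "mann-whitney"

    def test_type_i_error_control_on_null_cohorts(self):
        # no group effect anywhere: the average fraction of metrics with
        # adjusted p < 0.05 stays at or below 0.05
        rng = np.random.default_rng(9)
        metrics = [f"M{i}" for i in range(6)]
        frac = []
        for _ in range(200):
            n = 30
            term = {m: rng.normal(0, 1, n) for m in metrics}
            pre = {m: rng.normal(0, 1, n) for m in metrics}
            res = group_compare(_resid_two_group(term, pre, metrics=metrics))
            frac.append(np.mean([res[m].p_fdr < 0.05 for m in metrics]))
        assert np.mean(frac) <= 0.05


class TestCvClassify:
    def test_separable_cohort_is_perfect(self):
        rng = np.random.default_rng(10)
        term = {"PSMD": rng.normal(0.0, 1.0, 30)}
        pre = {"PSMD": rng.normal(10.0, 1.0, 30)}
        resid = _resid_two_group(term, pre)
        res = cv_classify(resid, n_repeats=5, n_folds=10, seed=1)[("PSMD",)]
        assert res.accuracy_mean == 1.0
        assert res.accuracy_sd == 0.0

    def test_permuted_labels_give_chance_level(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(0.0, 1.0, 60)      # labels independent of values
        resid = _resid_two_group({"PSMD": vals[:30]}, {"PSMD": vals[30:]})
        res = cv_classify(resid, n_repeats=30, n_folds=10, seed=2)[("PSMD",)]
        assert 0.40 <= res.accuracy_mean <= 0.60

    def test_multivariate_close_to_univariate_when_one_feature_informative(self):
        rng = np.random.default_rng(12)
        n = 60
        term = {"PSMD": rng.normal(0.0, 1.0, n), "PSFA": rng.normal(0, 1, n)}
        pre = {"PSMD": rng.normal(1.8, 1.0, n), "PSFA": rng.normal(0, 1, n)}
        resid = _resid_two_group(term, pre, metrics=("PSMD", "PSFA"))
        res = cv_classify(
            resid, feature_sets=[("PSMD",), ("PSMD", "PSFA")],
            n_repeats=10, n_folds=10, seed=3,
        )
        assert abs(res[("PSMD",)].accuracy_mean
                   - res[("PSMD", "PSFA")].accuracy_mean) <= 0.05

    def test_stratification_keeps_fold_proportions(self):
        from sklearn.model_selection import StratifiedKFold

        labels = np.array([0] * 59 + [1] * 76)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        overall = labels.mean()
        for _, test in skf.split(np.zeros((135, 1)), labels):
            n_pre = labels[test].sum()
            expected = overall * len(test)
            assert abs(n_pre - expected) <= 1.0

    def test_too_many_folds_rejected(self):
        rng = np.random.default_rng(13)
        resid = _resid_two_group(
            {"PSMD": rng.normal(0, 1, 5)}, {"PSMD": rng.normal(0, 1, 30)}
        )
        with pytest.raises(ValidationError, match="n_folds"):
            cv_classify(resid, n_folds=10)


class TestStatReport:
    def test_full_report_deterministic_given_seed(self):
        cohort = simulate_cohort(CohortSpec(n_term=20, n_preterm=25, seed=14))
        a = compute_stat_report(cohort, n_repeats=3, n_folds=5, seed=9).to_dict()
        b = compute_stat_report(cohort, n_repeats=3, n_folds=5, seed=9).to_dict()
        assert a == b

    def test_report_structure_covers_all_metrics(self):
        cohort = simulate_cohort(CohortSpec(n_term=20, n_preterm=25, seed=15))
        rep = compute_stat_report(cohort, n_repeats=2, n_folds=5, seed=0)
        d = rep.to_dict()
        for m in ("PSMD", "PSFA", "PSAD", "PSRD", "PSNDI", "PSODI"):
            assert m in d["correlations"]
            assert m in d["group_tests"]
            assert d["group_tests"][m]["p_fdr"] >= d["group_tests"][m]["p_raw"] - 1e-15
            assert m in d["classification"]
        assert "PSMD+PSFA+PSAD+PSRD" in d["classification"]
        for c in d["classification"].values():
            assert 0.0 <= c["accuracy_mean"] <= 1.0
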