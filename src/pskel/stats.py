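"""Cohort statistics on the peak-width metrics.

The analysis mirrors the study design: each metric is first adjusted for
age at scan by ordinary least squares on GA at scan over the whole sample
(retaining residuals); residualized metrics are then (a) correlated with
GA at birth (Pearson), (b) compared between term and preterm groups with
a D'Agostino-Pearson normality gate choosing between the equal-variance
two-sample t-test and the Mann-Whitney U test, with Benjamini-Hochberg
FDR adjustment across the six metrics, and (c) fed to a logistic
regression classifier evaluated by repeated stratified k-fold
cross-validation (30 repeats x 10 folds by default), with features
standardized inside each training fold so no information leaks from the
held-out fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .io import PS_METRICS, CohortTable, ValidationError

ALPHA_NORMALITY = 0.05
N_REPEATS = 30
N_FOLDS = 10
_MIN_GROUP_FOR_NORMALITY = 8


@dataclass
class ResidualizedMetrics:
    """Residuals of each metric after removing a linear GA-at-scan effect."""

    residuals: pd.DataFrame        # index: subject_id, columns: metrics
    coefficients: dict             # metric -> (intercept, slope)
    ga_scan: np.ndarray
    ga_birth: np.ndarray
    group: np.ndarray              # "term"/"preterm", aligned with residuals

    @property
    def metrics(self):
        return list(self.residuals.columns)


def _metric_frame(cohort: CohortTable, metrics) -> pd.DataFrame:
    df = cohort.to_dataframe()
    if metrics is None:
        metrics = [m for m in PS_METRICS if m in df.columns]
    missing = [m for m in metrics if m not in df.columns]
    if missing:
        raise ValidationError(f"cohort lacks metric columns {missing}")
    if not metrics:
        raise ValidationError("cohort has no peak-width metric columns")
    return df.set_index("subject_id"), list(metrics)


def residualize(cohort: CohortTable, metrics=None) -> ResidualizedMetrics:
    """OLS of each metric on GA at scan over the whole sample; residuals
    sum to zero and are exactly uncorrelated with GA at scan."""
    df, metrics = _metric_frame(cohort, metrics)
    if len(df) < 3:
        raise ValidationError("residualization needs at least 3 subjects")
    ga_scan = df["ga_scan"].to_numpy(dtype=float)
    if np.ptp(ga_scan) < 1e-12:
        raise ValidationError("GA at scan is constant; cannot residualize")
    X = np.column_stack([np.ones_like(ga_scan), ga_scan])
    resid = {}
    coefs = {}
    for m in metrics:
        y = df[m].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid[m] = y - X @ beta
        coefs[m] = (float(beta[0]), float(beta[1]))
    return ResidualizedMetrics(
        residuals=pd.DataFrame(resid, index=df.index),
        coefficients=coefs,
        ga_scan=ga_scan,
        ga_birth=df["ga_birth"].to_numpy(dtype=float),
        group=df["group"].to_numpy(),
    )


def correlate_with_ga(resid: ResidualizedMetrics) -> dict:
    """Pearson r (and two-sided p) of each residualized metric vs GA at birth."""
    if len(resid.ga_birth) < 3:
        raise ValidationError("correlation needs at least 3 subjects")
    out = {}
    for m in resid.metrics:
        y = resid.residuals[m].to_numpy()
        if np.ptp(y) < 1e-15:
            raise ValidationError(f"metric {m} has zero variance")
        r, p = sps.pearsonr(y, resid.ga_birth)
        out[m] = (float(r), float(p))
    return out


@dataclass
class GroupTestResult:
    metric: str
    normality_p: float
    test: str              # "t" or "mann-whitney"
    statistic: float
    p_raw: float
    p_fdr: float = np.nan


def group_compare(resid: ResidualizedMetrics,
                  alpha_normality: float = ALPHA_NORMALITY) -> dict:
    """Normality-gated two-group tests with Benjamini-Hochberg adjustment.

    Pooled residuals of each metric pass through the D'Agostino-Pearson
    omnibus test; metrics that look normal (p >= alpha) use the
    equal-variance two-sample t-test, the rest the two-sided Mann-Whitney
    U.  With fewer than 8 subjects in a group the normality test is
    unreliable and the Mann-Whitney branch is used with a warning.
    """
    is_term = resid.group == "term"
    if not is_term.any() or is_term.all():
        raise ValidationError("group comparison needs both term and preterm subjects")
    results = {}
    for m in resid.metrics:
        y = resid.residuals[m].to_numpy()
        a, b = y[~is_term], y[is_term]          # preterm, term
        if min(len(a), len(b)) < _MIN_GROUP_FOR_NORMALITY:
            warnings.warn(
                f"{m}: a group has n < {_MIN_GROUP_FOR_NORMALITY}; normality "
                "test unreliable, falling back to Mann-Whitney",
                stacklevel=2,
            )
            norm_p = np.nan
            use_t = False
        else:
            norm_p = float(sps.normaltest(y).pvalue)
            use_t = norm_p >= alpha_normality
        if use_t:
            stat, p = sps.ttest_ind(a, b, equal_var=True)
            test = "t"
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann-whitney"
        results[m] = GroupTestResult(
            metric=m, normality_p=norm_p, test=test,
            statistic=float(stat), p_raw=float(p),
        )
    raw = [results[m].p_raw for m in resid.metrics]
    _, p_adj, _, _ = multipletests(raw, method="fdr_bh")
    for m, pa in zip(resid.metrics, p_adj):
        results[m].p_fdr = float(pa)
    return results


@dataclass
class CVResult:
    feature_set: tuple
    accuracy_mean: float
    accuracy_sd: float      # across all fold-level accuracies
    fold_accuracies: np.ndarray


def cv_classify(
    resid: ResidualizedMetrics,
    feature_sets=None,
    n_repeats: int = N_REPEATS,
    n_folds: int = N_FOLDS,
    seed: int = 0,
) -> dict:
    """Repeated stratified k-fold logistic classification of term vs preterm.

    Per repeat, a fresh seeded stratified partition; logistic regression
    (unregularized maximum likelihood, with intercept) is trained on k-1
    folds with features standardized by the training fold's mean/sd, and
    evaluated on the held-out fold.  Reports mean and sd of accuracy over
    all folds x repeats per feature set.
    """
    if feature_sets is None:
        feature_sets = [(m,) for m in resid.metrics]
    labels = (resid.group == "preterm").astype(int)
    n_min = min(int(labels.sum()), int((1 - labels).sum()))
    if n_folds > n_min:
        raise ValidationError(
            f"n_folds={n_folds} exceeds the smaller group size {n_min}"
        )
    master = np.random.default_rng(seed)
    repeat_seeds = master.integers(0, 2**31 - 1, size=n_repeats)

    out = {}
    for fs in feature_sets:
        fs = tuple(fs)
        X_all = resid.residuals[list(fs)].to_numpy(dtype=float)
        accs = []
        for rep_seed in repeat_seeds:
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=int(rep_seed))
            for train, test in skf.split(X_all, labels):
                y_tr, y_te = labels[train], labels[test]
                if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
                    raise RuntimeError(
                        "single-class fold despite stratification (internal error)"
                    )
                mu = X_all[train].mean(axis=0)
                sd = X_all[train].std(axis=0)
                sd[sd == 0] = 1.0
                X_tr = (X_all[train] - mu) / sd
                X_te = (X_all[test] - mu) / sd
                # C=inf: plain (unregularized) maximum likelihood
                clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
                clf.fit(X_tr, y_tr)
                accs.append(float((clf.predict(X_te) == y_te).mean()))
        accs = np.array(accs)
        out[fs] = CVResult(
            feature_set=fs,
            accuracy_mean=float(accs.mean()),
            accuracy_sd=float(accs.std()),
            fold_accuracies=accs,
        )
    return out


@dataclass
class StatReport:
    """Per-metric correlation, group-comparison and classification results."""

    correlations: dict          # metric -> (r, p)
    group_tests: dict           # metric -> GroupTestResult
    classification: dict        # feature-set tuple -> CVResult
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "settings": self.settings,
            "correlations": {
                m: {"r": r, "p": p} for m, (r, p) in self.correlations.items()
            },
            "group_tests": {
                m: {
                    "normality_p": g.normality_p,
                    "test": g.test,
                    "statistic": g.statistic,
                    "p_raw": g.p_raw,
                    "p_fdr": g.p_fdr,
                }
                for m, g in self.group_tests.items()
            },
            "classification": {
                "+".join(fs): {
                    "accuracy_mean": c.accuracy_mean,
                    "accuracy_sd": c.accuracy_sd,
                }
                for fs, c in self.classification.items()
            },
        }


def default_feature_sets(metrics) -> list:
    """Each metric alone, plus the DTI-only, NODDI-only and all-metric models."""
    sets = [(m,) for m in metrics]
    dti = tuple(m for m in metrics if m in ("PSMD", "PSFA", "PSAD", "PSRD"))
    noddi = tuple(m for m in metrics if m in ("PSNDI", "PSODI"))
    if len(dti) > 1:
        sets.append(dti)
    if len(noddi) > 1:
        sets.append(noddi)
    if len(metrics) > 1:
        sets.append(tuple(metrics))
    return sets


def compute_stat_report(
    cohort: CohortTable,
    metrics=None,
    feature_sets=None,
    alpha_normality: float = ALPHA_NORMALITY,
    n_repeats: int = N_REPEATS,
    n_folds: int = N_FOLDS,
    seed: int = 0,
) -> StatReport:
    """Run the full statistical analysis on a cohort with metrics filled in."""
    resid = residualize(cohort, metrics=metrics)
    if feature_sets is None:
        feature_sets = default_feature_sets(resid.metrics)
    report = StatReport(
        correlations=correlate_with_ga(resid),
        group_tests=group_compare(resid, alpha_normality=alpha_normality),
        classification=cv_classify(
            resid, feature_sets=feature_sets, n_repeats=n_repeats,
            n_folds=n_folds, seed=seed,
        ),
        settings={
            "alpha_normality": alpha_normality,
            "n_repeats": n_repeats,
            "n_folds": n_folds,
            "seed": seed,
            "metrics": resid.metrics,
        },
    )
    return report
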