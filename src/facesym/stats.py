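"""Cohort statistics: SAI group comparisons, multivariate regression,
multi-folded discrimination testing and anthropometric group tests.

All SAI statistics operate on the log scale (the SAI itself), which is
approximately normally distributed in both cases and controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import InputError, StatisticsError


@dataclass
class GroupComparisonResult:
    groups: tuple[str, ...]
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    statistic: float
    p_value: float
    corrected_p: float
    test: str  # 'welch_t', 'pooled_t', or 'anova'
    correction: str = "none"


@dataclass
class RegressionResult:
    params: pd.DataFrame  # index: term; columns coef, se, t, p, ci_low, ci_high
    n: int
    r_squared: float


def compare_sai_groups(values_by_group: dict[str, np.ndarray],
                       correction: str = "bonferroni",
                       equal_var: bool = False) -> list[GroupComparisonResult]:
    """Pairwise two-sample t-tests plus a one-way ANOVA across all groups.

    Welch (unequal-variance) t-test by default.  Bonferroni multiplies
    each pairwise p by the number of pairwise comparisons, capped at 1;
    the ANOVA p is reported uncorrected.
    """
    if correction not in ("none", "bonferroni"):
        raise InputError(f"unknown correction {correction!r}")
    groups = {g: np.asarray(v, float) for g, v in values_by_group.items()}
    for g, v in groups.items():
        if len(v) < 2:
            raise StatisticsError(f"group {g!r} has fewer than 2 subjects")
    names = sorted(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    n_tests = len(pairs)
    results: list[GroupComparisonResult] = []

    def summarize(sel: tuple[str, ...]) -> tuple[dict, dict, dict]:
        means = {g: float(groups[g].mean()) for g in sel}
        sds = {g: float(groups[g].std(ddof=1)) for g in sel}
        ns = {g: int(len(groups[g])) for g in sel}
        return means, sds, ns

    for a, b in pairs:
        t, p = sps.ttest_ind(groups[a], groups[b], equal_var=equal_var)
        cp = min(1.0, p * n_tests) if correction == "bonferroni" else p
        means, sds, ns = summarize((a, b))
        results.append(GroupComparisonResult(
            groups=(a, b), means=means, sds=sds, ns=ns, statistic=float(t),
            p_value=float(p), corrected_p=float(cp),
            test="pooled_t" if equal_var else "welch_t", correction=correction))

    if len(names) > 2:
        f, p = sps.f_oneway(*(groups[g] for g in names))
        means, sds, ns = summarize(tuple(names))
        results.append(GroupComparisonResult(
            groups=tuple(names), means=means, sds=sds, ns=ns,
            statistic=float(f), p_value=float(p), corrected_p=float(p),
            test="anova", correction="none"))
    return results


def sai_regression(cohort: pd.DataFrame, sai: pd.Series | np.ndarray,
                   predictors: tuple[str, ...] = ("age", "gender", "group")) -> RegressionResult:
    """OLS of SAI on age, gender (male = 1) and epilepsy-type dummies.

    Group dummies use controls (CTRL) as the reference level.  Reports
    coefficient, SE, t, two-sided p and 95% CI per predictor.
    """
    df = cohort.reset_index(drop=True)
    y = np.asarray(sai, float)
    if len(y) != len(df):
        raise InputError("SAI vector and cohort table have different lengths")
    cols: dict[str, np.ndarray] = {}
    if "age" in predictors:
        cols["age"] = df["age"].to_numpy(float)
    if "gender" in predictors:
        cols["gender_male"] = (df["gender"].astype(str) == "M").to_numpy(float)
    if "group" in predictors:
        for g in ("FC", "FS", "IGE"):
            if (df["group"] == g).any():
                cols[g] = (df["group"] == g).to_numpy(float)
    x = pd.DataFrame(cols)
    constant = [c for c in x.columns if x[c].nunique() == 1]
    if constant:
        raise StatisticsError(f"collinear (constant) design columns: {constant}")
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        # name the columns involved in the collinearity
        bad = []
        base = design.to_numpy()
        for j, c in enumerate(design.columns):
            others = np.delete(base, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(base):
                bad.append(c)
        raise StatisticsError(f"collinear design columns: {bad}")
    if len(df) <= design.shape[1]:
        raise StatisticsError("not enough subjects for the number of predictors")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    params = pd.DataFrame({
        "coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues,
        "ci_low": ci[0], "ci_high": ci[1],
    })
    return RegressionResult(params=params, n=int(fit.nobs), r_squared=float(fit.rsquared))


class ClosestMeanClassifier:
    """Assign to the nearest class centroid in PC space (Euclidean)."""

    def fit(self, x: np.ndarray, y: np.ndarray) -> "ClosestMeanClassifier":
        x = np.asarray(x, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.centroids_ = np.stack([x[y == c].mean(axis=0) for c in self.classes_])
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(np.asarray(x, float)[:, None, :] - self.centroids_[None], axis=2)
        return self.classes_[np.argmin(d, axis=1)]


def discrimination_rates(features: np.ndarray, labels: np.ndarray,
                         folds: int = 10,
                         classifiers: tuple[str, ...] = ("closest_mean", "svm", "lda"),
                         random_state: int = 0) -> dict[str, float]:
    """Stratified k-fold cross-validated accuracy per classifier."""
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise StatisticsError("discrimination requires at least 2 classes")
    if counts.min() < folds:
        raise StatisticsError(
            f"smallest class has {counts.min()} members, fewer than {folds} folds")
    makers = {
        "closest_mean": lambda: ClosestMeanClassifier(),
        "svm": lambda: SVC(kernel="linear"),
        "lda": lambda: LinearDiscriminantAnalysis(),
    }
    unknown = set(classifiers) - set(makers)
    if unknown:
        raise InputError(f"unknown classifiers {sorted(unknown)}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    rates: dict[str, float] = {}
    for name in classifiers:
        correct = 0
        for train, test in skf.split(features, labels):
            clf = makers[name]().fit(features[train], labels[train])
            correct += int(np.sum(clf.predict(features[test]) == labels[test]))
        rates[name] = correct / len(labels)
    return rates


def anthropometric_group_test(lengths: pd.DataFrame,
                              control_group: str = "CTRL",
                              equal_var: bool = False) -> pd.DataFrame:
    """Per-gender, per-measure t-tests of each case group against controls.

    ``lengths`` is tidy: columns subject_id, gender, group, measure,
    value (mm).  Output rows carry the group means and the two-sided p.
    """
    needed = {"gender", "group", "measure", "value"}
    missing = needed - set(lengths.columns)
    if missing:
        raise InputError(f"lengths table missing columns {sorted(missing)}")
    rows = []
    for (gender, measure), sub in lengths.groupby(["gender", "measure"]):
        ctrl = sub.loc[sub["group"] == control_group, "value"].to_numpy(float)
        if len(ctrl) < 2:
            raise StatisticsError(f"too few controls for {gender}/{measure}")
        for case in sorted(set(sub["group"]) - {control_group}):
            vals = sub.loc[sub["group"] == case, "value"].to_numpy(float)
            if len(vals) < 2:
                raise StatisticsError(f"group {case!r} has fewer than 2 subjects")
            t, p = sps.ttest_ind(ctrl, vals, equal_var=equal_var)
            rows.append({
                "gender": gender, "measure": measure, "comparison":
                f"{control_group}:{case}", "mean_control": float(ctrl.mean()),
                "mean_case": float(vals.mean()), "n_control": len(ctrl),
                "n_case": len(vals), "t": float(t), "p": float(p),
            })
    return pd.DataFrame(rows)
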