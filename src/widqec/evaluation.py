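"""Diagnostic test accuracy statistics.

Everything a diagnostic-accuracy report needs: confusion matrices,
sensitivity/specificity with exact (Clopper–Pearson) 95% intervals, PPV/NPV
at an assumed prevalence with prevalence sweeps, empirical ROC curves and
AUC with the pairwise-comparison definition, DeLong's paired AUC test, exact
McNemar paired comparisons, covariate-stratified summaries, and
time-to-diagnosis stratified sensitivity.

Conventions, fixed throughout the package: a score at or above the cutoff is
positive; AUC counts tied case/control score pairs as 1/2; exact binomial
intervals use beta-distribution quantiles; printed percentages round to one
decimal, predictive values to the nearest integer percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import binom, fisher_exact, norm, rankdata

CASE, CONTROL = "case", "control"
POSITIVE, NEGATIVE = "positive", "negative"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class DiagnosticSummary:
    sensitivity: float
    specificity: float
    sens_ci: tuple
    spec_ci: tuple
    ppv: float
    npv: float
    assumed_prevalence: float
    n_cases: int
    n_controls: int

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sens_ci": list(self.sens_ci),
            "spec_ci": list(self.spec_ci),
            "ppv": self.ppv,
            "npv": self.npv,
            "assumed_prevalence": self.assumed_prevalence,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }


@dataclass(frozen=True)
class RocResult:
    auc: float
    curve: np.ndarray  # ordered (fpr, tpr) points
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float


def _check_binary(values: np.ndarray, allowed: tuple, what: str) -> None:
    bad = set(values) - set(allowed)
    if bad:
        raise ValueError(f"unknown {what} categories: {sorted(bad)}")


def confusion(predictions: Sequence[str], truth: Sequence[str]) -> ConfusionMatrix:
    """Exact confusion counts from aligned prediction/truth vectors."""
    pred = np.asarray(predictions)
    ref = np.asarray(truth)
    if pred.shape != ref.shape:
        raise ValueError("predictions and truth must be equal length")
    _check_binary(pred, (POSITIVE, NEGATIVE), "prediction")
    _check_binary(ref, (CASE, CONTROL), "truth")
    return ConfusionMatrix(
        tp=int(((pred == POSITIVE) & (ref == CASE)).sum()),
        fp=int(((pred == POSITIVE) & (ref == CONTROL)).sum()),
        tn=int(((pred == NEGATIVE) & (ref == CONTROL)).sum()),
        fn=int(((pred == NEGATIVE) & (ref == CASE)).sum()),
    )


def sensitivity_specificity(cm: ConfusionMatrix) -> tuple:
    """(tp/(tp+fn), tn/(tn+fp)); errors on an empty class."""
    if cm.n_cases == 0:
        raise ValueError("sensitivity undefined: no reference-positive samples")
    if cm.n_controls == 0:
        raise ValueError("specificity undefined: no reference-negative samples")
    return cm.tp / cm.n_cases, cm.tn / cm.n_controls


def clopper_pearson(successes: int, n: int, conf: float = 0.95) -> tuple:
    """Exact two-sided binomial confidence interval.

    The bounds are beta-distribution quantiles: lower is the ``alpha/2``
    quantile of Beta(successes, n-successes+1) (0 when successes = 0),
    upper the ``1-alpha/2`` quantile of Beta(successes+1, n-successes)
    (1 when successes = n).
    """
    if not (0 <= successes <= n):
        raise ValueError(f"need 0 <= successes <= n, got {successes}/{n}")
    if n < 1:
        raise ValueError("n must be at least 1")
    alpha = 1.0 - conf
    lower = 0.0 if successes == 0 else float(
        beta_dist.ppf(alpha / 2, successes, n - successes + 1)
    )
    upper = 1.0 if successes == n else float(
        beta_dist.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return lower, upper


def predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple:
    """PPV and NPV from sensitivity, specificity and assumed prevalence.

    Bayes' rule on the 2x2 population table; returns NaN where the
    corresponding predictive value is undefined (zero denominator).
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    s, sp, pi = sensitivity, specificity, prevalence
    ppv_den = s * pi + (1 - sp) * (1 - pi)
    npv_den = sp * (1 - pi) + (1 - s) * pi
    ppv = s * pi / ppv_den if ppv_den > 0 else math.nan
    npv = sp * (1 - pi) / npv_den if npv_den > 0 else math.nan
    return ppv, npv


def predictive_value_curve(
    sensitivity: float, specificity: float, prevalence_grid: Sequence[float]
) -> pd.DataFrame:
    """PPV/NPV swept over a prevalence grid.

    For any informative test (0 < sens, spec < 1) PPV rises and NPV falls
    strictly with prevalence — PPV is the prevalence-fragile quantity.
    """
    rows = []
    for pi in prevalence_grid:
        if not (0 < pi < 1):
            raise ValueError(f"grid prevalences must lie in (0, 1), got {pi}")
        ppv, npv = predictive_values(sensitivity, specificity, pi)
        rows.append({"prevalence": pi, "ppv": ppv, "npv": npv})
    return pd.DataFrame(rows, columns=["prevalence", "ppv", "npv"])


def _split_scores(scores: np.ndarray, truth: np.ndarray) -> tuple:
    _check_binary(truth, (CASE, CONTROL), "truth")
    cases = scores[truth == CASE]
    controls = scores[truth == CONTROL]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    return cases, controls


def roc_auc(scores: Sequence[float], truth: Sequence[str]) -> RocResult:
    """Empirical ROC curve and AUC with the pairwise tie convention.

    AUC is the fraction of case/control pairs ranked correctly, ties
    counting one half.  The curve enumerates the ``score >= cutoff``
    operating points over all distinct observed scores, anchored at (0,0)
    and (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    cases, controls = _split_scores(scores, truth)
    n1, n0 = len(cases), len(controls)

    # Mann-Whitney form via mid-ranks: exact pair counting, O(n log n).
    ranks = rankdata(np.concatenate([cases, controls]))
    auc = (ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    cutoffs = np.unique(scores)[::-1]
    points = [(0.0, 0.0)]
    for c in cutoffs:
        tpr = float((cases >= c).sum()) / n1
        fpr = float((controls >= c).sum()) / n0
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return RocResult(auc=float(auc), curve=np.asarray(points), n_cases=n1, n_controls=n0)


def _placements(scores: np.ndarray, truth: np.ndarray) -> tuple:
    """DeLong placement values (mid-rank convention) for one score vector.

    V10[i] = Pr(case_i outranks a random control); V01[j] symmetric.
    """
    cases, controls = _split_scores(scores, truth)
    diff = cases[:, None] - controls[None, :]
    indicator = (diff > 0) + 0.5 * (diff == 0)
    return indicator.mean(axis=1), 1.0 - indicator.mean(axis=0)


def delong_test(
    scores_a: Sequence[float], scores_b: Sequence[float], truth: Sequence[str]
) -> DeLongResult:
    """DeLong's paired comparison of two correlated empirical AUCs.

    Placement values per modality give empirical covariance matrices S10
    (cases) and S01 (controls); the variance of the AUC difference is
    ``(S10[aa]+S10[bb]-2 S10[ab])/n1 + (S01[aa]+S01[bb]-2 S01[ab])/n0``
    and the z statistic is referred to the standard normal.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    truth = np.asarray(truth)
    if a.shape != b.shape or a.shape != truth.shape:
        raise ValueError("paired score vectors must align with truth")
    n1 = int((truth == CASE).sum())
    n0 = int((truth == CONTROL).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 cases and 2 controls")

    v10_a, v01_a = _placements(a, truth)
    v10_b, v01_b = _placements(b, truth)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())

    if np.array_equal(a, b):
        return DeLongResult(auc_a, auc_b, 0.0, 0.0, 1.0)

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([1 - v01_a, 1 - v01_b]), ddof=1)
    var = float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    )
    if var <= 0:
        if auc_a == auc_b:
            return DeLongResult(auc_a, auc_b, 0.0, 0.0, 1.0)
        raise ZeroDivisionError(
            "degenerate variance of the AUC difference with unequal AUCs"
        )
    z = (auc_a - auc_b) / math.sqrt(var)
    p = float(2 * norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, var, float(z), p)


def mcnemar_exact(
    modality_a: Sequence[str], modality_b: Sequence[str]
) -> float:
    """Exact two-sided McNemar p-value for paired binary modalities.

    Conditions on the discordant pairs b = #(a+, b-) and c = #(a-, b+):
    under the null the smaller count is Binomial(b+c, 1/2), and the
    two-sided p is ``min(1, 2 * P(X <= min(b, c)))``; 1 when no pairs
    disagree.
    """
    a = np.asarray(modality_a)
    bb = np.asarray(modality_b)
    if a.shape != bb.shape:
        raise ValueError("paired vectors must be equal length")
    _check_binary(a, (POSITIVE, NEGATIVE), "modality a")
    _check_binary(bb, (POSITIVE, NEGATIVE), "modality b")
    b = int(((a == POSITIVE) & (bb == NEGATIVE)).sum())
    c = int(((a == NEGATIVE) & (bb == POSITIVE)).sum())
    n = b + c
    if n == 0:
        return 1.0
    return min(1.0, 2.0 * float(binom.cdf(min(b, c), n, 0.5)))


def summarize(
    cm: ConfusionMatrix, prevalence: float = 0.09, conf: float = 0.95
) -> DiagnosticSummary:
    """Full summary of a confusion matrix at an assumed prevalence."""
    sens, spec = sensitivity_specificity(cm)
    ppv, npv = predictive_values(sens, spec, prevalence)
    return DiagnosticSummary(
        sensitivity=sens,
        specificity=spec,
        sens_ci=clopper_pearson(cm.tp, cm.n_cases, conf),
        spec_ci=clopper_pearson(cm.tn, cm.n_controls, conf),
        ppv=ppv,
        npv=npv,
        assumed_prevalence=prevalence,
        n_cases=cm.n_cases,
        n_controls=cm.n_controls,
    )


def stratified_performance(
    predictions: Sequence[str],
    truth: Sequence[str],
    strata: Sequence,
    prevalence: float = 0.09,
    conf: float = 0.95,
) -> dict:
    """Per-stratum diagnostic summaries.

    Strata lacking one class report only the defined statistic (the other
    is NaN with an empty CI).
    """
    pred = np.asarray(predictions)
    ref = np.asarray(truth)
    strat = np.asarray(strata)
    if not (len(pred) == len(ref) == len(strat)):
        raise ValueError("inputs must align")
    out: dict = {}
    for value in pd.unique(strat):
        mask = strat == value
        cm = confusion(pred[mask], ref[mask])
        sens = cm.tp / cm.n_cases if cm.n_cases else math.nan
        spec = cm.tn / cm.n_controls if cm.n_controls else math.nan
        ppv, npv = (
            predictive_values(sens, spec, prevalence)
            if cm.n_cases and cm.n_controls
            else (math.nan, math.nan)
        )
        out[value] = DiagnosticSummary(
            sensitivity=sens,
            specificity=spec,
            sens_ci=clopper_pearson(cm.tp, cm.n_cases, conf) if cm.n_cases else (math.nan, math.nan),
            spec_ci=clopper_pearson(cm.tn, cm.n_controls, conf) if cm.n_controls else (math.nan, math.nan),
            ppv=ppv,
            npv=npv,
            assumed_prevalence=prevalence,
            n_cases=cm.n_cases,
            n_controls=cm.n_controls,
        )
    return out


def time_stratified_sensitivity(
    predictions: Sequence[str],
    truth: Sequence[str],
    months_to_event: Sequence[float],
    cutpoint_months: float = 12.0,
    conf: float = 0.95,
) -> dict:
    """Sensitivity by lead time to diagnosis, split at a cutpoint.

    Cases split into ``< cutpoint`` and ``>= cutpoint`` months before
    diagnosis; each side reports sensitivity with its exact CI (NaN for an
    empty side).  Controls contribute a single overall specificity.  A
    Fisher exact p-value compares detection between the two case groups —
    a stand-in, since no particular test is canonical for this contrast.
    """
    pred = np.asarray(predictions)
    ref = np.asarray(truth)
    months = np.asarray(months_to_event, dtype=float)
    case_mask = ref == CASE
    if np.isnan(months[case_mask]).any():
        raise ValueError("months_to_event required for all cases")

    def _side(mask: np.ndarray) -> dict:
        n = int(mask.sum())
        if n == 0:
            return {"n_cases": 0, "n_detected": 0,
                    "sensitivity": math.nan, "ci": (math.nan, math.nan)}
        detected = int((pred[mask] == POSITIVE).sum())
        return {
            "n_cases": n,
            "n_detected": detected,
            "sensitivity": detected / n,
            "ci": clopper_pearson(detected, n, conf),
        }

    early = case_mask & (months < cutpoint_months)
    late = case_mask & (months >= cutpoint_months)
    result = {
        "lt_cutpoint": _side(early),
        "ge_cutpoint": _side(late),
        "cutpoint_months": cutpoint_months,
    }

    ctrl = ~case_mask
    if ctrl.any():
        tn = int((pred[ctrl] == NEGATIVE).sum())
        result["specificity"] = tn / int(ctrl.sum())
        result["spec_ci"] = clopper_pearson(tn, int(ctrl.sum()), conf)

    if early.any() and late.any():
        table = [
            [result["lt_cutpoint"]["n_detected"],
             result["lt_cutpoint"]["n_cases"] - result["lt_cutpoint"]["n_detected"]],
            [result["ge_cutpoint"]["n_detected"],
             result["ge_cutpoint"]["n_cases"] - result["ge_cutpoint"]["n_detected"]],
        ]
        result["fisher_p"] = float(fisher_exact(table)[1])
    return result


def round_percent(p: float, decimals: int = 1) -> float:
    """Report-style rounding of a proportion to percent."""
    return round(100.0 * p, decimals)
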