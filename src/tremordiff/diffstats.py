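"""Differentiation statistics: the discrimination coefficient against the 0.7
level, and single-feature binary-logistic ROC analysis with the
Youden-optimal cut-off mapped back to feature units.

The discrimination coefficient between two groups of feature values is

    alpha = |mean_A - mean_B| / (sd_A + sd_B)

with sample standard deviations (n-1 denominator); alpha > 0.7 marks good
differentiation. ET is the positive class throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "DiscriminationResult",
    "LogisticFit",
    "RocAnalysis",
    "YoudenResult",
    "DIFFERENTIATION_LEVEL",
    "discrimination_coefficient",
    "discrimination_from_summary",
    "fit_logistic",
    "roc_curve",
    "youden_optimal_cutoff",
    "analyze_pair",
]

#: Level above which a discrimination coefficient counts as good separation.
DIFFERENTIATION_LEVEL = 0.7


@dataclass
class DiscriminationResult:
    """Group-pair summary for one feature: means, SDs, alpha and pass flag."""

    feature_name: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    alpha: float
    passes_level: bool
    level: float = DIFFERENTIATION_LEVEL
    degenerate: bool = False
    n_a: int | None = None
    n_b: int | None = None


def _alpha(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> tuple[float, bool]:
    denom = sd_a + sd_b
    diff = abs(mean_a - mean_b)
    if denom == 0:
        if diff == 0:
            return 0.0, False
        return math.inf, True
    return diff / denom, False


def discrimination_from_summary(
    mean_a: float,
    sd_a: float,
    mean_b: float,
    sd_b: float,
    feature_name: str = "",
    group_a: str = "A",
    group_b: str = "B",
    level: float = DIFFERENTIATION_LEVEL,
) -> DiscriminationResult:
    """Discrimination coefficient from printed/summary group statistics."""
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    alpha, degenerate = _alpha(mean_a, sd_a, mean_b, sd_b)
    return DiscriminationResult(
        feature_name=feature_name,
        group_a=group_a,
        group_b=group_b,
        mean_a=mean_a,
        sd_a=sd_a,
        mean_b=mean_b,
        sd_b=sd_b,
        alpha=alpha,
        passes_level=bool(alpha > level),
        level=level,
        degenerate=degenerate,
    )


def discrimination_coefficient(
    values_a,
    values_b,
    feature_name: str = "",
    group_a: str = "A",
    group_b: str = "B",
    level: float = DIFFERENTIATION_LEVEL,
) -> DiscriminationResult:
    """Discrimination coefficient between two groups of feature values.

    Symmetric in the two groups; requires at least two values per group
    (sample SD with n-1 denominator).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    result = discrimination_from_summary(
        float(a.mean()),
        float(a.std(ddof=1)),
        float(b.mean()),
        float(b.std(ddof=1)),
        feature_name=feature_name,
        group_a=group_a,
        group_b=group_b,
        level=level,
    )
    result.n_a = int(a.size)
    result.n_b = int(b.size)
    return result


@dataclass
class LogisticFit:
    """Maximum-likelihood fit of p(y=1|x) = expit(beta0 + beta1 * x)."""

    beta0: float
    beta1: float
    converged: bool
    separation_detected: bool
    n_iter: int
    deviance: float
    beta0_se: float = float("nan")
    beta1_se: float = float("nan")

    def predict_proba(self, x) -> np.ndarray:
        return expit(self.beta0 + self.beta1 * np.asarray(x, dtype=float))


def _log_likelihood(beta0: float, beta1: float, x: np.ndarray, y: np.ndarray) -> float:
    eta = np.clip(beta0 + beta1 * x, -700, 700)
    # log L = sum y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(features, labels, tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Fit a single-predictor logistic model by IRLS.

    Iterates reweighted least squares until the deviance changes by less than
    ``tol`` (at most ``max_iter`` iterations). Complete separation — a feature
    threshold perfectly splitting the classes, under which the ML coefficients
    diverge — is detected both from the data and from coefficient blow-up, and
    flagged; the returned coefficients are then large but finite, and any
    downstream ROC built on the fitted probabilities is unchanged because the
    probabilities remain a monotone map of the feature.
    """
    x = np.asarray(features, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("features and labels must have the same length")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be binary 0/1")
    n0, n1 = int(np.sum(y == 0)), int(np.sum(y == 1))
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")

    # data-level separation check: some threshold splits the classes perfectly
    x0, x1 = x[y == 0], x[y == 1]
    separated = bool(x0.max() < x1.min() or x1.max() < x0.min())

    # standardize internally for conditioning; map coefficients back at the end
    xm, xs = x.mean(), x.std()
    if xs == 0:
        # constant feature: intercept-only model
        p = n1 / (n0 + n1)
        beta0 = math.log(p / (1 - p))
        dev = -2.0 * _log_likelihood(beta0, 0.0, x, y)
        se0 = 1.0 / math.sqrt((n0 + n1) * p * (1 - p))
        return LogisticFit(beta0, 0.0, True, False, 0, dev, se0, float("nan"))
    z = (x - xm) / xs

    X = np.column_stack([np.ones_like(z), z])
    beta = np.zeros(2)
    dev_old = math.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        work = eta + (y - p) / w
        A = X.T @ (X * w[:, None])
        rhs = X.T @ (w * work)
        try:
            beta = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(A, rhs, rcond=None)[0]
        dev = -2.0 * _log_likelihood(beta[0], beta[1], z, y)
        if abs(dev - dev_old) < tol:
            converged = True
            break
        dev_old = dev

    if not converged and abs(beta[1]) > 20:
        separated = True

    # observed-information standard errors (on the original feature scale)
    eta = np.clip(X @ beta, -30, 30)
    p = expit(eta)
    w = np.clip(p * (1 - p), 1e-12, None)
    A = X.T @ (X * w[:, None])
    try:
        cov_z = np.linalg.inv(A)
        se0_z, se1_z = math.sqrt(cov_z[0, 0]), math.sqrt(cov_z[1, 1])
        # beta1 = beta1_z / xs ; beta0 = beta0_z - beta1_z * xm / xs
        se1 = se1_z / xs
        var0 = (
            cov_z[0, 0]
            + (xm / xs) ** 2 * cov_z[1, 1]
            - 2 * (xm / xs) * cov_z[0, 1]
        )
        se0 = math.sqrt(max(var0, 0.0))
    except np.linalg.LinAlgError:
        se0 = se1 = float("nan")

    beta1 = beta[1] / xs
    beta0 = beta[0] - beta[1] * xm / xs
    dev = -2.0 * _log_likelihood(beta0, beta1, x, y)
    return LogisticFit(
        beta0=float(beta0),
        beta1=float(beta1),
        converged=converged,
        separation_detected=separated,
        n_iter=n_iter,
        deviance=dev,
        beta0_se=se0,
        beta1_se=se1,
    )


@dataclass
class RocAnalysis:
    """ROC curve with AUC; optionally the logistic fit and Youden cut-off."""

    roc_points: np.ndarray  # (n, 2) of (FPR, TPR), ordered from (0,0) to (1,1)
    auc: float
    thresholds: np.ndarray = field(default_factory=lambda: np.array([]))
    positive_class: str = "ET"
    beta0: float = float("nan")
    beta1: float = float("nan")
    converged: bool | None = None
    separation_detected: bool | None = None
    youden_cutoff_prob: float = float("nan")
    youden_cutoff_feature: float = float("nan")
    tpr: float = float("nan")
    fpr: float = float("nan")
    acc: float = float("nan")


def roc_curve(scores, labels, positive_class: str = "ET") -> RocAnalysis:
    """ROC curve and trapezoidal AUC from scores and binary labels.

    Thresholds sweep all distinct score values (rule: positive when score >=
    threshold), so the curve runs from (0, 0) to (1, 1) and the trapezoidal
    area equals the Mann-Whitney rank statistic with ties counted 1/2.
    ``labels`` may be 0/1 integers or booleans; 1/True is the positive class.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).astype(float).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = float(np.sum(y == 1))
    n_neg = float(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # group tied scores so ROC points land only at distinct thresholds
    distinct = np.r_[True, np.diff(s_sorted) != 0]
    boundaries = np.r_[np.flatnonzero(distinct), s_sorted.size]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    tpr = [0.0]
    fpr = [0.0]
    thresholds = [math.inf]
    for end, start in zip(boundaries[1:], boundaries[:-1]):
        tpr.append(tp[end - 1] / n_pos)
        fpr.append(fp[end - 1] / n_neg)
        thresholds.append(s_sorted[start])
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return RocAnalysis(
        roc_points=points,
        auc=auc,
        thresholds=np.asarray(thresholds),
        positive_class=positive_class,
    )


@dataclass
class YoudenResult:
    """Youden-optimal cut-off in feature units with its operating point.

    ``direction`` is ``">="`` when instances at or above the cut-off are
    called positive, ``"<="`` otherwise.
    """

    cutoff_feature: float
    tpr: float
    fpr: float
    acc: float
    youden: float
    direction: str = ">="
    cutoff_score: float = float("nan")


def _confusion_rates(
    pred_pos: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    tp = float(np.sum(pred_pos & (y == 1)))
    fp = float(np.sum(pred_pos & (y == 0)))
    fn = float(np.sum(~pred_pos & (y == 1)))
    tn = float(np.sum(~pred_pos & (y == 0)))
    tpr = tp / (tp + fn)
    fpr = fp / (fp + tn)
    acc = (tp + tn) / (tp + fp + fn + tn)
    return tpr, fpr, acc


def youden_optimal_cutoff(
    scores, labels, feature_values=None
) -> YoudenResult:
    """Cut-off maximizing the Youden index TPR - FPR.

    Candidate cut-offs are the midpoints between adjacent distinct sorted
    values plus the two infinite sentinels; ties on the Youden index are
    broken by higher accuracy, then lower FPR, then lower cut-off. When
    ``feature_values`` is given it must be monotone in the scores (the
    single-feature logistic case) and the cut-off is reported in feature
    units; otherwise it is reported on the score scale.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).astype(float).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    if np.sum(y == 1) == 0 or np.sum(y == 0) == 0:
        raise ValueError("both classes must be present")

    if feature_values is None:
        values = s
        direction = ">="
    else:
        values = np.asarray(feature_values, dtype=float).ravel()
        if values.shape != s.shape:
            raise ValueError("feature_values must match scores in length")
        order = np.argsort(s, kind="stable")
        fv = values[order]
        if np.all(np.diff(fv) >= 0):
            direction = ">="
        elif np.all(np.diff(fv) <= 0):
            direction = "<="
        else:
            raise ValueError("feature_values are not monotone in the scores")

    distinct = np.unique(values)
    candidates = np.concatenate(
        [[-math.inf], (distinct[:-1] + distinct[1:]) / 2.0, [math.inf]]
    )
    best: YoudenResult | None = None
    for c in candidates:
        pred_pos = values >= c if direction == ">=" else values <= c
        tpr, fpr, acc = _confusion_rates(pred_pos, y)
        j = tpr - fpr
        cand = YoudenResult(
            cutoff_feature=float(c),
            tpr=tpr,
            fpr=fpr,
            acc=acc,
            youden=j,
            direction=direction,
        )
        if best is None:
            best = cand
            continue
        key_new = (cand.youden, cand.acc, -cand.fpr, -cand.cutoff_feature)
        key_old = (best.youden, best.acc, -best.fpr, -best.cutoff_feature)
        if key_new > key_old:
            best = cand
    assert best is not None
    return best


def _select_pair(
    table: pd.DataFrame, group_pair: tuple[str, str], posture: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    subset = table[table["posture"] == posture]

    def mask_for(label: str) -> pd.Series:
        if label in ("PD", "ET"):
            return subset["group"] == label
        if label in ("PD1", "PD2", "ET1", "ET2"):
            if "stage" not in subset.columns or subset["stage"].isna().any():
                raise ValueError(
                    f"selection {label!r} needs a populated 'stage' column"
                )
            stage = "S1" if label.endswith("1") else "S2"
            return (subset["group"] == label[:2]) & (subset["stage"] == stage)
        raise ValueError(f"unknown group label {label!r}")

    part_a = subset[mask_for(group_pair[0])]
    part_b = subset[mask_for(group_pair[1])]
    for label, part in zip(group_pair, (part_a, part_b)):
        if part.empty:
            raise ValueError(
                f"empty selection: no rows for {label} with posture {posture}"
            )
    return part_a, part_b


def analyze_pair(
    feature_table: pd.DataFrame,
    feature_name: str,
    group_pair: tuple[str, str],
    posture: str,
    level: float = DIFFERENTIATION_LEVEL,
) -> tuple[DiscriminationResult, RocAnalysis]:
    """Run both analyses for one (feature, group pair, posture) cell.

    Each segment row is one instance. The first pair element is the negative
    class, the second (the ET side) the positive class. Rows with missing
    feature values are excluded from the model (their count is visible in the
    discrimination result ``n_a``/``n_b`` versus the selection size).
    """
    if feature_name not in feature_table.columns:
        raise ValueError(f"feature {feature_name!r} not in table")
    part_a, part_b = _select_pair(feature_table, group_pair, posture)
    values_a = part_a[feature_name].dropna().to_numpy(dtype=float)
    values_b = part_b[feature_name].dropna().to_numpy(dtype=float)
    if values_a.size < 2 or values_b.size < 2:
        raise ValueError(
            f"selection {group_pair} / {posture} has fewer than 2 usable "
            f"values per group for {feature_name!r}"
        )
    disc = discrimination_coefficient(
        values_a,
        values_b,
        feature_name=feature_name,
        group_a=group_pair[0],
        group_b=group_pair[1],
        level=level,
    )

    x = np.concatenate([values_a, values_b])
    y = np.concatenate([np.zeros(values_a.size), np.ones(values_b.size)])
    fit = fit_logistic(x, y)
    if fit.separation_detected:
        # rank fallback: identical ROC by monotonicity of the logit, and
        # immune to probability saturation at huge |beta|
        scores = x if fit.beta1 >= 0 else -x
    else:
        scores = fit.predict_proba(x)
    roc = roc_curve(scores, y, positive_class=group_pair[1])
    youden = youden_optimal_cutoff(scores, y, feature_values=x)
    cutoff_prob = (
        float(expit(fit.beta0 + fit.beta1 * youden.cutoff_feature))
        if math.isfinite(youden.cutoff_feature)
        else float("nan")
    )
    roc = replace(
        roc,
        beta0=fit.beta0,
        beta1=fit.beta1,
        converged=fit.converged,
        separation_detected=fit.separation_detected,
        youden_cutoff_prob=cutoff_prob,
        youden_cutoff_feature=youden.cutoff_feature,
        tpr=youden.tpr,
        fpr=youden.fpr,
        acc=youden.acc,
    )
    return disc, roc
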