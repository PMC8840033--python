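"""Logistic prediction models and ROC evaluation.

Single markers, trajectory slopes and their combinations are turned into
anastomotic-leak predictors via logistic regression; each predictor's score is
evaluated by ROC analysis: AUC as the pairwise concordance probability (ties
half-weighted), a DeLong 95% confidence interval and two-sided p-value against
the chance diagonal (AUC = 0.5), a Youden-optimal cutoff, and the confusion
metrics sensitivity / specificity / PPV / NPV at that cutoff. Binary rise-rule
predictors are evaluated directly from their 2x2 table; fed through the same
concordance machinery their AUC is (SN + SP) / 2, the single-point-ROC area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cohort import MARKER_DAYS
from .errors import ConfigurationError, SingleClassError
from .trajectory import RuleConfig, marker_pairs

__all__ = [
    "LogisticModel", "RocCurve", "RocSummary", "ConfusionTable", "ModelSpec",
    "fit_logistic", "predicted_scores", "auc", "roc_curve", "trapezoid_auc",
    "auc_inference", "optimal_cutoff", "confusion_metrics",
    "evaluate_marker_panel", "default_model_specs",
]


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticModel:
    """Fitted logistic model: intercept-first coefficients on feature units."""

    coef: np.ndarray          # [beta0, beta1, ...]
    loglik: float
    converged: bool
    n_iter: int
    feature_names: tuple[str, ...] = ()

    @property
    def intercept(self) -> float:
        return float(self.coef[0])


def _check_two_classes(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise SingleClassError("both outcome classes must be present")


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _irls(
    X: np.ndarray, y: np.ndarray, penalty: float, tol: float, maxiter: int
) -> tuple[np.ndarray, float, bool, int]:
    """Ridge-stabilised IRLS; the penalty never touches the intercept."""
    p = X.shape[1]
    pen = np.full(p, penalty)
    pen[0] = 0.0
    beta = np.zeros(p)
    ll_old = _loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        z = X @ beta + (y - mu) / w
        A = X.T @ (w[:, None] * X) + np.diag(pen)
        beta = np.linalg.solve(A, X.T @ (w * z))
        ll = _loglik(X, y, beta)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    return beta, _loglik(X, y, beta), converged, it


def fit_logistic(
    X,
    y,
    feature_names: tuple[str, ...] | None = None,
    penalty: float = 0.0,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogisticModel:
    """Maximum-likelihood logistic fit of outcome on features.

    The main path delegates to statsmodels' binomial GLM (iteratively
    reweighted least squares). Under perfect separation the MLE diverges; the
    fit then falls back to a capped IRLS, returns the last iterate with
    ``converged=False`` and emits a warning. ``penalty`` adds a small ridge
    term (intercept excluded) as an optional stabiliser.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ConfigurationError("X and y have incompatible shapes")
    _check_two_classes(y)
    names = tuple(feature_names) if feature_names else tuple(
        f"x{j}" for j in range(X.shape[1])
    )
    Xd = np.column_stack([np.ones(X.shape[0]), X])

    if penalty > 0.0:
        beta, ll, conv, it = _irls(Xd, y, penalty, tol, maxiter)
        return LogisticModel(beta, ll, conv, it, names)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(y, Xd, family=sm.families.Binomial()).fit(
                maxiter=maxiter, tol=tol
            )
        n_iter = max(len(res.fit_history.get("deviance", [])) - 1, 1)
        return LogisticModel(
            np.asarray(res.params, dtype=float),
            float(res.llf),
            bool(getattr(res, "converged", True)),
            n_iter,
            names,
        )
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        warnings.warn(
            "perfect separation detected; returning last IRLS iterate",
            UserWarning,
            stacklevel=2,
        )
        beta, ll, _, it = _irls(Xd, y, 0.0, tol, maxiter)
        return LogisticModel(beta, ll, False, it, names)


def predicted_scores(model: LogisticModel, X) -> np.ndarray:
    """Inverse-logit of the linear predictor: per-patient risk scores in (0, 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coef.size - 1:
        if X.shape[0] == model.coef.size - 1:
            X = X.T
        else:
            raise ConfigurationError(
                f"feature dimension {X.shape[1]} does not match model "
                f"({model.coef.size - 1})"
            )
    eta = model.coef[0] + X @ model.coef[1:]
    return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# ROC machinery


@dataclass
class RocCurve:
    """Operating points (fpr, tpr) from (0,0) to (1,1), thresholds descending.

    ``thresholds[i]`` is the score at or above which a patient is called
    positive to reach point i; the leading (0,0) point carries +inf.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass
class RocSummary:
    """One evaluated predictor: discrimination, inference, cutoff and metrics."""

    name: str
    auc: float
    ci_low: float
    ci_high: float
    p_vs_chance: float
    cutoff: float
    sn: float
    sp: float
    ppv: float
    npv: float
    n: int


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise SingleClassError("AUC is undefined with a single outcome class")
    return pos, neg


def auc(scores, labels) -> float:
    """Concordance AUC: P(score_AL > score_noAL) with ties counted 1/2.

    Computed from midranks, so ties are handled exactly; identical to the
    trapezoidal area under :func:`roc_curve`.
    """
    pos, neg = _split(scores, labels)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float(
        (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0)
        / (pos.size * neg.size)
    )


def roc_curve(scores, labels) -> RocCurve:
    """Empirical ROC curve; one operating point per distinct score threshold."""
    pos, neg = _split(scores, labels)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(y == 1)[distinct]
    fp = np.cumsum(y == 0)[distinct]
    return RocCurve(
        thresholds=np.r_[np.inf, s[distinct]],
        fpr=np.r_[0.0, fp / neg.size],
        tpr=np.r_[0.0, tp / pos.size],
    )


def trapezoid_auc(curve: RocCurve) -> float:
    """Trapezoidal area under an ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def _delong_variance(scores, labels) -> tuple[float, float]:
    """DeLong's AUC and variance via midrank structural components."""
    pos, neg = _split(scores, labels)
    m, n = pos.size, neg.size
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))
    a = float((tz[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    v10 = (tz[:m] - tx) / n            # per-positive placement values
    v01 = 1.0 - (tz[m:] - ty) / m      # per-negative placement values
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return a, s10 / m + s01 / n


def _hanley_mcneil_variance(a: float, m: int, n: int) -> float:
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    return (a * (1 - a) + (m - 1) * (q1 - a * a) + (n - 1) * (q2 - a * a)) / (m * n)


def auc_inference(
    scores, labels, level: float = 0.95, method: str = "delong"
) -> tuple[float, float, float, float]:
    """AUC with a confidence interval and two-sided p versus chance.

    Returns ``(auc, ci_low, ci_high, p_vs_chance)``. ``method`` selects the
    variance estimator: "delong" (default) or "hanley" (Hanley–McNeil, for
    cross-checking). The interval is truncated to [0, 1]; with zero estimated
    variance the p-value degenerates to 1 at AUC = 0.5 and 0 otherwise.
    """
    if method == "delong":
        a, var = _delong_variance(scores, labels)
    elif method == "hanley":
        pos, neg = _split(scores, labels)
        a = auc(scores, labels)
        var = _hanley_mcneil_variance(a, pos.size, neg.size)
    else:
        raise ConfigurationError(f"unknown AUC variance method {method!r}")
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    if se == 0.0:
        p = 1.0 if a == 0.5 else 0.0
    else:
        p = 2.0 * stats.norm.sf(abs(a - 0.5) / se)
    return a, max(a - z * se, 0.0), min(a + z * se, 1.0), float(p)


def optimal_cutoff(scores, labels) -> tuple[float, ConfusionTable]:
    """Youden-optimal threshold (J = SN + SP - 1), ties toward specificity.

    Candidate cutoffs are midpoints between adjacent distinct scores plus
    sentinels below/above the range; a patient is called positive when
    score >= cutoff. Among J-maximisers the cutoff with the highest
    specificity (the largest threshold) is returned.
    """
    pos, neg = _split(scores, labels)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    u = np.unique(scores)
    candidates = np.r_[u[0] - 1.0, (u[:-1] + u[1:]) / 2.0, u[-1] + 1.0]
    pred = scores[None, :] >= candidates[:, None]
    tp = (pred & (labels == 1)).sum(axis=1)
    fp = (pred & (labels == 0)).sum(axis=1)
    sn = tp / pos.size
    sp = (neg.size - fp) / neg.size
    j = sn + sp - 1.0
    tied = np.flatnonzero(j >= j.max() - 1e-12)
    # among J-maximisers prefer higher specificity, i.e. the larger cutoff
    i = tied[np.lexsort((candidates[tied], sp[tied]))[-1]]
    table = ConfusionTable(
        int(tp[i]), int(fp[i]), int(pos.size - tp[i]), int(neg.size - fp[i])
    )
    return float(candidates[i]), table


def confusion_metrics(t: ConfusionTable) -> dict[str, float]:
    """SN, SP, PPV, NPV as percentages; NaN marks an undefined (0/0) metric."""

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "sn": pct(t.tp, t.tp + t.fn),
        "sp": pct(t.tn, t.tn + t.fp),
        "ppv": pct(t.tp, t.tp + t.fp),
        "npv": pct(t.tn, t.tn + t.fn),
    }


# ---------------------------------------------------------------------------
# marker panels


@dataclass(frozen=True)
class ModelSpec:
    """One predictor to evaluate.

    kind:
      - "raw": the marker's value on one postoperative day (cutoff in marker
        units, as clinicians would apply it);
      - "trajectory": logistic model on one or more markers' window slopes
        (cutoff on the predicted-risk scale);
      - "rule": the binary rise-rule flag, any-pair or one specific pair,
        evaluated from its 2x2 table.
    """

    name: str
    kind: str
    markers: tuple[str, ...]
    day: int | None = None
    pair: tuple[int, int] | None = None


def default_model_specs(window: str = "0-5") -> list[ModelSpec]:
    """The standard panel: per-POD raw values, single/pairwise/triple
    trajectory models, and rise rules (any-pair plus each consecutive pair)."""
    specs: list[ModelSpec] = []
    for marker in ("CRP", "PCT", "WBC"):
        for day in MARKER_DAYS[marker]:
            if day == 0:
                continue
            specs.append(
                ModelSpec(f"{marker} POD {day}", "raw", (marker,), day=day)
            )
    for combo in (("CRP",), ("PCT",), ("WBC",), ("CRP", "PCT"),
                  ("PCT", "WBC"), ("CRP", "WBC"), ("CRP", "PCT", "WBC")):
        specs.append(
            ModelSpec(f"{'+'.join(combo)} trajectory", "trajectory", combo)
        )
    for marker in ("CRP", "PCT", "WBC"):
        specs.append(ModelSpec(f"{marker} rise any pair", "rule", (marker,)))
        for a, b in marker_pairs(marker, window):
            specs.append(
                ModelSpec(f"{marker} rise POD {a} to {b}", "rule", (marker,), pair=(a, b))
            )
    return specs


def _binary_summary(name: str, flags: np.ndarray, labels: np.ndarray) -> RocSummary:
    # concordance on a 0/1 score gives (SN+SP)/2 exactly, the one-point ROC area
    a, lo, hi, p = auc_inference(flags.astype(float), labels)
    pred = flags.astype(bool)
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    m = confusion_metrics(ConfusionTable(tp, fp, fn, tn))
    return RocSummary(name, a, lo, hi, p, float("nan"),
                      m["sn"], m["sp"], m["ppv"], m["npv"], labels.size)


def _score_summary(name: str, scores: np.ndarray, labels: np.ndarray) -> RocSummary:
    a, lo, hi, p = auc_inference(scores, labels)
    cutoff, table = optimal_cutoff(scores, labels)
    m = confusion_metrics(table)
    return RocSummary(name, a, lo, hi, p, cutoff,
                      m["sn"], m["sp"], m["ppv"], m["npv"], labels.size)


def evaluate_marker_panel(
    cohort: pd.DataFrame,
    features: pd.DataFrame,
    specs: list[ModelSpec],
    rule: RuleConfig | None = None,
    logistic_penalty: float = 0.0,
) -> list[RocSummary]:
    """Evaluate every requested predictor on one cohort.

    ``cohort`` supplies raw per-day values, ``features`` the trajectory slopes
    and rise flags (from :func:`leaktraj.trajectory.compute_features`).
    """
    del rule  # thresholds are already baked into the features table
    summaries: list[RocSummary] = []
    patients = (
        cohort[["patient_id", "al_label"]]
        .drop_duplicates()
        .sort_values("patient_id")
        .reset_index(drop=True)
    )
    labels = patients["al_label"].to_numpy()

    for spec in specs:
        if spec.kind == "raw":
            marker, day = spec.markers[0], spec.day
            sub = cohort[(cohort["marker"] == marker) & (cohort["day"] == day)]
            sub = sub.set_index("patient_id").loc[patients["patient_id"]]
            summaries.append(
                _score_summary(spec.name, sub["value"].to_numpy(), labels)
            )
        elif spec.kind == "trajectory":
            slopes = (
                features[features["marker"].isin(spec.markers)]
                .pivot(index="patient_id", columns="marker", values="slope")
                .loc[patients["patient_id"], list(spec.markers)]
            )
            X = slopes.to_numpy()
            model = fit_logistic(
                X, labels, feature_names=spec.markers, penalty=logistic_penalty
            )
            summaries.append(
                _score_summary(spec.name, predicted_scores(model, X), labels)
            )
        elif spec.kind == "rule":
            marker = spec.markers[0]
            col = "rise_any" if spec.pair is None else f"rise_{spec.pair[0]}_{spec.pair[1]}"
            sub = features[features["marker"] == marker]
            if col not in sub.columns:
                raise ConfigurationError(f"feature column {col!r} absent for {marker}")
            flags = (
                sub.set_index("patient_id")
                .loc[patients["patient_id"], col]
                .astype(bool)
                .to_numpy()
            )
            summaries.append(_binary_summary(spec.name, flags, labels))
        else:
            raise ConfigurationError(f"unknown model kind {spec.kind!r}")
    return summaries


def panel_to_frame(summaries: list[RocSummary]) -> pd.DataFrame:
    """Panel results as a tidy DataFrame (one row per predictor)."""
    return pd.DataFrame([vars(s) for s in summaries])
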