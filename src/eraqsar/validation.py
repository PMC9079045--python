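"""Model robustness battery.

Four complementary checks guard against a QSAR model that merely memorizes:

* **Y-scrambling** retrains the forest on permuted activity labels (X fixed);
  a robust model's real (R²_train, Q²_CV) point sits in the upper-right
  quadrant of the acceptability thresholds while every scrambled model's
  Q²_CV falls below them.
* **Acceptability thresholds**: R² > 0.6 and Q² > 0.5, both strict.
* **Chance-correlation margin** R²_train - Q²_ext: values up to 0.2 indicate
  a predictive model, 0.2-0.3 deserve a warning, and larger gaps suggest
  chance correlation or outliers.
* **PCA bounding-box applicability domain**: principal components are fitted
  on the scaled training matrix only; an external compound is inside the
  domain iff its score on every retained component lies within the training
  score range.

Censored records (IC50 reported only as '<' or '>' a bound) cannot enter the
regression but check directional consistency: a '>' record is predicted
correctly iff the model places its pIC50 strictly below the bound, and a '<'
record iff strictly above.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .modeling import (
    ModelBundle,
    PerformanceReport,
    RFConfig,
    cross_validate,
    evaluate,
    train,
)

R2_THRESHOLD = 0.6
Q2_THRESHOLD = 0.5


class ValidationError(ValueError):
    pass


@dataclass
class ScramblingReport:
    real_point: tuple[float, float]  # (r2_train, q2_cv)
    scrambled_points: list[tuple[float, float]]
    n_scrambles: int
    seed: int
    verdict: str  # "robust" or "chance_correlation"

    def to_frame(self) -> pd.DataFrame:
        rows = [{"model": "real", "r2_train": self.real_point[0],
                 "q2_cv": self.real_point[1]}]
        rows += [{"model": f"scramble_{i}", "r2_train": r2, "q2_cv": q2}
                 for i, (r2, q2) in enumerate(self.scrambled_points)]
        return pd.DataFrame(rows)


@dataclass
class AcceptabilityResult:
    passed: bool
    reasons: list[str]


@dataclass
class ADReport:
    n_components: int
    train_score_bounds: list[tuple[float, float]]
    external_scores: np.ndarray
    inside_flags: np.ndarray
    fraction_inside: float


@dataclass
class CensoredEvalReport:
    n_gt: int
    accuracy_gt: float | None
    n_lt: int
    accuracy_lt: float | None
    verdicts: pd.DataFrame


def y_scramble(
    X, y, model_config: RFConfig, n: int = 100, seed: int = 0,
    folds: int = 10,
    r2_threshold: float = R2_THRESHOLD, q2_threshold: float = Q2_THRESHOLD,
) -> ScramblingReport:
    """Label-permutation null for (R²_train, Q²_CV).

    Each of ``n`` permutations of y (X fixed) retrains the forest with the
    same fixed hyperparameters and records the training R² and pooled 10-fold
    CV Q².  Verdict is ``robust`` iff the real point clears both thresholds
    and every scrambled Q²_CV falls below the Q² threshold.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)

    def point(labels: np.ndarray, cv_seed: int) -> tuple[float, float]:
        bundle = train(X, labels, model_config)
        r2, _ = evaluate(labels, bundle.predict(X))
        cv = cross_validate(X, labels, model_config, folds=folds, seed=cv_seed)
        return r2, cv.q2_cv

    real = point(y, cv_seed=seed)
    scrambled = []
    for i in range(n):
        perm = rng.permutation(len(y))
        scrambled.append(point(y[perm], cv_seed=seed + 1 + i))
    robust = (
        real[0] > r2_threshold
        and real[1] > q2_threshold
        and all(q2 < q2_threshold for _, q2 in scrambled)
    )
    return ScramblingReport(
        real_point=real,
        scrambled_points=scrambled,
        n_scrambles=n,
        seed=seed,
        verdict="robust" if robust else "chance_correlation",
    )


def acceptability_check(
    report: PerformanceReport | tuple[float, float],
    r2_threshold: float = R2_THRESHOLD,
    q2_threshold: float = Q2_THRESHOLD,
) -> AcceptabilityResult:
    """Strict R² > 0.6 and Q² > 0.5 acceptability test."""
    if isinstance(report, PerformanceReport):
        r2, q2 = report.r2_train, report.q2_cv
    else:
        r2, q2 = report
    reasons = []
    if not r2 > r2_threshold:
        reasons.append(f"R2 {r2:.3f} not > {r2_threshold}")
    if not q2 > q2_threshold:
        reasons.append(f"Q2 {q2:.3f} not > {q2_threshold}")
    return AcceptabilityResult(passed=not reasons, reasons=reasons)


def eriksson_margin(
    report: PerformanceReport | tuple[float, float]
) -> tuple[float, str]:
    """Chance-correlation margin R²_train - Q²_ext and its flag.

    <= 0.2 is ``ok``; 0.2-0.3 is ``warn``; above 0.3 flags possible chance
    correlation or outliers.
    """
    if isinstance(report, PerformanceReport):
        if report.q2_ext is None:
            raise ValidationError("report has no external Q2")
        r2, q2_ext = report.r2_train, report.q2_ext
    else:
        r2, q2_ext = report
    margin = r2 - q2_ext
    # tolerance keeps reported two-decimal margins (e.g. 0.93 - 0.73 = 0.20)
    # from tipping a band through float subtraction error
    if margin <= 0.2 + 1e-9:
        flag = "ok"
    elif margin <= 0.3 + 1e-9:
        flag = "warn"
    else:
        flag = "chance_correlation_or_outliers"
    return margin, flag


def pca_bounding_box(
    train_X_scaled, external_X_scaled, n_components: int = 2
) -> ADReport:
    """Applicability domain as a per-component min/max box in PCA score space.

    PCA is fitted on the (already scaled) training matrix only; both sets are
    projected and an external compound is inside the domain iff its score on
    every retained component lies within the training range (inclusive).
    """
    Xtr = np.asarray(
        train_X_scaled.to_numpy() if isinstance(train_X_scaled, pd.DataFrame)
        else train_X_scaled, dtype=float,
    )
    Xex = np.asarray(
        external_X_scaled.to_numpy() if isinstance(external_X_scaled, pd.DataFrame)
        else external_X_scaled, dtype=float,
    )
    if n_components > Xtr.shape[1]:
        raise ValidationError(
            f"n_components {n_components} exceeds feature count {Xtr.shape[1]}"
        )
    pca = PCA(n_components=n_components, random_state=0)
    pca.fit(Xtr)
    # project both sets through the same code path so a training row used as
    # an external compound lands exactly on (not epsilon outside) its bound
    train_scores = pca.transform(Xtr)
    ext_scores = pca.transform(Xex)
    bounds = [
        (float(train_scores[:, j].min()), float(train_scores[:, j].max()))
        for j in range(n_components)
    ]
    inside = np.ones(len(ext_scores), dtype=bool)
    for j, (lo, hi) in enumerate(bounds):
        inside &= (ext_scores[:, j] >= lo) & (ext_scores[:, j] <= hi)
    return ADReport(
        n_components=n_components,
        train_score_bounds=bounds,
        external_scores=ext_scores,
        inside_flags=inside,
        fraction_inside=float(inside.mean()) if len(inside) else 1.0,
    )


def censored_accuracy(
    predict,
    gt: tuple | None,
    lt: tuple | None,
) -> CensoredEvalReport:
    """Directional accuracy on bound-only external records.

    ``predict`` maps a feature matrix to predicted pIC50; ``gt``/``lt`` are
    (X, bound_pic50) pairs for records with IC50 '>' or '<' their bound.  On
    the pIC50 scale, '>' (less potent than the bound) is correct iff the
    prediction is strictly below the bound and '<' iff strictly above; a
    prediction equal to its bound is incorrect.  An empty set leaves that
    accuracy absent rather than zero.
    """
    rows = []

    def run(pair, relation):
        if pair is None:
            return 0, None
        X, bounds = pair
        bounds = np.asarray(bounds, dtype=float)
        if len(bounds) == 0:
            return 0, None
        pred = np.asarray(predict(X), dtype=float)
        correct = pred < bounds if relation == ">" else pred > bounds
        for p, b, c in zip(pred, bounds, correct):
            rows.append({"relation": relation, "predicted_pic50": float(p),
                         "bound_pic50": float(b), "correct": bool(c)})
        return len(bounds), float(np.mean(correct))

    n_gt, acc_gt = run(gt, ">")
    n_lt, acc_lt = run(lt, "<")
    return CensoredEvalReport(
        n_gt=n_gt, accuracy_gt=acc_gt, n_lt=n_lt, accuracy_lt=acc_lt,
        verdicts=pd.DataFrame(
            rows, columns=["relation", "predicted_pic50", "bound_pic50", "correct"]
        ),
    )
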