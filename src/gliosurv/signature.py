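"""Stage 1: radiomic survival-prediction index (SPI) from risk-extreme classifiers.

Two linear maximum-margin classifiers are trained on the discovery cohort's
radiomic features with nested cross-validation and recursive feature
elimination: one separating high-risk patients (OS < 6 months) from all
others, one separating low-risk patients (OS ≥ 18 months) from all others.
Their decision values are mapped to pseudo-probabilities by Platt-style
sigmoid calibration fitted on out-of-fold decisions, oriented toward long
survival, and averaged into a per-patient SPI in [0, 1] — higher SPI,
longer predicted survival.

Feature preprocessing: a mean-absolute-deviation filter drops (near-)constant
columns on the raw scale, then features are z-scored with discovery-cohort
statistics only (the replication cohort is transformed, never refit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.feature_selection import RFECV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cohort import Cohort

__all__ = [
    "RiskLabelConfig",
    "SigmoidCalibration",
    "RiskEndpointClassifier",
    "SignatureModel",
    "mad_filter",
    "zscore_fit",
    "zscore_apply",
    "zscore_fit_apply",
    "make_endpoint_labels",
    "nested_cv_train",
    "fit_sigmoid_calibration",
    "compute_spi",
    "train_signature",
    "apply_signature",
    "roc_auc_with_ci",
]

MODEL_FORMAT_VERSION = 1
DEFAULT_C_GRID: tuple[float, ...] = tuple(np.logspace(-3, 3, 7))


@dataclass
class RiskLabelConfig:
    """Risk-extreme endpoint thresholds in months."""

    high_risk_threshold: float = 6.0
    low_risk_threshold: float = 18.0

    def __post_init__(self) -> None:
        if not (0 < self.high_risk_threshold < self.low_risk_threshold):
            raise ValueError("need 0 < high_risk_threshold < low_risk_threshold")


def make_endpoint_labels(
    os_months: Sequence[float], endpoint: str, labels: RiskLabelConfig
) -> np.ndarray:
    """Binary endpoint labels: positives are the risk-extreme class."""
    t = np.asarray(os_months, dtype=float)
    if endpoint == "high_risk":
        return t < labels.high_risk_threshold
    if endpoint == "low_risk":
        return t >= labels.low_risk_threshold
    raise ValueError(f"unknown endpoint {endpoint!r}")


def mad_filter(
    features: pd.DataFrame, epsilon: float = 1e-8
) -> tuple[pd.DataFrame, list[str]]:
    """Drop columns whose mean absolute deviation about the mean is ≤ epsilon.

    Runs on raw (pre-z-scoring) values; epsilon=0 removes exactly the
    constant columns. Column order is preserved.
    """
    if features.shape[1] == 0:
        raise ValueError("feature matrix has no columns")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    X = features.to_numpy(dtype=float)
    mad = np.mean(np.abs(X - X.mean(axis=0)), axis=0)
    keep = mad > epsilon
    dropped = [c for c, k in zip(features.columns, keep) if not k]
    if not keep.any():
        raise ValueError("MAD filter removed every feature column")
    return features.loc[:, keep], dropped


def zscore_fit(train: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-column mean and (ddof=0) standard deviation of the training data."""
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise ValueError(f"zero standard deviation in column(s): {zero}")
    return mean, sd


def zscore_apply(
    apply_to: pd.DataFrame, mean: pd.Series, sd: pd.Series
) -> pd.DataFrame:
    missing = [c for c in apply_to.columns if c not in mean.index]
    if missing:
        raise ValueError(f"no normalization statistics for column(s): {missing}")
    return (apply_to - mean[apply_to.columns]) / sd[apply_to.columns]


def zscore_fit_apply(train: pd.DataFrame, apply_to: pd.DataFrame) -> pd.DataFrame:
    """Transform ``apply_to`` with statistics fitted on ``train`` only."""
    if not set(apply_to.columns) <= set(train.columns):
        extra = sorted(set(apply_to.columns) - set(train.columns))
        raise ValueError(f"apply_to has columns unseen in training: {extra}")
    mean, sd = zscore_fit(train)
    return zscore_apply(apply_to, mean, sd)


@dataclass
class SigmoidCalibration:
    """Platt sigmoid p = 1 / (1 + exp(A·d + B)) of the positive class."""

    A: float
    B: float

    def __post_init__(self) -> None:
        if self.A == 0:
            raise ValueError("calibration slope A must be nonzero")

    def predict(self, decision_values: Sequence[float]) -> np.ndarray:
        d = np.asarray(decision_values, dtype=float)
        z = self.A * d + self.B
        # numerically safe logistic: 1/(1+e^z) = e^{-log(1+e^z)}
        return np.exp(-np.logaddexp(0.0, z))


def fit_sigmoid_calibration(
    decision_values: Sequence[float], labels: Sequence[bool]
) -> SigmoidCalibration:
    """Maximum-likelihood Platt calibration of decision values.

    Targets are smoothed to (N±+1)/(N±+2) so perfect separation yields a
    finite slope rather than divergence.
    """
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("decision_values and labels must be aligned 1-d arrays")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to fit a calibration")
    t = np.where(y, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params: np.ndarray) -> float:
        a, b = params
        z = a * d + b
        # -[t log p + (1-t) log(1-p)] with p = 1/(1+e^z)
        return float(np.sum(t * z + np.logaddexp(0, -z)))

    # init slope negative: larger decision value ⇒ more positive
    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="BFGS")
    a, b = res.x
    if a == 0:
        a = -1e-12
    return SigmoidCalibration(A=float(a), B=float(b))


@dataclass
class RiskEndpointClassifier:
    """A trained risk-extreme linear classifier with its selected features."""

    endpoint: str
    selected_features: list[str]
    weights: np.ndarray
    intercept: float
    C: float
    fold_diagnostics: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.selected_features) != self.weights.size:
            raise ValueError("one weight per selected feature is required")

    @property
    def feature_importance(self) -> pd.Series:
        """|weight| per selected feature, descending."""
        return pd.Series(
            np.abs(self.weights), index=self.selected_features
        ).sort_values(ascending=False)

    def decision_function(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.selected_features if c not in features.columns]
        if missing:
            raise ValueError(f"missing model feature column(s): {missing}")
        X = features[self.selected_features].to_numpy(dtype=float)
        return X @ self.weights + self.intercept


def nested_cv_train(
    features: pd.DataFrame,
    labels: Sequence[bool],
    endpoint: str,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
    n_external_folds: int = 5,
    n_internal_folds: int = 5,
    rfe_step: float = 0.1,
    min_features: int = 8,
) -> tuple[RiskEndpointClassifier, pd.DataFrame]:
    """Nested-CV training of one risk-extreme classifier.

    Stratified external folds estimate generalization; within each external
    training portion, internal CV drives recursive feature elimination
    (weight-ranked, ~10% of columns per round, floor ``min_features``) and
    the regularization-strength grid search, scored by balanced accuracy.
    The external-fold model with the best validation accuracy is returned.

    Returns the winning classifier and a frame of pooled out-of-fold
    decision values (columns ``decision``, ``label``, ``fold``) for
    downstream calibration.
    """
    y = np.asarray(labels, dtype=bool)
    if len(features) != y.size:
        raise ValueError("features and labels must be aligned")
    n_min = int(min(y.sum(), (~y).sum()))
    if n_min < 10:
        raise ValueError(
            f"both classes need >= 10 members (minority has {n_min})"
        )
    if len(c_grid) == 0 or any(c <= 0 for c in c_grid):
        raise ValueError("regularization grid must be non-empty and positive")

    outer = StratifiedKFold(n_external_folds, shuffle=True, random_state=seed)
    X = features.to_numpy(dtype=float)
    candidates: list[RiskEndpointClassifier] = []
    oof_rows: list[pd.DataFrame] = []
    diagnostics: list[dict] = []

    for k, (tr, va) in enumerate(outer.split(X, y)):
        best = None  # (inner_score, C, support, estimator)
        for C in c_grid:
            svc = SVC(kernel="linear", C=C, class_weight="balanced")
            inner = StratifiedKFold(
                n_internal_folds, shuffle=True, random_state=seed + 1 + k
            )
            rfecv = RFECV(
                svc,
                step=rfe_step,
                min_features_to_select=min_features,
                cv=inner,
                scoring="balanced_accuracy",
            )
            rfecv.fit(X[tr], y[tr])
            inner_score = float(np.max(rfecv.cv_results_["mean_test_score"]))
            if best is None or inner_score > best[0]:
                best = (inner_score, float(C), rfecv.support_.copy())
        inner_score, C, support = best
        cols = features.columns[support]
        final = SVC(kernel="linear", C=C, class_weight="balanced")
        final.fit(X[tr][:, support], y[tr])
        d_va = final.decision_function(X[va][:, support])
        val_acc = float(np.mean((d_va > 0) == y[va]))
        val_auc = (
            float(roc_auc_score(y[va], d_va)) if len(np.unique(y[va])) == 2 else np.nan
        )
        diagnostics.append(
            {
                "fold": k,
                "C": C,
                "n_selected": int(support.sum()),
                "inner_balanced_accuracy": inner_score,
                "validation_accuracy": val_acc,
                "validation_auc": val_auc,
            }
        )
        candidates.append(
            RiskEndpointClassifier(
                endpoint=endpoint,
                selected_features=list(cols),
                weights=final.coef_.ravel(),
                intercept=float(final.intercept_[0]),
                C=C,
                fold_diagnostics=[],
            )
        )
        oof_rows.append(
            pd.DataFrame(
                {"decision": d_va, "label": y[va], "fold": k},
                index=features.index[va],
            )
        )

    winner_idx = int(
        np.argmax([d["validation_accuracy"] for d in diagnostics])
    )
    winner = candidates[winner_idx]
    winner.fold_diagnostics = diagnostics
    oof = pd.concat(oof_rows).loc[features.index]
    return winner, oof


def compute_spi(p_not_high_risk, p_low_risk):
    """SPI = mean of the two longevity-oriented pseudo-probabilities."""
    p1 = np.asarray(p_not_high_risk, dtype=float)
    p2 = np.asarray(p_low_risk, dtype=float)
    if np.any(p1 < 0) or np.any(p1 > 1) or np.any(p2 < 0) or np.any(p2 > 1):
        raise ValueError("pseudo-probabilities must lie in [0, 1]")
    return (p1 + p2) / 2.0


@dataclass
class SignatureModel:
    """The trained SPI model: two classifiers, their calibrations, and the
    discovery-cohort preprocessing state (MAD drops, z-scoring statistics)."""

    high_risk: RiskEndpointClassifier
    low_risk: RiskEndpointClassifier
    calibration_high: SigmoidCalibration
    calibration_low: SigmoidCalibration
    norm_mean: pd.Series
    norm_sd: pd.Series
    mad_dropped: list[str]
    labels: RiskLabelConfig = field(default_factory=RiskLabelConfig)
    format_version: int = MODEL_FORMAT_VERSION

    def preprocess(self, features: pd.DataFrame) -> pd.DataFrame:
        kept = [c for c in features.columns if c not in set(self.mad_dropped)]
        needed = set(self.high_risk.selected_features) | set(
            self.low_risk.selected_features
        )
        missing = sorted(needed - set(kept))
        if missing:
            raise ValueError(f"cohort lacks model feature column(s): {missing}")
        return zscore_apply(features[kept], self.norm_mean, self.norm_sd)

    def spi(self, features: pd.DataFrame) -> pd.Series:
        Z = self.preprocess(features)
        p_high = self.calibration_high.predict(self.high_risk.decision_function(Z))
        p_low = self.calibration_low.predict(self.low_risk.decision_function(Z))
        # orient both toward longevity before averaging
        return pd.Series(compute_spi(1.0 - p_high, p_low), index=features.index,
                         name="spi")

    # --- structured text serialization -------------------------------------
    def to_json(self) -> str:
        payload = {
            "format_version": self.format_version,
            "labels": asdict(self.labels),
            "mad_dropped": self.mad_dropped,
            "norm_mean": self.norm_mean.to_dict(),
            "norm_sd": self.norm_sd.to_dict(),
            "calibration": {
                "high_risk": asdict(self.calibration_high),
                "low_risk": asdict(self.calibration_low),
            },
            "classifiers": {
                name: {
                    "endpoint": clf.endpoint,
                    "selected_features": clf.selected_features,
                    "weights": clf.weights.tolist(),
                    "intercept": clf.intercept,
                    "C": clf.C,
                    "fold_diagnostics": clf.fold_diagnostics,
                }
                for name, clf in (("high_risk", self.high_risk),
                                  ("low_risk", self.low_risk))
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        obj = json.loads(text)
        if obj.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported signature model format version")

        def clf(name: str) -> RiskEndpointClassifier:
            c = obj["classifiers"][name]
            return RiskEndpointClassifier(
                endpoint=c["endpoint"],
                selected_features=list(c["selected_features"]),
                weights=np.asarray(c["weights"], dtype=float),
                intercept=float(c["intercept"]),
                C=float(c["C"]),
                fold_diagnostics=list(c["fold_diagnostics"]),
            )

        return cls(
            high_risk=clf("high_risk"),
            low_risk=clf("low_risk"),
            calibration_high=SigmoidCalibration(**obj["calibration"]["high_risk"]),
            calibration_low=SigmoidCalibration(**obj["calibration"]["low_risk"]),
            norm_mean=pd.Series(obj["norm_mean"], dtype=float),
            norm_sd=pd.Series(obj["norm_sd"], dtype=float),
            mad_dropped=list(obj["mad_dropped"]),
            labels=RiskLabelConfig(**obj["labels"]),
        )


def train_signature(
    discovery: Cohort,
    labels: RiskLabelConfig | None = None,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
    mad_epsilon: float = 1e-8,
    n_external_folds: int = 5,
    n_internal_folds: int = 5,
    rfe_step: float = 0.1,
    min_features: int = 8,
) -> SignatureModel:
    """Fit the full SPI model on the discovery cohort only.

    Pipeline: MAD filter (raw scale) → z-scoring (discovery statistics) →
    per-endpoint nested-CV classifier training → Platt calibration on pooled
    out-of-fold decision values. All randomness flows from ``seed``.
    """
    labels = labels or RiskLabelConfig()
    filtered, dropped = mad_filter(discovery.features, mad_epsilon)
    mean, sd = zscore_fit(filtered)
    Z = zscore_apply(filtered, mean, sd)

    classifiers: dict[str, RiskEndpointClassifier] = {}
    calibrations: dict[str, SigmoidCalibration] = {}
    for offset, endpoint in enumerate(("high_risk", "low_risk")):
        y = make_endpoint_labels(discovery.os_months, endpoint, labels)
        clf, oof = nested_cv_train(
            Z, y, endpoint,
            c_grid=c_grid,
            seed=seed + offset,
            n_external_folds=n_external_folds,
            n_internal_folds=n_internal_folds,
            rfe_step=rfe_step,
            min_features=min_features,
        )
        classifiers[endpoint] = clf
        calibrations[endpoint] = fit_sigmoid_calibration(
            oof["decision"].to_numpy(), oof["label"].to_numpy(dtype=bool)
        )
    return SignatureModel(
        high_risk=classifiers["high_risk"],
        low_risk=classifiers["low_risk"],
        calibration_high=calibrations["high_risk"],
        calibration_low=calibrations["low_risk"],
        norm_mean=mean,
        norm_sd=sd,
        mad_dropped=dropped,
        labels=labels,
    )


def apply_signature(model: SignatureModel, cohort: Cohort) -> pd.Series:
    """Per-patient SPI for an unseen cohort; nothing is refit."""
    return model.spi(cohort.features)


def roc_auc_with_ci(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """ROC AUC with a stratified percentile-bootstrap 95% CI.

    AUC is the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, s))
    rng = np.random.default_rng(seed)
    pos, neg = np.flatnonzero(y), np.flatnonzero(~y)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=pos.size, replace=True)
        ineg = rng.choice(neg, size=neg.size, replace=True)
        idx = np.concatenate([ip, ineg])
        stats[b] = roc_auc_score(y[idx], s[idx])
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return auc, (float(lo), float(hi))
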