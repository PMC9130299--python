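"""Risk-group assignment, group survival curves, and log-rank separation.

Patients are cut into low / medium / high risk groups at tertiles of a
fitted model's linear predictor (higher predictor = higher hazard); the
rule is rank-based, so any strictly monotone rescoring yields the same
groups. Separation is tested with the k-sample log-rank statistic and
visualized through per-group Kaplan–Meier curves with Greenwood log-log
95% bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "RiskGroups",
    "LogrankResult",
    "assign_risk_groups",
    "logrank_test",
    "group_km_curves",
]

GROUP_ORDER = ("low", "medium", "high")


@dataclass
class RiskGroups:
    labels: pd.Series                  # per-patient {low, medium, high}
    cuts: tuple[float, float]
    sizes: dict[str, int]


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def assign_risk_groups(
    linear_predictors: pd.Series | np.ndarray,
    quantiles: tuple[float, float] = (1 / 3, 2 / 3),
) -> RiskGroups:
    """Tertile cut (configurable quantiles) on the predicted-risk scale.

    A patient exactly on a cut point goes to the lower-risk group.
    """
    lp = pd.Series(linear_predictors).astype(float)
    if lp.size < 3:
        raise ValueError("need at least 3 patients to form three groups")
    if lp.nunique() < 3:
        raise ValueError("need at least 3 distinct risk scores")
    if not (0 < quantiles[0] < quantiles[1] < 1):
        raise ValueError("cut quantiles must satisfy 0 < q1 < q2 < 1")
    q1, q2 = np.quantile(lp.to_numpy(), quantiles)
    labels = pd.Series(
        np.where(lp > q2, "high", np.where(lp > q1, "medium", "low")),
        index=lp.index,
        name="risk_group",
    )
    sizes = {g: int((labels == g).sum()) for g in GROUP_ORDER}
    return RiskGroups(labels=labels, cuts=(float(q1), float(q2)), sizes=sizes)


def logrank_test(times, groups: RiskGroups) -> LogrankResult:
    """k-sample log-rank test across the risk groups (hypergeometric
    variance handles tied event times exactly)."""
    t = np.asarray(times, dtype=float)
    labels = groups.labels.to_numpy()
    present = pd.unique(labels)
    if len(present) < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    res = multivariate_logrank_test(t, labels, np.ones_like(t, dtype=int))
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=len(present) - 1,
        p_value=float(res.p_value),
    )


def group_km_curves(times, groups: RiskGroups, alpha: float = 0.05) -> pd.DataFrame:
    """Per-group Kaplan–Meier curves with Greenwood log-log bands.

    Returns a plot-ready long table: group, time, survival, lower, upper.
    """
    t = np.asarray(times, dtype=float)
    labels = groups.labels.to_numpy()
    frames = []
    for g in GROUP_ORDER:
        mask = labels == g
        if not mask.any():
            continue
        km = KaplanMeierFitter(alpha=alpha)
        km.fit(t[mask], event_observed=np.ones(mask.sum()), label=g)
        ci = km.confidence_interval_survival_function_
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "time": km.survival_function_.index.to_numpy(),
                    "survival": km.survival_function_[g].to_numpy(),
                    "lower": ci.iloc[:, 0].to_numpy(),
                    "upper": ci.iloc[:, 1].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
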