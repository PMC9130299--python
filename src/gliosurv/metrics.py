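"""Survival-model evaluation for fully observed event times.

All estimators here assume *no censoring*: every patient's event time is
observed. That assumption is asserted, not silently exploited — with unit
weights the Kaplan–Meier estimator collapses to the empirical survival
function and the Brier score needs no inverse-probability-of-censoring
weighting.

Conventions
-----------
* ``risk_scores`` are oriented so that a *higher* score means a *higher*
  hazard (shorter expected survival).
* Survival curves are right-continuous step functions on a shared grid that
  starts at 0 with S(0) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SurvivalCurveSet",
    "MetricWithCI",
    "concordance_index",
    "kaplan_meier",
    "brier_score",
    "integrated_brier_score",
    "ibs_reduction_pct",
    "bootstrap_ci",
]


@dataclass
class SurvivalCurveSet:
    """Per-patient survival curves S_i(t) on a shared time grid.

    Parameters
    ----------
    grid : ndarray of shape (G,)
        Strictly increasing time points; ``grid[0]`` must be 0.
    surv : ndarray of shape (n, G) or (1, G)
        Survival probabilities; a single row is broadcast to every patient.
        Each row must start at 1, lie in [0, 1], and be non-increasing.
    """

    grid: np.ndarray
    surv: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.surv = np.atleast_2d(np.asarray(self.surv, dtype=float))
        if self.grid.ndim != 1 or self.grid.size == 0:
            raise ValueError("time grid must be a non-empty 1-d array")
        if self.grid[0] != 0:
            raise ValueError("time grid must start at 0")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.surv.shape[1] != self.grid.size:
            raise ValueError("surv and grid lengths disagree")
        if np.any(self.surv < -1e-12) or np.any(self.surv > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.abs(self.surv[:, 0] - 1.0) > 1e-12):
            raise ValueError("S(0) must equal 1 for every patient")
        if np.any(np.diff(self.surv, axis=1) > 1e-12):
            raise ValueError("survival curves must be non-increasing in t")

    @property
    def n_curves(self) -> int:
        return self.surv.shape[0]

    def at(self, t: float) -> np.ndarray:
        """Evaluate every curve at time ``t`` (right-continuous step)."""
        if t < 0 or t > self.grid[-1]:
            raise ValueError(
                f"t={t} outside the curve grid [0, {self.grid[-1]}]"
            )
        idx = int(np.searchsorted(self.grid, t, side="right")) - 1
        return self.surv[:, idx]


@dataclass
class MetricWithCI:
    """A point estimate with a 95% percentile-bootstrap interval."""

    point: float
    lower: float
    upper: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.lower <= self.point + 1e-12 and self.point <= self.upper + 1e-12):
            raise ValueError("CI bounds must bracket the point estimate")


def concordance_index(risk_scores: Sequence[float], times: Sequence[float]) -> float:
    """Harrell's concordance index for fully observed times.

    Over all patient pairs with distinct event times, counts the fraction in
    which the patient with the higher risk score dies earlier; pairs tied on
    the risk score contribute 1/2, pairs tied on time are excluded.
    """
    r = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    if r.shape != t.shape or r.ndim != 1:
        raise ValueError("risk_scores and times must be 1-d and aligned")
    if t.size < 2:
        raise ValueError("concordance index needs at least two patients")
    # pair (i, j) usable when t_i < t_j; concordant when r_i > r_j
    earlier = t[:, None] < t[None, :]
    n_usable = int(earlier.sum())
    if n_usable == 0:
        raise ValueError("all event times tied; concordance undefined")
    conc = np.sum(earlier & (r[:, None] > r[None, :]))
    ties = np.sum(earlier & (r[:, None] == r[None, :]))
    return float((conc + 0.5 * ties) / n_usable)


def kaplan_meier(times: Sequence[float]) -> SurvivalCurveSet:
    """Kaplan–Meier curve for fully observed times.

    With no censoring the product-limit estimator reduces to the empirical
    survival function S(t) = #{T_i > t} / n; one shared curve is returned.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("kaplan_meier requires at least one event time")
    grid = np.unique(np.concatenate(([0.0], t)))
    surv = np.array([[np.mean(t > g) for g in grid]])
    return SurvivalCurveSet(grid=grid, surv=surv)


def brier_score(curves: SurvivalCurveSet, times: Sequence[float], t: float) -> float:
    """Brier score at time ``t``: mean over patients of (1[T_i > t] − S_i(t))².

    Unit weights are exact because every event time is observed.
    """
    T = np.asarray(times, dtype=float)
    s = curves.at(t)
    if curves.n_curves == 1:
        s = np.broadcast_to(s, T.shape)
    elif curves.n_curves != T.size:
        raise ValueError("number of curves must be 1 or match the cohort size")
    ind = (T > t).astype(float)
    return float(np.mean((ind - s) ** 2))


def integrated_brier_score(
    curves: SurvivalCurveSet, times: Sequence[float], tau: float
) -> float:
    """IBS(τ) = (1/τ) ∫₀^τ BS(t) dt, trapezoidal rule on the event-time grid."""
    T = np.asarray(times, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be positive")
    if tau > T.max():
        raise ValueError("tau exceeds the largest observed time")
    grid = np.unique(np.concatenate(([0.0, tau], T[T <= tau])))
    bs = np.array([brier_score(curves, T, g) for g in grid])
    return float(np.trapezoid(bs, grid) / tau)


def ibs_reduction_pct(model_ibs: float, reference_ibs: float) -> float:
    """Signed percent change of a model's IBS versus a reference IBS.

    Negative values are improvements, e.g. (0.097, 0.113) → −14.2%.
    """
    if reference_ibs <= 0:
        raise ValueError("reference IBS must be positive")
    return 100.0 * (model_ibs - reference_ibs) / reference_ibs


def bootstrap_ci(
    metric: Callable[..., float],
    sample: Sequence[float] | tuple,
    n_boot: int = 1000,
    seed: int = 0,
) -> MetricWithCI:
    """Percentile bootstrap 95% CI for a statistic of one or more aligned arrays.

    ``sample`` may be a single array or a tuple of aligned arrays; patients are
    resampled jointly with replacement. Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    arrays = sample if isinstance(sample, tuple) else (sample,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("all sample arrays must be aligned on patients")
    if n < 2:
        raise ValueError("degenerate sample: need at least two observations")
    rng = np.random.default_rng(seed)
    point = float(metric(*arrays))
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            stats[b] = metric(*(a[idx] for a in arrays))
        except ValueError:
            stats[b] = np.nan  # e.g. all-tied resample; dropped below
    stats = stats[np.isfinite(stats)]
    lo, hi = np.percentile(stats, [2.5, 97.5])
    lo = min(lo, point)
    hi = max(hi, point)
    return MetricWithCI(point=point, lower=float(lo), upper=float(hi), n_boot=n_boot, seed=seed)
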