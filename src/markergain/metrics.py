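"""Performance measures for binary-outcome probability predictions.

Implements the five measures commonly reported when evaluating a logistic
prediction model — c-statistic (AUC), Brier score, scaled Brier score,
Nagelkerke's generalized R², and the discrimination slope — plus the
Integrated Discrimination Improvement (IDI), which is by definition the
change in discrimination slope between a model that includes a novel marker
and the nested model that omits it.

All functions take a vector of predicted event probabilities and a vector of
observed 0/1 outcomes (the :class:`PredictionSet` substrate) and operate on
apparent (in-sample) performance; no resampling or optimism correction is
applied.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PredictionSet",
    "MetricSet",
    "ModelComparison",
    "c_statistic",
    "brier_score",
    "brier_max",
    "brier_scaled",
    "nagelkerke_r2",
    "discrimination_slope",
    "idi",
    "metric_set",
    "compare_nested_models",
]


class DegenerateOutcomesError(ValueError):
    """Raised when a measure requires both events and non-events but the
    outcome vector is all 0 or all 1."""


def _as_prediction_arrays(probs, outcomes):
    """Validate and coerce a (probs, outcomes) pair to float/int arrays."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes)
    if p.ndim != 1 or y.ndim != 1:
        raise ValueError("probs and outcomes must be one-dimensional")
    if p.shape[0] != y.shape[0]:
        raise ValueError(
            f"length mismatch: {p.shape[0]} probabilities vs {y.shape[0]} outcomes"
        )
    if p.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("probabilities must be finite and in [0, 1]")
    yf = y.astype(float)
    if not np.all((yf == 0.0) | (yf == 1.0)):
        raise ValueError("outcomes must be 0 or 1")
    return p, yf.astype(np.int64)


def _require_both_classes(y, what: str):
    n_events = int(y.sum())
    if n_events == 0 or n_events == y.shape[0]:
        raise DegenerateOutcomesError(
            f"{what} is undefined when all outcomes are "
            f"{'1 (no non-events)' if n_events else '0 (no events)'}"
        )


@dataclass(frozen=True)
class PredictionSet:
    """Paired predicted event probabilities and observed binary outcomes.

    Parameters
    ----------
    probs : array-like of float in [0, 1]
        Predicted probabilities of the event, one per subject.
    outcomes : array-like of {0, 1}
        Observed outcomes, same length as ``probs``.
    """

    probs: np.ndarray
    outcomes: np.ndarray

    def __post_init__(self):
        p, y = _as_prediction_arrays(self.probs, self.outcomes)
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "outcomes", y)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.outcomes.sum())


def _unpack(ps, outcomes):
    if outcomes is None:
        if not isinstance(ps, PredictionSet):
            raise TypeError("pass a PredictionSet, or (probs, outcomes)")
        return ps.probs, ps.outcomes
    return _as_prediction_arrays(ps, outcomes)


def c_statistic(ps, outcomes=None) -> float:
    """Concordance probability (area under the ROC curve).

    The probability that a randomly chosen event subject has a higher
    predicted probability than a randomly chosen non-event subject, with
    ties between predictions counting one half (the Mann–Whitney
    convention).  Computed via midranks in O(n log n).
    """
    p, y = _unpack(ps, outcomes)
    _require_both_classes(y, "c-statistic")
    n1 = int(y.sum())
    n0 = y.shape[0] - n1
    ranks = rankdata(p)  # midranks handle ties
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def brier_score(ps, outcomes=None) -> float:
    """Mean squared prediction error, mean((p_i - Y_i)^2). Lower is better."""
    p, y = _unpack(ps, outcomes)
    return float(np.mean((p - y) ** 2))


def brier_max(mean_p: float) -> float:
    """Maximum attainable Brier score for a non-informative forecast.

    For a model whose predictions average ``mean_p``,
    ``brier_max = mean_p*(1-mean_p)^2 + (1-mean_p)*mean_p^2``, which
    simplifies to ``mean_p*(1-mean_p)``.
    """
    m = float(mean_p)
    return m * (1.0 - m) ** 2 + (1.0 - m) * m**2


def brier_scaled(ps, outcomes=None) -> float:
    """Scaled Brier score: 1 - Brier / Brier_max.

    ``Brier_max`` is evaluated at the mean of the predicted probabilities
    (for any logistic fit containing an intercept this equals the observed
    event rate).  Equals 0 for a non-informative model and 1 for perfect
    predictions; can be negative for a model worse than the mean forecast.
    """
    p, y = _unpack(ps, outcomes)
    bmax = brier_max(p.mean())
    if bmax == 0.0:
        raise ZeroDivisionError(
            "scaled Brier score undefined: mean predicted probability is 0 or 1, "
            "so the maximum Brier score is 0"
        )
    return 1.0 - brier_score(p, y) / bmax


def nagelkerke_r2(loglik_model: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's generalized R² from model and null log-likelihoods.

    Cox–Snell R² = 1 - exp(-LR/n) with LR = 2*(loglik_model - loglik_null),
    rescaled by its maximum 1 - exp(2*loglik_null/n) so that a saturated
    model attains 1.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if loglik_null == 0.0:
        raise ValueError(
            "null log-likelihood of 0 is impossible for a Bernoulli model "
            "with mixed outcomes; R² rescaling undefined"
        )
    lr = 2.0 * (loglik_model - loglik_null)
    if lr < -1e-8 * max(1.0, abs(loglik_null)):
        raise ValueError(
            f"loglik_model ({loglik_model}) < loglik_null ({loglik_null}): "
            "nested maximum-likelihood fits cannot decrease the likelihood; "
            "this signals a failed fit"
        )
    lr = max(lr, 0.0)
    r2_cs = -math.expm1(-lr / n)
    r2_max = -math.expm1(2.0 * loglik_null / n)
    return r2_cs / r2_max


def discrimination_slope(ps, outcomes=None) -> float:
    """Mean predicted probability among events minus among non-events."""
    p, y = _unpack(ps, outcomes)
    _require_both_classes(y, "discrimination slope")
    return float(p[y == 1].mean() - p[y == 0].mean())


def idi(new, old, outcomes=None) -> float:
    """Integrated Discrimination Improvement.

    Difference between the discrimination slope of the new model (with the
    marker) and of the old model (without it).  Both prediction sets must
    share the identical outcome vector.
    """
    if outcomes is None:
        if not (isinstance(new, PredictionSet) and isinstance(old, PredictionSet)):
            raise TypeError("pass two PredictionSets, or (new_probs, old_probs, outcomes)")
        if new.outcomes.shape != old.outcomes.shape or np.any(
            new.outcomes != old.outcomes
        ):
            raise ValueError("new and old prediction sets must share identical outcomes")
        return discrimination_slope(new) - discrimination_slope(old)
    return discrimination_slope(new, outcomes) - discrimination_slope(old, outcomes)


@dataclass(frozen=True)
class MetricSet:
    """The five performance measures for one model on one dataset."""

    c_statistic: float
    brier: float
    brier_scaled: float
    r2_nagelkerke: float
    discrimination_slope: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def __sub__(self, other: "MetricSet") -> "MetricSet":
        return MetricSet(
            c_statistic=self.c_statistic - other.c_statistic,
            brier=self.brier - other.brier,
            brier_scaled=self.brier_scaled - other.brier_scaled,
            r2_nagelkerke=self.r2_nagelkerke - other.r2_nagelkerke,
            discrimination_slope=self.discrimination_slope
            - other.discrimination_slope,
        )


MEASURES = (
    "c_statistic",
    "brier",
    "brier_scaled",
    "r2_nagelkerke",
    "discrimination_slope",
)


def metric_set(ps, loglik_model: float, loglik_null: float, outcomes=None) -> MetricSet:
    """Compute all five measures on one prediction set.

    ``loglik_model`` and ``loglik_null`` are the maximized log-likelihoods
    of the fitted model and of the intercept-only model on the same data.
    """
    p, y = _unpack(ps, outcomes)
    return MetricSet(
        c_statistic=c_statistic(p, y),
        brier=brier_score(p, y),
        brier_scaled=brier_scaled(p, y),
        r2_nagelkerke=nagelkerke_r2(loglik_model, loglik_null, n=p.shape[0]),
        discrimination_slope=discrimination_slope(p, y),
    )


@dataclass(frozen=True)
class ModelComparison:
    """Per-measure comparison of a nested pair of models on shared outcomes.

    ``delta`` is ``new - old`` for every measure; ``idi`` duplicates
    ``delta.discrimination_slope`` (the IDI is by definition the change in
    discrimination slope).
    """

    old: MetricSet
    new: MetricSet
    delta: MetricSet
    idi: float


def compare_nested_models(base, extended, outcomes) -> ModelComparison:
    """Compare a base and an extended (base + marker) logistic fit.

    Parameters
    ----------
    base, extended : FittedLogit
        Fits on the same outcome vector (see :mod:`markergain.engine`); the
        extended model nests the base model.
    outcomes : array-like of {0, 1}
        The shared outcome vector.

    Returns
    -------
    ModelComparison
        Measures for both models, per-measure deltas (new - old) and the IDI.
    """
    y = np.asarray(outcomes)
    if base.fitted_probs.shape[0] != y.shape[0] or extended.fitted_probs.shape[
        0
    ] != y.shape[0]:
        raise ValueError("fits and outcomes have mismatched lengths")
    # the null log-likelihood depends only on the event rate
    ybar = float(np.mean(y))
    n = y.shape[0]
    ll_null = n * (ybar * math.log(ybar) + (1 - ybar) * math.log(1 - ybar))
    m_old = metric_set(base.fitted_probs, base.loglik, ll_null, outcomes=y)
    m_new = metric_set(extended.fitted_probs, extended.loglik, ll_null, outcomes=y)
    delta = m_new - m_old
    return ModelComparison(old=m_old, new=m_new, delta=delta, idi=delta.discrimination_slope)
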