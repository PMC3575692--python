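"""Estimator interface for quantifying a marker's incremental value.

:class:`NestedLogisticComparison` fits two logistic regressions on the same
data — a base model and the base model plus one marker column — and exposes
the five performance measures of each together with their changes (including
the IDI).  It follows the scikit-learn estimator protocol so it can be used
inside pipelines and cross-validation utilities.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .engine import NonConvergenceError, fit_logistic
from .metrics import MEASURES, ModelComparison, compare_nested_models

__all__ = ["NestedLogisticComparison"]


class NestedLogisticComparison(BaseEstimator):
    """Compare a base logistic model with the same model plus one marker.

    Parameters
    ----------
    base_features : sequence of str or int, optional
        Columns of ``X`` used by the base model.  Defaults to every column
        except the marker.
    marker_feature : str or int, default last column
        The single column added in the extended model.
    drop_constant_marker : bool, default True
        If the marker column is constant, fit the extended model without it
        (all deltas are then exactly 0) and warn, instead of failing on a
        singular design.

    Attributes
    ----------
    base_fit_, extended_fit_ : FittedLogit
        The two maximum-likelihood fits (coefficients intercept-first).
    comparison_ : ModelComparison
        Both metric sets, the per-measure deltas, and the IDI.
    idi_ : float
        Change in discrimination slope (== comparison_.delta.discrimination_slope).
    """

    def __init__(
        self,
        base_features: Optional[Sequence] = None,
        marker_feature=None,
        drop_constant_marker: bool = True,
    ):
        self.base_features = base_features
        self.marker_feature = marker_feature
        self.drop_constant_marker = drop_constant_marker

    def _resolve_columns(self, X):
        if isinstance(X, pd.DataFrame):
            columns = list(X.columns)
            get = lambda c: X[c].to_numpy(dtype=float)  # noqa: E731
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("X must be two-dimensional")
            columns = list(range(X.shape[1]))
            get = lambda c: X[:, c]  # noqa: E731
        marker = self.marker_feature if self.marker_feature is not None else columns[-1]
        if marker not in columns:
            raise ValueError(f"marker column {marker!r} not found in X")
        base = (
            list(self.base_features)
            if self.base_features is not None
            else [c for c in columns if c != marker]
        )
        absent = [c for c in base if c not in columns]
        if absent:
            raise ValueError(f"base columns not found in X: {absent}")
        if marker in base:
            raise ValueError("marker column cannot also be a base column")
        return [get(c) for c in base], get(marker)

    def fit(self, X, y) -> "NestedLogisticComparison":
        """Fit base and extended models on (X, y) and compute the comparison."""
        base_cols, marker = self._resolve_columns(X)
        y = np.asarray(y, dtype=float)
        n = y.shape[0]
        ones = np.ones(n)
        X_base = np.column_stack([ones] + base_cols)
        use_marker = True
        if np.ptp(marker) == 0:
            if not self.drop_constant_marker:
                raise ValueError("marker column is constant")
            warnings.warn(
                "marker column is constant; extended model equals the base model"
            )
            use_marker = False
        X_ext = np.column_stack([X_base, marker]) if use_marker else X_base

        self.base_fit_ = fit_logistic(X_base, y)
        self.extended_fit_ = fit_logistic(X_ext, y) if use_marker else self.base_fit_
        for name, fit in (("base", self.base_fit_), ("extended", self.extended_fit_)):
            if not fit.converged:
                raise NonConvergenceError(
                    f"{name} model did not converge (possible separation); "
                    "refusing to report measures from a diverging fit"
                )
        self.comparison_ = compare_nested_models(
            self.base_fit_, self.extended_fit_, y
        )
        self.idi_ = self.comparison_.idi
        self.n_features_in_ = X_base.shape[1] - 1 + int(use_marker)
        return self

    def report(self) -> pd.DataFrame:
        """Table of both models' measures with absolute and relative changes.

        Relative change is delta / baseline except for the Brier score,
        where it is -delta / baseline so that an improvement (a Brier
        decrease) is reported as a positive percentage.
        """
        check_is_fitted(self, "comparison_")
        cmp = self.comparison_
        rows = []
        for m in MEASURES:
            old, new = getattr(cmp.old, m), getattr(cmp.new, m)
            delta = getattr(cmp.delta, m)
            improvement = -delta if m == "brier" else delta
            rel = 100.0 * improvement / old if old != 0 else np.nan
            rows.append(
                {
                    "measure": m,
                    "base": old,
                    "extended": new,
                    "absolute_change": delta,
                    "relative_change_pct": rel,
                }
            )
        return pd.DataFrame(rows)

    def predict_proba(self, X) -> np.ndarray:
        """Event probabilities from the extended model, sklearn-style (n, 2)."""
        check_is_fitted(self, "extended_fit_")
        base_cols, marker = self._resolve_columns(X)
        n = base_cols[0].shape[0] if base_cols else marker.shape[0]
        cols = [np.ones(n)] + base_cols
        if self.extended_fit_.coefficients.shape[0] == len(cols) + 1:
            cols.append(marker)
        eta = np.column_stack(cols) @ self.extended_fit_.coefficients
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p1, p1])
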