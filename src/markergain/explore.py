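"""Exploration of the simulation grid: how improvement depends on baseline
accuracy, marker prevalence, and marker odds ratio.

The central tool regresses the mean improvement in a performance measure on
the baseline value of that measure (continuous, 1 df), marker prevalence
(categorical, 2 df) and marker odds ratio (categorical, 4 df), together with
all two-way interactions (22 coefficients in total), then predicts the
improvement for every (prevalence, odds ratio) combination at the median
baseline accuracy — a compact description of the prevalence-by-odds-ratio
synergy.

A companion summary tabulates, per (odds ratio, prevalence, correlation)
stratum, the correlation between baseline accuracy and improvement — the
tabular counterpart of the improvement-versus-baseline scatter panels.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .metrics import MEASURES

__all__ = [
    "ImprovementAnova",
    "fit_exploration",
    "summarize_relationship",
    "dotchart_table",
]

#: baseline column used per measure (the measure's own baseline value)
def _baseline_column(measure: str) -> str:
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")
    return f"base_{measure}"


def _delta_column(measure: str) -> str:
    return f"delta_{measure}"


class ImprovementAnova(BaseEstimator):
    """ANOVA-style linear model for the improvement in one measure.

    Fits ``delta ~ baseline + C(p_binary) + C(exp_beta_rf)`` plus all
    two-way interactions by ordinary least squares on a grid of scenario
    results, and predicts the improvement at a reference baseline accuracy
    (the median of the supplied baseline column) for all 15
    (prevalence, odds ratio) cells.

    Parameters
    ----------
    measure : str
        One of ``c_statistic``, ``brier``, ``brier_scaled``,
        ``r2_nagelkerke``, ``discrimination_slope``.

    Attributes
    ----------
    ols_result_ : statsmodels RegressionResults
        The fitted 22-coefficient linear model (treatment coding, lowest
        prevalence and odds ratio as reference levels).
    reference_accuracy_ : float
        Median of the baseline-accuracy column actually supplied.
    predicted_improvement_ : pandas.DataFrame
        3 x 5 table indexed by prevalence with odds-ratio columns, holding
        the predicted improvement at the reference accuracy.
    """

    def __init__(self, measure: str = "c_statistic"):
        self.measure = measure

    def fit(self, results: pd.DataFrame, y=None) -> "ImprovementAnova":
        """Fit on a scenario-results table (binary-marker family).

        ``results`` must carry columns ``p_binary``, ``exp_beta_rf``, the
        measure's baseline column and its delta column.
        """
        base_col = _baseline_column(self.measure)
        delta_col = _delta_column(self.measure)
        required = {base_col, delta_col, "p_binary", "exp_beta_rf"}
        missing = required - set(results.columns)
        if missing:
            raise ValueError(f"results table missing columns: {sorted(missing)}")
        df = results[[base_col, delta_col, "p_binary", "exp_beta_rf"]].copy()
        df.columns = ["baseline", "delta", "p_binary", "or_rf"]

        prevalences = np.sort(df["p_binary"].unique())
        odds_ratios = np.sort(df["or_rf"].unique())
        if len(prevalences) < 2 or len(odds_ratios) < 2:
            raise ValueError(
                "need at least two prevalence and two odds-ratio levels; got "
                f"prevalences={list(prevalences)}, odds_ratios={list(odds_ratios)}"
            )

        formula = (
            "delta ~ baseline + C(p_binary) + C(or_rf)"
            " + baseline:C(p_binary) + baseline:C(or_rf)"
            " + C(p_binary):C(or_rf)"
        )
        self.ols_result_ = smf.ols(formula, data=df).fit()
        self.prevalences_ = prevalences
        self.odds_ratios_ = odds_ratios
        self.reference_accuracy_ = float(df["baseline"].median())

        cells = pd.DataFrame(
            list(itertools.product(prevalences, odds_ratios)),
            columns=["p_binary", "or_rf"],
        )
        cells["baseline"] = self.reference_accuracy_
        cells["predicted"] = self.ols_result_.predict(cells)
        self.predicted_improvement_ = cells.pivot(
            index="p_binary", columns="or_rf", values="predicted"
        )
        return self

    def predict(self, results: pd.DataFrame) -> np.ndarray:
        """Predicted improvement for new (baseline, prevalence, OR) rows."""
        check_is_fitted(self, "ols_result_")
        df = results.rename(
            columns={
                _baseline_column(self.measure): "baseline",
                "exp_beta_rf": "or_rf",
            }
        )
        return np.asarray(self.ols_result_.predict(df))

    def dotchart_table(self) -> pd.DataFrame:
        """Long-format (measure, prevalence, OR, predicted improvement)."""
        check_is_fitted(self, "predicted_improvement_")
        long = (
            self.predicted_improvement_.reset_index()
            .melt(id_vars="p_binary", var_name="exp_beta_rf", value_name="predicted_improvement")
            .sort_values(["exp_beta_rf", "p_binary"], kind="mergesort")
            .reset_index(drop=True)
        )
        long.insert(0, "measure", self.measure)
        return long


def fit_exploration(results: pd.DataFrame, measure: str) -> ImprovementAnova:
    """Fit the improvement-exploration model; see :class:`ImprovementAnova`."""
    return ImprovementAnova(measure=measure).fit(results)


def dotchart_table(fit: ImprovementAnova) -> pd.DataFrame:
    """Long-format prediction table suitable for dot-chart plotting."""
    return fit.dotchart_table()


def summarize_relationship(results: pd.DataFrame, measure: str, n_bins: int = 5) -> pd.DataFrame:
    """Baseline-versus-improvement association per design stratum.

    For every (exp_beta_rf, p_binary, correlation) stratum with at least 3
    scenarios, reports the Spearman and Pearson correlations between the
    baseline value of ``measure`` and its delta, plus means of the delta in
    ``n_bins`` equal-count bins of the baseline (NaN-padded when a bin is
    empty).  Strata where the delta is constant get NaN correlations.
    """
    if results.empty:
        raise ValueError("results table is empty")
    base_col = _baseline_column(measure)
    delta_col = _delta_column(measure)
    strata_cols = [c for c in ("exp_beta_rf", "p_binary", "correlation") if c in results.columns]
    rows = []
    for key, grp in results.groupby(strata_cols, dropna=False):
        if len(grp) < 3:
            warnings.warn(f"stratum {key} skipped: only {len(grp)} scenarios")
            continue
        base = grp[base_col].to_numpy()
        delta = grp[delta_col].to_numpy()
        if np.ptp(delta) == 0 or np.ptp(base) == 0:
            spearman = pearson = np.nan
        else:
            spearman = stats.spearmanr(base, delta).statistic
            pearson = stats.pearsonr(base, delta).statistic
        row = dict(zip(strata_cols, key if isinstance(key, tuple) else (key,)))
        row.update(
            n_scenarios=len(grp),
            spearman=spearman,
            pearson=pearson,
        )
        # binned means of the improvement over baseline-accuracy bins
        order = np.argsort(base, kind="mergesort")
        for b, chunk in enumerate(np.array_split(delta[order], n_bins)):
            row[f"bin{b + 1}_mean_delta"] = float(chunk.mean()) if chunk.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
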