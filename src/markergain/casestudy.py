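"""Case-study workflow: incremental value of a marker on a user's own table.

Reads a delimited table with a binary outcome column, a set of base
predictor columns, and a single marker column; fits the base and extended
logistic models; and reports the five performance measures for each model
with absolute and relative changes.  Rows with missing values in any used
column are dropped (complete-case analysis) with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import NestedLogisticComparison

__all__ = ["case_study", "case_study_frame"]

logger = logging.getLogger(__name__)


def case_study_frame(
    df: pd.DataFrame,
    outcome_col: str,
    base_cols: Sequence[str],
    marker_col: str,
) -> pd.DataFrame:
    """Run the nested-model comparison on an in-memory table.

    Returns the report table (one row per measure: base value, extended
    value, absolute change, relative change in percent).
    """
    used = [outcome_col, *base_cols, marker_col]
    absent = [c for c in used if c not in df.columns]
    if absent:
        raise ValueError(f"columns not found in table: {absent}")
    if len(set(used)) != len(used):
        raise ValueError("outcome, base, and marker columns must be distinct")

    complete = df[used].dropna()
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.info("dropped %d rows with missing values (complete-case)", n_dropped)

    y = complete[outcome_col].to_numpy()
    uniq = np.unique(y[~pd.isna(y)])
    if not np.all(np.isin(uniq, [0, 1])) or len(uniq) != 2:
        raise ValueError(
            f"outcome column {outcome_col!r} must be binary 0/1 with both "
            f"classes present; found values {list(uniq)}"
        )

    est = NestedLogisticComparison(
        base_features=list(base_cols), marker_feature=marker_col
    )
    est.fit(complete[[*base_cols, marker_col]], y.astype(float))
    return est.report()


def case_study(
    table_path,
    outcome_col: str,
    base_cols: Sequence[str],
    marker_col: str,
    sep: str = ",",
) -> pd.DataFrame:
    """Run the nested-model comparison on a delimited file with a header."""
    df = pd.read_csv(Path(table_path), sep=sep)
    return case_study_frame(df, outcome_col, base_cols, marker_col)
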