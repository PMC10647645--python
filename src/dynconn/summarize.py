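"""Static (mean) and dynamic (coefficient of variation) summaries.

Window-resolved graph metrics are collapsed into two indicators per
(participant, condition, network, threshold, metric):

* **static**: the mean of the metric across sliding windows — the
  time-averaged network property;
* **dynamic**: the coefficient of variation CV = (sigma/mu) x 100 across
  windows — a dimensionless percentage measuring how strongly the network
  property fluctuates from window to window.

By default both are computed within each epoch and then averaged across a
participant's epochs of the same condition; a pooled mode (CV over all
windows of all epochs) is available as a sensitivity analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

_MEAN_GUARD = 1e-12

KEY_COLUMNS = ["participant_id", "group", "condition", "network", "threshold", "metric"]


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """CV = (sigma / mu) x 100 over the finite entries of ``values``.

    Uses the sample (n-1) standard deviation by default; ``ddof=0`` gives
    the population form.  Returns NaN (with a log record) when the mean is
    numerically zero, so downstream statistics can drop the cell
    explicitly instead of propagating infinities.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError(f"need >= 2 finite values for a CV, got {v.size}")
    mu = v.mean()
    if abs(mu) < _MEAN_GUARD:
        logger.warning("CV undefined: |mean| < %.0e; returning NaN", _MEAN_GUARD)
        return float("nan")
    return float(v.std(ddof=ddof) / mu * 100.0)


def _summary_for_cell(vals: np.ndarray, ddof: int) -> tuple[float, float, int]:
    finite = vals[np.isfinite(vals)]
    n_used = int(finite.size)
    if n_used == 0:
        return float("nan"), float("nan"), 0
    static = float(finite.mean())
    if n_used < 2:
        return static, float("nan"), n_used
    mu = finite.mean()
    if abs(mu) < _MEAN_GUARD:
        dynamic = float("nan")
    else:
        dynamic = float(finite.std(ddof=ddof) / mu * 100.0)
    return static, dynamic, n_used


def summarize_epoch(window_metrics: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-epoch static/dynamic summaries.

    Expects the long table produced by ``GraphMetricsExtractor`` (one row
    per window); NaN window values are excluded and ``n_windows_used``
    reports the finite count.  Cells where every window is NaN are kept
    with NaN summaries and logged.
    """
    keys = KEY_COLUMNS[:3] + ["epoch_index"] + KEY_COLUMNS[3:]
    rows = []
    for key, sub in window_metrics.groupby(keys, sort=False, observed=True):
        static, dynamic, n_used = _summary_for_cell(
            sub["value"].to_numpy(dtype=float), ddof
        )
        if n_used == 0:
            logger.warning("all windows NaN for cell %s", key)
        rows.append((*key, static, dynamic, n_used))
    return pd.DataFrame(
        rows, columns=keys + ["static_mean", "dynamic_cv", "n_windows_used"]
    )


def aggregate_participant(epoch_summaries: pd.DataFrame) -> pd.DataFrame:
    """Average epoch-level summaries into one record per participant x
    condition x network x threshold x metric (unweighted mean across the
    participant's epochs; epoch order is immaterial)."""
    grouped = epoch_summaries.groupby(KEY_COLUMNS, sort=False, observed=True)
    out = grouped.agg(
        static_mean=("static_mean", "mean"),
        dynamic_cv=("dynamic_cv", "mean"),
        n_windows_used=("n_windows_used", "sum"),
    ).reset_index()
    return out


class WindowSummarizer(BaseEstimator, TransformerMixin):
    """Transformer from window-resolved metrics to participant summaries.

    Parameters
    ----------
    ddof
        Delta degrees of freedom for the CV's standard deviation (1 =
        sample sd, the default; 0 = population sd).
    pooling
        ``"per_epoch"`` (default): CV within each epoch, then averaged
        across epochs.  ``"pooled"``: one CV over all windows of all of a
        participant's epochs in a condition.
    """

    def __init__(self, ddof: int = 1, pooling: str = "per_epoch"):
        self.ddof = ddof
        self.pooling = pooling

    def fit(self, X=None, y=None):
        if self.pooling not in ("per_epoch", "pooled"):
            raise ValueError("pooling must be 'per_epoch' or 'pooled'")
        if self.ddof not in (0, 1):
            raise ValueError("ddof must be 0 or 1")
        return self

    def transform(self, window_metrics: pd.DataFrame) -> pd.DataFrame:
        self.fit()
        if self.pooling == "per_epoch":
            return aggregate_participant(summarize_epoch(window_metrics, self.ddof))
        rows = []
        for key, sub in window_metrics.groupby(KEY_COLUMNS, sort=False, observed=True):
            static, dynamic, n_used = _summary_for_cell(
                sub["value"].to_numpy(dtype=float), self.ddof
            )
            rows.append((*key, static, dynamic, n_used))
        return pd.DataFrame(
            rows, columns=KEY_COLUMNS + ["static_mean", "dynamic_cv", "n_windows_used"]
        )
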