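"""Daily expenditure series: data model, transforms, and evaluation metrics.

The universal input is a gap-free daily series of average per-patient
expenditure (USD per patient per day), obtained either directly or as the
quotient of total daily spend over the number of patients refilling that
day.  Models are scored on weekly blocks — consecutive 7-day windows whose
daily values are summed — using RMSE (error) and the coefficient of
determination R^2 (trend), combined into the joint objective
``RMSE/10 + (1 - R^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import adfuller

__all__ = [
    "DailySeries",
    "ScalerParams",
    "StationarityReport",
    "SupervisedSet",
    "EvaluationReport",
    "daily_average_expenditure",
    "scale_to_range",
    "difference",
    "invert_difference",
    "adf_recommend_d",
    "to_weekly_blocks",
    "evaluate",
    "score_weekly",
    "score_weekly_safe",
    "make_supervised",
]


@dataclass(frozen=True)
class DailySeries:
    """A gap-free daily series of average per-patient expenditure.

    Parameters
    ----------
    dates : pandas.DatetimeIndex
        Strictly increasing, consecutive calendar days (one entry per day).
    values : numpy.ndarray
        Finite, nonnegative expenditure in USD per patient per day.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        values = np.asarray(self.values, dtype=float)
        if len(dates) != len(values):
            raise ValueError("dates and values must have equal length")
        if len(values) == 0:
            raise ValueError("series must contain at least one day")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if len(dates) > 1:
            deltas = np.diff(dates.to_numpy())
            if not np.all(deltas == np.timedelta64(1, "D")):
                raise ValueError("dates must be consecutive calendar days")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    def split(self, n_train: int) -> tuple["DailySeries", "DailySeries"]:
        """Contiguous train/test split after ``n_train`` days."""
        if not 0 < n_train < len(self):
            raise ValueError(f"n_train must be in (0, {len(self)})")
        return (
            DailySeries(self.dates[:n_train], self.values[:n_train]),
            DailySeries(self.dates[n_train:], self.values[n_train:]),
        )

    @classmethod
    def from_csv(cls, path) -> "DailySeries":
        """Read the standard input CSV.

        Requires a ``date`` column (ISO-8601) and either a ``value`` column
        or the pair ``total_spent``/``patient_count``, from which the daily
        average is computed.
        """
        df = pd.read_csv(path)
        if "date" not in df.columns:
            raise ValueError("input CSV must have a 'date' column")
        dates = pd.DatetimeIndex(pd.to_datetime(df["date"], format="ISO8601"))
        if "value" in df.columns:
            values = df["value"].to_numpy(dtype=float)
        elif {"total_spent", "patient_count"} <= set(df.columns):
            values = daily_average_expenditure(
                df["total_spent"].to_numpy(dtype=float),
                df["patient_count"].to_numpy(dtype=float),
            )
        else:
            raise ValueError(
                "input CSV must have 'value' or 'total_spent'+'patient_count'"
            )
        return cls(dates, values)

    def to_csv(self, path) -> None:
        pd.DataFrame({"date": self.dates.strftime("%Y-%m-%d"), "value": self.values}).to_csv(
            path, index=False
        )


def daily_average_expenditure(total_spent, refill_count) -> np.ndarray:
    """Per-day average expenditure: total spent divided by patients refilling.

    Raises if any day has a zero or negative refill count (the quotient is
    undefined for such days; inputs are expected to be restricted to days
    with at least one refill).
    """
    total = np.asarray(total_spent, dtype=float)
    count = np.asarray(refill_count, dtype=float)
    if total.shape != count.shape:
        raise ValueError("total_spent and refill_count must have equal length")
    if np.any(count <= 0):
        bad = int(np.argmax(count <= 0))
        raise ValueError(f"refill count must be positive every day (day {bad}: {count[bad]})")
    return total / count


@dataclass(frozen=True)
class ScalerParams:
    """Affine map sending an observed [min, max] onto [-1, +1]."""

    observed_min: float
    observed_max: float
    target_lo: float = -1.0
    target_hi: float = +1.0

    def __post_init__(self) -> None:
        if not self.observed_min < self.observed_max:
            raise ValueError("scaling undefined for a constant series (min == max)")

    @classmethod
    def fit(cls, values) -> "ScalerParams":
        values = np.asarray(values, dtype=float)
        return cls(float(values.min()), float(values.max()))

    @property
    def slope(self) -> float:
        return (self.target_hi - self.target_lo) / (self.observed_max - self.observed_min)

    def scale(self, values):
        values = np.asarray(values, dtype=float)
        return self.target_lo + self.slope * (values - self.observed_min)

    def unscale(self, scaled):
        scaled = np.asarray(scaled, dtype=float)
        return self.observed_min + (scaled - self.target_lo) / self.slope


def scale_to_range(values, params_from=None) -> tuple[np.ndarray, ScalerParams]:
    """Rescale ``values`` to [-1, +1] using the range of ``params_from``.

    ``params_from`` defaults to ``values`` itself; fitting on training data
    only and applying to test avoids look-ahead leakage, so test values may
    legitimately fall outside [-1, +1].
    """
    values = np.asarray(values, dtype=float)
    ref = values if params_from is None else np.asarray(params_from, dtype=float)
    params = ScalerParams.fit(ref)
    return params.scale(values), params


def difference(values, order: int = 1) -> np.ndarray:
    """Apply ``order`` rounds of first differencing y'_t = y_t - y_{t-1}."""
    values = np.asarray(values, dtype=float)
    if order < 0:
        raise ValueError("order must be >= 0")
    if len(values) <= order:
        raise ValueError(f"series of length {len(values)} too short for d={order}")
    return np.diff(values, n=order)


def invert_difference(differenced, initial_values) -> np.ndarray:
    """Invert :func:`difference`; ``initial_values`` are the first value at
    each differencing level (d values; a scalar for d=1).

    ``invert_difference(difference(s, d), heads)`` reproduces ``s`` exactly
    when ``heads`` holds the leading value of each successively differenced
    series: ``[s[0], diff(s)[0], ...]``.
    """
    out = np.asarray(differenced, dtype=float)
    heads = np.atleast_1d(np.asarray(initial_values, dtype=float))
    for head in heads[::-1]:
        out = np.concatenate(([head], head + np.cumsum(out)))
    return out


@dataclass(frozen=True)
class StationarityReport:
    """ADF unit-root diagnostics and the recommended differencing order."""

    adf_statistic: float
    p_value: float
    recommended_d: int


def adf_recommend_d(values, alpha: float = 0.05, max_d: int = 2) -> StationarityReport:
    """Smallest d in {0..max_d} whose d-times-differenced series rejects the
    augmented Dickey-Fuller unit-root null at level ``alpha``.

    The report carries the ADF statistic and p-value at the recommended d.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 20:
        raise ValueError("series too short for a reliable ADF regression (need >= 20)")
    last = None
    for d in range(max_d + 1):
        candidate = difference(values, d) if d else values
        if np.ptp(candidate) == 0.0:  # constant: trivially free of a unit root
            return StationarityReport(float("-inf"), 0.0, d)
        stat, pval = adfuller(candidate, autolag="AIC")[:2]
        last = (stat, pval, d)
        if pval < alpha:
            return StationarityReport(float(stat), float(pval), d)
    stat, pval, d = last
    raise ValueError(
        f"no d <= {max_d} achieves stationarity at alpha={alpha} "
        f"(at d={d}: ADF={stat:.3f}, p={pval:.3f})"
    )


def to_weekly_blocks(values) -> np.ndarray:
    """Sum consecutive 7-day blocks from the series start.

    Trailing days that do not fill a complete block are dropped, so a
    1,306-day series yields 186 blocks and a 259-day series yields 37.
    """
    values = np.asarray(values, dtype=float)
    n_blocks = len(values) // 7
    if n_blocks == 0:
        raise ValueError("need at least 7 days to form a weekly block")
    return values[: 7 * n_blocks].reshape(n_blocks, 7).sum(axis=1)


@dataclass(frozen=True)
class EvaluationReport:
    """Weekly-block RMSE (USD/patient), R^2, and the joint objective.

    ``objective = rmse_for_objective/10 + (1 - r_squared)`` where the RMSE
    term is computed on the calibration (standardized) scale when a scaler
    is supplied, so that both terms vary on a comparable [0, 1] range.
    """

    rmse: float
    r_squared: float
    objective: float


def evaluate(pred, actual) -> EvaluationReport:
    """Score predictions against actuals on whatever scale they share.

    rmse = sqrt(mean squared error); r_squared = 1 - SS_res/SS_tot
    (coefficient of determination; may be negative);
    objective = rmse/10 + (1 - r_squared).
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("pred and actual must have equal length")
    if len(actual) < 2:
        raise ValueError("need at least two points to evaluate")
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: actual series is constant")
    rmse = float(np.sqrt(np.mean((pred - actual) ** 2)))
    r2 = 1.0 - float(np.sum((pred - actual) ** 2)) / ss_tot
    return EvaluationReport(rmse, r2, rmse / 10.0 + (1.0 - r2))


def score_weekly(pred_daily, actual_daily, scaler: ScalerParams | None = None) -> EvaluationReport:
    """Aggregate daily predictions to weekly blocks and score them.

    RMSE and R^2 are reported on the input (USD) scale.  When ``scaler`` is
    given, the objective's RMSE term is instead the weekly RMSE on the
    standardized scale (R^2 is invariant under the affine rescaling, so only
    the RMSE term changes).
    """
    weekly_pred = to_weekly_blocks(pred_daily)
    weekly_actual = to_weekly_blocks(actual_daily)
    report = evaluate(weekly_pred, weekly_actual)
    if scaler is None:
        return report
    rmse_std = report.rmse * scaler.slope
    return EvaluationReport(
        report.rmse, report.r_squared, rmse_std / 10.0 + (1.0 - report.r_squared)
    )


def score_weekly_safe(pred_daily, actual_daily, scaler: ScalerParams | None = None
                      ) -> EvaluationReport:
    """Like :func:`score_weekly`, but tolerates a constant actual series
    (degenerate input, e.g. a zero-noise simulation): R^2 is reported as NaN
    and the objective reduces to its RMSE term."""
    try:
        return score_weekly(pred_daily, actual_daily, scaler)
    except ValueError as exc:
        if "constant" not in str(exc):
            raise
        weekly_pred = to_weekly_blocks(pred_daily)
        weekly_actual = to_weekly_blocks(actual_daily)
        rmse = float(np.sqrt(np.mean((weekly_pred - weekly_actual) ** 2)))
        rmse_obj = rmse * scaler.slope if scaler is not None else rmse
        return EvaluationReport(rmse, float("nan"), rmse_obj / 10.0)


@dataclass(frozen=True)
class SupervisedSet:
    """Lag-window regression view of a series: each row of ``inputs`` holds
    ``lag`` consecutive past values (oldest first) and the matching entry of
    ``targets`` is the value that immediately follows."""

    inputs: np.ndarray
    targets: np.ndarray
    lag: int = field(default=1)

    def __post_init__(self) -> None:
        if self.inputs.shape != (len(self.targets), self.lag):
            raise ValueError("inputs shape must be (n_targets, lag)")

    def __len__(self) -> int:
        return len(self.targets)


def make_supervised(values, lag: int) -> SupervisedSet:
    """Slide a window of ``lag`` past values over the series; n - lag rows."""
    values = np.asarray(values, dtype=float)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if len(values) <= lag:
        raise ValueError(f"series of length {len(values)} too short for lag={lag}")
    n_rows = len(values) - lag
    inputs = np.lib.stride_tricks.sliding_window_view(values[:-1], lag)[:n_rows].copy()
    targets = values[lag:].copy()
    return SupervisedSet(inputs, targets, lag)
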