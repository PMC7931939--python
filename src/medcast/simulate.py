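"""Synthetic expenditure series with the statistical structure the pipeline assumes.

The real inputs — daily average per-patient expenditure on two pain
medications extracted from proprietary claims data — cannot be shipped, so
this module generates series with the two regimes the pipeline must handle:

* ``stationary`` — a positive base level plus ARMA(p, q) noise; an ADF test
  rejects the unit root without differencing (d = 0);
* ``integrated`` — a drifting random walk plus ARMA disturbance; stationary
  only after one differencing (d = 1).

Defaults put daily values around 40 USD/patient (weekly blocks in the
hundreds of USD), with a 1,565-day span splitting into 1,306 training and
259 test days — the shape every downstream stage expects.  Values are
truncated at zero after noise addition (expenditures are nonnegative),
a deliberate, documented deviation from a pure ARMA law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import DailySeries, to_weekly_blocks

__all__ = ["PAPER_N_DAYS", "PAPER_N_TRAIN", "PAPER_N_TEST", "SimConfig",
           "simulate_expenditure", "paper_shaped_split"]

PAPER_N_DAYS = 1565
PAPER_N_TRAIN = 1306
PAPER_N_TEST = 259

_START_DATE = "2011-01-02"


@dataclass(frozen=True)
class SimConfig:
    """Generator settings for one synthetic medicine.

    ``ar``/``ma`` are the ARMA coefficients of the noise process (the AR
    polynomial must be stationary); ``drift`` and ``walk_sd`` only act in
    the integrated regime.  ``refill_rate`` is the mean number of patients
    refilling per day, used when per-day totals/counts are requested.
    """

    n_days: int = PAPER_N_DAYS
    regime: str = "stationary"
    ar: tuple[float, ...] = (0.6, -0.2)
    ma: tuple[float, ...] = (0.3,)
    base_level: float = 40.0
    innovation_sd: float = 4.0
    drift: float = 0.02
    walk_sd: float = 1.2
    refill_rate: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("stationary", "integrated"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.base_level <= 0 or self.innovation_sd < 0 or self.refill_rate <= 0:
            raise ValueError("scales must be positive")
        if self.ar:
            roots = np.roots(np.r_[1.0, -np.asarray(self.ar)])
            if np.any(np.abs(roots) >= 1.0):
                raise ValueError("AR coefficients are explosive (unit/outside-circle root)")


def _arma_noise(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Simulate ARMA(p, q) noise by direct recursion, with burn-in."""
    p, q = len(config.ar), len(config.ma)
    burn = 200 + 10 * max(p, q)
    n = config.n_days + burn
    eps = rng.normal(0.0, config.innovation_sd, size=n)
    x = np.zeros(n)
    for t in range(n):
        acc = eps[t]
        for i in range(1, min(p, t) + 1):
            acc += config.ar[i - 1] * x[t - i]
        for j in range(1, min(q, t) + 1):
            acc += config.ma[j - 1] * eps[t - j]
        x[t] = acc
    return x[burn:]


def simulate_expenditure(config: SimConfig, with_counts: bool = False):
    """Generate a synthetic daily expenditure series.

    Returns a :class:`DailySeries`; with ``with_counts=True`` returns
    ``(series, frame)`` where the frame carries per-day ``total_spent`` and
    ``patient_count`` whose quotient reproduces the series exactly.
    """
    rng = np.random.default_rng(config.seed)
    noise = _arma_noise(config, rng)
    if config.regime == "stationary":
        values = config.base_level + noise
    else:
        walk = np.cumsum(rng.normal(config.drift, config.walk_sd, size=config.n_days))
        values = config.base_level + walk + noise
    values = np.maximum(values, 0.0)
    dates = pd.date_range(_START_DATE, periods=config.n_days, freq="D")
    series = DailySeries(dates, values)
    if not with_counts:
        return series
    counts = rng.poisson(config.refill_rate, size=config.n_days) + 1
    frame = pd.DataFrame(
        {
            "date": dates.strftime("%Y-%m-%d"),
            "total_spent": values * counts,
            "patient_count": counts,
        }
    )
    return series, frame


def paper_shaped_split(series: DailySeries) -> tuple[DailySeries, DailySeries]:
    """Split a 1,565-day series into the canonical 1,306 train / 259 test days
    (186 and 37 complete weekly blocks respectively)."""
    if len(series) != PAPER_N_DAYS:
        raise ValueError(f"expected a {PAPER_N_DAYS}-day series, got {len(series)}")
    train, test = series.split(PAPER_N_TRAIN)
    assert len(to_weekly_blocks(train.values)) == 186
    assert len(to_weekly_blocks(test.values)) == 37
    return train, test
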