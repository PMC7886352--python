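"""Leukocyte trend regression, subset-count normalization, and the
exponential cell-number model used to turn production rates into loss
rates."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "CountSeries",
    "LinearTrend",
    "LossRateBlock",
    "leukocyte_trend",
    "normalize_counts",
    "exponential_counts",
    "loss_rate",
]


@dataclass
class CountSeries:
    """Leukocyte counts and subset fractions over time for one individual.

    ``fractions`` maps subset name to an array of fractions of total
    leukocytes (NaN where missing). ``normalized`` is filled by
    :func:`normalize_counts` and maps subset to (times, counts/ml).
    """

    individual: str
    times: np.ndarray
    leukocytes: np.ndarray
    fractions: dict[str, np.ndarray] = field(default_factory=dict)
    normalized: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.leukocytes = np.asarray(self.leukocytes, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.leukocytes <= 0):
            raise ValueError("leukocyte counts must be > 0")
        for subset, fr in self.fractions.items():
            fr = np.asarray(fr, dtype=float)
            with np.errstate(invalid="ignore"):
                if np.any((fr < 0) | (fr > 1)):
                    raise ValueError(f"fractions for {subset!r} outside [0, 1]")
            self.fractions[subset] = fr


class LinearTrend(NamedTuple):
    """OLS line through (time, leukocytes); callable at any time."""

    intercept: float
    slope: float

    def __call__(self, t):
        return self.intercept + self.slope * np.asarray(t, dtype=float)


def leukocyte_trend(series: CountSeries) -> LinearTrend:
    """Ordinary least-squares line through total leukocyte counts.

    Smooths diurnal and measurement variation before subset counts are
    derived. Requires at least 3 time points.
    """
    if len(series.times) < 3:
        raise ValueError("leukocyte trend needs >= 3 time points")
    slope, intercept = np.polyfit(series.times, series.leukocytes, 1)
    return LinearTrend(float(intercept), float(slope))


def normalize_counts(series: CountSeries, trend: LinearTrend) -> CountSeries:
    """Derive normalized subset counts: trend(t) x subset fraction(t).

    Time points with a missing fraction are omitted (with a warning);
    raw leukocyte values are left untouched.
    """
    for subset, fr in series.fractions.items():
        ok = np.isfinite(fr)
        if not ok.all():
            warnings.warn(
                f"{series.individual}/{subset}: dropping "
                f"{int((~ok).sum())} point(s) with missing fraction",
                stacklevel=2,
            )
        t = series.times[ok]
        series.normalized[subset] = (t, trend(t) * fr[ok])
    return series


@dataclass(frozen=True)
class LossRateBlock:
    """Per-subset rate bookkeeping: production p (fixed from the
    enrichment fit), net growth r = p - d, loss d, and X0 at inclusion."""

    p: float
    r: float
    x0: float
    clipped: bool = False

    @property
    def d(self) -> float:
        return max(self.p - self.r, 0.0)


def exponential_counts(t, block: LossRateBlock):
    """Cell numbers under the exponential model X0 e^((p - d) t)."""
    t = np.asarray(t, dtype=float)
    out = block.x0 * np.exp((block.p - block.d) * t)
    return float(out) if out.ndim == 0 else out


def loss_rate(p: float, r: float) -> tuple[float, bool]:
    """Loss rate d = p - r, floored at 0.

    Returns ``(d, clipped)``; ``clipped`` is True when the naive
    difference was negative.
    """
    if p < 0:
        raise ValueError(f"production rate must be >= 0, got {p}")
    d = p - r
    if d < 0:
        return 0.0, True
    return d, False
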