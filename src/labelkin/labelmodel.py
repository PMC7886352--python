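"""Closed-form label-kinetics curves for heavy-water labeling studies.

Implements the body-water enrichment curve, the mono-exponential label
fraction of a cell compartment (closed-form solution of
``dl/dt = p (c U(t) - l)``, ``l(0) = 0``), mixtures of such curves for
kinetically heterogeneous subsets, scaling to the granulocyte maximum,
and the log-log standard-curve calibration of isotope ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "COMPARTMENTS",
    "LYMPHOCYTE_SUBSETS",
    "BodyWaterParams",
    "KineticMixture",
    "EnrichmentSeries",
    "body_water",
    "mono_label_fraction",
    "mixture_label_fraction",
    "average_production_rate",
    "granulocyte_max",
    "granulocyte_scale",
    "IsotopeCalibration",
    "calibrate_isotope_ratio",
]

#: Recognised cell compartments for enrichment series.
LYMPHOCYTE_SUBSETS = (
    "naive_cd4",
    "memory_cd4",
    "naive_cd8",
    "memory_cd8",
    "naive_b",
    "switched_memory_b",
    "igm_memory_b",
)

COMPARTMENTS = frozenset(
    ("urine", "granulocytes", "pbmc_baseline") + LYMPHOCYTE_SUBSETS
)


class DomainError(ValueError):
    """Input outside the model's domain (negative time, rate, ...)."""


@dataclass(frozen=True)
class BodyWaterParams:
    """Parameters of the piecewise body-water enrichment curve U(t).

    During label intake (t <= tau) enrichment relaxes exponentially from
    the ramp-up level ``beta`` towards the plateau ``f`` at rate
    ``delta``; after intake stops it washes out exponentially at the
    same rate.

    Attributes
    ----------
    f : float
        Asymptotic body-water label fraction (0-1).
    delta : float
        Body-water turnover rate per day (> 0).
    beta : float
        Enrichment attained by the ramp-up dose (0-1).
    tau : float
        End of label administration in days (> t0).
    t0 : float
        First label intake (days); 0 unless the study clock is shifted.
    """

    f: float
    delta: float
    beta: float
    tau: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise DomainError(f"f must be in [0, 1], got {self.f}")
        if not (0.0 <= self.beta <= 1.0):
            raise DomainError(f"beta must be in [0, 1], got {self.beta}")
        if not self.delta > 0.0:
            raise DomainError(f"delta must be > 0, got {self.delta}")
        if not self.tau > self.t0:
            raise DomainError(f"tau must be > t0, got tau={self.tau}, t0={self.t0}")


@dataclass(frozen=True)
class KineticMixture:
    """Kinetic-heterogeneity mixture: fractions alpha_i with rates p_i.

    Components are stored in decreasing-rate order (resolves label
    switching in fits). ``c`` is the amplification factor relating
    body-water enrichment to the maximal attainable DNA enrichment.
    """

    alphas: tuple[float, ...]
    rates: tuple[float, ...]
    c: float = 1.0

    def __post_init__(self) -> None:
        alphas = tuple(float(a) for a in np.atleast_1d(self.alphas))
        rates = tuple(float(p) for p in np.atleast_1d(self.rates))
        if len(alphas) != len(rates):
            raise DomainError("alphas and rates must have equal length")
        if len(alphas) not in (1, 2):
            raise DomainError("number of mixture components must be 1 or 2")
        if any(a < 0 for a in alphas):
            raise DomainError("component fractions must be >= 0")
        if abs(sum(alphas) - 1.0) > 1e-12:
            raise DomainError(f"component fractions must sum to 1, got {sum(alphas)}")
        if any(p < 0 for p in rates):
            raise DomainError("component rates must be >= 0")
        if not self.c > 0:
            raise DomainError(f"amplification factor c must be > 0, got {self.c}")
        order = sorted(range(len(rates)), key=lambda i: -rates[i])
        object.__setattr__(self, "alphas", tuple(alphas[i] for i in order))
        object.__setattr__(self, "rates", tuple(rates[i] for i in order))

    @property
    def n_components(self) -> int:
        return len(self.rates)


@dataclass
class EnrichmentSeries:
    """Time-stamped label-enrichment observations for one individual
    and one cell compartment."""

    individual: str
    compartment: str
    times: np.ndarray
    values: np.ndarray
    scaled: bool = False
    scale_max: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.compartment not in COMPARTMENTS:
            raise DomainError(f"unknown compartment {self.compartment!r}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise DomainError("times and values must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise DomainError("times must be >= 0")
        if np.any(self.values < 0):
            raise DomainError("enrichment values must be >= 0")
        if self.scaled and np.any(self.values > 1.5):
            raise DomainError("scaled enrichment values exceed sanity bound 1.5")

    def __len__(self) -> int:
        return len(self.times)


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be >= 0")
    return t


def body_water(t, params: BodyWaterParams) -> np.ndarray | float:
    """Body-water label fraction U(t).

    ``U(t) = f (1 - e^(-delta t)) + beta e^(-delta t)`` while label is
    administered (t <= tau) and ``U(tau) e^(-delta (t - tau))`` afterwards.
    Continuous at ``t = tau``; vectorized over ``t``. Times before the
    first intake ``t0`` evaluate at the ramp-up level ``beta``.
    """
    t = _check_times(t)
    f, d, b = params.f, params.delta, params.beta
    s = np.maximum(t - params.t0, 0.0)  # time since first intake
    tau = params.tau - params.t0
    up = f + (b - f) * np.exp(-d * np.minimum(s, tau))
    u_tau = f + (b - f) * np.exp(-d * tau)
    down = u_tau * np.exp(-d * np.maximum(s - tau, 0.0))
    out = np.where(s <= tau, up, down)
    return float(out) if out.ndim == 0 else out


def _phi(p: float, d: float, t: np.ndarray) -> np.ndarray:
    """(e^(-d t) - e^(-p t)) / (p - d) with the p -> d limit t e^(-p t).

    The direct difference cancels catastrophically only when
    |p - d| t is tiny; switch to a series expansion there.
    """
    t = np.asarray(t, dtype=float)
    x = (p - d) * t
    small = np.abs(x) < 1e-4
    denom = np.where(small, 1.0, p - d)
    with np.errstate(over="ignore"):
        direct = (np.exp(-d * t) - np.exp(-p * t)) / denom
    series = t * np.exp(-p * t) * (1.0 + x / 2.0 + x * x / 6.0)
    return np.where(small, series, direct)


def mono_label_fraction(t, p: float, bw: BodyWaterParams, c: float = 1.0):
    """Label fraction of a compartment turning over at rate ``p`` per day.

    Closed-form solution of ``dl/dt = p (c U(t) - l)`` with ``l(0) = 0``:

        l(t) = p c \\int_0^t U(s) e^{-p (t - s)} ds

    evaluated piecewise over the labeling and de-labeling phases. The
    degenerate case ``p = delta`` is handled by the analytic
    ``t e^{-p t}`` limit rather than a numerical guard.
    """
    t = _check_times(t)
    if p < 0:
        raise DomainError(f"production rate p must be >= 0, got {p}")
    if p == 0.0:
        out = np.zeros_like(np.asarray(t, dtype=float))
        return float(out) if out.ndim == 0 else out
    f, d, b = bw.f, bw.delta, bw.beta
    tau = bw.tau - bw.t0

    def up(tt):
        # l(t) = c [ f (1 - e^{-pt}) + (b - f) p phi(p, d, t) ]
        return c * (f * (-np.expm1(-p * tt)) + (b - f) * p * _phi(p, d, tt))

    t_arr = np.maximum(np.atleast_1d(t) - bw.t0, 0.0)  # time since first intake
    tl = np.minimum(t_arr, tau)
    l_up = up(tl)
    # washout phase: U decays from U(tau) at rate delta
    s = np.maximum(t_arr - tau, 0.0)
    u_tau = f + (b - f) * np.exp(-d * tau)
    l_tau = up(np.full_like(t_arr, tau))
    l_down = l_tau * np.exp(-p * s) + c * u_tau * p * _phi(p, d, s)
    out = np.where(t_arr <= tau, l_up, l_down)
    return float(out[0]) if np.ndim(t) == 0 else out


def mixture_label_fraction(t, mix: KineticMixture, bw: BodyWaterParams):
    """Label fraction of a mixture: sum_i alpha_i * mono(t, p_i)."""
    t_arr = np.atleast_1d(_check_times(t))
    out = np.zeros_like(t_arr)
    for a, p in zip(mix.alphas, mix.rates):
        out = out + a * mono_label_fraction(t_arr, p, bw, mix.c)
    return float(out[0]) if np.ndim(t) == 0 else out


def average_production_rate(mix: KineticMixture) -> float:
    """Average per-cell production rate: sum_i alpha_i p_i."""
    return float(np.dot(mix.alphas, mix.rates))


def granulocyte_max(
    curve: Callable[[np.ndarray], np.ndarray],
    window: Sequence[float],
    num: int = 2001,
) -> float:
    """Maximum of a fitted granulocyte enrichment curve over the
    observed sampling window (not an analytic global maximum)."""
    window = np.asarray(window, dtype=float)
    grid = np.linspace(window.min(), window.max(), num)
    return float(np.max(curve(grid)))


def granulocyte_scale(gran_fit, series: EnrichmentSeries) -> EnrichmentSeries:
    """Scale an enrichment series by the granulocyte maximum M.

    ``gran_fit`` is either the scaling maximum itself (a float) or any
    object exposing a ``scale_max`` attribute (e.g. the body-water /
    granulocyte fit result). M is attached to the returned series.
    """
    m = float(getattr(gran_fit, "scale_max", gran_fit))
    if not np.isfinite(m) or m <= 0:
        raise ValueError(f"invalid granulocyte scaling maximum M={m}")
    if series.scaled:
        raise ValueError("series is already scaled")
    return replace(
        series, values=series.values / m, scaled=True, scale_max=m
    )


class IsotopeCalibration(NamedTuple):
    """Log-log standard-curve calibration: log10(measured - baseline) =
    slope * log10(known) + intercept."""

    baseline: float
    slope: float
    intercept: float

    def correct(self, measured):
        """Invert the standard curve for one or more measured ratios.

        Returns ``(corrected, below_baseline)``; samples at or below
        the baseline map to 0 with the flag set.
        """
        measured = np.asarray(measured, dtype=float)
        net = measured - self.baseline
        below = net <= 0
        corrected = np.zeros_like(net)
        ok = ~below
        corrected[ok] = 10.0 ** ((np.log10(net[ok]) - self.intercept) / self.slope)
        if measured.ndim == 0:
            return float(corrected), bool(below)
        return corrected, below


def fit_isotope_calibration(known, measured) -> IsotopeCalibration:
    """Fit the calibration line from standards of known enrichment.

    The zero standard provides the additive baseline; the line is fit
    on log10 scale over the nonzero standards.
    """
    known = np.asarray(known, dtype=float)
    measured = np.asarray(measured, dtype=float)
    zero = known == 0
    baseline = float(np.mean(measured[zero])) if np.any(zero) else 0.0
    k = known[~zero]
    m = measured[~zero] - baseline
    if len(k) < 3:
        raise ValueError("need at least 3 nonzero standards")
    if np.any(m <= 0):
        raise ValueError("nonzero standards must measure above baseline")
    slope, intercept = np.polyfit(np.log10(k), np.log10(m), 1)
    if slope <= 0:
        raise ValueError("calibration line must be increasing")
    return IsotopeCalibration(baseline, float(slope), float(intercept))


def calibrate_isotope_ratio(known, measured_standards, measured):
    """Correct a measured tracer-to-tracee ratio against standards.

    Convenience wrapper: fits the log-log standard curve and inverts it
    for ``measured``. Returns ``(corrected, below_baseline_flag)``.
    """
    return fit_isotope_calibration(known, measured_standards).correct(measured)
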