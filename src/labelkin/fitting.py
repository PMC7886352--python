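"""Maximum-likelihood fitting of label-kinetics models.

Two joint fits mirror the study's estimation scheme:

* :func:`fit_body_water_and_granulocytes` — urine and granulocyte
  enrichment fitted together for (f, delta, beta) and (p_gran, c),
  yielding the scaling maximum M.
* :func:`fit_subset` — scaled subset enrichment and trend-normalized
  cell counts fitted together for the kinetic mixture (alpha_i, p_i),
  the loss rate d and the initial count X0, with body-water parameters
  and M fixed upstream.

Both maximize a Gaussian likelihood on transformed scales (arcsin-sqrt
for enrichment, log10 for counts) with each stream's error variance
profiled out analytically. Model selection between 1 and 2 kinetic
components uses an extra-sum-of-squares F-test on the enrichment RSS;
confidence intervals come from a residual bootstrap on the transformed
scales.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc

from .labelmodel import (
    BodyWaterParams,
    EnrichmentSeries,
    KineticMixture,
    average_production_rate,
    body_water,
    granulocyte_max,
    mixture_label_fraction,
    mono_label_fraction,
)

__all__ = [
    "FitResult",
    "FitFailureError",
    "SubsetCounts",
    "asin_sqrt",
    "inv_asin_sqrt",
    "fit_body_water_and_granulocytes",
    "fit_subset",
    "select_components",
    "component_f_test",
    "bootstrap_ci",
    "bootstrap_body_water",
    "bootstrap_subset",
]

LN10 = math.log(10.0)

# bounds on the natural scale; rates are optimized in log10 space
BW_BOUNDS = {
    "f": (1e-4, 0.1),
    "delta": (0.01, 0.5),
    "beta": (0.0, 0.1),
    "p_gran": (0.02, 2.0),
    "c": (1.0, 8.0),
}
RATE_BOUNDS = (1e-5, 2.0)  # component production rates, per day
D_BOUNDS = (0.0, 2.0)  # loss rate, per day
X0_BOUNDS = (1.0, 1e9)  # cells per ml


class FitFailureError(RuntimeError):
    """Optimization failed; carries the best candidate found."""

    def __init__(self, message: str, best=None, diagnostics=None):
        super().__init__(message)
        self.best = best
        self.diagnostics = diagnostics or {}


class SubsetCounts(NamedTuple):
    """Trend-normalized subset counts (cells/ml) over time."""

    times: np.ndarray
    values: np.ndarray


def asin_sqrt(x) -> tuple[np.ndarray, float]:
    """Variance-stabilizing transform for proportions.

    Values are clipped into [0, 1] before the transform; the clipped
    fraction is returned so callers can report it.
    """
    x = np.asarray(x, dtype=float)
    xc = np.clip(x, 0.0, 1.0)
    clipped = float(np.mean(x != xc)) if x.size else 0.0
    return np.arcsin(np.sqrt(xc)), clipped


def inv_asin_sqrt(y) -> np.ndarray:
    """Inverse of :func:`asin_sqrt` (clipped into its range)."""
    return np.sin(np.clip(np.asarray(y, dtype=float), 0.0, np.pi / 2)) ** 2


def _profiled_loglik(rss: float, n: int) -> float:
    """Gaussian log-likelihood with the variance profiled out."""
    if n == 0:
        return 0.0
    # variance floored so a stream that fits to machine precision
    # saturates instead of dominating the joint objective
    s2 = max(rss / n, 1e-14)
    return -0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0)


@dataclass
class FitResult:
    """Point estimates plus everything needed for inference and audit."""

    params: dict[str, float]
    n_components: int | None
    rss_enrichment: float
    rss_counts: float
    loglik: float
    residuals: dict[str, np.ndarray]
    fitted: dict[str, np.ndarray] = field(default_factory=dict)
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0
    seed: int | None = None
    fixed_inputs: dict = field(default_factory=dict)
    scale_max: float | None = None
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    clipped_fraction: float = 0.0

    @property
    def n_obs(self) -> int:
        return sum(len(r) for r in self.residuals.values())

    def body_water_params(self) -> BodyWaterParams:
        p = self.params
        return BodyWaterParams(
            f=p["f"],
            delta=p["delta"],
            beta=p["beta"],
            tau=self.fixed_inputs["tau"],
            t0=self.fixed_inputs.get("t0", 0.0),
        )

    def mixture(self) -> KineticMixture:
        p = self.params
        if self.n_components == 1:
            return KineticMixture((1.0,), (p["p_1"],), c=self.fixed_inputs["c_scaled"])
        return KineticMixture(
            (p["alpha_1"], 1.0 - p["alpha_1"]),
            (p["p_1"], p["p_2"]),
            c=self.fixed_inputs["c_scaled"],
        )

    def param_rows(self, **labels) -> list[dict]:
        """One serializable row per parameter (estimate + CI)."""
        rows = []
        for name, est in self.params.items():
            lo, hi = self.ci95.get(name, (math.nan, math.nan))
            rows.append(
                dict(labels, parameter=name, estimate=est, ci_low=lo, ci_high=hi)
            )
        return rows


# ---------------------------------------------------------------------------
# shared optimizer machinery


def _multistart_minimize(nll, bounds, starts, prescreen=None, polish=True):
    """L-BFGS-B from each start; returns (best_x, best_nll, any_success).

    With ``prescreen=k``, starts are ranked by their objective value and
    only the best k are optimized (cheap triage for expensive fits).
    """
    if prescreen is not None and len(starts) > prescreen:
        vals = []
        for x0 in starts:
            try:
                vals.append(nll(np.asarray(x0)))
            except (ValueError, FloatingPointError):
                vals.append(np.inf)
        order = np.argsort(vals)[:prescreen]
        starts = [starts[i] for i in order]
    best_x, best_val, ok = None, np.inf, False
    for x0 in starts:
        try:
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500},
            )
        except (ValueError, FloatingPointError):  # pathological start
            continue
        if np.isfinite(res.fun) and res.fun < best_val:
            best_x, best_val = res.x, float(res.fun)
            # abnormal line-search exit means no further progress was
            # possible (typical at the profiled-variance floor): accept
            converged = bool(res.success) or "ABNORMAL" in str(res.message).upper()
            ok = ok or converged
    # simplex polish: L-BFGS-B line searches stall in the narrow curved
    # valleys these models produce; Nelder-Mead finishes the job
    if polish and best_x is not None:
        try:
            res = optimize.minimize(
                nll, best_x, method="Nelder-Mead", bounds=bounds,
                options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12},
            )
            if np.isfinite(res.fun) and res.fun < best_val:
                best_x, best_val = res.x, float(res.fun)
        except (ValueError, FloatingPointError):
            pass
    return best_x, best_val, ok


def _lhs_starts(bounds, n_starts, seed, extra=()):
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    pts = lo + sampler.random(n_starts) * (hi - lo)
    return list(extra) + [p for p in pts]


# ---------------------------------------------------------------------------
# body water + granulocytes


def _bw_unpack(x, tau, t0):
    f, ldelta, beta, lp, lc = x
    bw = BodyWaterParams(f=f, delta=10.0**ldelta, beta=beta, tau=tau, t0=t0)
    return bw, 10.0**lp, 10.0**lc


def fit_body_water_and_granulocytes(
    urine: EnrichmentSeries,
    gran: EnrichmentSeries,
    tau: float = 42.0,
    t0: float = 0.0,
    n_starts: int = 20,
    seed: int = 0,
) -> FitResult:
    """Jointly estimate body-water (f, delta, beta) and granulocyte
    (p_gran, c) parameters from urine and granulocyte enrichment.

    Maximizes the sum of two profiled Gaussian log-likelihoods on
    arcsin-sqrt transformed enrichment. The fitted granulocyte curve's
    maximum over the granulocyte sampling window is returned as the
    scaling factor ``scale_max`` (M) for downstream subset fits.
    """
    if len(urine) < 4:
        raise ValueError("need >= 4 urine observations")
    if len(gran) < 4:
        raise ValueError("need >= 4 granulocyte observations")

    yu, clip_u = asin_sqrt(urine.values)
    yg, clip_g = asin_sqrt(gran.values)
    tu, tg = urine.times, gran.times

    def nll(x):
        bw, p_gran, c = _bw_unpack(x, tau, t0)
        mu, _ = asin_sqrt(body_water(tu, bw))
        mg, _ = asin_sqrt(mono_label_fraction(tg, p_gran, bw, c))
        rss_u = float(np.sum((yu - mu) ** 2))
        rss_g = float(np.sum((yg - mg) ** 2))
        return -(_profiled_loglik(rss_u, len(yu)) + _profiled_loglik(rss_g, len(yg)))

    b = BW_BOUNDS
    bounds = [
        b["f"],
        (math.log10(b["delta"][0]), math.log10(b["delta"][1])),
        b["beta"],
        (math.log10(b["p_gran"][0]), math.log10(b["p_gran"][1])),
        (math.log10(b["c"][0]), math.log10(b["c"][1])),
    ]
    # heuristic start from the data
    f0 = float(np.clip(np.max(urine.values), *b["f"]))
    beta0 = float(np.clip(urine.values[0], *b["beta"]))
    c0 = np.max(gran.values) / max(f0, 1e-6)
    x_heur = np.array(
        [
            f0,
            math.log10(0.06),
            beta0,
            math.log10(0.3),
            math.log10(float(np.clip(c0, *b["c"]))),
        ]
    )
    starts = _lhs_starts(bounds, n_starts, seed, extra=[x_heur])
    x, val, ok = _multistart_minimize(nll, bounds, starts,
                                      prescreen=max(6, n_starts // 3))
    if x is None:
        raise FitFailureError("body-water fit failed from all starts")

    bw, p_gran, c = _bw_unpack(x, tau, t0)
    mu, _ = asin_sqrt(body_water(tu, bw))
    mg, _ = asin_sqrt(mono_label_fraction(tg, p_gran, bw, c))
    rss_u = float(np.sum((yu - mu) ** 2))
    rss_g = float(np.sum((yg - mg) ** 2))
    m = granulocyte_max(lambda tt: mono_label_fraction(tt, p_gran, bw, c), tg)

    result = FitResult(
        params={"f": bw.f, "delta": bw.delta, "beta": bw.beta,
                "p_gran": p_gran, "c": c},
        n_components=None,
        rss_enrichment=rss_u + rss_g,
        rss_counts=0.0,
        loglik=-val,
        residuals={"urine": yu - mu, "granulocytes": yg - mg},
        fitted={"urine": mu, "granulocytes": mg},
        fixed_inputs={"tau": tau, "t0": t0},
        scale_max=m,
        converged=ok,
        clipped_fraction=(clip_u * len(yu) + clip_g * len(yg)) / (len(yu) + len(yg)),
    )
    if not ok:
        result.flags.append("no_start_converged")
        raise FitFailureError(
            "body-water fit did not converge", best=result,
            diagnostics={"nll": val},
        )
    return result


# ---------------------------------------------------------------------------
# subset fit (enrichment + counts)


def _subset_bounds(n_components):
    lp = (math.log10(RATE_BOUNDS[0]), math.log10(RATE_BOUNDS[1]))
    lx = (math.log10(X0_BOUNDS[0]), math.log10(X0_BOUNDS[1]))
    if n_components == 1:
        return [lp, D_BOUNDS, lx]
    return [(0.0, 1.0), lp, lp, D_BOUNDS, lx]


def _subset_unpack(x, n_components):
    """-> (alphas, rates, d, x0) with components ordered fast-first."""
    if n_components == 1:
        lp, d, lx = x
        return (1.0,), (10.0**lp,), float(d), 10.0**lx
    a1, lp1, lp2, d, lx = x
    p1, p2 = 10.0**lp1, 10.0**lp2
    if p2 > p1:  # reorder, label switching
        p1, p2, a1 = p2, p1, 1.0 - a1
    return (a1, 1.0 - a1), (p1, p2), float(d), 10.0**lx


def _subset_nll_factory(t_enr, y_enr, t_cnt, y_cnt, bw, c_scaled, n_components):
    def nll(x):
        alphas, rates, d, x0 = _subset_unpack(x, n_components)
        l = np.zeros_like(t_enr)
        for a, p in zip(alphas, rates):
            l = l + a * mono_label_fraction(t_enr, p, bw, c_scaled)
        m_enr, _ = asin_sqrt(l)
        p_avg = float(np.dot(alphas, rates))
        m_cnt = math.log10(x0) + (p_avg - d) * t_cnt / LN10
        rss_e = float(np.sum((y_enr - m_enr) ** 2))
        rss_c = float(np.sum((y_cnt - m_cnt) ** 2))
        return -(
            _profiled_loglik(rss_e, len(y_enr)) + _profiled_loglik(rss_c, len(y_cnt))
        )

    return nll


def _enr_rss_factory(t_enr, y_enr, bw, c_scaled, n_components):
    """Enrichment-stream RSS over the kinetic parameters alone."""

    def rss(x):
        if n_components == 1:
            alphas, rates = (1.0,), (10.0 ** x[0],)
        else:
            a1, lp1, lp2 = x
            alphas, rates = (a1, 1.0 - a1), (10.0**lp1, 10.0**lp2)
        l = np.zeros_like(t_enr)
        for a, p in zip(alphas, rates):
            l = l + a * mono_label_fraction(t_enr, p, bw, c_scaled)
        m, _ = asin_sqrt(l)
        return float(np.sum((y_enr - m) ** 2))

    return rss


def _counts_profile(t_cnt, y_cnt, p_avg):
    """Given the average production rate, the counts stream is a linear
    model in (log10 X0, net rate): solve it by OLS, clipping the implied
    loss rate into its bounds (refitting the intercept if clipped)."""
    slope, intercept = np.polyfit(t_cnt, y_cnt, 1)
    d = p_avg - slope * LN10
    if d < D_BOUNDS[0] or d > D_BOUNDS[1]:
        d = float(np.clip(d, *D_BOUNDS))
        slope = (p_avg - d) / LN10
        intercept = float(np.mean(y_cnt - slope * t_cnt))
    return float(d), float(10.0**intercept)


def _solve_subset(t_enr, y_enr, t_cnt, y_cnt, bw, c_scaled, n_components,
                  n_starts, seed, warm=None, polish=True):
    """Core subset solver.

    The joint likelihood separates: (d, X0) enter only the counts stream
    and are OLS given the average production rate, so the search runs
    over the enrichment parameters alone and a single joint polish
    restores exact joint-ML semantics (the streams couple only when d
    hits a bound).
    """
    rss = _enr_rss_factory(t_enr, y_enr, bw, c_scaled, n_components)
    lp_lo, lp_hi = math.log10(RATE_BOUNDS[0]), math.log10(RATE_BOUNDS[1])
    if n_components == 1:
        bounds_e = [(lp_lo, lp_hi)]
        grid = np.linspace(lp_lo, lp_hi, max(2 * n_starts, 24))
        best = np.argsort([rss([g]) for g in grid])[:3]
        starts = [np.array([grid[i]]) for i in best]
    else:
        bounds_e = [(0.0, 1.0), (lp_lo, lp_hi), (lp_lo, lp_hi)]
        heur = np.array([0.5, math.log10(0.1), math.log10(0.005)])
        starts = _lhs_starts(bounds_e, n_starts, seed, extra=[heur])
    if warm is not None:
        starts = [np.asarray(warm)] + starts
    xe, _, ok = _multistart_minimize(rss, bounds_e, starts, polish=polish)
    if xe is None:
        raise FitFailureError("subset enrichment fit failed from all starts")

    if n_components == 1:
        p_avg = 10.0 ** xe[0]
    else:
        p_avg = xe[0] * 10.0 ** xe[1] + (1.0 - xe[0]) * 10.0 ** xe[2]
    d, x0 = _counts_profile(t_cnt, y_cnt, p_avg)
    lx0 = float(np.clip(math.log10(x0), math.log10(X0_BOUNDS[0]),
                        math.log10(X0_BOUNDS[1])))
    x_full = np.concatenate([xe, [d, lx0]])

    nll = _subset_nll_factory(t_enr, y_enr, t_cnt, y_cnt, bw, c_scaled,
                              n_components)
    x, val, ok2 = _multistart_minimize(nll, _subset_bounds(n_components),
                                       [x_full], polish=polish)
    if x is None:
        x, val, ok2 = x_full, nll(x_full), True
    return x, float(val), bool(ok or ok2)


def _finish_subset_fit(x, nll_val, ok, t_enr, y_enr, t_cnt, y_cnt, bw, c_scaled,
                       n_components, clip_frac, fixed):
    alphas, rates, d, x0 = _subset_unpack(x, n_components)
    mix = KineticMixture(alphas, rates, c=c_scaled)
    m_enr, _ = asin_sqrt(mixture_label_fraction(t_enr, mix, bw))
    p_avg = average_production_rate(mix)
    m_cnt = math.log10(x0) + (p_avg - d) * t_cnt / LN10
    rss_e = float(np.sum((y_enr - m_enr) ** 2))
    rss_c = float(np.sum((y_cnt - m_cnt) ** 2))

    params = {"p_avg": p_avg, "d": d, "r": p_avg - d, "x0": x0}
    if n_components == 1:
        params.update({"alpha_1": 1.0, "p_1": rates[0]})
    else:
        params.update({"alpha_1": alphas[0], "p_1": rates[0], "p_2": rates[1]})

    result = FitResult(
        params=params,
        n_components=n_components,
        rss_enrichment=rss_e,
        rss_counts=rss_c,
        loglik=-nll_val,
        residuals={"enrichment": y_enr - m_enr, "counts": y_cnt - m_cnt},
        fitted={"enrichment": m_enr, "counts": m_cnt},
        fixed_inputs=fixed,
        converged=ok,
        clipped_fraction=clip_frac,
    )
    for name, value, bnds in (
        ("d", d, D_BOUNDS),
        ("p_1", rates[0], RATE_BOUNDS),
        ("p_2", rates[-1] if n_components == 2 else None, RATE_BOUNDS),
    ):
        if value is not None and (value <= bnds[0] or value >= bnds[1]):
            result.flags.append(f"{name}_at_bound")
    return result


def fit_subset(
    enrichment: EnrichmentSeries,
    counts,
    bw,
    scale_max: float | None = None,
    amplification: float | None = None,
    n_components: int = 1,
    n_starts: int = 12,
    seed: int = 0,
) -> FitResult:
    """Estimate subset kinetics from scaled enrichment and normalized
    cell counts, with body-water parameters fixed upstream.

    ``bw`` may be the :class:`FitResult` of
    :func:`fit_body_water_and_granulocytes` (in which case
    ``scale_max`` and ``amplification`` are taken from it) or a
    :class:`BodyWaterParams` with both given explicitly. The scaled
    enrichment follows the kinetic mixture with effective amplification
    ``c / M``; counts follow ``X0 * exp((p_avg - d) t)`` on log10 scale.
    """
    if isinstance(bw, FitResult):
        scale_max = bw.scale_max if scale_max is None else scale_max
        amplification = bw.params["c"] if amplification is None else amplification
        bw = bw.body_water_params()
    if scale_max is None or amplification is None:
        raise ValueError("scale_max and amplification are required")
    if not enrichment.scaled:
        raise ValueError("enrichment series must be scaled to the granulocyte maximum")
    if len(enrichment) < 6:
        raise ValueError("need >= 6 enrichment observations")
    if n_components == 2 and len(enrichment) < 8:
        raise ValueError("2-component fit under-identified with < 8 enrichment points")
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    t_cnt = np.asarray(counts[0], dtype=float)
    v_cnt = np.asarray(counts[1], dtype=float)
    if len(t_cnt) < 4:
        raise ValueError("need >= 4 count observations")
    if np.any(v_cnt <= 0):
        raise ValueError("normalized counts must be > 0")

    c_scaled = amplification / scale_max
    y_enr, clip_frac = asin_sqrt(enrichment.values)
    y_cnt = np.log10(v_cnt)
    t_enr = enrichment.times

    x, val, ok = _solve_subset(t_enr, y_enr, t_cnt, y_cnt, bw, c_scaled,
                               n_components, n_starts, seed)

    fixed = {
        "tau": bw.tau,
        "t0": bw.t0,
        "scale_max": scale_max,
        "amplification": amplification,
        "c_scaled": c_scaled,
        "body_water": {"f": bw.f, "delta": bw.delta, "beta": bw.beta},
        "t_enr": t_enr,
        "t_cnt": t_cnt,
    }
    result = _finish_subset_fit(
        x, val, ok, t_enr, y_enr, t_cnt, y_cnt, bw, c_scaled,
        n_components, clip_frac, fixed,
    )
    if not ok:
        result.flags.append("no_start_converged")
    return result


# ---------------------------------------------------------------------------
# model selection


def component_f_test(fit1: FitResult, fit2: FitResult) -> tuple[float, float]:
    """Extra-sum-of-squares F-test of 2 vs 1 kinetic components.

    The 2-component enrichment model has 2 extra parameters (alpha_1 and
    a second rate). Returns (F, p-value).
    """
    n = len(fit1.residuals["enrichment"])
    rss1, rss2 = fit1.rss_enrichment, fit2.rss_enrichment
    df2 = n - 3
    if df2 <= 0:
        raise ValueError("not enough enrichment points for the F-test")
    if rss1 - rss2 <= 1e-10 * max(rss1, 1e-30):
        return 0.0, 1.0
    f_stat = ((rss1 - rss2) / 2.0) / (rss2 / df2)
    return f_stat, float(stats.f.sf(f_stat, 2, df2))


def select_components(fit1: FitResult, fit2: FitResult, alpha: float = 0.05) -> int:
    """Return 2 iff the 2-component fit is significantly better (F-test,
    p < alpha); 1 otherwise. A 2-component RSS above the 1-component RSS
    (optimizer failure) yields 1 with a warning."""
    if fit2.rss_enrichment > fit1.rss_enrichment:
        warnings.warn(
            "2-component fit has higher enrichment RSS than 1-component; "
            "treating as optimizer failure",
            stacklevel=2,
        )
        return 1
    _, p = component_f_test(fit1, fit2)
    return 2 if p < alpha else 1


# ---------------------------------------------------------------------------
# residual bootstrap


def bootstrap_ci(
    fit: FitResult,
    refit: Callable[[dict[str, np.ndarray]], dict[str, float]],
    n_boot: int = 200,
    seed: int = 0,
    max_fail: float = 0.2,
    df_per_stream: dict[str, int] | None = None,
) -> FitResult:
    """Residual-bootstrap percentile intervals.

    Residuals of each data stream are resampled independently with
    replacement on the transformed scale and added to the fitted values;
    ``refit`` maps the pseudo-data (transformed scale, one array per
    stream) back to a parameter dict. Deterministic given ``seed``.

    ``df_per_stream`` gives the parameter count absorbed by each stream's
    fit; its residuals are inflated by sqrt(n / (n - k)) to undo the
    variance deflation of fitted residuals.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    pools = {}
    for stream, res in fit.residuals.items():
        k = (df_per_stream or {}).get(stream, 0)
        n = len(res)
        pools[stream] = res * math.sqrt(n / (n - k)) if n > k else res
    draws: dict[str, list[float]] = {k: [] for k in fit.params}
    failures = 0
    for _ in range(n_boot):
        pseudo = {
            stream: fit.fitted[stream]
            + rng.choice(pool, size=len(pool), replace=True)
            for stream, pool in pools.items()
        }
        try:
            params_b = refit(pseudo)
        except (FitFailureError, ValueError, FloatingPointError):
            failures += 1
            continue
        for k in draws:
            draws[k].append(params_b[k])
    if failures > max_fail * n_boot:
        raise FitFailureError(
            f"{failures}/{n_boot} bootstrap refits failed",
            best=fit,
            diagnostics={"failures": failures, "n_boot": n_boot},
        )
    ci95 = {}
    for k, vals in draws.items():
        lo, hi = np.percentile(vals, [2.5, 97.5])
        # percentile interval widened (rarely) to contain the estimate
        ci95[k] = (min(float(lo), fit.params[k]), max(float(hi), fit.params[k]))
    return replace(fit, ci95=ci95, n_boot=n_boot, seed=seed)


def bootstrap_subset(
    fit: FitResult,
    n_boot: int = 200,
    seed: int = 0,
    n_starts: int = 2,
) -> FitResult:
    """Residual bootstrap for a subset fit.

    Each replicate is refit warm-started at the point estimate (plus a
    few random starts); the selected number of components is kept fixed
    across replicates.
    """
    fixed = fit.fixed_inputs
    bw = BodyWaterParams(
        f=fixed["body_water"]["f"],
        delta=fixed["body_water"]["delta"],
        beta=fixed["body_water"]["beta"],
        tau=fixed["tau"],
        t0=fixed.get("t0", 0.0),
    )
    c_scaled = fixed["c_scaled"]
    n_comp = fit.n_components
    t_enr = fit.fixed_inputs["t_enr"]  # stashed by fit_subset
    t_cnt = fit.fixed_inputs["t_cnt"]

    p = fit.params
    if n_comp == 1:
        warm = np.array([math.log10(max(p["p_1"], RATE_BOUNDS[0]))])
    else:
        warm = np.array([
            p["alpha_1"],
            math.log10(max(p["p_1"], RATE_BOUNDS[0])),
            math.log10(max(p["p_2"], RATE_BOUNDS[0])),
        ])

    def refit(pseudo):
        y_enr = inv_asin_sqrt(pseudo["enrichment"])
        y_enr, _ = asin_sqrt(y_enr)  # mirror the clipping applied to real data
        x, _, _ = _solve_subset(
            t_enr, y_enr, t_cnt, pseudo["counts"], bw, c_scaled, n_comp,
            n_starts=n_starts, seed=0, warm=warm, polish=False,
        )
        alphas, rates, d, x0 = _subset_unpack(x, n_comp)
        p_avg = float(np.dot(alphas, rates))
        out = {"p_avg": p_avg, "d": d, "r": p_avg - d, "x0": x0,
               "alpha_1": alphas[0], "p_1": rates[0]}
        if n_comp == 2:
            out["p_2"] = rates[1]
        return out

    df = {"enrichment": 1 if n_comp == 1 else 3, "counts": 2}
    return bootstrap_ci(fit, refit, n_boot=n_boot, seed=seed, df_per_stream=df)


def bootstrap_body_water(
    fit: FitResult,
    urine_times: Sequence[float],
    gran_times: Sequence[float],
    n_boot: int = 200,
    seed: int = 0,
) -> FitResult:
    """Residual bootstrap for the joint body-water/granulocyte fit,
    warm-started at the point estimate."""
    tau = fit.fixed_inputs["tau"]
    t0 = fit.fixed_inputs.get("t0", 0.0)
    tu = np.asarray(urine_times, dtype=float)
    tg = np.asarray(gran_times, dtype=float)
    p = fit.params
    x_hat = np.array([
        p["f"], math.log10(p["delta"]), p["beta"],
        math.log10(p["p_gran"]), math.log10(p["c"]),
    ])
    b = BW_BOUNDS
    bounds = [
        b["f"],
        (math.log10(b["delta"][0]), math.log10(b["delta"][1])),
        b["beta"],
        (math.log10(b["p_gran"][0]), math.log10(b["p_gran"][1])),
        (math.log10(b["c"][0]), math.log10(b["c"][1])),
    ]

    def refit(pseudo):
        yu, yg = pseudo["urine"], pseudo["granulocytes"]

        def nll(x):
            bw, p_gran, c = _bw_unpack(x, tau, t0)
            mu, _ = asin_sqrt(body_water(tu, bw))
            mg, _ = asin_sqrt(mono_label_fraction(tg, p_gran, bw, c))
            return -(
                _profiled_loglik(float(np.sum((yu - mu) ** 2)), len(yu))
                + _profiled_loglik(float(np.sum((yg - mg) ** 2)), len(yg))
            )

        x, _, _ = _multistart_minimize(nll, bounds, [x_hat])
        if x is None:
            raise FitFailureError("bootstrap refit failed")
        bw, p_gran, c = _bw_unpack(x, tau, t0)
        return {"f": bw.f, "delta": bw.delta, "beta": bw.beta,
                "p_gran": p_gran, "c": c}

    df = {"urine": 3, "granulocytes": 2}
    return bootstrap_ci(fit, refit, n_boot=n_boot, seed=seed, df_per_stream=df)
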