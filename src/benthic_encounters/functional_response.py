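"""Generalised functional responses and depletion-corrected fitting.

The per-capita consumption rate of a consumer facing resource density N is
modelled by the generalised Holling form

    f(N) = b N^(q+1) / (1 + b h N^(q+1)),

where b is the capture (search) coefficient, h the handling time and q a
dimensionless shape exponent interpolating between the hyperbolic type II
(q = 0) and sigmoidal type III (q = 1) responses.  Feeding trials that do
not replace consumed resources violate the constant-density assumption;
the Rogers random-predator correction instead solves the implicit
depletion equation for the expected number eaten over a trial, and this
module fits that expectation to replicate counts by binomial maximum
likelihood, compares the four classical variants (I, II, III, general) by
small-sample AIC, and derives the comparable rate quantities (capture
rate at half-saturation, maximum feeding rate) used downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .trials import TrialSet

__all__ = [
    "HollingParams", "FittedResponse", "holling_rate", "rogers_eaten",
    "neg_log_likelihood", "fit_model", "fit_all_variants", "select_response",
    "classify_proportional_trend", "capture_rate_at_half_saturation",
    "max_feeding_rate", "bootstrap_mean_q", "aicc", "VARIANTS",
]

VARIANTS = ("I", "II", "III", "general")

#: Probability clip applied inside the binomial likelihood.
_P_EPS = 1e-9


@dataclass(frozen=True)
class HollingParams:
    """Parameters of the generalised functional response.

    b : capture/search coefficient, individuals^-q x arena-units per time
    h : handling time per resource unit (same time unit as the trials)
    q : shape exponent, >= 0 (0 = type II, 1 = type III)
    dimensionality : 2 or 3, the arena dimension the rates refer to
    """

    b: float
    h: float = 0.0
    q: float = 0.0
    dimensionality: int = 2

    def __post_init__(self) -> None:
        if self.b < 0 or self.h < 0 or self.q < 0:
            raise ValueError("b, h and q must all be non-negative")
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")


def holling_rate(N, params: HollingParams):
    """Instantaneous per-capita consumption rate at resource density N.

    Monotone non-decreasing in N; saturates at 1/h as N grows when h > 0.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("resource density must be non-negative")
    Ns = np.power(N, params.q + 1.0)
    out = params.b * Ns / (1.0 + params.b * params.h * Ns)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Rogers depletion solver
# ---------------------------------------------------------------------------

def _lambertw_exp(log_a: np.ndarray) -> np.ndarray:
    """Principal-branch Lambert W of exp(log_a), stable for huge arguments.

    For log_a beyond the overflow threshold, W(e^y) is obtained by
    iterating the fixed point w <- y - log(w), which converges rapidly
    once y is large.
    """
    log_a = np.asarray(log_a, dtype=float)
    w = np.empty_like(log_a)
    small = log_a < 700.0
    if np.any(small):
        w[small] = special.lambertw(np.exp(log_a[small])).real
    if np.any(~small):
        y = log_a[~small]
        v = y - np.log(y)
        for _ in range(4):
            v = y - np.log(v)
        w[~small] = v
    return w


def _depletion_coefficient(N0: np.ndarray, params: HollingParams,
                           exponent_convention: str) -> np.ndarray:
    if exponent_convention == "q":
        return params.b * np.power(N0, params.q)
    if exponent_convention == "q_plus_1":
        return params.b * np.power(N0, params.q + 1.0)
    raise ValueError("exponent_convention must be 'q' or 'q_plus_1'")


def rogers_eaten(N0, T: float, params: HollingParams,
                 exponent_convention: str = "q",
                 method: str = "lambertw"):
    """Expected number eaten in a depletion trial (Rogers random-predator).

    Solves the implicit equation

        Ne = N0 * (1 - exp(c * (h * Ne - T))),    c = b * N0^q,

    whose unique root in [0, N0] is the depletion-corrected expected
    consumption over a trial of duration T started at N0 resources.  For
    h > 0 the closed form via the Lambert W function is

        Ne = N0 - W(c h N0 exp(-c (T - h N0))) / (c h),

    and at h = 0 the equation collapses to the exponential-depletion form
    N0 * (1 - exp(-c T)).

    Parameters
    ----------
    N0 : scalar or array of initial densities (individuals per arena).
    T : trial duration (same time unit as b and h).
    exponent_convention : {"q", "q_plus_1"}
        Depletion coefficient c = b*N0^q (default; reduces to the classic
        Rogers equation at q = 0 and matches the instantaneous per-capita
        attack b*N^q of the generalised response) or the alternative
        c = b*N0^(q+1).
    method : {"lambertw", "brentq"}
        Closed form via Lambert W (default) or a bracketed root-finder;
        the two agree to high precision and the second serves as an
        independent numerical check.
    """
    if T <= 0:
        raise ValueError("trial duration T must be positive")
    N0_arr = np.asarray(N0, dtype=float)
    if np.any(N0_arr < 0):
        raise ValueError("initial density must be non-negative")
    scalar = N0_arr.ndim == 0
    N0_arr = np.atleast_1d(N0_arr)

    out = np.zeros_like(N0_arr)
    pos = N0_arr > 0
    if params.b > 0 and np.any(pos):
        n0 = N0_arr[pos]
        c = _depletion_coefficient(n0, params, exponent_convention)
        if params.h == 0:
            ne = n0 * (-np.expm1(-np.clip(c * T, None, 700.0)))
        elif method == "lambertw":
            ch = c * params.h
            log_arg = np.log(ch * n0) - c * (T - params.h * n0)
            ne = n0 - _lambertw_exp(log_arg) / ch
        elif method == "brentq":
            ne = np.array([_rogers_brentq(x, T, ci, params.h)
                           for x, ci in zip(n0, c)])
        else:
            raise ValueError("method must be 'lambertw' or 'brentq'")
        ne = np.clip(ne, 0.0, n0)
        if np.any(np.isnan(ne)):
            raise FloatingPointError("depletion solver produced NaN")
        out[pos] = ne
    return float(out[0]) if scalar else out


def _rogers_brentq(n0: float, T: float, c: float, h: float) -> float:
    """Bracketed root of x - N0*(1 - exp(c(hx - T))) on [0, N0]."""

    def f(x: float) -> float:
        return x - n0 * (-math.expm1(min(c * (h * x - T), 700.0)))

    lo, hi = 0.0, n0
    if f(hi) < 0:  # root at the boundary within float tolerance
        return hi
    if f(lo) > 0:
        return lo
    return optimize.brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)


# ---------------------------------------------------------------------------
# Likelihood and fitting
# ---------------------------------------------------------------------------

def neg_log_likelihood(params: HollingParams, trials: TrialSet,
                       exponent_convention: str = "q") -> float:
    """Negative binomial log-likelihood of the eaten counts.

    Each replicate contributes log Binomial(eaten | N0, p) with
    p = rogers_eaten(N0, T)/N0, clipped away from {0, 1}.
    """
    if not np.any(trials.N0 > 0):
        raise ValueError("trial set has no positive initial densities")
    expected = rogers_eaten(trials.N0, trials.T, params,
                            exponent_convention=exponent_convention)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(trials.N0 > 0,
                     expected / np.maximum(trials.N0, 1), 0.0)
    p = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    ll = stats.binom.logpmf(trials.eaten, trials.N0, p)
    return float(-np.sum(ll))


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class FittedResponse:
    """One maximum-likelihood fit of a functional-response variant."""

    params: HollingParams
    variant: str
    loglik: float
    k: int
    n: int
    AICc: float
    converged: bool = True
    flag: str = ""
    selected: bool = False
    diagnostic_trend: str | None = None
    param_se: dict = field(default_factory=dict)
    capture_rate_half_sat: float | None = None
    max_feeding_rate: float | None = None
    capture_biomass_g_per_day: float | None = None
    max_feed_biomass_g_per_day: float | None = None
    pair_id: str | None = None


_VARIANT_CONSTRAINTS = {
    # (h free, q free, fixed q value)
    "I": (False, False, 0.0),
    "II": (True, False, 0.0),
    "III": (True, False, 1.0),
    "general": (True, True, None),
}

_Q_MAX = 5.0


def _unpack_theta(theta: np.ndarray, variant: str) -> HollingParams:
    h_free, q_free, q_fixed = _VARIANT_CONSTRAINTS[variant]
    b = math.exp(theta[0])
    i = 1
    h = 0.0
    if h_free:
        h = math.exp(theta[i])
        i += 1
    q = theta[i] if q_free else q_fixed
    return HollingParams(b=b, h=h, q=max(q, 0.0))


def _start_grid(trials: TrialSet, variant: str) -> list[np.ndarray]:
    """Coarse multi-start grid on the optimisation scale."""
    p_bar = float(np.clip(np.mean(trials.proportions()), 1e-4, 1 - 1e-4))
    # crude b scale from exponential depletion at the mean proportion
    b0 = -math.log1p(-p_bar) / trials.T
    max_eaten = max(int(trials.eaten.max()), 1)
    h0 = trials.T / max_eaten  # handling time if the busiest trial saturated
    h_free, q_free, _ = _VARIANT_CONSTRAINTS[variant]
    b_grid = [math.log(b0) + d for d in (-4.6, -2.3, 0.0, 2.3, 4.6)]
    h_grid = [math.log(h0) + d for d in (-2.3, 0.0, 2.3)] if h_free else [None]
    q_grid = [0.1, 1.0, 2.0] if q_free else [None]
    starts = []
    for lb in b_grid:
        for lh in h_grid:
            for q in q_grid:
                theta = [lb]
                if lh is not None:
                    theta.append(lh)
                if q is not None:
                    theta.append(q)
                starts.append(np.array(theta))
    return starts


def _wald_se(objective, theta: np.ndarray, variant: str) -> dict:
    """Finite-difference observed-information standard errors.

    Returned on the natural scale for b and h (delta method from the log
    scale) and directly for q.
    """
    k = theta.size
    hstep = 1e-4
    H = np.zeros((k, k))
    f0 = objective(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hstep
            ej = np.zeros(k); ej[j] = hstep
            fpp = objective(theta + ei + ej)
            fpm = objective(theta + ei - ej)
            fmp = objective(theta - ei + ej)
            fmm = objective(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hstep * hstep)
    try:
        cov = np.linalg.inv(H)
        se_theta = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return {}
    params = _unpack_theta(theta, variant)
    h_free, q_free, _ = _VARIANT_CONSTRAINTS[variant]
    out = {"b": params.b * se_theta[0]}
    i = 1
    if h_free:
        out["h"] = params.h * se_theta[i]
        i += 1
    if q_free:
        out["q"] = se_theta[i]
    return out


def fit_model(trials: TrialSet, variant: str,
              exponent_convention: str = "q",
              n_starts: int | None = None,
              compute_se: bool = True) -> FittedResponse:
    """Fit one functional-response variant by maximum likelihood.

    Optimisation is on log(b) and log(h) (scale invariance; keeps the
    handling-time boundary h -> 0 approachable without pathology) with q
    box-constrained to [0, 5], from a coarse multi-start grid to avoid
    local optima.  Non-convergence across all starts is flagged, never
    silently returned.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    h_free, q_free, _ = _VARIANT_CONSTRAINTS[variant]
    k = 1 + h_free + q_free
    n = trials.n
    if n < k + 2:
        raise ValueError(f"variant {variant} needs at least {k + 2} replicates, "
                         f"got {n}")
    if trials.n_levels < 4:
        warnings.warn("fewer than 4 distinct density levels; fit is weakly "
                      "identified", stacklevel=2)

    if trials.eaten.sum() == 0:
        params = HollingParams(b=0.0, h=0.0,
                               q=_VARIANT_CONSTRAINTS[variant][2] or 0.0)
        ll = -neg_log_likelihood(HollingParams(b=0.0), trials)
        fit = FittedResponse(params=params, variant=variant, loglik=ll, k=k,
                             n=n, AICc=aicc(ll, k, n), converged=True,
                             flag="all_zero_null_fit", pair_id=trials.pair_id)
        _attach_derived(fit, trials)
        return fit

    def objective(theta: np.ndarray) -> float:
        try:
            return neg_log_likelihood(_unpack_theta(theta, variant), trials,
                                      exponent_convention)
        except (OverflowError, FloatingPointError):
            return 1e12

    bounds = [(-30.0, 30.0)]
    if h_free:
        bounds.append((-30.0, 15.0))
    if q_free:
        bounds.append((0.0, _Q_MAX))

    starts = _start_grid(trials, variant)
    if n_starts is not None:
        starts = starts[:max(n_starts, 1)]
    best = None
    any_converged = False
    for theta0 in starts:
        res = optimize.minimize(objective, theta0, method="L-BFGS-B",
                                bounds=bounds)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        any_converged = any_converged or bool(res.success)

    params = _unpack_theta(best.x, variant)
    ll = -float(best.fun)
    fit = FittedResponse(
        params=params, variant=variant, loglik=ll, k=k, n=n,
        AICc=aicc(ll, k, n), converged=any_converged,
        flag="" if any_converged else "no_start_converged",
        param_se=_wald_se(objective, best.x, variant) if compute_se else {},
        pair_id=trials.pair_id,
    )
    _attach_derived(fit, trials)
    return fit


def _attach_derived(fit: FittedResponse, trials: TrialSet) -> None:
    """Fill the derived comparable rates in per-day biomass units.

    The fitted b is in per-arena density units; converting the density
    argument N = n * arena (n in individuals per m^dim) rescales the
    capture coefficient by arena^(q+1), after which the half-saturation
    capture rate is in m^dim per time and the biomass rates follow by
    multiplying by resource wet mass and converting the trial time unit
    to days.
    """
    p = fit.params
    sec_per_unit = trials.seconds_per_time_unit
    per_day = 86400.0 / sec_per_unit
    fit.max_feeding_rate = math.inf if p.h == 0 else 1.0 / p.h
    if p.b == 0:
        fit.capture_rate_half_sat = 0.0
        fit.capture_biomass_g_per_day = 0.0
        fit.max_feed_biomass_g_per_day = (
            math.inf if p.h == 0 else trials.resource_mass * per_day / p.h)
        return
    b_area = p.b * trials.arena ** (p.q + 1.0)
    area_params = HollingParams(b=b_area, h=p.h, q=p.q,
                                dimensionality=trials.arena_dim)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit.capture_rate_half_sat = capture_rate_at_half_saturation(area_params)
    fit.capture_biomass_g_per_day = (
        fit.capture_rate_half_sat * trials.resource_mass * per_day)
    fit.max_feed_biomass_g_per_day = (
        math.inf if p.h == 0 else trials.resource_mass * per_day / p.h)


def fit_all_variants(trials: TrialSet, exponent_convention: str = "q",
                     **kwargs) -> dict[str, FittedResponse]:
    """Fit variants I, II, III and general to one trial set."""
    return {v: fit_model(trials, v, exponent_convention, **kwargs)
            for v in VARIANTS}


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def classify_proportional_trend(trials: TrialSet, span: float = 0.75,
                                flat_tol: float = 0.05) -> str:
    """Classify the shape of proportional consumption versus density.

    A locally weighted regression (lowess with the given span) of
    eaten/N0 on N0 is evaluated at the observed density levels and
    classified: constant proportions indicate a linear
    (type I) response, monotonically decreasing proportions a hyperbolic
    (type II), and a rise followed by a fall a sigmoidal (type III).
    "Flat" means the total smoothed change is below `flat_tol` times the
    mean proportion per decade of density spanned.
    """
    levels = np.unique(trials.N0[trials.N0 > 0])
    if levels.size < 4:
        raise ValueError("need at least 4 distinct density levels")
    props = trials.proportions()[trials.N0 > 0]
    n0 = trials.N0[trials.N0 > 0]
    # smooth the per-level mean proportions on the log-density axis:
    # densities are typically geometric series, and replicate-level
    # smoothing at a wide span washes out interior structure
    level_means = np.array([props[n0 == lv].mean() for lv in levels])
    sm_xy = lowess(level_means, np.log(levels.astype(float)), frac=span,
                   return_sorted=True)
    smoothed = sm_xy[:, 1]

    mean_prop = float(np.mean(props))
    if mean_prop == 0.0:
        return "flat"
    decades = math.log10(levels.max() / levels.min())
    tol = flat_tol * mean_prop * max(decades, 1e-9)

    s_first, s_last = smoothed[0], smoothed[-1]
    interior = smoothed[1:-1]
    if interior.size and interior.max() > max(s_first, s_last) + tol:
        return "hump"
    if s_last < s_first - tol:
        return "decreasing"
    if abs(s_last - s_first) <= tol:
        return "flat"
    return "ambiguous"


_TREND_TO_VARIANT = {"flat": "I", "decreasing": "II", "hump": "III"}


def _effective_class(fit: FittedResponse) -> str:
    """Collapse the general variant onto II/III by its fitted exponent."""
    if fit.variant != "general":
        return fit.variant
    return "III" if fit.params.q >= 0.5 else "II"


def select_response(fits: dict[str, FittedResponse], trials: TrialSet,
                    delta_competitive: float = 2.0,
                    span: float = 0.75, flat_tol: float = 0.05) -> FittedResponse:
    """Choose the supported response variant by AICc with a shape tie-break.

    The lowest-AICc fit wins outright; when two or more fits are
    competitive (delta AICc < 2) the proportional-consumption diagnostic
    decides among them (flat -> I, decreasing -> II, rise-then-fall ->
    III; the general variant is treated as II-like or III-like by its
    fitted q).  Remaining ties go to the most parsimonious fit.
    """
    usable = {v: f for v, f in fits.items()
              if np.isfinite(f.AICc) and f.flag != "no_start_converged"}
    if not usable:
        raise ValueError("no usable fits to select from")
    ranked = sorted(usable.values(), key=lambda f: (f.AICc, f.k))
    best = ranked[0]
    competitors = [f for f in ranked if f.AICc - best.AICc < delta_competitive]
    trend = None
    if len(competitors) > 1:
        try:
            trend = classify_proportional_trend(trials, span, flat_tol)
        except ValueError:
            trend = "ambiguous"
        preferred = _TREND_TO_VARIANT.get(trend)
        if preferred is not None:
            matching = [f for f in competitors
                        if _effective_class(f) == preferred]
            if matching:
                best = min(matching, key=lambda f: (f.k, f.AICc))
    chosen = replace(best)
    chosen.selected = True
    chosen.diagnostic_trend = trend
    return chosen


# ---------------------------------------------------------------------------
# Derived rates and exponent bootstrap
# ---------------------------------------------------------------------------

def capture_rate_at_half_saturation(params: HollingParams,
                                    mode: str = "attack") -> float:
    """Per-capita capture rate at the half-saturation density.

    The half-saturation density solves b h N^(q+1) = 1, i.e.
    N_half = (b h)^(-1/(q+1)).  With ``mode="attack"`` (default) the
    comparable quantity is the effective attack coefficient b * N_half^q
    evaluated there — equal to b itself when q = 0, which is what makes
    capture rates with q > 0 commensurable with plain type-II capture
    coefficients.  ``mode="derivative"`` instead returns the local slope
    of the response curve at N_half, b (q+1) N_half^q / 4.
    """
    if params.b <= 0:
        raise ValueError("capture rate undefined for b <= 0")
    if params.h == 0:
        warnings.warn("h = 0: response never saturates; returning b",
                      stacklevel=2)
        return params.b
    n_half = (params.b * params.h) ** (-1.0 / (params.q + 1.0))
    if mode == "attack":
        return params.b * n_half ** params.q
    if mode == "derivative":
        return params.b * (params.q + 1.0) * n_half ** params.q / 4.0
    raise ValueError("mode must be 'attack' or 'derivative'")


def max_feeding_rate(params: HollingParams) -> float:
    """Asymptotic feeding rate 1/h (resource units per time unit)."""
    return math.inf if params.h == 0 else 1.0 / params.h


def bootstrap_mean_q(q_by_group: dict[str, np.ndarray], n_boot: int = 2000,
                     seed: int | None = None) -> pd.DataFrame:
    """Nonparametric bootstrap of the mean shape exponent per strategy.

    Fitted q values have an atypical distribution (spikes at 0 and 1 plus
    positive non-integer values), so group means are compared by
    resampling with replacement within each group; returns the observed
    mean and 2.5/97.5 percentile interval.  Single-member groups yield a
    degenerate interval and are flagged.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, values in q_by_group.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError(f"group {group!r} is empty")
        idx = rng.integers(0, values.size, size=(n_boot, values.size))
        boot_means = values[idx].mean(axis=1)
        lo, hi = np.percentile(boot_means, [2.5, 97.5])
        rows.append({
            "group": group, "n": values.size, "mean_q": float(values.mean()),
            "ci_lo": float(lo), "ci_hi": float(hi),
            "degenerate": values.size == 1,
        })
    return pd.DataFrame(rows)


def fits_to_frame(selected: list[FittedResponse]) -> pd.DataFrame:
    """Tabulate selected fits for the per-pair CSV interface."""
    rows = []
    for f in selected:
        rows.append({
            "pair_id": f.pair_id, "variant": f.variant,
            "b": f.params.b, "h": f.params.h, "q": f.params.q,
            "loglik": f.loglik, "k": f.k, "n": f.n, "AICc": f.AICc,
            "converged": f.converged, "flag": f.flag,
            "selected": f.selected, "diagnostic": f.diagnostic_trend,
            "capture_half_sat": f.capture_rate_half_sat,
            "max_feed": f.max_feeding_rate,
            "capture_biomass_g_d": f.capture_biomass_g_per_day,
            "max_feed_biomass_g_d": f.max_feed_biomass_g_per_day,
        })
    return pd.DataFrame(rows)
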