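"""Linear vs. sigmoid trajectory models and the tempo/mode classification.

The distance of each venom sample from the individual's juvenile baseline
traces an ontogenetic trajectory.  A gradual shift is well described by a
straight line or a shallow logistic; a discrete shift by a steep logistic.
The machinery here fits both candidate models, compares them with the
small-sample Akaike criterion (AICc), converts the fitted logistic scale
into a tempo (days to traverse 90% of the asymptotic change at the
maximum, inflection-point rate), and applies the classification rule: a
sigmoid-preferred shift completing in fewer days than one 244-day active
season is discrete, anything slower is gradual.

Model forms
-----------
linear      d(t) = a*t + b                             (k = 3 incl. sigma)
sigmoid     d(t) = A / (1 + exp((t0 - t)/s)),  s > 0   (k = 4 incl. sigma)
constant    d(t) = c                                   (k = 2 incl. sigma)

The logistic has a zero left asymptote because distance from the juvenile
baseline starts near zero by construction; a free-baseline 4-parameter
variant is available via ``fit_sigmoid(..., free_baseline=True)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ConvergenceError, InsufficientDataError, ParameterError

__all__ = [
    "TrajectoryFit",
    "ShiftClassification",
    "fit_constant",
    "fit_linear",
    "fit_sigmoid",
    "aicc",
    "tempo",
    "classify_mode",
    "classify_series",
    "SEASON_DAYS",
]

SEASON_DAYS = 244  # April through November, a temperate-zone active season
TEMPO_MAX_RATE_FACTOR = 3.6  # 0.9*A / (A/(4s)) = 3.6*s
TEMPO_CURVE_SPAN_FACTOR = 2 * math.log(19.0)  # t(95%) - t(5%) = 5.89*s


@dataclass
class TrajectoryFit:
    model: str  # "linear" | "sigmoid" | "constant"
    params: dict[str, float]
    rss: float
    n: int
    k: int  # parameter count including the error variance
    aicc: float
    r_squared: float
    p_value: float
    converged: bool = True
    boundary_warning: bool = False


@dataclass
class ShiftClassification:
    mode: str  # no_shift | linear_gradual | sigmoid_gradual | sigmoid_discrete
    tempo_days: float
    delta_aicc: float  # AICc(linear) - AICc(sigmoid); NaN if sigmoid failed
    season_days: float = SEASON_DAYS
    best_model: str = ""
    p_value: float = float("nan")


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike criterion under a Gaussian likelihood.

    ``n*ln(rss/n) + 2k + 2k(k+1)/(n-k-1)``, with additive constants
    dropped consistently across the models being compared.
    """
    if rss <= 0:
        raise ParameterError("rss must be positive (perfect fits have no AICc)")
    if n - k - 1 <= 0:
        raise InsufficientDataError(
            f"AICc undefined for n={n}, k={k} (n - k - 1 must be positive)"
        )
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _check_series(t: np.ndarray, d: np.ndarray, n_min: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    if t.shape != d.shape or t.ndim != 1:
        raise ParameterError("t and d must be matching 1-D vectors")
    if len(t) < n_min:
        raise InsufficientDataError(f"need >= {n_min} points, have {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise ParameterError("t must be strictly increasing")
    return t, d


_RSS_FLOOR = 1e-12


def fit_constant(t: np.ndarray, d: np.ndarray) -> TrajectoryFit:
    t, d = _check_series(t, d, 2)
    n = len(d)
    mean = float(d.mean())
    rss = float(((d - mean) ** 2).sum())
    return TrajectoryFit(
        model="constant",
        params={"mean": mean},
        rss=rss,
        n=n,
        k=2,
        aicc=aicc(max(rss, _RSS_FLOOR), n, 2),
        r_squared=0.0,
        p_value=1.0,
    )


def fit_linear(t: np.ndarray, d: np.ndarray) -> TrajectoryFit:
    """Ordinary least squares with the slope F-test p-value."""
    t, d = _check_series(t, d, 3)
    n = len(d)
    tss = float(((d - d.mean()) ** 2).sum())
    if tss == 0:  # exactly constant response: flat fit, nothing to explain
        return TrajectoryFit(
            model="linear",
            params={"slope": 0.0, "intercept": float(d[0])},
            rss=0.0,
            n=n,
            k=3,
            aicc=aicc(_RSS_FLOOR, n, 3),
            r_squared=0.0,
            p_value=1.0,
        )
    res = stats.linregress(t, d)
    pred = res.intercept + res.slope * t
    rss = float(((d - pred) ** 2).sum())
    r2 = 1.0 - rss / tss
    return TrajectoryFit(
        model="linear",
        params={"slope": float(res.slope), "intercept": float(res.intercept)},
        rss=rss,
        n=n,
        k=3,
        aicc=aicc(max(rss, _RSS_FLOOR), n, 3),
        r_squared=r2,
        p_value=float(res.pvalue),
    )


def _logistic(t: np.ndarray, a: float, t0: float, s: float) -> np.ndarray:
    return a / (1.0 + np.exp(np.clip((t0 - t) / s, -500, 500)))


def fit_sigmoid(
    t: np.ndarray,
    d: np.ndarray,
    seed: int | None = None,
    free_baseline: bool = False,
    sign_free: bool = False,
    max_nfev: int = 2000,
) -> TrajectoryFit:
    """Three-parameter logistic fit by bounded nonlinear least squares.

    Multi-start initialization: A0 = max(d), t0 the first day the series
    exceeds A0/2, and scale starts span/50, span/20, span/8, span/3; the
    start with the lowest residual sum of squares wins.  The p-value is
    the extra-sum-of-squares F-test against the constant model (one p per
    fit, mirroring how a single regression p is reported per curve).

    ``sign_free`` lifts the positivity bound on the asymptote so a
    baseline-centered response may shift downward (per-peak clr series);
    distance trajectories keep A > 0.  ``free_baseline`` adds a fourth
    parameter for a nonzero left asymptote.
    """
    n_min = 6 if free_baseline else 5
    t, d = _check_series(t, d, n_min)
    n = len(d)
    span = float(t[-1] - t[0])
    head = float(d[: min(3, n)].mean())
    tail = float(d[-min(3, n):].mean())
    if sign_free:
        a0 = tail - head if tail != head else float(np.abs(d).max() or 1.0)
        crossed = np.flatnonzero(np.abs(d - head) > abs(a0) / 2)
    else:
        a0 = float(d.max()) if d.max() > 0 else 1.0
        crossed = np.flatnonzero(d > a0 / 2)
    t0_0 = float(t[crossed[0]]) if crossed.size else float(t[n // 2])
    b0 = float(d.min()) if free_baseline else None
    a_low = -np.inf if sign_free else 1e-9

    best = None
    for s0 in (span / 50, span / 20, span / 8, span / 3):
        if free_baseline:
            x0 = [a0 - (b0 or 0.0), t0_0, s0, b0]
            lb = [a_low, t[0] - 2 * span, 1e-9, -np.inf]
            ub = [np.inf, t[-1] + 2 * span, np.inf, np.inf]

            def resid(p, t=t, d=d):
                return _logistic(t, p[0], p[1], p[2]) + p[3] - d
        else:
            x0 = [a0, t0_0, s0]
            lb = [a_low, t[0] - 2 * span, 1e-9]
            ub = [np.inf, t[-1] + 2 * span, np.inf]

            def resid(p, t=t, d=d):
                return _logistic(t, p[0], p[1], p[2]) - d

        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lb, ub), method="trf", max_nfev=max_nfev
            )
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float((sol.fun**2).sum())
        if best is None or rss < best[0]:
            best = (rss, sol)

    if best is None:
        raise ConvergenceError("sigmoid fit failed to converge from every start")

    rss, sol = best
    a_hat, t0_hat, s_hat = (float(v) for v in sol.x[:3])
    params = {"asymptote": a_hat, "inflection": t0_hat, "scale": s_hat}
    if free_baseline:
        params["baseline"] = float(sol.x[3])
    k = 5 if free_baseline else 4
    n_mean_params = k - 1

    tss = float(((d - d.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    # extra-SS F vs the 1-parameter constant model
    df1 = n_mean_params - 1
    df2 = n - n_mean_params
    if tss > rss and df2 > 0:
        f = ((tss - rss) / df1) / (rss / df2) if rss > 0 else np.inf
        p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    else:
        p = 1.0

    boundary = bool(s_hat <= 2e-9 or (not sign_free and a_hat <= 2e-9))
    return TrajectoryFit(
        model="sigmoid",
        params=params,
        rss=rss,
        n=n,
        k=k,
        aicc=aicc(max(rss, _RSS_FLOOR), n, k),
        r_squared=r2,
        p_value=p,
        converged=True,
        boundary_warning=boundary,
    )


def tempo(fit: TrajectoryFit, formula: str = "max_rate") -> float:
    """Days to complete 90% of the compositional change.

    ``max_rate`` (default): 0.9*A divided by the inflection-point slope
    A/(4s), i.e. 3.6*s — the change completed at the maximum estimated
    rate.  ``curve_span``: the curve's own 5%-to-95% transit time,
    2*ln(19)*s.  Both are invariant to rescaling the distance axis.
    """
    if fit.model != "sigmoid":
        raise TypeError(f"tempo requires a sigmoid fit, got {fit.model!r}")
    s = fit.params["scale"]
    if s <= 0:
        raise ParameterError("sigmoid scale must be positive")
    if formula == "max_rate":
        return TEMPO_MAX_RATE_FACTOR * s
    if formula == "curve_span":
        return TEMPO_CURVE_SPAN_FACTOR * s
    raise ParameterError(f"unknown tempo formula {formula!r}")


def classify_mode(
    linear: TrajectoryFit,
    sigmoid: TrajectoryFit | None,
    span_days: float,
    alpha: float = 0.05,
    season_days: float = SEASON_DAYS,
    decisive_delta: float = 2.0,
    tempo_formula: str = "max_rate",
) -> ShiftClassification:
    """Apply the mode/tempo decision rule to a fitted pair of models.

    * best (lowest-AICc) model not significant at ``alpha`` -> ``no_shift``;
    * sigmoid preferred -> sigmoid mode, discrete iff tempo < season;
    * linear preferred but not decisively (delta AICc <= ``decisive_delta``)
      and the sigmoid converged -> ``linear_gradual`` with the
      sigmoid-derived tempo (the steep-but-linear-best case);
    * linear decisively better, or no sigmoid fit -> ``linear_gradual``
      with tempo equal to the sampling span.
    """
    if sigmoid is not None and sigmoid.n != linear.n:
        raise ParameterError("linear and sigmoid fits must use identical data")
    if span_days <= 0:
        raise ParameterError("span_days must be positive")

    if sigmoid is not None:
        delta = linear.aicc - sigmoid.aicc
        sigmoid_preferred = sigmoid.aicc < linear.aicc
    else:
        delta = float("nan")
        sigmoid_preferred = False

    best = sigmoid if sigmoid_preferred else linear
    if sigmoid_preferred:
        tempo_days = tempo(sigmoid, tempo_formula)
        mode = "sigmoid_discrete" if tempo_days < season_days else "sigmoid_gradual"
    elif sigmoid is not None and delta >= -decisive_delta:
        # linear wins on AICc but not decisively; report the linear mode
        # with the tempo implied by the (competitive) sigmoid
        tempo_days = tempo(sigmoid, tempo_formula)
        mode = "linear_gradual"
    else:
        tempo_days = float(span_days)
        mode = "linear_gradual"

    if best.p_value >= alpha:
        mode = "no_shift"

    return ShiftClassification(
        mode=mode,
        tempo_days=tempo_days,
        delta_aicc=delta,
        season_days=season_days,
        best_model=best.model,
        p_value=best.p_value,
    )


def classify_series(
    t: np.ndarray,
    d: np.ndarray,
    alpha: float = 0.05,
    season_days: float = SEASON_DAYS,
    decisive_delta: float = 2.0,
    tempo_formula: str = "max_rate",
    seed: int | None = None,
    sign_free: bool = False,
) -> tuple[TrajectoryFit, TrajectoryFit | None, ShiftClassification]:
    """Fit both models to a series and classify, falling back to linear
    when the sigmoid cannot be fit (non-convergence or too few points)."""
    linear = fit_linear(t, d)
    try:
        sig = fit_sigmoid(t, d, seed=seed, sign_free=sign_free)
    except (ConvergenceError, InsufficientDataError):
        sig = None
    span = float(t[-1] - t[0])
    cls = classify_mode(
        linear,
        sig,
        span_days=span,
        alpha=alpha,
        season_days=season_days,
        decisive_delta=decisive_delta,
        tempo_formula=tempo_formula,
    )
    return linear, sig, cls
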