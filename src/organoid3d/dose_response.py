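"""n-parameter logistic dose–response fitting and IC50 estimation.

The model on x = log10(dose) is

    f(x) = B + (T - B) / (1 + 10^(b (x_mid - x)))^s

with bottom B, top T, inflection x_mid, slope b and asymmetry s (s = 1
gives the familiar 4PL).  The relative IC50 is the dose at which the fitted
curve crosses the midpoint (T + B)/2 of its asymptotes, available in closed
form; the absolute variant (response = 0.5 of control) is also reported.
Confidence intervals come from a seeded nonparametric bootstrap (scaled
residual resampling by default; well-level case resampling optional).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Dose–response fit could not be carried out."""


@dataclass
class DoseResponseFit:
    """Result of an n-parameter logistic fit."""

    bottom: float
    top: float
    x_mid: float  # log10(dose) at inflection
    slope: float
    asymmetry: float
    n_params: int
    ic50: float  # µM, relative (midpoint of asymptotes)
    ic50_absolute: float | None  # µM, response == 0.5; None if not crossed
    ic50_ci_95: tuple[float, float] | None
    rss: float
    extrapolated: bool
    per_dose: pd.DataFrame = field(repr=False, default=None)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.bottom, self.top, self.x_mid, self.slope, self.asymmetry])


def logistic5(x: np.ndarray, bottom: float, top: float, x_mid: float,
              slope: float, asymmetry: float = 1.0) -> np.ndarray:
    """Evaluate the 5-parameter logistic on x = log10(dose)."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (x_mid - x))) ** asymmetry


def normalize_response(treated: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Fraction-of-control responses: treated / mean(control), replicates kept."""
    control = np.asarray(control, dtype=float)
    c = control.mean()
    if not np.isfinite(c) or c <= 0:
        raise ValueError(f"control mean must be positive, got {c}")
    return np.asarray(treated, dtype=float) / c


def _ic50_from_params(bottom, top, x_mid, slope, asymmetry) -> float:
    """Dose where f equals (T+B)/2, in original dose units (closed form)."""
    if asymmetry == 1.0:
        return 10.0 ** x_mid
    # (1 + 10^(b(x_mid - x)))^s = 2  =>  x = x_mid - log10(2^(1/s) - 1)/b
    return 10.0 ** (x_mid - np.log10(2.0 ** (1.0 / asymmetry) - 1.0) / slope)


def _absolute_ic50(bottom, top, x_mid, slope, asymmetry, level: float = 0.5) -> float | None:
    """Dose where the fitted response equals ``level`` of control, or None."""
    lo, hi = min(bottom, top), max(bottom, top)
    if not lo < level < hi:
        return None
    u = ((top - bottom) / (level - bottom)) ** (1.0 / asymmetry) - 1.0
    if u <= 0:
        return None
    return 10.0 ** (x_mid - np.log10(u) / slope)


def _fit_once(x, y, n_params, p0, bounds) -> tuple[np.ndarray, float]:
    def resid(p):
        if n_params == 4:
            return logistic5(x, p[0], p[1], p[2], p[3], 1.0) - y
        return logistic5(x, *p) - y

    sol = least_squares(resid, p0, bounds=bounds, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return sol.x, float(np.sum(sol.fun ** 2))


def _starts(x, y, n_params, n_starts, rng) -> list[np.ndarray]:
    b0, t0 = float(np.min(y)), float(np.max(y))
    xm0 = float(np.median(x))
    xr = float(np.ptp(x)) or 1.0
    base = []
    for slope in (1.0, -1.0):
        p = [b0, t0, xm0, slope] + ([1.0] if n_params == 5 else [])
        base.append(np.array(p))
    starts = list(base)
    while len(starts) < n_starts:
        p = base[len(starts) % 2].copy()
        p[2] += rng.uniform(-0.5, 0.5) * xr
        p[3] *= rng.uniform(0.3, 3.0)
        if n_params == 5:
            p[4] = rng.uniform(0.3, 3.0)
        starts.append(p)
    return starts


def fit_nplr(
    doses: np.ndarray,
    responses: np.ndarray,
    n_params: int = 4,
    n_starts: int = 10,
    n_boot: int = 1000,
    seed: int | None = None,
    flat_tolerance: float = 1e-3,
    ci: bool = True,
    boot_method: str = "residual",
) -> DoseResponseFit:
    """Fit an n-parameter (4 or 5) logistic curve and estimate the IC50.

    ``doses`` (µM, > 0) and ``responses`` (fraction of control) are
    replicate-level vectors of equal length.  Fitting is bounded nonlinear
    least squares on x = log10(dose), multi-started from data-driven
    initials; the bootstrap CI (default: scaled residual resampling, see
    ``_bootstrap_ic50``) refits from the point estimate.

    Raises
    ------
    FitError
        If fewer than ``n_params`` distinct doses, the response is flat
        (range < ``flat_tolerance``), or no start converges.
    """
    if n_params not in (4, 5):
        raise ValueError(f"n_params must be 4 or 5, got {n_params}")
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have equal length")
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive (log scale)")
    if len(np.unique(doses)) < n_params:
        raise FitError(
            f"need >= {n_params} distinct doses for a {n_params}-parameter fit, "
            f"got {len(np.unique(doses))}"
        )
    if float(np.ptp(responses)) < flat_tolerance:
        raise FitError("no dose effect: response range below tolerance")
    x, y = np.log10(doses), responses
    rng = np.random.default_rng(seed)
    span = float(np.ptp(y))
    xr = float(np.ptp(x)) or 1.0
    lo = [y.min() - 2 * span, y.min() - 2 * span, x.min() - 2 * xr, -50.0]
    hi = [y.max() + 2 * span, y.max() + 2 * span, x.max() + 2 * xr, 50.0]
    if n_params == 5:
        lo.append(1e-2)
        hi.append(1e2)
    best_p, best_rss = None, np.inf
    for p0 in _starts(x, y, n_params, n_starts, rng):
        try:
            p, rss = _fit_once(x, y, n_params, np.clip(p0, lo, hi), (lo, hi))
        except Exception:
            continue
        if rss < best_rss:
            best_p, best_rss = p, rss
    if best_p is None:
        raise FitError("no optimizer start converged; check the input responses")
    p5 = np.concatenate([best_p, [1.0]]) if n_params == 4 else best_p
    bottom, top, x_mid, slope, asym = (float(v) for v in p5)
    ic50 = _ic50_from_params(bottom, top, x_mid, slope, asym)
    extrapolated = not (doses.min() <= ic50 <= doses.max())
    ci_95 = None
    if ci and n_boot > 0:
        boots = _bootstrap_ic50(x, y, n_params, best_p, (lo, hi), n_boot, rng,
                                method=boot_method)
        if len(boots) >= max(10, n_boot // 2):
            # expanded percentile interval: small-sample t-correction of the
            # 2.5/97.5 levels (reduces to the plain percentiles as n grows)
            from scipy import stats

            n = len(y)
            z = np.sqrt(n / max(n - 1, 1)) * stats.t.ppf(0.975, max(n - 1, 1))
            lo_lvl = 100.0 * stats.norm.cdf(-z)
            ci_95 = (float(np.percentile(boots, lo_lvl)),
                     float(np.percentile(boots, 100.0 - lo_lvl)))
        else:
            logger.warning("bootstrap unstable: only %d/%d refits usable", len(boots), n_boot)
    per_dose = (
        pd.DataFrame({"dose": doses, "response": responses})
        .groupby("dose")["response"].agg(mean="mean", sd="std", n="count").reset_index()
    )
    return DoseResponseFit(
        bottom=bottom, top=top, x_mid=x_mid, slope=slope, asymmetry=asym,
        n_params=n_params, ic50=float(ic50),
        ic50_absolute=_absolute_ic50(bottom, top, x_mid, slope, asym),
        ic50_ci_95=ci_95, rss=best_rss, extrapolated=extrapolated, per_dose=per_dose,
    )


def _bootstrap_ic50(x, y, n_params, p_hat, bounds, n_boot, rng,
                    method: str = "residual") -> np.ndarray:
    """Bootstrap distribution of the IC50, refitting from the point estimate.

    ``"residual"`` (default) resamples pooled fitted residuals scaled by
    sqrt(n/(n-p)) — the small-sample inflation that keeps nominal coverage
    when each dose has only a few replicate wells.  ``"case"`` resamples
    replicate wells within each dose.
    """
    out = []
    p5 = np.concatenate([p_hat, [1.0]]) if n_params == 4 else p_hat
    yhat = logistic5(x, *p5)
    resid = (y - yhat) * np.sqrt(len(y) / max(len(y) - n_params, 1))
    groups = [np.flatnonzero(x == u) for u in np.unique(x)]
    for _ in range(n_boot):
        if method == "residual":
            xb, yb = x, yhat + rng.choice(resid, size=len(y), replace=True)
        elif method == "case":
            idx = np.concatenate([rng.choice(g, size=len(g), replace=True) for g in groups])
            xb, yb = x[idx], y[idx]
        else:
            raise ValueError(f"unknown bootstrap method {method!r}")
        try:
            p, _ = _fit_once(xb, yb, n_params, p_hat, bounds)
        except Exception:
            continue
        p5b = np.concatenate([p, [1.0]]) if n_params == 4 else p
        v = _ic50_from_params(*p5b)
        if np.isfinite(v) and v > 0:
            out.append(v)
    return np.asarray(out)
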