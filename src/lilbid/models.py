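"""Errors-in-both-variables calibration models for binding affinities.

The LILBID readout (% ssDNA at 1.1 mm) carries a replicate s.d., and so do
the solution-state reference values (UV melting temperature, ITC K_d).  A
straight line between two such error-bearing quantities is therefore
fitted with the York method: iterative weighted least squares with weights
in both x and y (York, Earth & Planetary Science Letters 1966; unified
expressions York et al., Am. J. Phys. 2004), assuming uncorrelated errors
by default.  The fitted lines serve as transfer functions:

    predicted T_m     = slope * (% ssDNA at 1.1 mm) + intercept
    predicted log K_d = slope * (% ssDNA at 1.1 mm) + intercept

with K_d on the log10 molar scale.  UV melting temperatures themselves are
read off a melting curve as the temperature of the maximum of the first
derivative of absorbance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

LN10 = np.log(10.0)


@dataclass(frozen=True)
class AffinityDatum:
    """One sample's (x = % ssDNA at 1.1 mm, y = T_m or log10 K_d) pair
    with standard deviations on both axes."""

    sample: str
    x: float
    sx: float
    y: float
    sy: float


@dataclass(frozen=True)
class YorkFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n: int
    iterations: int
    chi2_reduced: float  # goodness: S / (n - 2)
    x_weighted_mean: float  # adjusted-x weighted centroid
    inv_sum_weights: float  # 1 / sum(W_i)

    def line(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class PredictionModel:
    kind: Literal["tm", "log_kd"]
    fit: YorkFit
    training_samples: tuple[str, ...]
    x_range: tuple[float, float]


def sd_from_sem(sem: float, n: int) -> float:
    """Replicate s.d. from a printed s.e.m.: s.d. = s.e.m. * sqrt(n)."""
    return float(sem) * float(np.sqrt(n))


def log10_kd_molar(kd_nm: float, sd_nm: float | None = None):
    """Convert K_d in nM to log10(K_d / M); optionally propagate its s.d.
    by the delta method, sd(log10 K_d) = sd(K_d) / (K_d * ln 10)."""
    y = float(np.log10(kd_nm * 1e-9))
    if sd_nm is None:
        return y
    return y, float(sd_nm / (kd_nm * LN10))


def york_fit(
    data: Sequence[AffinityDatum],
    r_xy: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 500,
    error_floor: float = 0.0,
) -> YorkFit:
    """Iterative York solution for a line with errors in both variables.

    Weights are the inverse error variances, 1/sx^2 and 1/sy^2; each
    point's combined weight depends on the current slope, so the slope is
    iterated from the OLS estimate until it changes by less than ``tol``.
    Standard errors come from the York (2004) variance expressions on the
    adjusted x values.  ``error_floor``, if positive, replaces any smaller
    error bar (use it when a replicate s.d. is exactly zero).
    """
    if len(data) < 3:
        raise ValueError("need at least 3 points for a York fit")
    x = np.array([d.x for d in data], dtype=float)
    y = np.array([d.y for d in data], dtype=float)
    sx = np.maximum(np.array([d.sx for d in data], dtype=float), error_floor)
    sy = np.maximum(np.array([d.sy for d in data], dtype=float), error_floor)
    if (sx <= 0).any() or (sy <= 0).any():
        raise ValueError(
            "zero or negative error bars; pass error_floor > 0 to impose a small floor"
        )
    wx, wy = 1.0 / sx**2, 1.0 / sy**2
    alpha = np.sqrt(wx * wy)
    b = float(np.polyfit(x, y, 1)[0])  # OLS initialisation
    history = [b]
    for iteration in range(1, max_iter + 1):
        w = wx * wy / (wx + b**2 * wy - 2.0 * b * r_xy * alpha)
        xbar = float((w * x).sum() / w.sum())
        ybar = float((w * y).sum() / w.sum())
        u, v = x - xbar, y - ybar
        beta = w * (u / wy + b * v / wx - (b * u + v) * r_xy / alpha)
        b_new = float((w * beta * v).sum() / (w * beta * u).sum())
        history.append(b_new)
        if abs(b_new - b) < tol:
            b = b_new
            break
        b = b_new
    else:
        raise RuntimeError(
            f"York iteration did not converge in {max_iter} steps; "
            f"last slopes: {history[-5:]}"
        )
    a = ybar - b * xbar
    x_adj = xbar + beta
    xbar_adj = float((w * x_adj).sum() / w.sum())
    u_adj = x_adj - xbar_adj
    slope_var = 1.0 / float((w * u_adj**2).sum())
    inv_sum_w = 1.0 / float(w.sum())
    intercept_var = inv_sum_w + xbar_adj**2 * slope_var
    s = float((w * (y - b * x - a) ** 2).sum())
    return YorkFit(
        slope=b,
        intercept=a,
        slope_se=float(np.sqrt(slope_var)),
        intercept_se=float(np.sqrt(intercept_var)),
        n=len(x),
        iterations=iteration,
        chi2_reduced=s / (len(x) - 2),
        x_weighted_mean=xbar_adj,
        inv_sum_weights=inv_sum_w,
    )


def confidence_band(
    fit: YorkFit, x_grid: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise confidence band for the fitted line.

    var(yhat(x)) = chi2_red * (1/sum W + (x - xbar)^2 * se_b^2), scaled by
    the Student-t quantile with n-2 degrees of freedom.  Scaling by the
    reduced goodness statistic makes the band collapse to zero width for
    residual-free data and gives near-nominal coverage when the stated
    errors are realistic.
    """
    if fit.n <= 2:
        raise ValueError("confidence band needs n > 2")
    x = np.asarray(x_grid, dtype=float)
    se = np.sqrt(
        fit.chi2_reduced
        * (fit.inv_sum_weights + (x - fit.x_weighted_mean) ** 2 * fit.slope_se**2)
    )
    tq = stats.t.ppf(0.5 + level / 2.0, df=fit.n - 2)
    center = fit.line(x)
    return center - tq * se, center + tq * se


def build_model(
    data: Sequence[AffinityDatum], kind: Literal["tm", "log_kd"], **york_kwargs
) -> PredictionModel:
    fit = york_fit(data, **york_kwargs)
    xs = [d.x for d in data]
    return PredictionModel(
        kind=kind,
        fit=fit,
        training_samples=tuple(d.sample for d in data),
        x_range=(min(xs), max(xs)),
    )


def predict(model: PredictionModel, pct_ss_at_ref: float) -> float:
    """Evaluate the calibration line (unrounded coefficients) at a % ssDNA
    value; extrapolation beyond the training range is flagged."""
    lo, hi = model.x_range
    if not lo <= pct_ss_at_ref <= hi:
        warnings.warn(
            f"% ssDNA {pct_ss_at_ref} outside the training range [{lo}, {hi}]; "
            "prediction is an extrapolation",
            stacklevel=2,
        )
    return float(model.fit.line(pct_ss_at_ref))


def cross_model(
    tm_data: Sequence[tuple[str, float, float]],
    kd_data: Sequence[tuple[str, float, float]],
    direction: Literal["kd_from_tm", "tm_from_kd"] = "kd_from_tm",
    **york_kwargs,
) -> PredictionModel:
    """York fit directly between the two solution-state affinity scales.

    ``tm_data`` and ``kd_data`` are (sample, value, sd) triples; only
    samples present in both are used.  The default direction predicts
    log10 K_d from T_m, mirroring the benchmark of predicting ITC results
    from UV melting curves.
    """
    tm = {s: (v, e) for s, v, e in tm_data}
    kd = {s: (v, e) for s, v, e in kd_data}
    common = sorted(set(tm) & set(kd))
    if len(common) < 3:
        raise ValueError("need at least 3 paired samples")
    data = []
    for s in common:
        (xv, xe), (yv, ye) = (
            (tm[s], kd[s]) if direction == "kd_from_tm" else (kd[s], tm[s])
        )
        data.append(AffinityDatum(sample=s, x=xv, sx=xe, y=yv, sy=ye))
    kind = "log_kd" if direction == "kd_from_tm" else "tm"
    return build_model(data, kind, **york_kwargs)


def melting_tm(
    temperature: np.ndarray,
    absorbance: np.ndarray,
    smooth_halfwidth: float = 0.0,
) -> float:
    """Melting temperature from a UV melting curve: the temperature of the
    maximum of the first derivative of absorbance.

    Optional boxcar smoothing (mean within +/- smooth_halfwidth °C)
    precedes a central-difference derivative; the three points around the
    discrete maximum are refined parabolically.  A derivative maximum on
    the boundary means no transition was captured.
    """
    t = np.asarray(temperature, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if t.ndim != 1 or t.shape != a.shape or len(t) < 5:
        raise ValueError("need >= 5 (temperature, absorbance) pairs")
    if not np.all(np.diff(t) > 0):
        raise ValueError("temperature must be strictly increasing")
    if smooth_halfwidth > 0:
        sm = np.empty_like(a)
        for i, ti in enumerate(t):
            sel = np.abs(t - ti) <= smooth_halfwidth
            sm[i] = a[sel].mean()
        a = sm
    deriv = np.gradient(a, t)
    i = int(np.argmax(deriv))
    if i == 0 or i == len(t) - 1:
        raise ValueError("no transition detected: derivative maximum at curve boundary")
    # Parabolic vertex through the three (t, deriv) points around the max.
    t3, d3 = t[i - 1 : i + 2], deriv[i - 1 : i + 2]
    coeff = np.polyfit(t3, d3, 2)
    if coeff[0] >= 0:
        return float(t[i])
    return float(-coeff[1] / (2.0 * coeff[0]))
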