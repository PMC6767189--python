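"""Regression analysis of thermodynamic series.

Provides ordinary least squares with a full ANOVA decomposition and 95%
confidence/prediction bands, the F-distribution upper tail (via the
regularized incomplete beta identity), the isobaric thermal expansion
coefficient from the slope of ln(rho) vs T, and glass-transition detection
as the breakpoint of a continuous two-segment linear fit of specific volume
vs temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from gelkit.structure_io import ThermoSeries


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of y on x with ANOVA about the mean.

    Identities (held to ~1e-12 relative): sse_total = sse_model + sse_error,
    df_total = df_model + df_error, f_value = mse_model / mse_error.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    df_model: int
    df_error: int
    df_total: int
    sse_model: float
    sse_error: float
    sse_total: float
    mse_model: float
    mse_error: float
    f_value: float
    p_value: float
    n: int
    x_mean: float
    sxx: float

    def predict(self, x0) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x0, dtype=float)

    def _band_half_width(self, x0, prediction: bool, level: float) -> np.ndarray:
        x0 = np.asarray(x0, dtype=float)
        t = stats.t.ppf(0.5 + level / 2.0, self.df_error)
        leverage = 1.0 / self.n + (x0 - self.x_mean) ** 2 / self.sxx
        if prediction:
            leverage = leverage + 1.0
        return t * np.sqrt(self.mse_error * leverage)

    def confidence_band(self, x0, level: float = 0.95):
        """Pointwise band for the mean response at x0: (lower, upper)."""
        hw = self._band_half_width(x0, prediction=False, level=level)
        yhat = self.predict(x0)
        return yhat - hw, yhat + hw

    def prediction_band(self, x0, level: float = 0.95):
        """Pointwise band for a new observation at x0: (lower, upper)."""
        hw = self._band_half_width(x0, prediction=True, level=level)
        yhat = self.predict(x0)
        return yhat - hw, yhat + hw

    def anova_table(self) -> dict:
        """ANOVA rows in the conventional DF/SSE/MSE/F/p layout."""
        return {
            "model": {
                "df": self.df_model,
                "sse": self.sse_model,
                "mse": self.mse_model,
                "f_value": self.f_value,
                "p_value": self.p_value,
            },
            "error": {
                "df": self.df_error,
                "sse": self.sse_error,
                "mse": self.mse_error,
            },
            "total": {"df": self.df_total, "sse": self.sse_total},
        }


@dataclass(frozen=True)
class TgFit:
    """Continuous two-segment fit of specific volume vs temperature."""

    breakpoint: float
    left_slope: float
    right_slope: float
    intercept_at_break: float
    sse: float
    sse_one_segment: float
    reliable: bool

    @property
    def improvement(self) -> float:
        """Fractional SSE reduction of the two-segment over one-segment fit."""
        if self.sse_one_segment == 0:
            return 0.0
        return 1.0 - self.sse / self.sse_one_segment


@dataclass(frozen=True)
class ExpansionResult:
    """Isobaric thermal expansion coefficient alpha_p = -(d ln rho / dT)_p."""

    alpha_p: float
    alpha_p_se: float
    fit: RegressionFit


def linear_fit_anova(x, y) -> RegressionFit:
    """OLS of y on x with full ANOVA decomposition and an F test of zero slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need at least 3 paired observations")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("x values are degenerate (all equal)")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    yhat = intercept + slope * x
    sse_error = float(np.sum((y - yhat) ** 2))
    sse_model = float(np.sum((yhat - y.mean()) ** 2))
    sse_total = sse_model + sse_error
    df_model, df_error = 1, n - 2
    mse_model = sse_model / df_model
    mse_error = sse_error / df_error
    if mse_error > 0:
        f_value = mse_model / mse_error
        p_value = f_sf(f_value, df_model, df_error)
    else:
        f_value = np.inf
        p_value = np.nextafter(0.0, 1.0)  # perfect fit: smallest positive double
    slope_se = float(np.sqrt(mse_error / sxx))
    intercept_se = float(np.sqrt(mse_error * (1.0 / n + x.mean() ** 2 / sxx)))
    return RegressionFit(
        slope=float(slope),
        intercept=intercept,
        slope_se=slope_se,
        intercept_se=intercept_se,
        df_model=df_model,
        df_error=df_error,
        df_total=n - 1,
        sse_model=sse_model,
        sse_error=sse_error,
        sse_total=sse_total,
        mse_model=mse_model,
        mse_error=mse_error,
        f_value=float(f_value),
        p_value=float(p_value),
        n=n,
        x_mean=float(x.mean()),
        sxx=sxx,
    )


def f_sf(f_value: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F distribution.

    Evaluated through the regularized incomplete beta identity
    P(F > f) = I_{df2/(df2 + df1 f)}(df2/2, df1/2).
    """
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if f_value < 0:
        raise ValueError("f_value must be non-negative")
    if f_value == 0:
        return 1.0
    x = df2 / (df2 + df1 * f_value)
    return float(special.betainc(df2 / 2.0, df1 / 2.0, x))


def total_sse(sse_model: float, sse_error: float) -> float:
    """ANOVA decomposition identity: SSE_total = SSE_model + SSE_error."""
    return sse_model + sse_error


def expansion_coefficient(series: ThermoSeries) -> ExpansionResult:
    """alpha_p from the slope of ln(rho) vs T of a thermo series."""
    T = series.column("temperature")
    rho = series.column("density")
    if np.any(rho <= 0):
        raise ValueError("densities must be positive to take the logarithm")
    fit = linear_fit_anova(T, np.log(rho))
    return ExpansionResult(alpha_p=-fit.slope, alpha_p_se=fit.slope_se, fit=fit)


def _two_segment_sse(temps, values, bp):
    """LSQ of a continuous two-segment line with knee at bp; returns (sse, params)."""
    left = np.minimum(temps - bp, 0.0)
    right = np.maximum(temps - bp, 0.0)
    design = np.column_stack([np.ones_like(temps), left, right])
    coef, _, _, _ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ coef
    return float(resid @ resid), coef


def glass_transition(
    temps,
    specific_volume,
    min_points_per_side: int = 3,
    improvement_threshold: float = 0.5,
    tol: float = 0.1,
) -> TgFit:
    """Breakpoint of a continuous two-segment fit (dilatometric Tg estimate).

    Candidate breakpoints are the midpoints between consecutive temperatures
    that leave at least ``min_points_per_side`` points on each side; the best
    candidate is refined by golden-section search to ``tol`` K. When the
    two-segment fit improves on a single line by less than
    ``improvement_threshold`` (fractional SSE reduction) the result is
    flagged unreliable (no detectable knee).
    """
    temps = np.asarray(temps, dtype=float)
    vals = np.asarray(specific_volume, dtype=float)
    n = len(temps)
    if n < 2 * min_points_per_side:
        raise ValueError(f"need at least {2 * min_points_per_side} points")
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperatures must be strictly increasing")

    lo = min_points_per_side - 1
    hi = n - min_points_per_side
    candidates = 0.5 * (temps[lo:hi] + temps[lo + 1 : hi + 1])
    if len(candidates) == 0:
        raise ValueError("fewer than 3 points per side at every candidate breakpoint")

    sses = [_two_segment_sse(temps, vals, bp)[0] for bp in candidates]
    best = int(np.argmin(sses))

    # golden-section refinement between the neighboring candidates
    bracket_lo = candidates[max(best - 1, 0)]
    bracket_hi = candidates[min(best + 1, len(candidates) - 1)]
    if bracket_hi > bracket_lo:
        res = optimize.minimize_scalar(
            lambda bp: _two_segment_sse(temps, vals, bp)[0],
            bounds=(bracket_lo, bracket_hi),
            method="bounded",
            options={"xatol": tol / 2.0},
        )
        bp = float(res.x)
    else:
        bp = float(candidates[best])

    sse, coef = _two_segment_sse(temps, vals, bp)
    one_seg = linear_fit_anova(temps, vals)
    improvement = 1.0 - sse / one_seg.sse_error if one_seg.sse_error > 0 else 0.0
    return TgFit(
        breakpoint=bp,
        left_slope=float(coef[1]),
        right_slope=float(coef[2]),
        intercept_at_break=float(coef[0]),
        sse=sse,
        sse_one_segment=one_seg.sse_error,
        reliable=improvement >= improvement_threshold,
    )
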