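"""Single power-law fitting: OLS on log10-transformed data with 95% CIs.

A power law y = c * x^beta is linear in log space, log10 y = log10 c +
beta * log10 x, so the scaling exponent is the OLS slope of the
log-transformed data and the normalization constant is 10**intercept.
Confidence intervals use the t distribution with n-2 degrees of freedom.
The binned variant guards against uneven sampling along the x axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from cogscale.errors import DegenerateDesignError, InsufficientDataError, ValidationError

MIN_FIT_N = 3


@dataclass(frozen=True)
class FitInput:
    """Log10-transformed (x, y) points for one (category, group) cell."""

    x: np.ndarray  # log10 total annotations
    y: np.ndarray  # log10 category count
    n_dropped_zero: int = 0
    label: tuple[str, str] = ("", "")  # (category, group)

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValidationError("x and y must be 1-D arrays of equal length")
        if len(self.x) < MIN_FIT_N:
            raise InsufficientDataError(
                f"{self.label}: {len(self.x)} usable points, need >= {MIN_FIT_N}"
            )
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValidationError("non-finite values in fit input")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit in log-log space.

    ``slope`` is the scaling exponent; ``intercept`` the log10 normalization
    constant.  ``slope_ci95`` / ``intercept_ci95`` are 95% CI half-widths
    (t-quantile at n-2 df times the standard error); the raw standard errors
    are kept alongside.
    """

    slope: float
    intercept: float
    slope_ci95: float
    intercept_ci95: float
    slope_se: float
    intercept_se: float
    n: int
    rss: float
    r: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def make_fit_input(
    matrix,
    category: str,
    *,
    selector=None,
    zero_policy: str = "drop",
    label_group: str = "all",
) -> FitInput:
    """Extract the log-log points for one category from a count matrix.

    x = log10(total annotations), y = log10(category count).  Organisms with
    a zero count are dropped and tallied under the default ``drop`` policy,
    or kept via log10(count + 1) under ``pseudocount``.  ``selector`` is an
    optional boolean mask or list of organism ids restricting the rows.
    """
    if category not in matrix.counts.columns:
        raise ValidationError(f"category {category!r} not in matrix")
    if zero_policy not in ("drop", "pseudocount"):
        raise ValidationError(f"unknown zero_policy {zero_policy!r}")
    counts = matrix.counts[category]
    total = matrix.total
    if selector is not None:
        counts = counts.loc[selector]
        total = total.loc[selector]
    c = counts.to_numpy(dtype=float)
    t = total.to_numpy(dtype=float)
    keep_t = t > 0
    c, t = c[keep_t], t[keep_t]
    if zero_policy == "drop":
        keep = c > 0
        n_dropped = int((~keep).sum())
        x = np.log10(t[keep])
        y = np.log10(c[keep])
    else:
        n_dropped = 0
        x = np.log10(t)
        y = np.log10(c + 1.0)
    if len(x) < MIN_FIT_N:
        raise InsufficientDataError(
            f"category {category!r}, group {label_group!r}: "
            f"{len(x)} usable points after zero handling, need >= {MIN_FIT_N}"
        )
    return FitInput(x=x, y=y, n_dropped_zero=n_dropped, label=(category, label_group))


def ols_fit(inp: FitInput) -> PowerLawFit:
    """Ordinary least squares on the log-transformed data.

    Returns slope (exponent), intercept (log10 normalization), 95% CI
    half-widths, residual sum of squares, and Pearson r.
    """
    x, y = inp.x, inp.y
    if np.ptp(x) == 0:
        raise DegenerateDesignError(f"{inp.label}: constant x, slope undefined")
    res = stats.linregress(x, y)
    n = inp.n
    resid = y - (res.intercept + res.slope * x)
    rss = float(resid @ resid)
    tq = stats.t.ppf(0.975, df=n - 2) if n > 2 else np.inf
    slope_se = float(res.stderr)
    intercept_se = float(res.intercept_stderr)
    return PowerLawFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci95=float(tq * slope_se),
        intercept_ci95=float(tq * intercept_se),
        slope_se=slope_se,
        intercept_se=intercept_se,
        n=n,
        rss=rss,
        r=float(res.rvalue),
    )


def bin_points(inp: FitInput, n_bins: int = 20, statistic: str = "mean") -> FitInput:
    """Average y within equal-width bins of the log10 x axis.

    Each non-empty bin yields one point (mean log10 x, mean log10 y); empty
    bins are dropped.  Using the within-bin mean of x keeps collinear data
    exactly collinear after binning.  Fitting the binned points
    counterweights ranges of x oversampled in the raw data.
    """
    if n_bins < 3:
        raise ValidationError("n_bins must be >= 3")
    if np.ptp(inp.x) == 0:
        raise DegenerateDesignError(f"{inp.label}: zero x span, cannot bin")
    ystat, edges, _ = stats.binned_statistic(inp.x, inp.y, statistic=statistic, bins=n_bins)
    xstat, _, _ = stats.binned_statistic(inp.x, inp.x, statistic="mean", bins=edges)
    keep = np.isfinite(ystat)
    if keep.sum() < MIN_FIT_N:
        raise InsufficientDataError(
            f"{inp.label}: only {int(keep.sum())} non-empty bins, need >= {MIN_FIT_N}"
        )
    return replace(inp, x=xstat[keep], y=ystat[keep])
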