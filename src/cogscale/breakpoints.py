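"""Continuous two-segment (breakpoint) fits in log-log space.

The segmented model is

    y = b0 + b1 * x + b2 * max(x - psi, 0)

so the two segments share the value at the breakpoint ``psi`` (slope1 = b1
below, slope2 = b1 + b2 above, intercept of the upper segment derived from
continuity).  ``segmented_fit`` estimates ``psi`` by Muggeo-style iterative
linearization from a grid of starting points; ``grid_oracle`` is an
exhaustive-search reference used to validate it.  ``select_model`` applies
the model-selection rule: adopt the breakpoint model when its residual sum
of squares is at least 5% below the single-line RSS (the RSS ratio
segmented/single is <= 0.95).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from cogscale.errors import InsufficientDataError, ValidationError
from cogscale.powerlaw import FitInput, PowerLawFit, ols_fit

logger = logging.getLogger(__name__)

_MUGGEO_TOL = 1e-10
_MUGGEO_MAXITER = 60


def default_min_segment(n: int) -> int:
    """Smallest number of points allowed on either side of the breakpoint."""
    return max(10, math.ceil(0.05 * n))


@dataclass(frozen=True)
class SegmentedFit:
    """A continuous two-segment least-squares fit.

    ``slope1``/``slope2`` and their CIs come from independent per-side OLS
    refits (the same procedure as the single-line fits) when each side has
    enough points; the slopes of the joint continuous model are kept in
    ``joint_slope1``/``joint_slope2``.  ``rss`` is the joint model's residual
    sum of squares.  ``break_ci95`` is derived from the linearization's
    standard error and is NaN when unavailable.
    """

    break_x: float
    slope1: float
    slope2: float
    intercept1: float
    joint_slope1: float
    joint_slope2: float
    rss: float
    n1: int
    n2: int
    slope1_ci95: float
    slope2_ci95: float
    break_ci95: float
    converged: bool
    seg1_refit: PowerLawFit | None = None
    seg2_refit: PowerLawFit | None = None

    @property
    def break_percentile(self) -> float:
        """Percent of points lying below the breakpoint."""
        return 100.0 * self.n1 / (self.n1 + self.n2)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (
            self.intercept1
            + self.joint_slope1 * x
            + (self.joint_slope2 - self.joint_slope1) * np.maximum(x - self.break_x, 0.0)
        )


@dataclass(frozen=True)
class ScalingModel:
    """Model-selection record for one (group, category) cell."""

    kind: str  # "single" | "segmented"
    single: PowerLawFit
    segmented: SegmentedFit | None
    rss_ratio: float
    threshold: float


def _fit_at_break(x: np.ndarray, y: np.ndarray, psi: float):
    """LS fit of the continuous two-segment model at a fixed breakpoint."""
    u = np.maximum(x - psi, 0.0)
    design = np.column_stack([np.ones_like(x), x, u])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(resid @ resid)


def _breakpoint_bounds(xs: np.ndarray, min_segment: int) -> tuple[float, float]:
    """Open interval of breakpoints leaving >= min_segment points per side."""
    return xs[min_segment - 1], xs[len(xs) - min_segment]


def _check_input(inp: FitInput, min_segment: int) -> np.ndarray:
    if min_segment < 2:
        raise ValidationError("min_segment must be >= 2")
    xs = np.sort(np.unique(inp.x))
    if inp.n < 2 * min_segment:
        raise InsufficientDataError(
            f"{inp.label}: n={inp.n} < 2*min_segment={2 * min_segment}"
        )
    if len(xs) < 2 * min_segment:
        raise InsufficientDataError(
            f"{inp.label}: only {len(xs)} distinct x values, need >= {2 * min_segment}"
        )
    return xs


def _finalize(
    inp: FitInput, psi: float, converged: bool, break_se: float
) -> SegmentedFit:
    x, y = inp.x, inp.y
    coef, rss = _fit_at_break(x, y, psi)
    b0, b1, b2 = coef
    below = x <= psi
    n1, n2 = int(below.sum()), int((~below).sum())

    def _refit(mask):
        if mask.sum() < 3 or np.ptp(x[mask]) == 0:
            return None
        return ols_fit(FitInput(x=x[mask], y=y[mask], label=inp.label))

    f1, f2 = _refit(below), _refit(~below)
    from scipy import stats as _st

    dof = max(inp.n - 4, 1)
    tq = _st.t.ppf(0.975, df=dof)
    return SegmentedFit(
        break_x=float(psi),
        slope1=float(f1.slope) if f1 else float(b1),
        slope2=float(f2.slope) if f2 else float(b1 + b2),
        intercept1=float(b0),
        joint_slope1=float(b1),
        joint_slope2=float(b1 + b2),
        rss=rss,
        n1=n1,
        n2=n2,
        slope1_ci95=float(f1.slope_ci95) if f1 else float("nan"),
        slope2_ci95=float(f2.slope_ci95) if f2 else float("nan"),
        break_ci95=float(tq * break_se) if np.isfinite(break_se) else float("nan"),
        converged=converged,
        seg1_refit=f1,
        seg2_refit=f2,
    )


def _muggeo_from(x, y, psi, lo, hi):
    """Iterate the breakpoint linearization from one starting value.

    Returns (psi, rss, break_se, converged); (nan, inf, nan, False) when the
    iteration degenerates.
    """
    ones = np.ones_like(x)
    psi = float(np.clip(psi, lo, hi))
    break_se = float("nan")
    _, rss_cur = _fit_at_break(x, y, psi)
    for _ in range(_MUGGEO_MAXITER):
        above = x > psi
        u = (x - psi) * above
        v = -above.astype(float)
        design = np.column_stack([ones, x, u, v])
        coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < 4:
            return float("nan"), float("inf"), break_se, False
        b2, gamma = coef[2], coef[3]
        if abs(b2) < 1e-12:
            return float("nan"), float("inf"), break_se, False
        step = gamma / b2
        # step-halving: accept the first damped update that does not worsen rss
        new_psi = float(np.clip(psi + step, lo, hi))
        for _half in range(8):
            _, rss_new = _fit_at_break(x, y, new_psi)
            if rss_new <= rss_cur + 1e-12:
                break
            step *= 0.5
            new_psi = float(np.clip(psi + step, lo, hi))
        rss_cur = rss_new
        if abs(new_psi - psi) < _MUGGEO_TOL or abs(gamma) < _MUGGEO_TOL:
            psi = new_psi
            # se(psi) ~= se(gamma)/|b2| from the linearized model
            resid = y - design @ coef
            dof = max(len(x) - 4, 1)
            sigma2 = float(resid @ resid) / dof
            try:
                cov = sigma2 * np.linalg.inv(design.T @ design)
                break_se = math.sqrt(max(cov[3, 3], 0.0)) / abs(b2)
            except np.linalg.LinAlgError:
                pass
            _, rss = _fit_at_break(x, y, psi)
            return psi, rss, break_se, True
        psi = new_psi
    _, rss = _fit_at_break(x, y, psi)
    return psi, rss, break_se, False


def segmented_fit(inp: FitInput, min_segment: int | None = None) -> SegmentedFit:
    """Best continuous two-segment fit by multi-start iterative linearization.

    Starts the Muggeo update from a grid of quantiles of x; if no start
    converges, falls back to the best non-converged iterate / coarse grid
    optimum with a logged warning.  Both segments are constrained to hold at
    least ``min_segment`` points (default ``max(10, 5% of n)``).
    """
    if min_segment is None:
        min_segment = default_min_segment(inp.n)
    xs = _check_input(inp, min_segment)
    lo, hi = _breakpoint_bounds(xs, min_segment)
    if hi <= lo:
        raise InsufficientDataError(f"{inp.label}: no admissible breakpoint interval")
    x, y = inp.x, inp.y
    # coarse scan of the rss profile picks the starting basins; the Muggeo
    # update then refines the breakpoint within each
    n_scan = min(max(len(xs) - 1, 10), 120)
    grid = np.unique(np.clip(np.quantile(x, np.linspace(0.0, 1.0, n_scan)), lo, hi))
    grid_rss = np.array([_fit_at_break(x, y, p)[1] for p in grid])
    order = np.argsort(grid_rss)
    starts = grid[order[:10]]
    best = (float(grid[order[0]]), float(grid_rss[order[0]]), float("nan"), False)
    for s in starts:
        psi, rss, se, conv = _muggeo_from(x, y, s, lo, hi)
        if conv and rss < best[1]:
            best = (psi, rss, se, True)
    if not best[3]:
        logger.warning(
            "segmented_fit %s: no start converged; keeping best grid-scan point",
            inp.label,
        )
    psi, _, se, converged = best
    return _finalize(inp, psi, converged=converged, break_se=se)


def grid_oracle(inp: FitInput, min_segment: int | None = None) -> SegmentedFit:
    """Exhaustive breakpoint search over per-gap candidate positions.

    Reference implementation: for every gap between consecutive distinct x
    values it evaluates the continuous two-segment LS fit at the gap
    midpoint, plus at the intersection of the two sides' unconstrained lines
    when that intersection falls inside the gap (for fixed segment
    membership the continuous model's optimum is exactly that intersection,
    which lets the oracle interpolate saturated inputs to rss 0).  Returns
    the rss-minimal candidate, smallest break_x on ties.
    """
    if min_segment is None:
        min_segment = default_min_segment(inp.n)
    xs = _check_input(inp, min_segment)
    lo, hi = _breakpoint_bounds(xs, min_segment)
    x, y = inp.x, inp.y
    candidates = []
    for k in range(len(xs) - 1):
        gap_lo, gap_hi = xs[k], xs[k + 1]
        mid = 0.5 * (gap_lo + gap_hi)
        if lo <= mid <= hi:
            candidates.append(mid)
        below = x <= gap_lo
        if below.sum() < 2 or (~below).sum() < 2:
            continue
        c1 = np.polyfit(x[below], y[below], 1)
        c2 = np.polyfit(x[~below], y[~below], 1)
        if c1[0] == c2[0]:
            continue
        cross = (c2[1] - c1[1]) / (c1[0] - c2[0])
        tol = 1e-9 * max(1.0, gap_hi - gap_lo)
        if gap_lo - tol <= cross <= gap_hi + tol:
            cross = float(np.clip(cross, max(gap_lo, lo), min(gap_hi, hi)))
            if lo <= cross <= hi:
                candidates.append(cross)
    candidates = np.sort(np.asarray(candidates))
    if candidates.size == 0:
        raise InsufficientDataError(f"{inp.label}: no admissible breakpoint candidates")
    best_psi, best_rss = None, float("inf")
    for psi in candidates:  # ascending: ties keep the smallest break_x
        _, rss = _fit_at_break(inp.x, inp.y, psi)
        if rss < best_rss * (1.0 - 1e-12):
            best_psi, best_rss = float(psi), rss
    return _finalize(inp, best_psi, converged=True, break_se=float("nan"))


def select_model(
    inp: FitInput,
    threshold: float = 0.05,
    min_segment: int | None = None,
) -> ScalingModel:
    """Choose between the single-line and breakpoint models by RSS reduction.

    rss_ratio = RSS(one breakpoint) / RSS(no breakpoint); the segmented model
    is selected when the ratio is <= 1 - threshold (default: a 5% decrease).
    A perfect single line (RSS 0) never selects a breakpoint, and a cell too
    small for a segmented fit stays single.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must be in (0, 1)")
    single = ols_fit(inp)
    # numerically perfect line: rss at float rounding scale needs no breakpoint
    if single.rss <= 1e-12 * inp.n:
        return ScalingModel("single", single, None, 1.0, threshold)
    try:
        seg = segmented_fit(inp, min_segment)
    except InsufficientDataError:
        return ScalingModel("single", single, None, 1.0, threshold)
    ratio = seg.rss / single.rss
    kind = "segmented" if ratio <= 1.0 - threshold else "single"
    return ScalingModel(kind, single, seg, float(ratio), threshold)
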