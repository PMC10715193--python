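"""Per-domain and per-phylum scaling fits, Z-statistics, and breakpoint spans.

The Z-statistic quantifies how far a phylum's scaling exponent deviates from
its domain's exponent relative to the slope error bars:

    as_printed:       z = (beta_p - beta_d) / sqrt(err_p^2 - err_d^2)
    sum_of_squares:   z = (beta_p - beta_d) / sqrt(err_p^2 + err_d^2)

The printed difference form is undefined when the phylum error does not
exceed the domain error (negative radicand); such cells are reported as NA
with a reason.  Errors are the 95% CI half-widths of the slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cogscale.breakpoints import ScalingModel
from cogscale.errors import DegenerateDesignError, InsufficientDataError, ValidationError
from cogscale.powerlaw import PowerLawFit, make_fit_input, ols_fit

Z_MODES = ("as_printed", "sum_of_squares")


@dataclass(frozen=True)
class ZScoreRecord:
    category: str
    group: str
    group_slope: float
    group_err: float
    domain_slope: float
    domain_err: float
    z: float  # NaN when undefined
    denominator_mode: str
    na_reason: str = ""


@dataclass(frozen=True)
class BreakpointSpanRow:
    group: str
    category: str
    group_min_x: float
    group_max_x: float
    break_x: float
    spans_break: bool


def fit_groups(
    matrix,
    level: str = "phylum",
    *,
    categories=None,
    zero_policy: str = "drop",
) -> pd.DataFrame:
    """One OLS fit per (group, category); unfittable cells become NA rows.

    Returns a long-form table with columns group, category, n,
    n_dropped_zero, slope, slope_ci95, slope_se, intercept, intercept_ci95,
    rss, r, na_reason.  A cell is NA when the group has fewer than the
    minimum number of usable points or a degenerate design.
    """
    labels = matrix.groups(level)
    cats = list(categories) if categories is not None else matrix.categories
    rows = []
    for group in sorted(labels.dropna().unique()):
        members = labels.index[labels == group]
        for cat in cats:
            row = {"group": group, "category": cat}
            try:
                inp = make_fit_input(
                    matrix, cat, selector=members,
                    zero_policy=zero_policy, label_group=group,
                )
                fit = ols_fit(inp)
            except (InsufficientDataError, DegenerateDesignError) as err:
                row.update(
                    n=np.nan, n_dropped_zero=np.nan, slope=np.nan,
                    slope_ci95=np.nan, slope_se=np.nan, intercept=np.nan,
                    intercept_ci95=np.nan, rss=np.nan, r=np.nan,
                    na_reason=type(err).__name__,
                )
            else:
                row.update(
                    n=fit.n, n_dropped_zero=inp.n_dropped_zero, slope=fit.slope,
                    slope_ci95=fit.slope_ci95, slope_se=fit.slope_se,
                    intercept=fit.intercept, intercept_ci95=fit.intercept_ci95,
                    rss=fit.rss, r=fit.r, na_reason="",
                )
            rows.append(row)
    return pd.DataFrame(rows)


def z_statistic(
    group: PowerLawFit, domain: PowerLawFit, mode: str = "as_printed"
) -> float:
    """Deviation of a group exponent from its domain exponent in error units.

    Returns NaN where the chosen denominator is undefined (non-positive
    radicand under ``as_printed``, or both errors zero).
    """
    if mode not in Z_MODES:
        raise ValidationError(f"mode must be one of {Z_MODES}, got {mode!r}")
    diff = group.slope - domain.slope
    ge, de = group.slope_ci95, domain.slope_ci95
    if ge == 0.0 and de == 0.0:
        return float("nan")
    if mode == "as_printed":
        radicand = ge**2 - de**2
        if radicand <= 0.0:
            return 0.0 if diff == 0.0 else float("nan")
        return diff / math.sqrt(radicand)
    return diff / math.sqrt(ge**2 + de**2)


def _z_from_row(row_g, row_d, mode: str) -> tuple[float, str]:
    if not np.isfinite(row_g["slope"]) or not np.isfinite(row_d["slope"]):
        return float("nan"), "missing fit"
    diff = row_g["slope"] - row_d["slope"]
    ge, de = row_g["slope_ci95"], row_d["slope_ci95"]
    if ge == 0.0 and de == 0.0:
        return float("nan"), "degenerate (both errors zero)"
    if mode == "as_printed":
        radicand = ge**2 - de**2
        if radicand <= 0.0:
            if diff == 0.0:
                return 0.0, ""
            return float("nan"), "negative radicand"
        return diff / math.sqrt(radicand), ""
    return diff / math.sqrt(ge**2 + de**2), ""


def z_table(
    group_fits: pd.DataFrame,
    domain_fits: pd.DataFrame,
    mode: str = "as_printed",
    *,
    group_to_domain: dict | None = None,
) -> pd.DataFrame:
    """Z-score records for every (group, category), ordered by z-range.

    ``domain_fits`` may hold one domain or several; ``group_to_domain`` maps
    each group to its parent domain (single-domain tables need no map).
    Categories are ordered by the spread (max z - min z) of their defined
    z values, descending; NA cells are listed with a reason, never dropped.
    """
    if mode not in Z_MODES:
        raise ValidationError(f"mode must be one of {Z_MODES}, got {mode!r}")
    domains = list(domain_fits["group"].unique())
    if group_to_domain is None:
        if len(domains) != 1:
            raise ValidationError("group_to_domain required with multiple domains")
        group_to_domain = {g: domains[0] for g in group_fits["group"].unique()}
    dom_idx = domain_fits.set_index(["group", "category"])

    rows = []
    for _, row_g in group_fits.iterrows():
        dom = group_to_domain[row_g["group"]]
        key = (dom, row_g["category"])
        if key not in dom_idx.index:
            z, reason = float("nan"), "no domain fit"
            row_d = None
        else:
            row_d = dom_idx.loc[key]
            z, reason = _z_from_row(row_g, row_d, mode)
        rows.append(
            ZScoreRecord(
                category=row_g["category"],
                group=row_g["group"],
                group_slope=float(row_g["slope"]),
                group_err=float(row_g["slope_ci95"]),
                domain_slope=float(row_d["slope"]) if row_d is not None else float("nan"),
                domain_err=float(row_d["slope_ci95"]) if row_d is not None else float("nan"),
                z=float(z),
                denominator_mode=mode,
                na_reason=reason,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    zrange = (
        df.groupby("category")["z"]
        .agg(lambda s: s.max() - s.min() if s.notna().any() else float("-inf"))
        .sort_values(ascending=False)
    )
    order = {cat: i for i, cat in enumerate(zrange.index)}
    df["z_range"] = df["category"].map(zrange.replace(float("-inf"), np.nan))
    return (
        df.sort_values(["category", "group"], kind="stable")
        .sort_values("category", key=lambda s: s.map(order), kind="stable")
        .reset_index(drop=True)
    )


def breakpoint_spans(
    matrix,
    domain_models: dict,
    level: str = "phylum",
) -> pd.DataFrame:
    """Which phyla straddle the domain-level breakpoints.

    ``domain_models`` maps category -> ScalingModel for the parent domain.
    Emits one row per (group, segmented category) with the group's log10
    total-annotation span and whether it contains the breakpoint, ordered
    from the most-spanning group to the least.
    """
    segmented = {
        cat: m for cat, m in domain_models.items()
        if isinstance(m, ScalingModel) and m.kind == "segmented"
    }
    if not segmented:
        return pd.DataFrame(
            columns=["group", "category", "group_min_x", "group_max_x",
                     "break_x", "spans_break"]
        )
    labels = matrix.groups(level)
    log_total = np.log10(matrix.total.to_numpy(dtype=float))
    rows = []
    for group in sorted(labels.dropna().unique()):
        mask = (labels == group).to_numpy()
        gmin, gmax = float(log_total[mask].min()), float(log_total[mask].max())
        for cat, model in segmented.items():
            bx = model.segmented.break_x
            rows.append(
                BreakpointSpanRow(
                    group=group, category=cat, group_min_x=gmin,
                    group_max_x=gmax, break_x=bx,
                    spans_break=bool(gmin < bx < gmax),
                )
            )
    df = pd.DataFrame([r.__dict__ for r in rows])
    n_spanned = df.groupby("group")["spans_break"].sum().sort_values(ascending=False)
    order = {g: i for i, g in enumerate(n_spanned.index)}
    return (
        df.sort_values(["group", "category"], kind="stable")
        .sort_values("group", key=lambda s: s.map(order), kind="stable")
        .reset_index(drop=True)
    )
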