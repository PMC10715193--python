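import math

import numpy as np
import pandas as pd
import pytest

from cogscale import (
    PowerLawFit,
    ScalingLaw,
    SimulationSpec,
    breakpoint_spans,
    fit_groups,
    simulate_matrix,
    z_statistic,
    z_table,
)
from cogscale.breakpoints import select_model
from cogscale.errors import ValidationError
from cogscale.pipeline import model_selection_table
from cogscale.powerlaw import make_fit_input
from cogscale.simulate import BreakpointLaw, PhylumSpec


def _fit(slope, err):
    return PowerLawFit(
        slope=slope, intercept=0.0, slope_ci95=err, intercept_ci95=0.0,
        slope_se=err / 2, intercept_se=0.0, n=10, rss=1.0, r=0.9,
    )


class TestZStatistic:
    def test_zero_when_slopes_equal(self):
        g, d = _fit(1.2, 0.1), _fit(1.2, 0.05)
        assert z_statistic(g, d, "as_printed") == 0.0
        assert z_statistic(g, d, "sum_of_squares") == 0.0

    def test_hand_computed_values(self):
        g, d = _fit(1.5, 0.1), _fit(1.2, 0.05)
        assert z_statistic(g, d, "as_printed") == pytest.approx(
            0.3 / math.sqrt(0.0075), rel=1e-12
        )
        assert z_statistic(g, d, "sum_of_squares") == pytest.approx(
            0.3 / math.sqrt(0.0125), rel=1e-12
        )

    def test_negative_radicand_is_na(self):
        g, d = _fit(1.5, 0.02), _fit(1.2, 0.05)
        assert math.isnan(z_statistic(g, d, "as_printed"))
        assert not math.isnan(z_statistic(g, d, "sum_of_squares"))

    def test_antisymmetry(self):
        g, d = _fit(1.5, 0.1), _fit(1.2, 0.05)
        g2 = _fit(0.9, 0.1)  # slope difference negated
        for mode in ("as_printed", "sum_of_squares"):
            assert z_statistic(g2, d, mode) == pytest.approx(
                -z_statistic(g, d, mode)
            )

    def test_degenerate_errors(self):
        g, d = _fit(1.5, 0.0), _fit(1.2, 0.0)
        assert math.isnan(z_statistic(g, d, "sum_of_squares"))
        with pytest.raises(ValidationError):
            z_statistic(g, d, "bogus")


class TestFitGroups:
    def test_phyla_recover_their_own_exponents(self, phyla_matrix):
        matrix, truth = phyla_matrix
        fits = fit_groups(matrix, "phylum")
        for phylum in ("Alpha", "Beta"):
            row = fits[(fits.group == phylum) & (fits.category == "T")].iloc[0]
            beta = truth["laws"][phylum]["T"].exponent
            assert abs(row.slope - beta) < 3 * row.slope_ci95

    def test_small_group_is_na_with_reason(self, phyla_matrix):
        matrix, _ = phyla_matrix
        sub = matrix.subset(matrix.organisms[:2] + matrix.organisms[-50:])
        fits = fit_groups(sub, "phylum")
        small_phylum = sub.groups("phylum").value_counts().idxmin()
        rows = fits[fits.group == small_phylum]
        if (sub.groups("phylum") == small_phylum).sum() < 3:
            assert (rows.na_reason != "").all()

    def test_domain_level_equals_whole_matrix(self, het_matrix):
        matrix, _ = het_matrix
        fits = fit_groups(matrix, "domain")
        assert set(fits.group) == {"Bacteria"}
        from cogscale.powerlaw import ols_fit

        whole = ols_fit(make_fit_input(matrix, "E"))
        row = fits[fits.category == "E"].iloc[0]
        assert row.slope == pytest.approx(whole.slope)


class TestZTable:
    def test_identical_groups_give_zero_range(self):
        dom = pd.DataFrame(
            [{"group": "D", "category": "J", "slope": 1.0, "slope_ci95": 0.05}]
        )
        grp = pd.DataFrame(
            [
                {"group": p, "category": "J", "slope": 1.0, "slope_ci95": 0.1}
                for p in ("P1", "P2")
            ]
        )
        zt = z_table(grp, dom, mode="sum_of_squares")
        assert (zt.z == 0).all()
        assert (zt.z_range == 0).all()

    def test_deviant_phylum_takes_extreme_z(self, phyla_matrix):
        matrix, _ = phyla_matrix
        dom = fit_groups(matrix, "domain")
        phy = fit_groups(matrix, "phylum")
        zt = z_table(phy, dom, mode="sum_of_squares")
        t_rows = zt[zt.category == "T"].set_index("group")
        # offsets were -0.3 (Alpha) and +0.3 (Beta): opposite-signed, large z
        assert t_rows.loc["Alpha", "z"] < -1.5
        assert t_rows.loc["Beta", "z"] > 1.5
        # the injected-offset category spreads far wider than the neutral one
        ranges = zt.groupby("category")["z_range"].first()
        assert ranges["T"] > 3 * ranges["J"]

    def test_category_ordering_is_permutation(self, phyla_matrix):
        matrix, _ = phyla_matrix
        dom = fit_groups(matrix, "domain")
        phy = fit_groups(matrix, "phylum")
        zt = z_table(phy, dom)
        assert sorted(zt.category.unique()) == sorted(matrix.categories)


@pytest.fixture(scope="module")
def span_setup():
    law = BreakpointLaw(ScalingLaw(1.6, -3.0, 0.08), 0.8, 10**3.2)
    phyla = (
        PhylumSpec("Low", 0.4, {}),
        PhylumSpec("High", 0.4, {}),
        PhylumSpec("Wide", 0.2, {}),
    )
    spec = SimulationSpec(
        900, (100, 100000), {"T": law, "J": ScalingLaw(1.0, -1.0, 0.08)},
        phyla=phyla, filler_category="S", seed=31,
    )
    matrix, _ = simulate_matrix(spec)
    # carve phylum ranges: Low below the break, High above, Wide straddles
    lt = np.log10(matrix.total)
    phylum = pd.Series("Wide", index=matrix.counts.index)
    phylum[lt < 3.0] = "Low"
    phylum[lt > 3.4] = "High"
    matrix.taxon["phylum"] = phylum
    _, models = model_selection_table(matrix, level="domain")
    return matrix, models


class TestBreakpointSpans:
    def test_span_flags(self, span_setup):
        matrix, models = span_setup
        dom_models = {c: m for (g, c), m in models.items() if g == "Bacteria"}
        assert dom_models["T"].kind == "segmented"
        spans = breakpoint_spans(matrix, dom_models)
        t = spans[spans.category == "T"].set_index("group")
        assert not t.loc["Low", "spans_break"]
        assert not t.loc["High", "spans_break"]
        assert t.loc["Wide", "spans_break"]

    def test_no_segmented_models_gives_empty_table(self, het_matrix):
        matrix, _ = het_matrix
        spans = breakpoint_spans(matrix, {})
        assert spans.empty
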