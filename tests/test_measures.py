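"""The four inequality summary measures and their uncertainty intervals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import equiprev as eq
from equiprev import synthetic as syn
from equiprev.core import round_half_away
from equiprev.measures import MeasureError, bootstrap_measures

WEALTH = eq.DimensionSpec(
    "wealth", "ordered", ("poorest", "mid", "richest"), favourable=True
)
REGION = eq.DimensionSpec("region", "non_ordered", ("A", "B", "C"), favourable=True)


def sg(spec, label, estimate, se=0.0):
    return eq.SubgroupEstimate(
        dimension_name=spec.name, subgroup_label=label, estimate=estimate, se=se
    )


def make(spec, estimates, ses=None):
    ses = ses or [0.0] * len(estimates)
    return [sg(spec, lbl, e, s) for lbl, e, s in zip(spec.subgroups, estimates, ses)]


@pytest.fixture(scope="module")
def ghana(specs):
    from equiprev.pipeline import _fill_ses

    groups = eq.read_disaggregated_table(eq.table1_fixture_path(), specs)
    _fill_ses(groups)  # recover SEs from the published CIs
    by_name = {s.name: s for s in specs}
    return groups, by_name


class TestSelectExtremes:
    def test_region_2017_extremes_are_data_driven(self, ghana):
        groups, by_name = ghana
        ests = groups[("Ghana", 2017, "Sub-national region")]
        adv, dis = eq.select_extremes(ests, by_name["Sub-national region"])
        assert (adv.subgroup_label, adv.estimate) == ("Upper East", 75.5)
        assert (dis.subgroup_label, dis.estimate) == ("Greater Accra", 17.5)

    def test_ordered_rule_ignores_estimate_values(self):
        ests = make(WEALTH, [60.0, 40.0, 20.0])  # richest lowest
        adv, dis = eq.select_extremes(ests, WEALTH)
        assert adv.subgroup_label == "richest"
        assert dis.subgroup_label == "poorest"

    def test_missing_subgroup_is_named(self):
        ests = make(WEALTH, [60.0, 40.0, 20.0])[:2]
        with pytest.raises(MeasureError, match="richest"):
            eq.select_extremes(ests, WEALTH)

    def test_tie_broken_by_label_sort_with_warning(self):
        ests = make(REGION, [30.0, 70.0, 70.0])
        with pytest.warns(UserWarning, match="tie"):
            adv, _dis = eq.select_extremes(ests, REGION)
        assert adv.subgroup_label == "B"

    def test_adverse_indicator_mirrors_reference(self):
        adverse = eq.DimensionSpec("region", "non_ordered", ("A", "B"), favourable=False)
        ests = make(adverse, [30.0, 70.0])
        adv, dis = eq.select_extremes(ests, adverse)
        assert adv.estimate == 30.0  # lower is better for an adverse indicator
        assert dis.estimate == 70.0


class TestPublishedValues:
    """Worked examples straight from the packaged Ghana tables."""

    def test_region_difference_2011(self, ghana):
        groups, by_name = ghana
        d = eq.difference(
            groups[("Ghana", 2011, "Sub-national region")],
            by_name["Sub-national region"],
        )
        assert d.estimate == pytest.approx(50.5)
        assert (d.reference_subgroup, d.comparison_subgroup) == (
            "Eastern",
            "Greater Accra",
        )

    def test_economic_difference_2011_is_negative(self, ghana):
        groups, by_name = ghana
        d = eq.difference(
            groups[("Ghana", 2011, "Economic status")], by_name["Economic status"]
        )
        assert d.estimate == pytest.approx(-35.6)

    def test_region_ratio_2011(self, ghana):
        groups, by_name = ghana
        r = eq.ratio(
            groups[("Ghana", 2011, "Sub-national region")],
            by_name["Sub-national region"],
        )
        assert round_half_away(r.estimate, 1) == 5.3

    def test_education_ratio_2011(self, ghana):
        groups, by_name = ghana
        r = eq.ratio(groups[("Ghana", 2011, "Education")], by_name["Education"])
        assert round_half_away(r.estimate, 1) == 0.6

    def test_region_par_2017(self, ghana):
        groups, by_name = ghana
        par = eq.par_measure(
            groups[("Ghana", 2017, "Sub-national region")],
            eq.SettingAverage(mu=49.7),
            by_name["Sub-national region"],
        )
        assert par.estimate == pytest.approx(25.8)
        assert par.reference_subgroup == "Upper East"

    def test_economic_par_2011_truncates_to_zero(self, ghana):
        groups, by_name = ghana
        par = eq.par_measure(
            groups[("Ghana", 2011, "Economic status")],
            eq.SettingAverage(mu=32.6),
            by_name["Economic status"],
        )
        assert par.estimate == 0.0
        # the interval stays symmetric about the truncated estimate
        assert par.ui_low == pytest.approx(-par.ui_high)

    def test_region_paf_2017(self, ghana):
        groups, by_name = ghana
        par = eq.par_measure(
            groups[("Ghana", 2017, "Sub-national region")],
            eq.SettingAverage(mu=49.7),
            by_name["Sub-national region"],
        )
        paf = eq.paf_measure(par, eq.SettingAverage(mu=49.7))
        assert round_half_away(paf.estimate, 1) == 51.9


class TestEdgeCases:
    def test_all_equal_no_inequality(self):
        for spec in (WEALTH, REGION):
            ests = make(spec, [40.0, 40.0, 40.0])
            mu = eq.SettingAverage(mu=40.0)
            if spec.kind == "non_ordered":
                with pytest.warns(UserWarning):
                    assert eq.difference(ests, spec).estimate == 0.0
                    assert eq.ratio(ests, spec).estimate == 1.0
                    par = eq.par_measure(ests, mu, spec)
            else:
                assert eq.difference(ests, spec).estimate == 0.0
                assert eq.ratio(ests, spec).estimate == 1.0
                par = eq.par_measure(ests, mu, spec)
            assert par.estimate == 0.0
            assert eq.paf_measure(par, mu).estimate == 0.0

    def test_zero_denominator_ratio_errors(self):
        ests = make(WEALTH, [0.0, 40.0, 20.0])
        with pytest.raises(MeasureError, match="denominator"):
            eq.ratio(ests, WEALTH)

    def test_reference_equal_to_mu_gives_zero_par(self):
        ests = make(WEALTH, [20.0, 30.0, 45.0])
        par = eq.par_measure(ests, eq.SettingAverage(mu=45.0), WEALTH)
        assert par.estimate == 0.0

    def test_par_equal_to_mu_gives_paf_100(self):
        ests = make(REGION, [10.0, 20.0, 60.0])
        mu = eq.SettingAverage(mu=30.0)
        par = eq.par_measure(ests, mu, REGION)
        assert par.estimate == pytest.approx(30.0)
        assert eq.paf_measure(par, mu).estimate == pytest.approx(100.0)

    def test_paf_errors_on_zero_mu(self):
        ests = make(REGION, [10.0, 20.0, 60.0])
        par = eq.par_measure(ests, eq.SettingAverage(mu=30.0), REGION)
        with pytest.raises(MeasureError, match="positive"):
            eq.paf_measure(par, eq.SettingAverage(mu=0.0))


class TestMeasureUI:
    def test_difference_three_four_five(self):
        lo, hi = eq.measure_ui("D", 10.0, [(30.0, 3.0), (20.0, 4.0)])
        half = hi - 10.0
        assert half == pytest.approx(1.959963984540054 * 5.0)
        assert round_half_away(half, 1) == 9.8
        assert 10.0 - lo == pytest.approx(half)

    def test_zero_ses_give_zero_width(self):
        assert eq.measure_ui("D", 5.0, [(30.0, 0.0), (25.0, 0.0)]) == (5.0, 5.0)
        assert eq.measure_ui("R", 1.2, [(30.0, 0.0), (25.0, 0.0)]) == (1.2, 1.2)

    def test_missing_ses_instruct_bootstrap(self):
        with pytest.raises(MeasureError, match="bootstrap"):
            eq.measure_ui("D", 5.0, [(30.0, None), (25.0, 4.0)])

    def test_ratio_interval_is_log_symmetric(self):
        lo, hi = eq.measure_ui("R", 2.0, [(40.0, 4.0), (20.0, 3.0)])
        assert lo * hi == pytest.approx(4.0)  # geometric symmetry about R

    def test_paf_interval_scales_par_interval(self):
        par_lo, par_hi = eq.measure_ui("PAR", 10.0, [(50.0, 3.0), (40.0, 1.0)])
        paf_lo, paf_hi = eq.measure_ui(
            "PAF", 25.0, [(10.0, math.hypot(3.0, 1.0)), (40.0, None)]
        )
        assert paf_lo == pytest.approx(par_lo * 100.0 / 40.0)
        assert paf_hi == pytest.approx(par_hi * 100.0 / 40.0)

    def test_delta_close_to_cluster_bootstrap(self, two_stratum_frame, design):
        df = syn.draw_sample_frame(
            two_stratum_frame, ea_take=15, households_per_ea=40, seed=21
        )
        res = eq.DimensionSpec("Place of residence", "binary", ("Rural", "Urban"))
        ests = eq.weighted_prevalence(df, design, res)
        d = eq.difference(ests, res)
        r = eq.ratio(ests, res)
        boot = bootstrap_measures(df, design, res, reps=1000, seed=13)
        for summary, (blo, bhi) in ((d, boot["D"]), (r, boot["R"])):
            half = (summary.ui_high - summary.ui_low) / 2
            assert summary.ui_low == pytest.approx(blo, abs=0.15 * half)
            assert summary.ui_high == pytest.approx(bhi, abs=0.15 * half)


class TestComputeAll:
    def test_sixteen_rows_for_2017_fixture(self, ghana, specs):
        groups, _ = ghana
        table = {dim: e for (s, y, dim), e in groups.items() if y == 2017}
        summaries, failures = eq.compute_all(
            table, eq.SettingAverage(mu=49.7), specs
        )
        assert failures == []
        assert len(summaries) == 16
        by_key = {(s.dimension, s.measure): s for s in summaries}
        assert round_half_away(
            by_key[("Sub-national region", "D")].estimate, 1
        ) == 58.0
        assert round_half_away(
            by_key[("Sub-national region", "PAF")].estimate, 1
        ) == 51.9

    def test_measure_order_is_deterministic(self, ghana, specs):
        groups, _ = ghana
        table = {dim: e for (s, y, dim), e in groups.items() if y == 2011}
        summaries, _ = eq.compute_all(table, eq.SettingAverage(mu=32.6), specs)
        assert [s.measure for s in summaries[:4]] == ["D", "R", "PAR", "PAF"]
        assert [s.dimension for s in summaries[::4]] == [s.name for s in specs]

    def test_failed_dimension_is_isolated(self, ghana, specs):
        groups, _ = ghana
        table = {dim: list(e) for (s, y, dim), e in groups.items() if y == 2017}
        table["Education"] = table["Education"][:-1]  # drop a subgroup
        summaries, failures = eq.compute_all(table, eq.SettingAverage(mu=49.7), specs)
        assert len(summaries) == 12
        assert len(failures) == 1
        assert failures[0].dimension == "Education"
        assert "Secondary/higher education" in failures[0].message


# ---------------------------------------------------------------------------
# Invariants
# ---------------------------------------------------------------------------

estimates_strategy = st.lists(
    st.floats(min_value=0.5, max_value=99.5), min_size=2, max_size=6
)
mu_strategy = st.floats(min_value=1.0, max_value=99.0)


def _spec_for(kind, n):
    labels = tuple(f"g{i}" for i in range(n))
    if kind == "binary":
        labels = labels[:2]
    return eq.DimensionSpec("dim", kind, labels)


@settings(derandomize=True, max_examples=80, deadline=None)
@given(values=estimates_strategy, mu=mu_strategy, kind=st.sampled_from(["ordered", "non_ordered"]))
def test_paf_is_par_over_mu_identity(values, mu, kind):
    spec = _spec_for(kind, len(values))
    ests = make(spec, values[: len(spec.subgroups)])
    mu_avg = eq.SettingAverage(mu=mu)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        par = eq.par_measure(ests, mu_avg, spec)
        paf = eq.paf_measure(par, mu_avg)
    assert paf.estimate == pytest.approx(100.0 * par.estimate / mu, abs=1e-12)
    # truncation semantics: zero PAR exactly when the reference does not
    # exceed the overall average
    ref = max(values[: len(spec.subgroups)]) if kind == "non_ordered" else values[
        len(spec.subgroups) - 1
    ]
    assert (par.estimate == 0.0) == (ref <= mu)
    assert par.estimate >= 0.0


@settings(derandomize=True, max_examples=80, deadline=None)
@given(values=estimates_strategy)
def test_non_ordered_measures_bounds(values):
    spec = _spec_for("non_ordered", len(values))
    ests = make(spec, values[: len(spec.subgroups)])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = eq.difference(ests, spec)
        r = eq.ratio(ests, spec)
    assert d.estimate >= 0.0
    assert r.estimate >= 1.0


@settings(derandomize=True, max_examples=80, deadline=None)
@given(
    values=st.lists(st.floats(min_value=0.5, max_value=99.5), min_size=2, max_size=2)
)
def test_ordered_difference_and_log_ratio_share_sign(values):
    spec = _spec_for("ordered", 2)
    ests = make(spec, values)
    d = eq.difference(ests, spec)
    r = eq.ratio(ests, spec)
    assert math.copysign(1.0, d.estimate) == math.copysign(
        1.0, math.log(r.estimate)
    ) or d.estimate == 0.0


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    values=st.lists(st.floats(min_value=1.0, max_value=90.0), min_size=3, max_size=3),
    mu=st.floats(min_value=5.0, max_value=90.0),
    k=st.floats(min_value=0.1, max_value=1.1),
)
def test_scale_equivariance(values, mu, k):
    """Scaling all prevalences by k scales D and PAR by k and leaves R and
    PAF unchanged."""
    if max(max(values), mu) * k > 100.0:
        k = 100.0 / max(max(values), mu)
    spec = _spec_for("ordered", 3)
    base = make(spec, values)
    scaled = make(spec, [v * k for v in values])
    mu1, mu2 = eq.SettingAverage(mu=mu), eq.SettingAverage(mu=mu * k)
    assert eq.difference(scaled, spec).estimate == pytest.approx(
        k * eq.difference(base, spec).estimate, abs=1e-9
    )
    assert eq.ratio(scaled, spec).estimate == pytest.approx(
        eq.ratio(base, spec).estimate, rel=1e-9
    )
    par1 = eq.par_measure(base, mu1, spec)
    par2 = eq.par_measure(scaled, mu2, spec)
    assert par2.estimate == pytest.approx(k * par1.estimate, abs=1e-9)
    assert eq.paf_measure(par2, mu2).estimate == pytest.approx(
        eq.paf_measure(par1, mu1).estimate, abs=1e-9
    )
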