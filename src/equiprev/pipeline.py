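"""End-to-end analysis pipelines.

``reproduce`` recomputes every published summary-measure point estimate for
the packaged Ghana ITN-in-pregnancy tables (MICS 2011 and 2017) from the
packaged disaggregated estimates plus the published overall prevalences
(32.6% and 49.7%), compares at one-decimal rounding, and reports per-cell
agreement.  Two cells are known not to match at the printed precision
because the published values were computed from unrounded survey internals
while this package necessarily starts from the rounded published subgroup
estimates; those cells are annotated rather than failed.

``estimate_table``/``summarize_records`` run the record-level path: survey
records -> design-based subgroup estimates -> inequality measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    DimensionSpec,
    GroupKey,
    InequalitySummary,
    SettingAverage,
    SubgroupEstimate,
    SurveyRecord,
    ValidationError,
    mics_dimensions,
    packaged_data_path,
    read_disaggregated_table,
    read_summary_table,
    round_half_away,
    table1_fixture_path,
    table2_fixture_path,
)
from .estimation import DesignSpec, overall_average, se_from_logit_ci, weighted_prevalence
from .measures import DEFAULT_CONFIG, MeasureConfig, MeasureFailure, compute_all

__all__ = [
    "ReportRow",
    "ReproductionReport",
    "reproduce",
    "published_overall_averages",
    "estimate_table",
    "summarize_records",
    "measures_for_groups",
]

#: Cells whose published value is known to differ at one-decimal precision
#: from what the published subgroup estimates imply, because the source
#: analysis used unrounded internals: the 2011 regional PAF (published 91.3;
#: 100*29.7/32.6 = 91.1 from the published PAR and average) and the 2017
#: residence D (published -26.1; 35.5 - 61.5 = -26.0).
KNOWN_ROUNDING_NOTES: dict[tuple[int, str, str], str] = {
    (2011, "Sub-national region", "PAF"): (
        "published 91.3 was derived from unrounded internals; the published "
        "subgroup estimates and overall average imply 100*29.7/32.6 = 91.1"
    ),
    (2017, "Place of residence", "D"): (
        "published -26.1 was derived from unrounded internals; the published "
        "subgroup estimates imply 35.5 - 61.5 = -26.0"
    ),
}


def published_overall_averages(
    path: str | Path | None = None,
) -> dict[tuple[str, int], SettingAverage]:
    """The published overall prevalences μ per setting and year (their SEs
    are not published, so se_mu is left None)."""
    path = Path(path) if path is not None else packaged_data_path("ghana_itn_overall.csv")
    df = pd.read_csv(path)
    return {
        (str(r.setting), int(r.year)): SettingAverage(mu=float(r.mu))
        for r in df.itertuples(index=False)
    }


@dataclass
class ReportRow:
    setting: str
    year: int
    dimension: str
    measure: str
    computed: float  # rounded to report precision
    printed: float
    match: bool
    expected_mismatch: bool
    note: str


@dataclass
class ReproductionReport:
    rows: list[ReportRow]
    summaries: list[InequalitySummary]
    failures: list[MeasureFailure]

    @property
    def n_cells(self) -> int:
        return len(self.rows)

    @property
    def n_match(self) -> int:
        return sum(r.match for r in self.rows)

    @property
    def all_accounted_for(self) -> bool:
        """Every cell either matches or is a known annotated exception."""
        return all(r.match or r.expected_mismatch for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "setting": r.setting,
                    "year": r.year,
                    "dimension": r.dimension,
                    "measure": r.measure,
                    "computed": r.computed,
                    "printed": r.printed,
                    "match": r.match,
                    "expected_mismatch": r.expected_mismatch,
                    "note": r.note,
                }
                for r in self.rows
            ]
        )


def _fill_ses(groups: Mapping[GroupKey, list[SubgroupEstimate]]) -> None:
    """Back-derive percent-scale SEs from published logit-method CIs for
    estimates that carry bounds but no SE."""
    for estimates in groups.values():
        for e in estimates:
            if e.se is None and e.ci_low is not None and e.ci_high is not None:
                e.se = se_from_logit_ci(e.estimate, e.ci_low, e.ci_high)


def measures_for_groups(
    groups: Mapping[GroupKey, list[SubgroupEstimate]],
    mu_by: Mapping[tuple[str, int], SettingAverage],
    specs: Sequence[DimensionSpec],
    cfg: MeasureConfig = DEFAULT_CONFIG,
) -> tuple[list[InequalitySummary], list[MeasureFailure]]:
    """All measures for every (setting, year) in a grouped estimate table."""
    keys = sorted({(setting, year) for (setting, year, _dim) in groups})
    summaries: list[InequalitySummary] = []
    failures: list[MeasureFailure] = []
    for setting, year in keys:
        if (setting, year) not in mu_by:
            raise ValidationError(
                f"no overall average μ provided for setting {setting!r}, year {year}"
            )
        table = {
            dim: ests
            for (s, y, dim), ests in groups.items()
            if s == setting and y == year
        }
        res, fails = compute_all(table, mu_by[(setting, year)], specs, cfg)
        for summary in res:
            summary.setting = setting
            summary.year = year
        summaries.extend(res)
        failures.extend(fails)
    return summaries, failures


def reproduce(
    table1_path: str | Path | None = None,
    table2_path: str | Path | None = None,
    cfg: MeasureConfig = DEFAULT_CONFIG,
) -> ReproductionReport:
    """Recompute the published summary table from the published
    disaggregated table and overall averages; compare point estimates at
    one-decimal, round-half-away-from-zero precision."""
    specs = mics_dimensions()
    t1 = Path(table1_path) if table1_path is not None else table1_fixture_path()
    t2 = Path(table2_path) if table2_path is not None else table2_fixture_path()
    if not t1.exists() or not t2.exists():
        raise ValidationError(f"reproduction fixture missing: {t1} / {t2}")
    groups = read_disaggregated_table(t1, specs)
    _fill_ses(groups)
    published = read_summary_table(t2)
    mu_by = published_overall_averages()
    summaries, failures = measures_for_groups(groups, mu_by, specs, cfg)

    computed_by = {
        (s.setting, s.year, s.dimension, s.measure): s.estimate for s in summaries
    }
    rows: list[ReportRow] = []
    seen = set()
    for pub in published:
        key = (pub.setting, pub.year, pub.dimension, pub.measure)
        if key in seen:
            raise ValidationError(f"published table lists cell {key} twice")
        seen.add(key)
        if key not in computed_by:
            raise ValidationError(f"no computed value for published cell {key}")
        value = round_half_away(computed_by[key], cfg.report_decimals)
        match = abs(value - pub.estimate) < 10.0 ** (-cfg.report_decimals) / 2.0
        note_key = (pub.year, pub.dimension, pub.measure)
        expected = (not match) and note_key in KNOWN_ROUNDING_NOTES
        if match:
            note = ""
        elif expected:
            note = KNOWN_ROUNDING_NOTES[note_key]
        else:
            note = f"computed {value} differs from published {pub.estimate}"
        rows.append(
            ReportRow(
                setting=pub.setting,
                year=pub.year,
                dimension=pub.dimension,
                measure=pub.measure,
                computed=value,
                printed=pub.estimate,
                match=match,
                expected_mismatch=expected,
                note=note,
            )
        )
    return ReproductionReport(rows=rows, summaries=summaries, failures=failures)


# ---------------------------------------------------------------------------
# Record-level path
# ---------------------------------------------------------------------------


def estimate_table(
    records: Sequence[SurveyRecord] | pd.DataFrame,
    design: DesignSpec,
    specs: Sequence[DimensionSpec],
    setting: str = "synthetic",
    year: int = 0,
) -> tuple[dict[GroupKey, list[SubgroupEstimate]], SettingAverage]:
    """Design-based subgroup estimates for every dimension, plus the
    overall average, shaped like a read disaggregated table."""
    groups: dict[GroupKey, list[SubgroupEstimate]] = {}
    for spec in specs:
        groups[(setting, year, spec.name)] = weighted_prevalence(records, design, spec)
    return groups, overall_average(records, design)


def summarize_records(
    records: Sequence[SurveyRecord] | pd.DataFrame,
    design: DesignSpec,
    specs: Sequence[DimensionSpec],
    cfg: MeasureConfig = DEFAULT_CONFIG,
    setting: str = "synthetic",
    year: int = 0,
) -> tuple[list[InequalitySummary], list[MeasureFailure]]:
    """records -> subgroup estimation -> all four inequality measures."""
    groups, mu = estimate_table(records, design, specs, setting, year)
    return measures_for_groups(groups, {(setting, year): mu}, specs, cfg)
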