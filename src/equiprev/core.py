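"""Shared data model and tabular I/O for survey-based inequality analysis.

The package works on two plain-CSV interchange formats:

* a *disaggregated estimate table* — one row per setting/year/dimension/
  subgroup carrying a prevalence estimate in percent with optional SE,
  95% CI, unweighted sample size and weighted population share (the shape
  in which disaggregated health-indicator data are published);
* an *individual record table* — one row per respondent with sampling
  design columns (stratum, cluster, weight), a binary outcome, and one
  column per equity stratifier.

Estimates are carried on the 0–100 percent scale throughout; conversion
to proportions happens only inside variance formulas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd


class EquiprevError(Exception):
    """Base class for package errors."""


class ValidationError(EquiprevError, ValueError):
    """A value violates a documented invariant."""


class ParseError(ValidationError):
    """A cell could not be parsed; the message names the offending row."""


DimensionKind = Literal["ordered", "binary", "non_ordered"]
MeasureName = Literal["D", "R", "PAR", "PAF"]

#: Order in which the four summary measures are reported.
MEASURE_ORDER: tuple[MeasureName, ...] = ("D", "R", "PAR", "PAF")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties going away from zero (the convention used when
    reporting estimates to one decimal, where banker's rounding would
    disagree with published tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DimensionSpec:
    """An equity stratifier: how a population is partitioned into subgroups.

    For ``ordered`` and ``binary`` dimensions ``subgroups`` is listed from
    most-disadvantaged to most-advantaged, so the advantaged extreme is the
    last label.  ``favourable`` is True when higher indicator values are
    desirable (e.g. net use), False for adverse indicators (e.g. mortality).
    """

    name: str
    kind: DimensionKind
    subgroups: tuple[str, ...]
    favourable: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "subgroups", tuple(self.subgroups))
        if self.kind not in ("ordered", "binary", "non_ordered"):
            raise ValidationError(f"unknown dimension kind {self.kind!r}")
        if len(self.subgroups) < 2:
            raise ValidationError(
                f"dimension {self.name!r} needs >=2 subgroups, got {len(self.subgroups)}"
            )
        if self.kind == "binary" and len(self.subgroups) != 2:
            raise ValidationError(f"binary dimension {self.name!r} must have 2 subgroups")
        if len(set(self.subgroups)) != len(self.subgroups):
            raise ValidationError(f"dimension {self.name!r} has duplicate subgroup labels")

    @property
    def advantaged_label(self) -> str:
        """Most-advantaged subgroup for ordered/binary dimensions."""
        if self.kind == "non_ordered":
            raise ValidationError(
                f"dimension {self.name!r} is non-ordered; extremes are data-driven"
            )
        return self.subgroups[-1]

    @property
    def disadvantaged_label(self) -> str:
        if self.kind == "non_ordered":
            raise ValidationError(
                f"dimension {self.name!r} is non-ordered; extremes are data-driven"
            )
        return self.subgroups[0]


@dataclass
class SubgroupEstimate:
    """One subgroup's prevalence estimate (percent scale) with uncertainty."""

    dimension_name: str
    subgroup_label: str
    estimate: float  # percent, 0–100
    se: float | None = None  # percentage points
    ci_low: float | None = None
    ci_high: float | None = None
    n: int = 0  # unweighted respondent count
    pop_share: float | None = None  # weighted share in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.estimate <= 100.0:
            raise ValidationError(
                f"estimate {self.estimate} for {self.dimension_name}/"
                f"{self.subgroup_label} outside [0, 100]"
            )
        if self.se is not None and self.se < 0:
            raise ValidationError(f"negative se for {self.subgroup_label}")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.estimate <= self.ci_high:
                raise ValidationError(
                    f"CI [{self.ci_low}, {self.ci_high}] does not bracket estimate "
                    f"{self.estimate} for {self.dimension_name}/{self.subgroup_label}"
                )
        if self.n < 0:
            raise ValidationError(f"negative n for {self.subgroup_label}")
        if self.pop_share is not None and not 0.0 <= self.pop_share <= 1.0:
            raise ValidationError(f"pop_share {self.pop_share} outside [0, 1]")


@dataclass
class SettingAverage:
    """Overall weighted prevalence μ of the setting (percent scale)."""

    mu: float
    se_mu: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 100.0:
            raise ValidationError(f"mu {self.mu} outside [0, 100]")
        if self.se_mu is not None and self.se_mu < 0:
            raise ValidationError("negative se_mu")


@dataclass
class InequalitySummary:
    """One summary measure's point estimate with a 95% uncertainty interval.

    Units: percentage points for D and PAR, dimensionless for R, percent
    of μ for PAF.  ``reference_subgroup`` holds the y_ref label (the
    advantaged / best-performing subgroup), ``comparison_subgroup`` the
    subgroup it is contrasted with (the disadvantaged extreme for D and R,
    the whole-population average for PAR/PAF).
    """

    measure: MeasureName
    estimate: float
    ui_low: float
    ui_high: float
    reference_subgroup: str
    comparison_subgroup: str
    dimension: str = ""
    setting: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.ui_low <= self.estimate <= self.ui_high:
            raise ValidationError(
                f"UI [{self.ui_low}, {self.ui_high}] does not bracket estimate "
                f"{self.estimate} for measure {self.measure}"
            )


@dataclass
class SurveyRecord:
    """One respondent: design variables, binary outcome, stratifier values.

    ``values`` maps dimension name to subgroup label; a missing stratifier
    is stored as ``None`` (the record still counts toward the overall
    average but is excluded from that dimension's disaggregation).
    """

    stratum_id: str
    cluster_id: str
    weight: float
    outcome: int
    values: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValidationError(f"weight {self.weight} must be positive")
        if self.outcome not in (0, 1):
            raise ValidationError(f"outcome {self.outcome!r} not in {{0, 1}}")


# ---------------------------------------------------------------------------
# Dimension schemas
# ---------------------------------------------------------------------------

def mics_dimensions() -> list[DimensionSpec]:
    """The four MICS equity stratifiers used throughout this package:
    wealth quintile (ordered), education (ordered), residence (binary),
    sub-national region (non-ordered).  Labels match the packaged
    disaggregated-table fixture."""
    return [
        DimensionSpec(
            "Economic status",
            "ordered",
            (
                "Quintile 1 (poorest)",
                "Quintile 2",
                "Quintile 3",
                "Quintile 4",
                "Quintile 5 (richest)",
            ),
        ),
        DimensionSpec(
            "Education",
            "ordered",
            ("No formal education", "Primary school", "Secondary/higher education"),
        ),
        DimensionSpec("Place of residence", "binary", ("Rural", "Urban")),
        DimensionSpec(
            "Sub-national region",
            "non_ordered",
            (
                "Ashanti",
                "Brong Ahafo",
                "Central",
                "Eastern",
                "Greater Accra",
                "Northern",
                "Upper East",
                "Upper West",
                "Volta",
                "Western",
            ),
        ),
    ]


def dimension_specs_from_yaml(path: str | Path) -> list[DimensionSpec]:
    """Load dimension declarations from a YAML file: a list of mappings
    with keys name, kind, subgroups, and optional favourable."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValidationError(f"{path}: expected a YAML list of dimension mappings")
    specs = []
    for entry in raw:
        try:
            specs.append(
                DimensionSpec(
                    name=entry["name"],
                    kind=entry["kind"],
                    subgroups=tuple(entry["subgroups"]),
                    favourable=bool(entry.get("favourable", True)),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"{path}: malformed dimension entry {entry!r}") from exc
    return specs


def dimension_specs_to_yaml(specs: Sequence[DimensionSpec], path: str | Path) -> None:
    import yaml

    payload = [
        {
            "name": s.name,
            "kind": s.kind,
            "subgroups": list(s.subgroups),
            "favourable": s.favourable,
        }
        for s in specs
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)


def packaged_data_path(name: str) -> Path:
    """Path of a CSV/YAML fixture shipped inside the package."""
    return Path(str(resources.files("equiprev").joinpath("data", name)))


def table1_fixture_path() -> Path:
    """Packaged disaggregated-estimate table: ITN use by pregnant women in
    Ghana, MICS 2011 and 2017, by wealth, education, residence and region."""
    return packaged_data_path("ghana_itn_disaggregated.csv")


def table2_fixture_path() -> Path:
    """Packaged published summary-measure table for the same surveys."""
    return packaged_data_path("ghana_itn_published_summaries.csv")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_DISAGG_REQUIRED = ("setting", "year", "dimension", "subgroup", "estimate")
_DISAGG_OPTIONAL = ("se", "ci_low", "ci_high", "n", "pop_share")

GroupKey = tuple[str, int, str]  # (setting, year, dimension name)


def _parse_float(cell, row_no: int, column: str, path) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"{path}: row {row_no}, column {column!r}: cannot parse {text!r} as a number"
        ) from None


def read_disaggregated_table(
    path: str | Path, schema: Sequence[DimensionSpec]
) -> dict[GroupKey, list[SubgroupEstimate]]:
    """Read a disaggregated estimate CSV, validated against ``schema``.

    Returns estimates grouped by (setting, year, dimension name), rows in
    file order within each group.  Rows whose dimension is not declared in
    the schema are dropped with a warning; an unknown subgroup label within
    a declared dimension raises :class:`ValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _DISAGG_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    by_name = {s.name: s for s in schema}

    groups: dict[GroupKey, list[SubgroupEstimate]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        dim = str(getattr(row, "dimension")).strip()
        spec = by_name.get(dim)
        if spec is None:
            warnings.warn(
                f"{path}: row {idx}: unknown dimension {dim!r} not in schema; row dropped",
                stacklevel=2,
            )
            continue
        subgroup = str(getattr(row, "subgroup")).strip()
        if subgroup not in spec.subgroups:
            raise ValidationError(
                f"{path}: row {idx}: unknown subgroup {subgroup!r} for dimension {dim!r}"
            )
        setting = str(getattr(row, "setting")).strip()
        year_raw = str(getattr(row, "year")).strip()
        try:
            year = int(year_raw)
        except ValueError:
            raise ParseError(
                f"{path}: row {idx}, column 'year': cannot parse {year_raw!r}"
            ) from None
        est = _parse_float(getattr(row, "estimate"), idx, "estimate", path)
        if est is None:
            raise ParseError(f"{path}: row {idx}: empty estimate cell")
        opt = {}
        for col in _DISAGG_OPTIONAL:
            opt[col] = (
                _parse_float(getattr(row, col), idx, col, path) if col in df.columns else None
            )
        n_val = opt["n"]
        try:
            sg = SubgroupEstimate(
                dimension_name=dim,
                subgroup_label=subgroup,
                estimate=est,
                se=opt["se"],
                ci_low=opt["ci_low"],
                ci_high=opt["ci_high"],
                n=int(n_val) if n_val is not None else 0,
                pop_share=opt["pop_share"],
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from None
        groups.setdefault((setting, year, dim), []).append(sg)

    for (setting, year, dim), ests in groups.items():
        shares = [e.pop_share for e in ests]
        if all(s is not None for s in shares):
            total = sum(shares)  # type: ignore[arg-type]
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"{path}: pop_share for {setting}/{year}/{dim} sums to {total}, not 1"
                )
    return groups


def write_disaggregated_table(
    groups: Mapping[GroupKey, Sequence[SubgroupEstimate]], path: str | Path
) -> None:
    """Write grouped subgroup estimates in the disaggregated CSV shape
    (inverse of :func:`read_disaggregated_table`, full float precision,
    missing optional fields as empty cells)."""
    if not groups:
        raise ValidationError("write_disaggregated_table: empty table")
    rows = []
    for (setting, year, dim), estimates in groups.items():
        for e in estimates:
            rows.append(
                {
                    "setting": setting,
                    "year": year,
                    "dimension": dim,
                    "subgroup": e.subgroup_label,
                    "estimate": e.estimate,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "n": e.n,
                    "pop_share": e.pop_share,
                }
            )
    cols = list(_DISAGG_REQUIRED[:4]) + ["estimate"] + list(_DISAGG_OPTIONAL)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


_SUMMARY_COLUMNS = (
    "setting",
    "year",
    "dimension",
    "measure",
    "estimate",
    "ui_low",
    "ui_high",
    "reference_subgroup",
    "comparison_subgroup",
)


def write_summary_table(results: Sequence[InequalitySummary], path: str | Path) -> None:
    """Write summary measures as CSV (one row per dimension × measure).

    Numeric cells are written at full float precision so that
    :func:`read_summary_table` round-trips exactly.
    """
    if not results:
        raise ValidationError("write_summary_table: empty result list")
    rows = [
        {
            "setting": r.setting,
            "year": r.year,
            "dimension": r.dimension,
            "measure": r.measure,
            "estimate": r.estimate,
            "ui_low": r.ui_low,
            "ui_high": r.ui_high,
            "reference_subgroup": r.reference_subgroup,
            "comparison_subgroup": r.comparison_subgroup,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=_SUMMARY_COLUMNS).to_csv(path, index=False)


def read_summary_table(path: str | Path) -> list[InequalitySummary]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _SUMMARY_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    # the subgroup-label columns are optional: published summary tables
    # usually omit them
    for col in _SUMMARY_COLUMNS[7:]:
        if col not in df.columns:
            df[col] = ""
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        measure = str(row.measure).strip()
        if measure not in MEASURE_ORDER:
            raise ValidationError(f"{path}: row {idx}: unknown measure {measure!r}")
        year_txt = str(row.year).strip()
        out.append(
            InequalitySummary(
                measure=measure,  # type: ignore[arg-type]
                estimate=_parse_float(row.estimate, idx, "estimate", path),
                ui_low=_parse_float(row.ui_low, idx, "ui_low", path),
                ui_high=_parse_float(row.ui_high, idx, "ui_high", path),
                reference_subgroup=str(row.reference_subgroup),
                comparison_subgroup=str(row.comparison_subgroup),
                dimension=str(row.dimension),
                setting=str(row.setting),
                year=int(year_txt) if year_txt else None,
            )
        )
    return out


_RECORD_REQUIRED = ("stratum", "cluster", "weight", "outcome")


def read_survey_records(
    path: str | Path, schema: Sequence[DimensionSpec]
) -> list[SurveyRecord]:
    """Read an individual-record CSV.

    Requires columns stratum, cluster, weight, outcome plus one column per
    declared dimension.  Empty stratifier cells are kept as missing
    (``None``) so records still contribute to the overall average.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _RECORD_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    missing_dims = [s.name for s in schema if s.name not in df.columns]
    if missing_dims:
        raise ValidationError(f"{path}: missing stratifier columns {missing_dims}")

    records: list[SurveyRecord] = []
    for idx, row_vals in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row_vals))
        weight = _parse_float(row["weight"], idx, "weight", path)
        if weight is None or weight <= 0:
            raise ValidationError(f"{path}: row {idx}: weight {row['weight']!r} not positive")
        outcome_txt = str(row["outcome"]).strip()
        if outcome_txt not in ("0", "1"):
            raise ValidationError(
                f"{path}: row {idx}: outcome {outcome_txt!r} not in {{0, 1}}"
            )
        values: dict[str, str | None] = {}
        for spec in schema:
            cell = str(row[spec.name]).strip()
            if cell == "":
                values[spec.name] = None
            elif cell not in spec.subgroups:
                raise ValidationError(
                    f"{path}: row {idx}: unknown subgroup {cell!r} for dimension "
                    f"{spec.name!r}"
                )
            else:
                values[spec.name] = cell
        records.append(
            SurveyRecord(
                stratum_id=str(row["stratum"]).strip(),
                cluster_id=str(row["cluster"]).strip(),
                weight=weight,
                outcome=int(outcome_txt),
                values=values,
            )
        )
    return records


def write_survey_records(
    records: Sequence[SurveyRecord], schema: Sequence[DimensionSpec], path: str | Path
) -> None:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "stratum": r.stratum_id,
            "cluster": r.cluster_id,
            "weight": r.weight,
            "outcome": r.outcome,
        }
        for spec in schema:
            val = r.values.get(spec.name)
            row[spec.name] = "" if val is None else val
        rows.append(row)
    cols = list(_RECORD_REQUIRED) + [s.name for s in schema]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
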