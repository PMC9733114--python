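"""Health-inequality summary measures over disaggregated prevalence estimates.

Four measures summarize how a binary indicator's prevalence varies across
the subgroups of an equity stratifier:

* **Difference (D)** — simple absolute measure, the gap between the two
  extreme subgroups (percentage points);
* **Ratio (R)** — simple relative measure, their quotient;
* **Population Attributable Risk (PAR)** — complex absolute measure, the
  gap between the reference subgroup y_ref and the overall average μ:
  the population-level gain attainable if everyone reached the reference
  level (percentage points);
* **Population Attributable Fraction (PAF)** — complex relative measure,
  PAR as a percentage of μ: ``PAF = 100 * PAR / μ``.

For ordered and binary dimensions the extremes are fixed by the subgroup
ordering (most-disadvantaged first, most-advantaged last) regardless of the
observed estimates, so D and R can fall below 0 and 1 respectively when the
disadvantaged subgroup outperforms the advantaged one.  For non-ordered
dimensions (e.g. region) the extremes are data-driven: D = max − min ≥ 0
and R = max/min ≥ 1.  For a favourable indicator, y_ref is the
most-advantaged subgroup (ordered/binary) or the best-performing one
(non-ordered); PAR is truncated at zero when the reference does not exceed
μ ("no inequality"), while its uncertainty bounds are reported unclipped.

Uncertainty intervals are delta-method normal intervals (on the log scale
for R), or percentile intervals from a stratified cluster bootstrap when
record-level data are available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import (
    DimensionSpec,
    EquiprevError,
    InequalitySummary,
    MEASURE_ORDER,
    SettingAverage,
    SubgroupEstimate,
)
from .estimation import DesignSpec, as_record_frame, bootstrap_statistics

__all__ = [
    "MeasureConfig",
    "MeasureError",
    "select_extremes",
    "difference",
    "ratio",
    "par_measure",
    "paf_measure",
    "measure_ui",
    "bootstrap_measures",
    "compute_all",
]


class MeasureError(EquiprevError):
    """A summary measure could not be computed from the given inputs."""


@dataclass(frozen=True)
class MeasureConfig:
    ui_level: float = 0.95
    ui_method: Literal["delta", "bootstrap"] = "delta"
    truncate_par_at_zero: bool = True
    report_decimals: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.ui_level < 1.0:
            raise MeasureError(f"ui_level {self.ui_level} outside (0, 1)")

    @property
    def z(self) -> float:
        return float(norm.ppf(0.5 + self.ui_level / 2.0))


DEFAULT_CONFIG = MeasureConfig()


def _by_label(
    estimates: Sequence[SubgroupEstimate], spec: DimensionSpec
) -> dict[str, SubgroupEstimate]:
    mapping = {e.subgroup_label: e for e in estimates if e.dimension_name == spec.name}
    missing = [lbl for lbl in spec.subgroups if lbl not in mapping]
    if missing:
        raise MeasureError(
            f"dimension {spec.name!r} is missing estimates for subgroups {missing}"
        )
    return mapping


def _data_driven_extremes(
    mapping: Mapping[str, SubgroupEstimate]
) -> tuple[SubgroupEstimate, SubgroupEstimate]:
    """(highest, lowest) estimate; ties broken by label sort with a warning."""
    items = sorted(mapping.values(), key=lambda e: e.subgroup_label)
    hi = max(items, key=lambda e: e.estimate)
    lo = min(items, key=lambda e: e.estimate)
    n_hi = sum(1 for e in items if e.estimate == hi.estimate)
    n_lo = sum(1 for e in items if e.estimate == lo.estimate)
    if n_hi > 1 or n_lo > 1:
        warnings.warn(
            f"tie for the extreme estimate in {hi.dimension_name!r}; "
            "picked first by label sort",
            stacklevel=3,
        )
    return hi, lo


def select_extremes(
    estimates: Sequence[SubgroupEstimate], spec: DimensionSpec
) -> tuple[SubgroupEstimate, SubgroupEstimate]:
    """Return (advantaged, disadvantaged) subgroup estimates.

    Ordered/binary dimensions use the spec's designated extreme labels
    regardless of the observed values.  Non-ordered dimensions are
    data-driven: the best-performing subgroup is "advantaged" (highest
    estimate for a favourable indicator, lowest for an adverse one).
    """
    mapping = _by_label(estimates, spec)
    if spec.kind in ("ordered", "binary"):
        return mapping[spec.advantaged_label], mapping[spec.disadvantaged_label]
    hi, lo = _data_driven_extremes(mapping)
    return (hi, lo) if spec.favourable else (lo, hi)


# ---------------------------------------------------------------------------
# Delta-method uncertainty intervals
# ---------------------------------------------------------------------------

Component = tuple[float, float | None]  # (value, se)


def _require_ses(components: Sequence[Component], measure: str) -> list[float]:
    ses = []
    for value, se in components:
        if se is None:
            raise MeasureError(
                f"missing standard errors for measure {measure}: delta-method UIs "
                "need component SEs; use the bootstrap UI on record-level data "
                "instead"
            )
        ses.append(se)
    return ses


def measure_ui(
    measure: str,
    estimate: float,
    components: Sequence[Component],
    cfg: MeasureConfig = DEFAULT_CONFIG,
) -> tuple[float, float]:
    """Delta-method uncertainty interval for one measure.

    ``components`` are the (value, se) pairs the measure was computed from:
    the two extreme subgroup estimates for D and R, ``(y_ref, se_ref)`` and
    ``(μ, se_μ)`` for PAR, and ``((PAR, se_PAR), (μ, None))`` for PAF,
    whose interval is the PAR interval rescaled by 100/μ.  D and PAR use
    a normal interval with the root-sum-square SE (the covariance between
    y_ref and μ is ignored — a documented approximation; the bootstrap is
    the covariance-honest alternative).  R uses a normal interval on log R,
    back-transformed.
    """
    z = cfg.z
    if measure in ("D", "PAR"):
        (v1, _), (v2, _) = components
        se1, se2 = _require_ses(components, measure)
        se = math.hypot(se1, se2)
        return estimate - z * se, estimate + z * se
    if measure == "R":
        (y1, _), (y2, _) = components
        se1, se2 = _require_ses(components, measure)
        if y2 <= 0:
            raise MeasureError("ratio UI undefined: zero denominator")
        if y1 <= 0:
            if se1 == 0 and se2 == 0:
                return estimate, estimate
            raise MeasureError("ratio UI undefined for a zero numerator")
        if se1 == 0 and se2 == 0:
            return estimate, estimate
        se_log = math.hypot(se1 / y1, se2 / y2)
        return estimate * math.exp(-z * se_log), estimate * math.exp(z * se_log)
    if measure == "PAF":
        (par, se_par), (mu, _) = components
        if mu <= 0:
            raise MeasureError("PAF UI undefined: μ must be positive")
        (se_par,) = _require_ses([(par, se_par)], measure)
        lo, hi = estimate - cfg.z * se_par * 100.0 / mu, estimate + cfg.z * se_par * 100.0 / mu
        return lo, hi
    raise MeasureError(f"unknown measure {measure!r}")


# ---------------------------------------------------------------------------
# The four measures
# ---------------------------------------------------------------------------


def difference(
    estimates: Sequence[SubgroupEstimate],
    spec: DimensionSpec,
    cfg: MeasureConfig = DEFAULT_CONFIG,
) -> InequalitySummary:
    """D: advantaged − disadvantaged for ordered/binary dimensions (signed),
    max − min for non-ordered ones (non-negative)."""
    if spec.kind in ("ordered", "binary"):
        ref, comp = select_extremes(estimates, spec)
    else:
        ref, comp = _data_driven_extremes(_by_label(estimates, spec))
    d = ref.estimate - comp.estimate
    lo, hi = measure_ui("D", d, [(ref.estimate, ref.se), (comp.estimate, comp.se)], cfg)
    return InequalitySummary(
        measure="D",
        estimate=d,
        ui_low=lo,
        ui_high=hi,
        reference_subgroup=ref.subgroup_label,
        comparison_subgroup=comp.subgroup_label,
        dimension=spec.name,
    )


def ratio(
    estimates: Sequence[SubgroupEstimate],
    spec: DimensionSpec,
    cfg: MeasureConfig = DEFAULT_CONFIG,
) -> InequalitySummary:
    """R: advantaged / disadvantaged for ordered/binary dimensions,
    max / min for non-ordered ones."""
    if spec.kind in ("ordered", "binary"):
        ref, comp = select_extremes(estimates, spec)
    else:
        ref, comp = _data_driven_extremes(_by_label(estimates, spec))
    if comp.estimate <= 0:
        raise MeasureError(
            f"ratio undefined for {spec.name!r}: denominator subgroup "
            f"{comp.subgroup_label!r} has estimate 0"
        )
    r = ref.estimate / comp.estimate
    lo, hi = measure_ui("R", r, [(ref.estimate, ref.se), (comp.estimate, comp.se)], cfg)
    return InequalitySummary(
        measure="R",
        estimate=r,
        ui_low=lo,
        ui_high=hi,
        reference_subgroup=ref.subgroup_label,
        comparison_subgroup=comp.subgroup_label,
        dimension=spec.name,
    )


def reference_subgroup(
    estimates: Sequence[SubgroupEstimate], spec: DimensionSpec
) -> SubgroupEstimate:
    """y_ref: most-advantaged subgroup for ordered/binary dimensions,
    best-performing subgroup for non-ordered ones."""
    advantaged, _ = select_extremes(estimates, spec)
    return advantaged


def par_measure(
    estimates: Sequence[SubgroupEstimate],
    mu: SettingAverage,
    spec: DimensionSpec,
    cfg: MeasureConfig = DEFAULT_CONFIG,
) -> InequalitySummary:
    """PAR: y_ref − μ, truncated at zero when the reference subgroup does
    not outperform the overall average (zero means no inequality).  The
    uncertainty interval is a normal interval about the reported estimate
    with SE √(se_ref² + se_μ²); bounds are not clipped, so a truncated PAR
    of 0 carries a symmetric interval.  A missing se_μ is treated as 0."""
    if mu is None:
        raise MeasureError("PAR needs the overall average μ")
    ref = reference_subgroup(estimates, spec)
    raw = ref.estimate - mu.mu
    if cfg.truncate_par_at_zero:
        reported = max(0.0, raw) if spec.favourable else min(0.0, raw)
    else:
        reported = raw
    se_mu = mu.se_mu if mu.se_mu is not None else 0.0
    lo, hi = measure_ui("PAR", reported, [(ref.estimate, ref.se), (mu.mu, se_mu)], cfg)
    return InequalitySummary(
        measure="PAR",
        estimate=reported,
        ui_low=lo,
        ui_high=hi,
        reference_subgroup=ref.subgroup_label,
        comparison_subgroup="overall average",
        dimension=spec.name,
    )


def paf_measure(par: InequalitySummary, mu: SettingAverage) -> InequalitySummary:
    """PAF = 100 · PAR / μ, applied to the estimate and both UI bounds."""
    if par.measure != "PAR":
        raise MeasureError("paf_measure expects a PAR summary")
    if mu.mu <= 0:
        raise MeasureError("PAF undefined: μ must be positive")
    scale = 100.0 / mu.mu
    return InequalitySummary(
        measure="PAF",
        estimate=par.estimate * scale,
        ui_low=par.ui_low * scale,
        ui_high=par.ui_high * scale,
        reference_subgroup=par.reference_subgroup,
        comparison_subgroup=par.comparison_subgroup,
        dimension=par.dimension,
        setting=par.setting,
        year=par.year,
    )


# ---------------------------------------------------------------------------
# Bootstrap uncertainty intervals
# ---------------------------------------------------------------------------


def _point_measures(
    prevalences: Mapping[str, float], mu: float, spec: DimensionSpec, truncate: bool
) -> tuple[float, float, float, float]:
    """(D, R, raw-or-truncated PAR, PAF) from subgroup prevalences alone."""
    if spec.kind in ("ordered", "binary"):
        y_adv = prevalences[spec.advantaged_label]
        y_dis = prevalences[spec.disadvantaged_label]
        d = y_adv - y_dis
        r = y_adv / y_dis if y_dis > 0 else np.nan
        y_ref = y_adv
    else:
        hi = max(prevalences.values())
        lo = min(prevalences.values())
        d = hi - lo
        r = hi / lo if lo > 0 else np.nan
        y_ref = hi if spec.favourable else lo
    raw = y_ref - mu
    if truncate:
        par = max(0.0, raw) if spec.favourable else min(0.0, raw)
    else:
        par = raw
    paf = 100.0 * par / mu if mu > 0 else np.nan
    return d, r, par, paf


def bootstrap_measures(
    records: Sequence | pd.DataFrame,
    design: DesignSpec,
    spec: DimensionSpec,
    cfg: MeasureConfig = DEFAULT_CONFIG,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict[str, tuple[float, float]]:
    """Percentile uncertainty intervals for D, R, PAR, PAF from a stratified
    cluster bootstrap of the records.  Each replicate recomputes subgroup
    prevalences, μ and all four measures, so extreme-subgroup selection and
    the y_ref/μ covariance are propagated honestly.  PAR and PAF replicates
    are left untruncated (the interval lives on the raw scale, matching the
    delta construction)."""
    df = as_record_frame(records)
    y = df["outcome"].to_numpy(dtype=float)
    labels = df[spec.name].to_numpy()
    masks = {lbl: (labels == lbl).astype(float) for lbl in spec.subgroups}
    if any(m.sum() == 0 for m in masks.values()):
        raise MeasureError(f"dimension {spec.name!r} has an empty subgroup")

    def stat(_df: pd.DataFrame, w: np.ndarray) -> np.ndarray:
        prev = {}
        for lbl, m in masks.items():
            wm = w * m
            total = wm.sum()
            prev[lbl] = 100.0 * (wm * y).sum() / total if total > 0 else np.nan
        w_total = w.sum()
        mu = 100.0 * (w * y).sum() / w_total if w_total > 0 else np.nan
        return np.array(_point_measures(prev, mu, spec, truncate=False))

    stats = bootstrap_statistics(df, design, stat, reps, seed)
    alpha = 1.0 - cfg.ui_level
    out: dict[str, tuple[float, float]] = {}
    for i, measure in enumerate(MEASURE_ORDER):
        col = stats[:, i]
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise MeasureError(f"bootstrap produced no finite replicates for {measure}")
        lo, hi = np.quantile(col, [alpha / 2.0, 1.0 - alpha / 2.0])
        out[measure] = (float(lo), float(hi))
    return out


# ---------------------------------------------------------------------------
# Batch computation
# ---------------------------------------------------------------------------


@dataclass
class MeasureFailure:
    dimension: str
    message: str


def compute_all(
    table: Mapping[str, Sequence[SubgroupEstimate]],
    mu: SettingAverage,
    specs: Sequence[DimensionSpec],
    cfg: MeasureConfig = DEFAULT_CONFIG,
) -> tuple[list[InequalitySummary], list[MeasureFailure]]:
    """All four measures for every dimension, in spec order with measures
    ordered D, R, PAR, PAF.  A failure in any measure aborts that dimension
    (recorded in the failure list) without affecting the others."""
    summaries: list[InequalitySummary] = []
    failures: list[MeasureFailure] = []
    for spec in specs:
        estimates = table.get(spec.name)
        if estimates is None:
            failures.append(MeasureFailure(spec.name, "no estimates for dimension"))
            continue
        try:
            d = difference(estimates, spec, cfg)
            r = ratio(estimates, spec, cfg)
            par = par_measure(estimates, mu, spec, cfg)
            paf = paf_measure(par, mu)
        except (MeasureError, EquiprevError) as exc:
            failures.append(MeasureFailure(spec.name, str(exc)))
            continue
        summaries.extend([d, r, par, paf])
    return summaries, failures
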