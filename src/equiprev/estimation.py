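"""Design-based prevalence estimation for stratified multistage cluster samples.

Point estimates are ratio (Hájek) estimators, ``100 * sum(w*y) / sum(w)``.
Standard errors use the stratified between-PSU Taylor linearization under
the with-replacement approximation (no finite-population correction) — the
standard variance estimator for MICS/DHS-type designs, where the first-stage
sampling fraction is small.  Confidence intervals use a normal interval on
the logit scale, back-transformed, which keeps them inside (0, 100) and
reproduces the asymmetric intervals typical of published survey tables.
Normal (not t) critical values are used throughout: household surveys of
this type have large PSU counts, and the approximation is documented in the
methods note.

Subgroup estimates are *domain* estimates: every PSU in the design
contributes to the linearized variance, including PSUs with no respondents
in the domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .core import (
    DimensionSpec,
    SettingAverage,
    SubgroupEstimate,
    SurveyRecord,
    ValidationError,
)

__all__ = [
    "DesignSpec",
    "as_record_frame",
    "weighted_prevalence",
    "overall_average",
    "logit_ci",
    "se_from_logit_ci",
    "iter_bootstrap_weights",
    "bootstrap_prevalence_se",
]


@dataclass(frozen=True)
class DesignSpec:
    """Which record columns play the design roles, and how to treat strata
    that contain a single PSU (``certainty``: zero variance contribution,
    with a warning; ``error``: raise; ``collapse``: pool all single-PSU
    strata into one pseudo-stratum)."""

    stratum: str = "stratum"
    cluster: str = "cluster"
    weight: str = "weight"
    single_psu: Literal["error", "certainty", "collapse"] = "certainty"


def as_record_frame(records: Sequence[SurveyRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalize records to a DataFrame with columns stratum, cluster,
    weight, outcome plus one column per stratifier (missing values as NaN)."""
    if isinstance(records, pd.DataFrame):
        return records
    if not records:
        raise ValidationError("no records")
    rows = []
    for r in records:
        row: dict[str, object] = {
            "stratum": r.stratum_id,
            "cluster": r.cluster_id,
            "weight": r.weight,
            "outcome": r.outcome,
        }
        for dim, val in r.values.items():
            row[dim] = np.nan if val is None else val
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Taylor linearization
# ---------------------------------------------------------------------------


class _DesignArrays:
    """Integer-coded design columns, cluster nesting validated."""

    def __init__(self, df: pd.DataFrame, design: DesignSpec):
        for col in (design.stratum, design.cluster, design.weight, "outcome"):
            if col not in df.columns:
                raise ValidationError(f"records are missing column {col!r}")
        self.w = df[design.weight].to_numpy(dtype=float)
        if not (self.w > 0).all():
            raise ValidationError("all weights must be positive")
        self.y = df["outcome"].to_numpy(dtype=float)
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValidationError("outcome must be binary 0/1")
        strat = df[design.stratum].astype(str).to_numpy()
        clust = df[design.cluster].astype(str).to_numpy()
        # a cluster is identified within its stratum
        pairs = np.char.add(np.char.add(strat, "\x1f"), clust)
        self.cluster_codes, cluster_index = pd.factorize(pairs)
        self.n_clusters = len(cluster_index)
        # stratum of each cluster
        strat_codes, self.strata = pd.factorize(strat)
        first = np.zeros(self.n_clusters, dtype=int)
        first[self.cluster_codes[::-1]] = np.arange(len(df))[::-1]
        self.cluster_stratum = strat_codes[first]
        self.n_strata = len(self.strata)

    def stratum_cluster_counts(self) -> np.ndarray:
        return np.bincount(self.cluster_stratum, minlength=self.n_strata)


def _taylor_variance(
    arrays: _DesignArrays, domain: np.ndarray, design: DesignSpec
) -> tuple[float, float]:
    """Return (p_hat, variance of p_hat) on the proportion scale for the
    ratio estimator restricted to ``domain`` (boolean mask)."""
    w = arrays.w * domain
    w_total = w.sum()
    if w_total <= 0:
        raise ValidationError("empty domain")
    p = float((w * arrays.y).sum() / w_total)

    # linearized score, summed to PSU level
    u = w * (arrays.y - p) / w_total
    z = np.bincount(arrays.cluster_codes, weights=u, minlength=arrays.n_clusters)

    counts = arrays.stratum_cluster_counts()
    single = counts == 1
    if single.any():
        if design.single_psu == "error":
            bad = [str(arrays.strata[i]) for i in np.flatnonzero(single)]
            raise ValidationError(
                f"strata with a single PSU under policy='error': {bad}"
            )
        if design.single_psu == "certainty":
            warnings.warn(
                "single-PSU strata treated as certainty units (zero variance "
                "contribution)",
                stacklevel=3,
            )

    strat_of_cluster = arrays.cluster_stratum.copy()
    if design.single_psu == "collapse" and single.any():
        # pool every single-PSU stratum into one pseudo-stratum
        pooled = arrays.n_strata
        strat_of_cluster[single[strat_of_cluster]] = pooled
        counts = np.bincount(strat_of_cluster, minlength=pooled + 1)
        if counts[pooled] == 1:
            warnings.warn(
                "collapse policy left one pooled PSU; treated as certainty",
                stacklevel=3,
            )

    n_groups = int(strat_of_cluster.max()) + 1
    n_h = np.bincount(strat_of_cluster, minlength=n_groups).astype(float)
    s1 = np.bincount(strat_of_cluster, weights=z, minlength=n_groups)
    s2 = np.bincount(strat_of_cluster, weights=z * z, minlength=n_groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        ssq = s2 - s1 * s1 / n_h
        contrib = np.where(n_h > 1, n_h / np.maximum(n_h - 1.0, 1.0) * ssq, 0.0)
    var = float(np.clip(contrib, 0.0, None).sum())
    return p, var


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------


def logit_ci(
    estimate: float, se: float, level: float = 0.95, n: int | None = None
) -> tuple[float, float]:
    """95% (by default) CI for a prevalence in percent, from a normal
    interval on logit(p) with delta-method SE, back-transformed.

    At the boundaries (estimate 0 or 100, where the logit SE degenerates)
    an exact binomial one-sided interval on the unweighted count ``n`` is
    used instead: for zero successes the upper bound is
    ``100*(1-(alpha/2)**(1/n))``, and symmetrically for ``n`` successes.
    """
    if not 0 < level < 1:
        raise ValidationError(f"level {level} outside (0, 1)")
    if se < 0:
        raise ValidationError("negative se")
    alpha = 1.0 - level
    if estimate <= 0.0 or estimate >= 100.0:
        if n is None or n <= 0:
            raise ValidationError(
                "boundary estimate needs the unweighted count n for an exact interval"
            )
        edge = 100.0 * (1.0 - (alpha / 2.0) ** (1.0 / n))
        return (0.0, edge) if estimate <= 0.0 else (100.0 - edge, 100.0)
    if se == 0.0:
        return (estimate, estimate)
    p = estimate / 100.0
    s_logit = (se / 100.0) / (p * (1.0 - p))
    z = norm.ppf(0.5 + level / 2.0)
    centre = logit(p)
    lo = 100.0 * expit(centre - z * s_logit)
    hi = 100.0 * expit(centre + z * s_logit)
    return float(lo), float(hi)


def se_from_logit_ci(
    estimate: float, ci_low: float, ci_high: float, level: float = 0.95
) -> float:
    """Invert :func:`logit_ci`: recover the percent-scale SE from a
    published logit-method interval.  Falls back to the plain normal width
    when a bound touches the boundary of the scale."""
    z = norm.ppf(0.5 + level / 2.0)
    if 0.0 < ci_low and ci_high < 100.0 and 0.0 < estimate < 100.0:
        s_logit = (logit(ci_high / 100.0) - logit(ci_low / 100.0)) / (2.0 * z)
        p = estimate / 100.0
        return float(s_logit * p * (1.0 - p) * 100.0)
    return float((ci_high - ci_low) / (2.0 * z))


# ---------------------------------------------------------------------------
# Public estimators
# ---------------------------------------------------------------------------


def weighted_prevalence(
    records: Sequence[SurveyRecord] | pd.DataFrame,
    design: DesignSpec,
    dimension: DimensionSpec,
    ci_level: float = 0.95,
) -> list[SubgroupEstimate]:
    """Per-subgroup weighted prevalence (percent) with Taylor-linearized SE,
    logit CI, unweighted count and weighted population share.

    Records with a missing value on this dimension are excluded from the
    disaggregation (they still belong in :func:`overall_average`); declared
    subgroups with no records are omitted with a warning.  ``pop_share``
    values partition the dimension's observed weight, summing to 1.
    """
    df = as_record_frame(records)
    if dimension.name not in df.columns:
        raise ValidationError(f"records have no column for dimension {dimension.name!r}")
    arrays = _DesignArrays(df, design)
    labels = df[dimension.name].to_numpy()
    observed = ~pd.isna(labels)
    w_observed = float((arrays.w * observed).sum())
    if w_observed <= 0:
        raise ValidationError(f"no records carry a value for {dimension.name!r}")

    out: list[SubgroupEstimate] = []
    for label in dimension.subgroups:
        mask = observed & (labels == label)
        n = int(mask.sum())
        if n == 0:
            warnings.warn(
                f"subgroup {label!r} of {dimension.name!r} has no records; omitted",
                stacklevel=2,
            )
            continue
        p, var = _taylor_variance(arrays, mask, design)
        se = float(np.sqrt(var)) * 100.0
        est = p * 100.0
        ci_low, ci_high = logit_ci(est, se, ci_level, n=n)
        out.append(
            SubgroupEstimate(
                dimension_name=dimension.name,
                subgroup_label=label,
                estimate=est,
                se=se,
                ci_low=ci_low,
                ci_high=ci_high,
                n=n,
                pop_share=float((arrays.w * mask).sum() / w_observed),
            )
        )
    return out


def overall_average(
    records: Sequence[SurveyRecord] | pd.DataFrame, design: DesignSpec
) -> SettingAverage:
    """Setting-level weighted prevalence μ (percent) over *all* records,
    including those with missing stratifier values, with linearized SE."""
    df = as_record_frame(records)
    if len(df) == 0:
        raise ValidationError("overall_average: empty record list")
    arrays = _DesignArrays(df, design)
    p, var = _taylor_variance(arrays, np.ones(len(df), dtype=bool), design)
    return SettingAverage(mu=p * 100.0, se_mu=float(np.sqrt(var)) * 100.0)


# ---------------------------------------------------------------------------
# Cluster bootstrap (Rao–Wu rescaling) — the resampling oracle / UI engine
# ---------------------------------------------------------------------------


def iter_bootstrap_weights(
    df: pd.DataFrame,
    design: DesignSpec,
    reps: int,
    seed: int | np.random.Generator,
) -> Iterator[np.ndarray]:
    """Yield ``reps`` replicate weight vectors from a stratified cluster
    bootstrap: within each stratum of n_h PSUs, resample n_h − 1 PSUs with
    replacement and rescale by n_h/(n_h − 1) (Rao–Wu), so replicate SEs are
    unbiased under the with-replacement design.  Single-PSU strata keep
    their weights fixed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arrays = _DesignArrays(df, design)
    counts = arrays.stratum_cluster_counts()
    cluster_ids_by_stratum = [
        np.flatnonzero(arrays.cluster_stratum == h) for h in range(arrays.n_strata)
    ]
    for _ in range(reps):
        mult = np.zeros(arrays.n_clusters)
        for h, clusters in enumerate(cluster_ids_by_stratum):
            n_h = counts[h]
            if n_h == 1:
                mult[clusters] = 1.0
                continue
            picks = rng.integers(0, n_h, size=n_h - 1)
            hits = np.bincount(picks, minlength=n_h).astype(float)
            mult[clusters] = hits * n_h / (n_h - 1.0)
        yield arrays.w * mult[arrays.cluster_codes]


def bootstrap_prevalence_se(
    df: pd.DataFrame,
    design: DesignSpec,
    domain: np.ndarray | None = None,
    reps: int = 2000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Bootstrap SE (percentage points) of the weighted prevalence over
    ``domain`` (all records when None).  Serves as the resampling oracle
    for the Taylor-linearized SE."""
    y = df["outcome"].to_numpy(dtype=float)
    if domain is None:
        domain = np.ones(len(df), dtype=bool)
    stats = np.empty(reps)
    for b, w in enumerate(iter_bootstrap_weights(df, design, reps, seed)):
        wd = w * domain
        stats[b] = (wd * y).sum() / wd.sum()
    return float(stats.std(ddof=1)) * 100.0


def bootstrap_statistics(
    df: pd.DataFrame,
    design: DesignSpec,
    func: Callable[[pd.DataFrame, np.ndarray], np.ndarray],
    reps: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Apply ``func(df, replicate_weights) -> vector`` across bootstrap
    replicates; returns an array of shape (reps, len(vector))."""
    out = None
    for b, w in enumerate(iter_bootstrap_weights(df, design, reps, seed)):
        vals = np.asarray(func(df, w), dtype=float)
        if out is None:
            out = np.empty((reps, vals.size))
        out[b] = vals
    if out is None:
        raise ValidationError("reps must be >= 1")
    return out
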