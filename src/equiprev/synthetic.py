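"""Synthetic multistage stratified cluster surveys with known truth.

Emulates a MICS-style design: regions crossed with urban/rural form the
sampling strata; census enumeration areas (EAs) of unequal household counts
are selected systematically with probability proportional to size; a fixed
number of households is then drawn by simple random sampling within each
selected EA.  Sampling weights are the inverse product of the two stage
inclusion probabilities, so the design is approximately self-weighting
within a stratum when the size measure is exact.

Each household carries a latent wealth score, a vector of binary asset
indicators loading on it (from which wealth quintiles are derived by PCA,
as survey programmes do), an education level, and an eligible-woman flag.
The binary outcome (e.g. slept under an insecticide-treated net) follows a
logistic model with region baselines and additive log-odds effects of
residence, wealth quintile and education, plus an EA-level normal random
intercept whose variance is calibrated to a target intra-cluster
correlation via the latent-threshold mapping ``sigma_u^2 = icc * pi^2/3 /
(1 - icc)``.

Outcomes are realized once when the frame is built (a pure function of the
config, including its seed), so a census sample reproduces the frame truth
exactly and repeated subsamples of one frame have a fixed estimand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.decomposition import PCA

from .core import (
    DimensionSpec,
    SurveyRecord,
    ValidationError,
    mics_dimensions,
)
from .measures import _point_measures

__all__ = [
    "RegionConfig",
    "PopulationConfig",
    "SyntheticTruth",
    "Frame",
    "default_config",
    "build_frame",
    "draw_sample",
    "draw_sample_frame",
    "assign_wealth_quintiles",
    "true_summaries",
    "config_from_yaml",
    "config_to_yaml",
]

QUINTILE_LABELS = (
    "Quintile 1 (poorest)",
    "Quintile 2",
    "Quintile 3",
    "Quintile 4",
    "Quintile 5 (richest)",
)
EDUCATION_LABELS = ("No formal education", "Primary school", "Secondary/higher education")


@dataclass(frozen=True)
class RegionConfig:
    """One region: its urban population share, frame size per stratum, and
    the baseline outcome prevalence (%) around which covariate effects act."""

    label: str
    baseline_prevalence: float
    urban_share: float = 0.45
    eas_per_stratum: int = 40
    households_per_ea: int = 100
    wealth_shift: float = 0.0  # shift of the latent wealth mean (SD units)

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prevalence < 100.0:
            raise ValidationError(
                f"baseline prevalence for {self.label!r} must be in (0, 100)"
            )
        if not 0.0 <= self.urban_share <= 1.0:
            raise ValidationError(f"urban share for {self.label!r} outside [0, 1]")
        if self.eas_per_stratum <= 0 or self.households_per_ea <= 0:
            raise ValidationError(f"EA and household counts for {self.label!r} must be positive")


@dataclass(frozen=True)
class PopulationConfig:
    regions: tuple[RegionConfig, ...]
    urban_effect: float = -0.8  # log-odds, centred on the region's urban share
    wealth_effect: float = -0.25  # log-odds per quintile step above Q3
    education_effect: float = -0.25  # log-odds per education level above primary
    icc: float = 0.06  # intra-cluster correlation of the outcome
    n_assets: int = 12
    asset_loading: float = 1.2  # scale of asset loadings on latent wealth
    eligible_rate: float = 0.26  # P(household contributes one eligible woman)
    urban_wealth_shift: float = 0.9  # latent wealth bonus for urban households
    ea_size_jitter: float = 0.35  # EA household counts ~ U(mean*(1±jitter))
    seed: int = 20170101

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if not self.regions:
            raise ValidationError("config needs at least one region")
        if not 0.0 <= self.icc < 1.0:
            raise ValidationError(f"icc {self.icc} outside [0, 1)")
        if self.n_assets < 2:
            raise ValidationError("need at least 2 asset indicators")
        if not 0.0 < self.eligible_rate <= 1.0:
            raise ValidationError("eligible_rate outside (0, 1]")
        if not 0.0 <= self.ea_size_jitter < 1.0:
            raise ValidationError("ea_size_jitter outside [0, 1)")

    @property
    def sigma_u(self) -> float:
        """EA random-intercept SD implied by the target ICC (logistic latent
        threshold: residual variance pi^2/3)."""
        if self.icc == 0.0:
            return 0.0
        return float(np.sqrt(self.icc * np.pi**2 / 3.0 / (1.0 - self.icc)))


def default_config(seed: int = 20170101) -> PopulationConfig:
    """The package's default scenario: ten regions with baselines near the
    2017 Ghana MICS pattern of ITN use in pregnancy (high in the north and
    Volta, low in the urbanized capital region), rural-leaning urban shares,
    and effects making poorer, less-educated and rural women more likely
    users — the gradient that survey showed."""
    presets = [
        # label, baseline %, urban share, latent-wealth shift
        ("Ashanti", 47.0, 0.60, 0.2),
        ("Brong Ahafo", 60.9, 0.45, 0.0),
        ("Central", 44.5, 0.45, 0.0),
        ("Eastern", 53.6, 0.45, 0.0),
        ("Greater Accra", 17.5, 0.90, 0.6),
        ("Northern", 49.1, 0.30, -0.4),
        ("Upper East", 75.5, 0.20, -0.5),
        ("Upper West", 61.8, 0.20, -0.5),
        ("Volta", 69.4, 0.35, 0.0),
        ("Western", 52.5, 0.45, 0.0),
    ]
    return PopulationConfig(
        regions=tuple(
            RegionConfig(label=lbl, baseline_prevalence=b, urban_share=u, wealth_shift=s)
            for lbl, b, u, s in presets
        ),
        seed=seed,
    )


#: Default two-stage sample: 5 EAs per stratum, 36 households per EA,
#: giving ~930 eligible women at the default eligibility rate — the scale
#: of the 2017 survey's analytic sample.
DEFAULT_EA_TAKE = 5
DEFAULT_HOUSEHOLD_TAKE = 36


# ---------------------------------------------------------------------------
# Wealth index
# ---------------------------------------------------------------------------


def assign_wealth_quintiles(
    assets: np.ndarray | pd.DataFrame, weights: np.ndarray | None = None
) -> np.ndarray:
    """Quintile labels from the first principal component of the
    standardized household asset matrix.

    The PC1 score is sign-aligned so that a higher score means more assets;
    quintile cuts are at the (weighted) 20/40/60/80th percentiles.  Constant
    asset columns are dropped with a warning; an all-constant matrix is an
    error.
    """
    x = np.asarray(assets, dtype=float)
    if x.ndim != 2 or x.shape[0] < 5:
        raise ValidationError("need a 2-D asset matrix with at least 5 households")
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.any() or keep.sum() < 2:
        raise ValidationError("asset matrix needs at least 2 non-constant columns")
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant asset column(s) before PCA",
            stacklevel=2,
        )
        x = x[:, keep]
        sd = sd[keep]
    z = (x - x.mean(axis=0)) / sd
    score = PCA(n_components=1, svd_solver="randomized", random_state=0).fit_transform(z)[:, 0]
    if np.corrcoef(score, x.sum(axis=1))[0, 1] < 0:
        score = -score
    cuts = _weighted_quantiles(score, np.array([0.2, 0.4, 0.6, 0.8]), weights)
    idx = np.searchsorted(cuts, score, side="right")
    return np.asarray(QUINTILE_LABELS)[idx]


def _weighted_quantiles(
    values: np.ndarray, qs: np.ndarray, weights: np.ndarray | None
) -> np.ndarray:
    if weights is None:
        return np.quantile(values, qs)
    order = np.argsort(values)
    v, w = values[order], np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return np.interp(qs, cum, v)


# ---------------------------------------------------------------------------
# Frame construction
# ---------------------------------------------------------------------------


@dataclass
class Frame:
    """A realized sampling frame: households nested in EAs nested in the
    region × urban/rural strata, with outcomes pre-drawn for eligible
    women."""

    config: PopulationConfig
    households: pd.DataFrame  # one row per household
    eas: pd.DataFrame  # one row per EA: stratum, ea, size

    def eligible_women(self) -> pd.DataFrame:
        return self.households[self.households["eligible"]]


def build_frame(config: PopulationConfig) -> Frame:
    """Deterministically realize the population implied by ``config``."""
    rng = np.random.default_rng(config.seed)

    ea_rows = []
    hh_parts: dict[str, list[np.ndarray]] = {
        k: [] for k in ("region", "residence", "stratum", "ea", "ea_size")
    }
    baselines = []
    urban_flags = []
    urban_shares = []
    wealth_shifts = []

    for region in config.regions:
        for residence, share in (("Urban", region.urban_share), ("Rural", 1 - region.urban_share)):
            if share <= 0:
                continue
            stratum = f"{region.label}|{residence}"
            jitter = config.ea_size_jitter
            sizes = np.maximum(
                2,
                np.rint(
                    region.households_per_ea
                    * (1.0 + jitter * rng.uniform(-1.0, 1.0, size=region.eas_per_stratum))
                ).astype(int),
            )
            for k, size in enumerate(sizes):
                ea = f"{stratum}|EA{k:03d}"
                ea_rows.append({"stratum": stratum, "ea": ea, "size": int(size)})
                hh_parts["region"].append(np.repeat(region.label, size))
                hh_parts["residence"].append(np.repeat(residence, size))
                hh_parts["stratum"].append(np.repeat(stratum, size))
                hh_parts["ea"].append(np.repeat(ea, size))
                hh_parts["ea_size"].append(np.repeat(size, size))
            n_hh = int(sizes.sum())
            baselines.append(np.repeat(region.baseline_prevalence, n_hh))
            urban_flags.append(np.repeat(1.0 if residence == "Urban" else 0.0, n_hh))
            urban_shares.append(np.repeat(region.urban_share, n_hh))
            wealth_shifts.append(np.repeat(region.wealth_shift, n_hh))

    if not ea_rows:
        raise ValidationError("degenerate config: no EAs")
    hh = pd.DataFrame({k: np.concatenate(v) for k, v in hh_parts.items()})
    n = len(hh)
    baseline = np.concatenate(baselines)
    urban = np.concatenate(urban_flags)
    urban_share = np.concatenate(urban_shares)
    wealth_shift = np.concatenate(wealth_shifts)

    # latent wealth and asset indicators
    wealth = rng.normal(size=n) + config.urban_wealth_shift * urban + wealth_shift
    a = config.n_assets
    alphas = np.linspace(-1.8, 1.8, a)
    loadings = config.asset_loading * (0.75 + 0.5 * np.arange(a) / (a - 1))
    asset_probs = expit(alphas[None, :] + loadings[None, :] * wealth[:, None])
    assets = (rng.uniform(size=(n, a)) < asset_probs).astype(np.int8)
    quintile = assign_wealth_quintiles(assets)
    q_index = np.searchsorted(np.asarray(QUINTILE_LABELS), quintile) + 1  # labels sort in order

    # education: ordinal cut of a wealth/urban-driven latent score
    edu_latent = 0.7 * wealth + 0.6 * urban + rng.normal(size=n)
    edu_index = np.searchsorted(np.array([-0.33, 0.32]), edu_latent, side="right")
    education = np.asarray(EDUCATION_LABELS)[edu_index]

    # EA random intercepts calibrated to the target ICC
    ea_effect_by_ea = rng.normal(scale=config.sigma_u or 0.0, size=len(ea_rows))
    ea_codes = pd.factorize(hh["ea"], sort=False)[0]
    u = ea_effect_by_ea[ea_codes] if config.sigma_u > 0 else np.zeros(n)

    eta = (
        logit(baseline / 100.0)
        + config.urban_effect * (urban - urban_share)
        + config.wealth_effect * (q_index - 3)
        + config.education_effect * (edu_index - 1)
        + u
    )
    p = expit(eta)

    eligible = rng.uniform(size=n) < config.eligible_rate
    outcome = np.where(
        eligible, (rng.uniform(size=n) < p).astype(float), np.nan
    )

    hh["latent_wealth"] = wealth
    for j in range(a):
        hh[f"asset_{j}"] = assets[:, j]
    hh["Economic status"] = quintile
    hh["Education"] = education
    hh["Place of residence"] = hh["residence"]
    hh["Sub-national region"] = hh["region"]
    hh["p_outcome"] = p
    hh["eligible"] = eligible
    hh["outcome"] = outcome
    return Frame(config=config, households=hh, eas=pd.DataFrame(ea_rows))


# ---------------------------------------------------------------------------
# Two-stage sampling
# ---------------------------------------------------------------------------


def _pps_systematic(
    sizes: np.ndarray, take: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Systematic PPS without replacement with a random start on the
    cumulated-size scale.  Units whose scaled size would exceed the
    sampling interval are selected with certainty and the remainder is
    re-run.  Returns (selected indices, inclusion probabilities)."""
    sizes = np.asarray(sizes, dtype=float)
    n_units = len(sizes)
    if take > n_units:
        raise ValidationError(f"EA take {take} exceeds available EAs ({n_units})")
    chosen: list[int] = []
    probs = np.ones(n_units)
    remaining = np.arange(n_units)
    need = take
    while need > 0:
        s = sizes[remaining]
        total = s.sum()
        oversize = need * s > total
        if oversize.any():
            certain = remaining[oversize]
            chosen.extend(certain.tolist())
            probs[certain] = 1.0
            remaining = remaining[~oversize]
            need = take - len(chosen)
            continue
        interval = total / need
        start = rng.uniform(0.0, interval)
        points = start + interval * np.arange(need)
        cum = np.cumsum(s)
        idx = np.searchsorted(cum, points, side="left")
        sel = remaining[idx]
        chosen.extend(sel.tolist())
        probs[sel] = need * sizes[sel] / total
        need = 0
    return np.array(sorted(chosen)), probs


def draw_sample_frame(
    frame: Frame,
    ea_take: int | Mapping[str, int] | None = DEFAULT_EA_TAKE,
    households_per_ea: int | None = DEFAULT_HOUSEHOLD_TAKE,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Two-stage sample as a record DataFrame (one row per eligible woman).

    Stage 1 selects ``ea_take`` EAs per stratum by systematic PPS on EA
    household counts (``None``: all EAs, a census of clusters); stage 2
    draws ``households_per_ea`` households by SRS within each selected EA
    (``None`` or more than available: all households).  The record weight
    is the inverse of the product of the two stage inclusion probabilities;
    all eligible women in a sampled household are interviewed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hh = frame.households
    members_by_ea = getattr(frame, "_members_by_ea", None)
    if members_by_ea is None:
        members_by_ea = {
            ea: idx.to_numpy() if hasattr(idx, "to_numpy") else np.asarray(idx)
            for ea, idx in hh.groupby("ea", sort=False).indices.items()
        }
        frame._members_by_ea = members_by_ea  # cache: frame is immutable by use

    picked_parts: list[np.ndarray] = []
    weight_parts: list[np.ndarray] = []
    for stratum, eas in frame.eas.groupby("stratum", sort=True):
        sizes = eas["size"].to_numpy()
        take = (
            len(eas)
            if ea_take is None
            else (ea_take[stratum] if isinstance(ea_take, Mapping) else int(ea_take))
        )
        if take > len(eas):
            raise ValidationError(
                f"EA take {take} exceeds available EAs ({len(eas)}) in stratum "
                f"{stratum!r}"
            )
        if take == len(eas):
            sel_idx = np.arange(len(eas))
            pi1 = np.ones(len(eas))
        else:
            sel_idx, pi1 = _pps_systematic(sizes, take, rng)
        ea_ids = eas["ea"].to_numpy()
        for i in sel_idx:
            members = members_by_ea[ea_ids[i]]
            m_avail = len(members)
            if households_per_ea is None or households_per_ea >= m_avail:
                picked = members
                pi2 = 1.0
            else:
                picked = members[
                    rng.choice(m_avail, size=households_per_ea, replace=False)
                ]
                pi2 = households_per_ea / m_avail
            picked_parts.append(picked)
            weight_parts.append(np.full(len(picked), 1.0 / (pi1[i] * pi2)))

    picked_all = np.concatenate(picked_parts)
    weights_all = np.concatenate(weight_parts)
    eligible = hh["eligible"].to_numpy()[picked_all]
    picked_all = picked_all[eligible]
    weights_all = weights_all[eligible]
    if picked_all.size == 0:
        raise ValidationError("sample contains no eligible women; enlarge the takes")
    dims = ["Economic status", "Education", "Place of residence", "Sub-national region"]
    df = hh.iloc[picked_all][["stratum", "ea", "outcome"] + dims].reset_index(drop=True)
    df = df.rename(columns={"ea": "cluster"})
    df.insert(2, "weight", weights_all)
    df["outcome"] = df["outcome"].astype(int)
    return df[["stratum", "cluster", "weight", "outcome"] + dims]


def draw_sample(
    frame: Frame,
    ea_take: int | Mapping[str, int] | None = DEFAULT_EA_TAKE,
    households_per_ea: int | None = DEFAULT_HOUSEHOLD_TAKE,
    seed: int | np.random.Generator = 0,
) -> list[SurveyRecord]:
    """Like :func:`draw_sample_frame` but returning SurveyRecord objects."""
    df = draw_sample_frame(frame, ea_take, households_per_ea, seed)
    dims = [s.name for s in mics_dimensions()]
    return [
        SurveyRecord(
            stratum_id=row.stratum,
            cluster_id=row.cluster,
            weight=row.weight,
            outcome=int(row.outcome),
            values={d: getattr(row, d.replace(" ", "_").replace("-", "_")) for d in dims},
        )
        for row in df.rename(
            columns={d: d.replace(" ", "_").replace("-", "_") for d in dims}
        ).itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Frame-level truth: subgroup prevalences (%) among eligible women,
    the overall prevalence μ, and the four inequality measures computed
    from those prevalences by the same closed-form rules the estimators
    use.  ``model_prevalences``/``model_mu``/``model_measures`` hold the
    same quantities computed from the model probabilities (conditional on
    the realized EA effects) instead of the realized outcomes: free of
    outcome-level binomial noise, e.g. exactly at the no-inequality values
    when all covariate effects are zero."""

    mu: float
    prevalences: dict[str, dict[str, float]]
    measures: dict[str, dict[str, float]]
    model_prevalences: dict[str, dict[str, float]]
    model_mu: float
    model_measures: dict[str, dict[str, float]]


def true_summaries(
    frame: Frame | PopulationConfig, specs: Sequence[DimensionSpec] | None = None
) -> SyntheticTruth:
    """Ground truth for a frame (or for the frame a config deterministically
    builds).  Census estimation reproduces these values exactly."""
    if isinstance(frame, PopulationConfig):
        frame = build_frame(frame)
    if specs is None:
        specs = mics_dimensions()
    women = frame.eligible_women()
    if len(women) == 0:
        raise ValidationError("frame has no eligible women")
    y = women["outcome"].to_numpy(dtype=float)
    p_model = women["p_outcome"].to_numpy(dtype=float)
    mu = float(y.mean()) * 100.0
    model_mu = float(p_model.mean()) * 100.0

    prevalences: dict[str, dict[str, float]] = {}
    model_prev: dict[str, dict[str, float]] = {}
    measures: dict[str, dict[str, float]] = {}
    model_measures: dict[str, dict[str, float]] = {}
    for spec in specs:
        labels = women[spec.name].to_numpy()
        prev = {}
        mprev = {}
        for lbl in spec.subgroups:
            mask = labels == lbl
            if not mask.any():
                raise ValidationError(
                    f"frame has no eligible women in {spec.name!r}/{lbl!r}"
                )
            prev[lbl] = float(y[mask].mean()) * 100.0
            mprev[lbl] = float(p_model[mask].mean()) * 100.0
        prevalences[spec.name] = prev
        model_prev[spec.name] = mprev
        d, r, par, paf = _point_measures(prev, mu, spec, truncate=True)
        measures[spec.name] = {"D": d, "R": r, "PAR": par, "PAF": paf}
        d, r, par, paf = _point_measures(mprev, model_mu, spec, truncate=True)
        model_measures[spec.name] = {"D": d, "R": r, "PAR": par, "PAF": paf}
    return SyntheticTruth(
        mu=mu,
        prevalences=prevalences,
        measures=measures,
        model_prevalences=model_prev,
        model_mu=model_mu,
        model_measures=model_measures,
    )


# ---------------------------------------------------------------------------
# Config (de)serialization — flat YAML for the CLI
# ---------------------------------------------------------------------------


def config_to_yaml(config: PopulationConfig, path) -> None:
    import yaml

    payload = asdict(config)
    payload["regions"] = [asdict(r) for r in config.regions]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(path) -> PopulationConfig:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        regions = tuple(RegionConfig(**r) for r in raw.pop("regions"))
        return PopulationConfig(regions=regions, **raw)
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed population config: {exc}") from exc
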