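# equiprev

**Design-based subgroup prevalence estimation and health-inequality summary
measures (D, R, PAR, PAF) for complex household surveys.**

Health-equity monitoring asks how a binary health indicator — here, whether
a pregnant woman slept under an insecticide-treated net (ITN) — varies
across the subgroups of an *equity stratifier* such as wealth quintile,
education, urban/rural residence, or sub-national region. `equiprev` is a
small toolkit for analysts who do this kind of work with data from
multistage stratified cluster surveys (MICS/DHS-type designs):

1. **Estimation** — weighted subgroup prevalences with Taylor-linearized
   standard errors and logit-scale confidence intervals under a stratified
   cluster design;
2. **Measurement** — the four standard inequality summary measures with
   95% uncertainty intervals;
3. **Simulation** — a synthetic MICS-like population and two-stage sampler
   with known ground truth, so every estimator in the package can be
   validated against closed-form answers without any microdata download.

The packaged worked example is ITN use by pregnant women in Ghana, from the
published disaggregated tables of the 2011 and 2017 Multiple Indicator
Cluster Surveys (overall use rose from 32.6% to 49.7%).

## The four measures

Let `y_j` be the prevalence (in percent) in subgroup `j` and `μ` the overall
weighted average. With the advantaged extreme `y_adv` (the top wealth
quintile, highest education, urban; or, for a non-ordered dimension such as
region, the best-performing subgroup) and disadvantaged extreme `y_dis`:

| measure | definition | type |
|---|---|---|
| Difference | `D = y_adv − y_dis` (region: `max − min`) | simple, absolute (pp) |
| Ratio | `R = y_adv / y_dis` (region: `max / min`) | simple, relative |
| Population Attributable Risk | `PAR = max(0, y_ref − μ)` | complex, absolute (pp) |
| Population Attributable Fraction | `PAF = 100 · PAR / μ` | complex, relative (%) |

`y_ref` is the reference (best-achievable) subgroup: PAR is the gain the
whole population would realize if every subgroup attained the reference
level, and zero PAR/PAF means no inequality in that direction. For ordered
dimensions the extremes are fixed by the ordering, so D and R can fall
below 0 and 1 when the disadvantaged groups outperform the advantaged ones
— as they do for wealth, education and residence in this indicator.
Uncertainty intervals are delta-method normal intervals (log scale for R),
or cluster-bootstrap percentile intervals when record-level data are
available.

## Worked example

Compute the 2017 regional inequality in ITN use from the packaged
disaggregated table, with the published overall average 49.7% as μ:

```python
import equiprev as eq
from equiprev.core import round_half_away
from equiprev.pipeline import _fill_ses

specs = eq.mics_dimensions()
groups = eq.read_disaggregated_table(eq.table1_fixture_path(), specs)
_fill_ses(groups)                       # recover SEs from the published CIs
region = next(s for s in specs if s.name == "Sub-national region")
ests = groups[("Ghana", 2017, "Sub-national region")]
mu = eq.SettingAverage(mu=49.7)

d = eq.difference(ests, region)
r = eq.ratio(ests, region)
par = eq.par_measure(ests, mu, region)
paf = eq.paf_measure(par, mu)
for s in (d, r, par, paf):
    print(s.measure, round_half_away(s.estimate, 1),
          round_half_away(s.ui_low, 1), round_half_away(s.ui_high, 1),
          s.reference_subgroup, s.comparison_subgroup)
```

prints

```
D 58.0 42.1 73.9 Upper East Greater Accra
R 4.3 2.2 8.4 Upper East Greater Accra
PAR 25.8 14.7 36.9 Upper East overall average
PAF 51.9 29.5 74.3 Upper East overall average
```

ITN use in the best-performing region (Upper East, 75.5%) exceeds the
worst (Greater Accra, 17.5%) by 58 percentage points, a ratio of 4.3; if
every region matched Upper East, national coverage would rise by 25.8
points, i.e. 51.9% above its current level — substantial regional
inequality, while the wealth, education and residence gradients all favour
the *disadvantaged* groups (D < 0, R < 1, PAR truncated to 0).

The same analysis runs from the shell:

```sh
equiprev reproduce --out report.csv
equiprev measures --table table1.csv --mu 2011=32.6 --mu 2017=49.7 --out summary.csv
equiprev simulate --seed 17 --out records.csv     # synthetic MICS-like survey
equiprev estimate --records records.csv --out estimates.csv
```

`equiprev reproduce` recomputes all 32 published summary point estimates
for 2011/2017 and reports per-cell agreement at one-decimal rounding
(30/32 reproduce exactly; two cells differ in the last decimal because the
published analysis used unrounded internals, and are annotated as such).

## Layout

- `src/equiprev/core.py` — data model and CSV interchange formats
- `src/equiprev/estimation.py` — design-based estimation (Taylor
  linearization, logit CIs, cluster bootstrap)
- `src/equiprev/measures.py` — D, R, PAR, PAF with uncertainty intervals
- `src/equiprev/synthetic.py` — MICS-like population/sampler with known truth
- `src/equiprev/pipeline.py`, `cli.py` — reproduction pipeline and CLI
- `docs/methods.md` — statistical methods, defaults and limitations
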