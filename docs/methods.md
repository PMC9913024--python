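# Methods

## Scenario model

The unit of input is a set of posterior trajectory samples per country: for
sample $s$ and year $t \in \{2019, \dots, 2030\}$, a triple
$(m_{s,t}, \tau_{s,t}, u_{s,t})$ of proportions of women of reproductive age
(WRA, 15–49) using a modern method, using a traditional method, and having
an unmet need for family planning. These come jointly from a probabilistic
projection model and satisfy the simplex constraint
$m + \tau + u \le 1$ in every sample. The package consumes such samples; it
does not estimate them.

Demand satisfied with modern methods is $DS = m/(m+\tau+u)$; the
denominator, total demand, is any-method use plus unmet need. Women counted
as "unmet need for modern methods" are traditional users plus women with
unmet need for any method, i.e. total demand minus modern users. If total
demand is zero, $DS$ is defined as 0 with a logged warning, so degenerate
toy inputs flow through rather than erroring.

A scenario is a percentile $p$ of the country-specific distribution of
change, $\Delta_s = DS_{s,2030} - DS_{s,2019}$, computed **within** each
trajectory. Because each $\Delta_s$ is a within-sample difference, baseline
uncertainty propagates and the construction does not depend on the central
2019 and 2030 levels separately. The scenario's 2030 level is

$$DS^{(p)}_{2030} = \mathrm{clip}\big(\mathrm{med}_s(DS_{s,2019}) + Q_p(\Delta_s),\ 0, 1\big).$$

This anchors at the central baseline estimate, uses the full change
distribution, and reduces to the median projection at $p = 50$. Clipping
events are logged per country; they arise only when a large change quantile
is added to an already-high baseline. Defaults are $p=50$ ("current
progress") and $p=90$ ("accelerated progress"); $p=90$ rather than a more
extreme percentile because countries with sparse data have wide intervals
whose far tails are not credible targets.

**Design choice (genuinely open).** The source analysis does not state how
the companion indicators (modern users, unmet need) are made consistent
with the selected change percentile. We carry the median total-demand
proportion for 2030 and split it by the scenario $DS$:
$m^{(p)} = DS^{(p)} \cdot d$, $\text{unmet}^{(p)} = d - m^{(p)}$ with
$d = \mathrm{med}_s(m_{s,2030}+\tau_{s,2030}+u_{s,2030})$. This preserves
the identity $DS = \text{users}/(\text{users}+\text{unmet})$ exactly at
every level of aggregation, which the published table itself obeys. The
alternative — conditioning the full joint trajectory set on the selected
change quantile — would need the original model output and is not
implemented.

**Quantile rule.** Linear interpolation between order statistics ("type 7"):
for $n$ sorted values, $Q_p$ interpolates at rank $(n-1)p/100$; $p=0$ is the
minimum, $p=100$ the maximum. The source names percentiles but no
estimator; type 7 is the numpy/R default and is fixed and tested against a
brute-force oracle.

## Accounting, impact, costs

Absolute numbers are proportions times the country's WRA count in the
target year, in thousands. Aggregates are sums over countries; the
aggregate percent of demand satisfied is the **ratio of sums**
$\sum \text{users} / (\sum \text{users} + \sum \text{unmet})$, which is what
makes the aggregate row internally consistent (the mean of country
percentages would not be).

Annual unintended pregnancies for a country-scenario:

$$UP = \sum_k \text{users} \cdot \text{mix}_k \cdot f_k + \text{unmet} \cdot r,$$

where $\text{mix}_k$ is the (time-invariant) share of modern users on method
$k$, $f_k$ the age-adjusted annual failure probability, and $r$ the
pregnancy rate for women who want to avoid pregnancy but use a traditional
method or none. The default $r = 0.448$/woman-year is the median of the
country-specific distribution estimated for this group; a per-country rate
column is accepted. Failure rates are annual per-user probabilities applied
to the scenario's user counts with no within-year dynamics. Women with no
desire to avoid pregnancy never enter the calculation. Note that published
aggregate pregnancy totals cannot be recovered from the scalar median rate
alone (a uniform 0.448 on the aggregate unmet count already exceeds them),
so country-specific rates evidently matter at scale; the package therefore
treats $r$ as an input, not a constant of nature.

Per-user annual direct cost in the target year is

$$c = P \cdot \pi(y) + D \cdot (1+r_{US})^{y-2020} + C,$$

with base-year (2020) components $P$ (personnel), $D$ (drugs & supplies),
$C$ (commodity). The personnel factor $\pi(y)$ compounds the country's
GDP-deflator rates for 2021–2024 and, for 2025 onward, the **arithmetic
mean** of those four rates (the geometric mean was rejected for simplicity
and documented here); $r_{US}$ is a single constant rate standing for the
2015–2019 US average. Commodity costs are deliberately flat: observed
commodity prices fell over 2015–2019, so not inflating them is
conservative. Costs are nominal target-year USD, no discounting. Scenario
total cost is $\text{users} \cdot \sum_k \text{mix}_k c_k$ (thousands of
users × USD/user-year = USD thousands/year). Savings from averted
pregnancies are out of scope by design.

## Synthetic data generator

The generator replaces the UN/OSF inputs for development and testing. It
emulates statistical *structure*, not real countries:

* **Trajectories.** Additive logistic-normal random walk on the 3-part
  composition vs. the remainder of WRA. Baselines per country:
  modern ~ U(0.10, 0.55), traditional ~ U(0.01, 0.10), unmet ~ U(0.05, 0.25)
  (typical LMIC ranges; max sum 0.90 keeps the remainder positive). On the
  additive log-ratio scale, year-over-year steps add a per-country drift on
  the modern coordinate (drawn from `drift_range`, default (0.0, 0.04)/yr —
  stagnation to strong growth) plus correlated Gaussian innovations with
  per-country scale from `noise_range` (default (0.01, 0.08)/yr). The
  innovation correlation (modern vs traditional −0.3, modern vs unmet −0.4,
  traditional vs unmet +0.2) encodes that rising modern use displaces
  traditional use and erodes unmet need. The inverse log-ratio map
  guarantees the simplex constraint. Year 0 carries no noise: projection
  uncertainty accumulates forward, reproducing the fan-out of real
  projections, and the country-specific scale reproduces the feature that
  data-poor countries have wider intervals. The width is a free knob, not
  an emulation of any survey-data mechanism.
* **Population.** WRA counts interpolate geometrically between log-uniform
  start and end levels inside `population_range` (default 200–60,000
  thousand, spanning small to very large countries), so counts are smooth
  in year, strictly positive, and a degenerate range yields exactly
  constant counts.
* **Methods.** Eight modern methods by default (the standard categories:
  pill, IUD, injectable, implant, condom, sterilisations, other), mix from
  a flat Dirichlet normalised to sum exactly to 1, failure rates
  U(0.002, 0.15) (sterilisation-like to withdrawal-adjacent), cost
  components in USD/user-year chosen so typical per-user totals land near
  the observed few-dollars range.
* **Inflation.** Country rates U(0.01, 0.12) within the declared
  (−0.05, 0.25) band; US rate U(0.015, 0.025), near the observed 2015–2019
  average.
* **Seeding.** One global seed spawns independent substreams per generator
  (`numpy` `SeedSequence.spawn`), so adding a generator never perturbs the
  others, and every generator is bit-reproducible given the seed.

Defaults (131 countries, 500 samples, 2019–2030) mirror the study setting;
500 samples give the 50th/90th percentiles a Monte-Carlo error far below
the effect sizes of interest. What passing tests on synthetic data do *not*
show: fidelity to any real country's level or trend, survey-driven
uncertainty width, COVID-era disruption, or the true joint posterior
dependence produced by the hierarchical model — only the simplex geometry,
uncertainty fan-out and accounting structure are emulated.

## Numerical choices

* Quantiles via `numpy.quantile(method="linear")`; the brute-force oracle in
  the tests is an independent sort-and-interpolate implementation.
* Aggregation uses `math.fsum`, making country sums exactly rounded and
  hence permutation-invariant.
* Trajectory CSVs are written with 17 significant digits and read with
  pandas' `round_trip` float parser, so write→read is lossless to the bit.
* Proportions are validated against the simplex with slack 1e-9; the
  users/(users+unmet) identity is enforced at 1e-9 relative; inflation
  factors match the year-by-year loop to 1e-12.
* Zero total demand ⇒ DS = 0 with a warning; scenario DS clipped to [0, 1]
  with a logged flag; population counts must be strictly positive (a
  zero-population country is rejected rather than silently ignored).
* Report rounding: aggregates print at 3 significant figures and the
  percent row at whole percents; differences are always computed on
  unrounded values first. Full precision is kept in all CSVs.

## Problem sizes

The test suite exercises up to 200 countries × 250 samples for the
monotonicity sweep and 2000 samples for the parameter-recovery check
(tolerance: 3 bootstrap standard errors of the sample median); the
acceptance script runs the full 131-country default study. These sizes were
chosen to make Monte-Carlo error negligible relative to the tolerances
while keeping any single check in the seconds range.

## Known limitations

* The split-median-demand construction for companion indicators is a
  modelling choice (see above); conditioning the joint posterior on the
  change quantile could give slightly different user/unmet splits.
* Point scenarios only: no uncertainty intervals around scenario outputs.
* The pregnancy rate is held constant over time and, by default, over
  countries.
* No sub-national, age- or marital-status disaggregation; no COVID
  adjustment; no cost savings from averted pregnancies; no currency
  conversion or discounting.
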