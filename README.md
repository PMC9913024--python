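# fpscenarios

Country-specific target setting for contraceptive coverage from
probabilistic projections.

## The problem

SDG indicator 3.7.1 — the proportion of women of reproductive age (15–49)
whose need for family planning is satisfied with modern contraceptive
methods — is tracked in every country, but targets for it are usually either
one-size-fits-all ("75% everywhere") or purely aspirational ("universal
access"). Neither respects a country's starting point or its plausible pace
of change. Probabilistic projections offer a better handle: each country's
joint posterior over future contraceptive prevalence (modern, traditional)
and unmet need defines a *probability distribution of the change* in demand
satisfied between a baseline year (2019) and a target year (2030).

`fpscenarios` builds scenarios from percentiles of that change
distribution and computes their consequences. For each country with
posterior trajectory samples $(m_{s,t}, \tau_{s,t}, u_{s,t})$ — modern use,
traditional use and unmet need as proportions of WRA — demand satisfied in
trajectory $s$ and year $t$ is

$$DS_{s,t} = \frac{m_{s,t}}{m_{s,t} + \tau_{s,t} + u_{s,t}},$$

and the scenario level at percentile $p$ is

$$DS^{(p)}_{2030} = \mathrm{clip}\Big(\mathrm{med}_s\, DS_{s,2019} +
Q_p\big(DS_{s,2030} - DS_{s,2019}\big),\ 0,\ 1\Big),$$

with $Q_p$ the linear-interpolation (type-7) percentile. $p=50$ is the
**current progress** scenario (what past trends make likely); $p=90$ is
**accelerated progress** (a one-in-ten chance the change is at that level or
higher). Downstream, the scenario proportions are multiplied by WRA counts
to get users and unmet-for-modern women in thousands; unintended
pregnancies are method-mix-weighted failure rates on users plus a
0.448/woman-year rate on the unmet group; and direct costs are base-year
(2020) personnel / drugs-&-supplies / commodity components inflated to 2030
under per-component rules (country GDP-deflator rates for personnel, a
constant US rate for drugs & supplies, commodities flat). Aggregates use the
ratio of summed counts, never the mean of country percentages.

The package is aimed at quantitative demographers and health-policy
analysts who have posterior trajectory files (or want the bundled synthetic
generator) and need reproducible scenario tables.

## Worked example

```bash
python examples/03_full_pipeline.py
```

generates a 12-country synthetic study (seed 42) and prints:

```
                                                 quantity current accelerated difference
                  % of demand satisfied by modern methods     64%         71%         7%
                 No. of women using modern methods (000s)  41,100      45,400      4,300
No. of women with an unmet need for modern methods (000s)  22,600      18,300     -4,300
                     No. of unintended pregnancies (000s)  12,500      10,800     -1,680
                     Annual total direct costs ($) (000s) 715,000     790,000     75,300

countries below 75% demand satisfied under accelerated progress: 7 of 12
```

Reading: under business as usual these 12 synthetic countries would reach
64% aggregate demand satisfied in 2030; pushing every country to the 90th
percentile of its own change distribution raises that to 71%, adds 4.3
million modern users, removes 4.3 million women from unmet need, averts
1.68 million unintended pregnancies per year, and costs an extra $75
million per year — and still leaves 7 of 12 countries under the 75% mark,
which is why uniform targets mislead. Values are rounded to 3 significant
figures for display only; differences are computed before rounding.

The same pipeline runs from the shell:

```bash
fpscenarios simulate --seed 42 --out bundle/
fpscenarios run --config bundle/run.config --out results/ --threshold 75
fpscenarios report results/country_results.csv
```

`examples/01_scenarios_from_trajectories.py` shows the percentile machinery
on a hand-sized trajectory set, and `examples/02_impact_and_costs.py` the
pregnancy and cost accounting in isolation.

## Input formats

All inputs are plain CSV: trajectories
(`country,sample,year,modern,traditional,unmet`, long format), population
(`country,year,wra_thousands`), method mix (`method,share`), failure rates
(`method,annual_failure_rate`), cost components
(`[country,]method,personnel,drugs_supplies,commodity` in 2020 USD/user-year),
inflation (`country,rate_2021,...,rate_2024`; the US rate and the scalar
pregnancy rate live in the flat `key = value` run config). The
`fpscenarios.synthetic` module writes a complete, mutually consistent bundle.

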