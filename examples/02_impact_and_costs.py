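"""Unintended pregnancies and direct costs for one country-scenario.

Starting from user counts (thousands of women), we apply method-mix-weighted
failure rates plus the 0.448/woman-year pregnancy rate for the unmet-for-
modern group, then project per-user costs from 2020 to 2030 under the three
inflation rules (country deflator for personnel, constant US rate for drugs
and supplies, commodities flat).
"""

import pandas as pd

import fpscenarios as fp

users_modern = 1_200.0  # thousands of modern-method users in 2030
unmet_modern = 400.0    # thousands of women with unmet need for modern methods

mix = fp.MethodMix({"pill": 0.35, "injectable": 0.40, "iud": 0.25})
failures = fp.FailureRateTable({"pill": 0.07, "injectable": 0.04, "iud": 0.014})
rate = fp.PregnancyRate()  # default 0.448 per woman-year

up = fp.unintended_pregnancies(users_modern, unmet_modern, mix, failures, rate)
print(f"unintended pregnancies: {up:.1f} thousand per year")
print("  (method failures among users + 0.448 x unmet-for-modern women)")

inflation = fp.InflationInputs(
    rates=pd.DataFrame(
        [[0.06, 0.08, 0.05, 0.05]],
        index=pd.Index(["DEMO"], name="country"),
        columns=["rate_2021", "rate_2022", "rate_2023", "rate_2024"],
    ),
    us_rate=0.018,
)
print(f"personnel inflation factor 2020->2030: "
      f"{fp.personnel_factor(inflation.country_rates('DEMO'), 2030):.4f}")
print(f"drugs & supplies factor 2020->2030:    "
      f"{fp.drugs_supplies_factor(inflation.us_rate, 2030):.4f}")
print(f"commodity factor (never inflated):     {fp.commodity_factor(2030):.4f}")

base_components = {  # (personnel, drugs_supplies, commodity), 2020 USD/user-year
    "pill": (1.8, 0.9, 0.6), "injectable": (2.4, 0.7, 1.1), "iud": (3.1, 0.4, 1.9),
}
per_user = {
    m: fp.cost_per_user(c, inflation, "DEMO", 2030) for m, c in base_components.items()
}
for m, c in per_user.items():
    print(f"  {m:>10}: ${c:.2f} per user-year in 2030")

total = fp.total_cost(users_modern, mix, per_user)
print(f"annual total direct cost: ${total:,.0f} thousand "
      f"(= mix-weighted per-user cost x {users_modern:,.0f}k users)")
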