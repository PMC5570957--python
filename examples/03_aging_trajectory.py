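"""Track neuronal responsiveness across adulthood: rise, peak, decline.

Simulates per-worm response cohorts whose mean amplitude rises into mid
adulthood (Day 7) and declines in late adulthood, then runs the aging
analysis: per-day means with SEM, a one-way ANOVA across days, and the
designated pairwise contrasts (Day 7 vs 3, Day 18 vs 7).
"""

import numpy as np

import fretscreen as fs
from fretscreen.screening import aging_trajectory

rng = np.random.default_rng(3)
day_profile = {2: 0.22, 3: 0.25, 5: 0.32, 7: 0.40, 8: 0.38, 9: 0.33,
               12: 0.27, 14: 0.22, 18: 0.15}
records = fs.simulate_aging_cohorts(day_profile, n_per_day=45, cv=0.3, rng=rng)

result = aging_trajectory(records, contrasts=[(7, 3), (18, 7)])

print(result.per_day.to_string(index=False,
                               float_format=lambda v: f"{v:.2f}"))
print(f"\none-way ANOVA across days: p = {result.anova_p_peak:.2e} (peak)")
for _, row in result.pairwise.iterrows():
    print(f"Day {row.day_a:>2.0f} vs Day {row.day_b:>2.0f}: "
          f"mean peak difference {row.diff_mean_peak:+.1f} %, p = {row.p_peak:.2e}")

mid = result.per_day.set_index("age_day").loc[7, "mean_peak"]
late = result.per_day.set_index("age_day").loc[18, "mean_peak"]
print(f"\nDay-18 responses are {100 * (1 - late / mid):.0f}% below the Day-7 maximum —")
print("the late-phase functional decline the screen aims to rescue.")
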