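"""Forecast per-day cumulative death risk for hypothetical stays.

Given a fitted full model and a patient's covariates, the trajectory
evaluates risk at discharge after 1, 2, ... days — the model's view of
the cumulative cost of continuing the hospitalization, which depends on
when in the week the stay starts.
"""

from datetime import datetime

from hosprisk import CohortConfig, fit_preset, forecast_trajectory, simulate_cohort

records = simulate_cohort(CohortConfig(n_admissions=60_000, seed=11))
model = fit_preset(records, "model5c")

patient = {"age": 76.0, "gender": "F", "charlson": 3}
monday = datetime(2007, 3, 5, 10, 0)
sunday = datetime(2007, 3, 4, 10, 0)

mon = forecast_trajectory(model, patient, monday, horizon=7)
sun = forecast_trajectory(model, patient, sunday, horizon=7)

print("day  Monday-10:00  Sunday-10:00")
for (d, pm), (_, ps) in zip(mon.points, sun.points):
    print(f"{d:>3}  {pm:>12.4f}  {ps:>12.4f}")
# A Sunday admission starts its stay inside the elevated weekend blocks,
# so its early-stay risk sits above the Monday curve; both curves bend
# upward again as the hypothetical stay reaches the next weekend.
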