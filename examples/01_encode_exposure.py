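"""Encode a hospital stay into its 21 weekly exposure counters.

The week is cut into 21 blocks (night 00:00–08:00, daytime 08:00–17:00,
evening 17:00–24:00, for each day); a stay collects one "dose" per
calendar block-instance it touches.
"""

from datetime import datetime

from hosprisk import assign_block, encode_exposure, weekday_weekend_exposure

admission = datetime(2007, 3, 2, 14, 30)   # Friday afternoon
discharge = datetime(2007, 3, 5, 11, 0)    # Monday morning

print("admission block:", assign_block(admission))

ev = encode_exposure(admission, discharge)
print(f"length of stay: {ev.los_days:.2f} days, admission hour {ev.admission_time:.1f}")
print("occupied blocks (the nonzero exposure counters):")
for name, count in ev.as_dict().items():
    if name.startswith("count_") and count:
        print(f"  {name}: {count}")
print(f"total doses: {ev.total_blocks}")

wd, we = weekday_weekend_exposure(admission, discharge)
print(f"weekday vs weekend time: {wd:.2f} vs {we:.2f} days")
# A Friday-to-Monday stay accrues most of its exposure on the weekend —
# exactly the kind of stay the weekend-risk coefficients act on.
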