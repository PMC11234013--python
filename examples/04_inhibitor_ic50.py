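"""Inhibitor potency from a dose series.

Simulates the inhibitor dilution series (78-620 nM against 500 nM
deaminase, N = 3), converts each well's deamination velocity to percent of
the uninhibited activity, and fits the variable-slope logistic with the
top and bottom constrained to 100 % and 0 %.
"""

import raddkit as rk

design, scenario = rk.preset("inhibition_series")
traces = rk.simulate_plate(design, scenario, seed=7)

fit = rk.analyze_ic50(traces)
print(f"IC50 = {fit.ic50:.1f} nM   95% CI [{fit.ic50_ci[0]:.1f}, {fit.ic50_ci[1]:.1f}]")
print(f"Hill slope = {fit.hill:.2f}   R2 = {fit.r2:.3f}   "
      f"within tested span: {fit.in_span}")
print("IC50 is the inhibitor concentration that halves deaminase activity;")
print("a Hill slope near 1 indicates simple one-site occupancy.")
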