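"""Screening-window statistics from an endpoint plate.

Simulates 18 positive (full reaction) and 18 negative (no deaminase)
wells, reads the 1-h endpoint of each, and computes the Z'-factor,
signal-to-noise and signal-to-background ratios.
"""

import raddkit as rk

design, scenario = rk.preset("zprime")
traces = rk.simulate_plate(design, scenario, seed=7)

stats = rk.analyze_qc(traces)
print(f"positive wells: mean {stats.mu_pos:7.0f} RFU, SD {stats.sd_pos:5.0f}  (n={stats.n_pos})")
print(f"negative wells: mean {stats.mu_neg:7.0f} RFU, SD {stats.sd_neg:5.0f}  (n={stats.n_neg})")
print(f"Z' = {stats.z_prime:.2f}   S:N = {stats.snr:.0f}   S:B = {stats.sbr:.1f}")
print("Z' >= 0.5 marks an excellent screening window: the mean +/- 3 SD bands")
print("of the two groups are well separated, so hits are unlikely to be noise.")
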