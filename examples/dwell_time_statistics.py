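"""Dwell-time distribution of the high alpha state.

Extracts run lengths from a simulated state sequence and summarizes the
high-state dwell distribution: mean, median, mode, coefficient of variation
(as a percentage) and the power-law tail exponent of the above-median tail.
"""

from alphastates import MarkovParams, dwell_stats, extract_dwells, simulate_state_sequence

seq = simulate_state_sequence(MarkovParams(0.37, 0.12), n_epochs=50_000, seed=4)
dwells = extract_dwells(seq)
stats = dwell_stats(dwells.high_dwells)

print(f"high-state visits: {len(dwells.high_dwells)}   low-state visits: {len(dwells.low_dwells)}")
print(f"mean dwell:     {stats.mean:6.2f} s")
print(f"median dwell:   {stats.median:6.2f} s")
print(f"mode:           {stats.mode:6.2f} s")
print(f"variance:       {stats.variance_pct:6.1f} %  (coefficient of variation)")
print(f"tail weight:    {stats.tail_weight:6.2f}    ({stats.tail_statistic})")
print()
print("Median below mean and a small tail exponent mark a heavy-tailed visit-")
print("duration distribution: most high-alpha visits are short, a few are long.")
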