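"""Replay the neurofeedback dial over a synthetic training stream.

Calibrates the 0-10 dial to the 2nd/98th percentiles of resting alpha power,
then runs the 10-s sliding window / last-2-s power computation over a
synthetic stream whose alpha amplitude steps up halfway through.
"""

import numpy as np

from alphastates import (
    EmissionParams,
    RawEEG,
    calibrate_dial,
    power_pipeline,
    sliding_feedback,
    simulate_state_sequence,
    synthesize_eeg,
    MarkovParams,
)

emission = EmissionParams(sampling_rate=250)
resting_states = simulate_state_sequence(MarkovParams(0.53, 0.25), 120, seed=20)
resting = synthesize_eeg(resting_states, emission, seed=21)
# online power totals the band bins, so calibrate on the same statistic
resting_power = power_pipeline(resting, agg="sum")
calib = calibrate_dial(resting_power, source="s1-resting")

fs = 250
t = np.arange(fs * 60) / fs
amp = np.where(t < 30, 6.0, 14.0)  # amplitude step at t = 30 s
stream = RawEEG(np.tile(amp * np.sin(2 * np.pi * 10 * t), (2, 1)), fs, ["AF3", "AF4"])

trace = sliding_feedback(stream, calib, update_interval=1.0)
print(f"calibration: dial 0 at {calib.p2:.1f} uV^2, dial 10 at {calib.p98:.1f} uV^2")
print(f"{trace.dial.size} dial updates from t=10 s to t=60 s")
print(f"mean dial before step (t<=30):  {trace.dial[trace.times <= 30].mean():.2f}")
print(f"mean dial after step  (t>=35):  {trace.dial[trace.times >= 35].mean():.2f}")
print()
print("The dial tracks alpha power: the amplitude step at 30 s lifts the needle")
print("from near zero into the mid-range within a few updates, exactly as the")
print("trainee would have seen it.")
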