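"""End-to-end cohort analysis on a synthetic two-group neurofeedback study.

Simulates a small patient/healthy cohort with planted learning (a per-session
drop in the high-to-low switch rate for patients) and a planted negative
dependence of pain on high-alpha occupancy, analyzes every recording through
the full pipeline, and prints the session trend and the pain correlations.
"""

from alphastates import AnalysisConfig, CohortSpec, EmissionParams, run_pipeline

spec = CohortSpec(
    n_per_group=4,
    n_sessions=5,
    resting_epochs=60,   # 1 min eyes-open (scaled down from 2 min)
    nfb_epochs=150,      # 2.5 min training (scaled down from 10 min)
    emission=EmissionParams(sampling_rate=250),
    seed=7,
)
config = AnalysisConfig(target_rate=250.0)

result = run_pipeline(config, cohort_spec=spec)
table = result.cohort_table

pat = table[(table.group == "patient") & (table.threshold_percent == 30.0)]
occ_by_session = pat.groupby("session")["fractional_occupancy"].mean()
print("patient-group mean fractional occupancy by session (30% threshold):")
for s, v in occ_by_session.items():
    print(f"  session {s}: {v:.3f}")

stats = result.stats
sel = stats[(stats.group == "patient") & (stats.threshold_percent == 30.0)]
print("\npatient-group correlations with pain change (30% threshold):")
for _, row in sel.iterrows():
    print(f"  {row.parameter:22s} r = {row.pearson_r:+.2f}  p = {row.pearson_p:.3f}  "
          f"(n = {row.n_pairs})")
print()
print("Occupancy climbs across sessions (the planted learning). Occupancy-type")
print("parameters correlate negatively with pain change, and the high-to-low")
print("switch rate positively: sessions with more time in the high alpha state")
print("come with larger pain reductions.")
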