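"""Run the full research-vs-real-world comparative study.

Generates all four cohorts, phenotypes them, consensus-extracts note scores
in the EMR-style cohort, derives events, and reports the headline
comparisons: diagnosis age, therapy-initiation timing, survival to key
events, progression slopes, and the proxy-vs-MMSE agreement (phi).
"""

from pdprog import StudyConfig, run_study

result = run_study(StudyConfig.default(seed=5, n_per_cohort=300,
                                       output_dir="scratch/study_demo"))

print("Cohort summary:")
cols = ["cohort", "n_included", "pct_male", "age_mean", "follow_up_mean"]
print(result.summary[cols].round(2).to_string(index=False))

print("\nSurvival comparisons (pooled research vs pooled real-world):")
cols = ["event_type", "median_research", "median_rwd", "logrank_p"]
print(result.survival[cols].to_string(index=False))

print("\nProgression fits:")
print(result.progression[["cohort", "scale", "slope", "intercept"]]
      .round(3).to_string(index=False))

print(f"\nProxy-vs-MMSE agreement: phi = {result.phi:.3f}")
print("\nReal-world-style cohorts are diagnosed older, start therapy later,")
print("reach H&Y 3 sooner, and progress faster on the UPDRS -- the")
print("directional contrasts the pipeline is designed to measure.")
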