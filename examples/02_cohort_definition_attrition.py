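"""Apply the new-onset PD cohort definition and read the attrition table.

Real-world patients must have a first PD code (the index), two years of
pre-index observability, a confirmation PD code 30+ days later, and no
parkinsonism-mimicking diagnosis during the quiescence window.  Each filter
removes some patients; the attrition table records the funnel.
"""

from pdprog import build_cohort, default_config, generate_population

records, truth = generate_population(default_config(n_per_cohort=400, seed=7))
emr = [r for r in records if r.cohort_label == "rwd_emr"]

entries, attrition = build_cohort(emr, mode="encounter")
print(attrition.to_frame().to_string(index=False))

excluded = [e for e in entries if not e.included]
reasons = {}
for e in excluded:
    for r in e.exclusion_reasons:
        reasons[r] = reasons.get(r, 0) + 1
print("\nExclusion reasons:", reasons)
print(f"Included {sum(e.included for e in entries)} of {len(entries)} "
      "patients; each row of the funnel applies one filter in fixed order.")
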