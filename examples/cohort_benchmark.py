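"""Benchmark practices on a synthetic cohort and flag outliers.

Generates a 60-patient prostate cohort spread over four practices, scores
every patient with the example measure set, aggregates per-practice pass
rates, and applies the exact-binomial outlier rule against the pooled rate.
"""

from rtqa import (
    flag_outliers,
    load_example_ruleset,
    make_cohort,
    score_patient,
    summarize,
)

cohort = make_cohort(60, ["Alfa", "Bravo", "Charlie", "Delta"], seed=7)
rules = load_example_ruleset("prostate")
cards = [score_patient(m.record, m.plan, m.constraint_report, rules)
         for m in cohort]
practice_of = {m.record.patient_key: m.practice_id for m in cohort}

summaries = summarize(cards, practice_of)
print(f"{'practice':10} {'measure':18} {'pass/n':>8}  rate")
for s in summaries:
    for mid in sorted(s.measures):
        m = s.measures[mid]
        rate = "  n/a" if m.pass_rate is None else f"{m.pass_rate:5.2f}"
        print(f"{s.practice_id:10} {mid:18} {m.n_pass:3}/{m.n_evaluable:<3}  {rate}")

out = flag_outliers(summaries, alpha=0.05)
print(f"\noutlier rule: {out['method']['rule']} "
      f"(alpha={out['method']['alpha']})")
if out["flags"]:
    for f in out["flags"]:
        print(f"  {f.practice_id} {f.measure_id}: {f.direction} "
              f"(practice {f.practice_rate:.2f} vs national {f.national_rate:.2f})")
else:
    print("  no practice falls outside its exact binomial interval")
# With only ~15 patients per practice the intervals are wide; flags appear
# only for departures far larger than sampling noise.
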