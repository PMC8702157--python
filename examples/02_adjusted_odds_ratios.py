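"""One-vs-rest adjusted odds ratios on a simulated cohort with known truth.

Simulates a large cohort in which interferon patients carry a planted 3.4-fold
odds of the composite outcome relative to the pooled other classes, then fits
the three one-vs-rest logistic models (each adjusted for age, sex and therapy
duration) and prints the recovered odds ratios.
"""

from rrms_cea import class_or_analysis
from rrms_cea.synth import SimulationParams, simulate_cohort

TRUE_OR = 3.4
p_rest = 0.30
odds_ifn = TRUE_OR * p_rest / (1 - p_rest)
p_ifn = odds_ifn / (1 + odds_ifn)

params = SimulationParams(
    arm_sizes={"ORAL": 1250, "IFN": 2500, "MAB": 1250},
    event_prob={"ORAL": p_rest, "IFN": p_ifn, "MAB": p_rest},
    seed=31,
)
cohort = simulate_cohort(params)
print(f"simulated cohort of {len(cohort)} patients; "
      f"true IFN-vs-rest composite odds ratio = {TRUE_OR}")

results, failures = class_or_analysis(cohort, "composite")
print("\nadjusted odds ratios (one model per class, class vs the other two):")
for res in results:
    print(
        f"  {res.exposure:4s}  OR {res.odds_ratio:5.3f}  "
        f"(95% CI {res.ci_low:5.3f}-{res.ci_high:5.3f})  p = {res.p_value:.2g}"
    )
for cls, msg in failures.items():
    print(f"  {cls}: model not estimable ({msg})")

print("\nThe IFN interval should cover 3.4; ORAL and MAB, sharing the baseline")
print("event rate, should sit below 1 (each is compared against a pool that")
print("includes the high-risk interferon arm).")
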