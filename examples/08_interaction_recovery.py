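"""Recover a planted additive interaction from a synthetic cohort.

Plants a logistic model with known cell odds ratios (OR10 = OR01 = 2,
multiplicative joint effect OR11 = 4, hence implied RERI = 1), simulates a
large cohort, and shows the crossover pipeline recovers the truth.
"""

import math

from circad import CohortConfig, EffectModel, generate_interaction_cohort, interaction_cis
from circad.interaction import CrossoverTable

model = EffectModel(
    intercept=-0.6,
    log_or_a=math.log(2.0),
    log_or_b=math.log(2.0),
    log_or_ab=0.0,
    prevalence_a=0.4,
    prevalence_b=0.3,
)
truth = model.implied_reri()
print(f"implied population RERI: {truth:.3f}\n")

covered = 0
for seed in range(1, 6):
    cfg = CohortConfig(n_cases=10_000, n_controls=10_000, effect_model=model, seed=seed)
    cohort = generate_interaction_cohort(cfg, "A", "B")
    cells = {}
    for a in (0, 1):
        for b in (0, 1):
            sub = cohort[(cohort.A == a) & (cohort.B == b)]
            cells[(a, b)] = (int((sub.group == "case").sum()), int((sub.group == "control").sum()))
    res = interaction_cis(CrossoverTable("A", "B", cells))
    inside = res.reri.lower <= truth <= res.reri.upper
    covered += inside
    print(f"seed {seed}: RERI {res.reri.value:.3f} "
          f"(95% CI {res.reri.lower:.3f}-{res.reri.upper:.3f})  covers truth: {inside}")

print(f"\n{covered}/5 intervals cover the planted RERI — a single 95% interval "
      "misses occasionally; the test suite checks 92-97% coverage over 500 replicates.")

# At multiplicative joint effects (OR11 = OR10*OR01) the additive-scale
# interaction is positive even though the logistic product term is zero:
# additivity and multiplicativity are different null hypotheses.
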