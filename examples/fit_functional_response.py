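"""Fit the four functional-response variants to one depletion experiment.

Generates a synthetic type-II feeding trial (known capture coefficient
b = 0.5, handling time h = 0.1), fits variants I, II, III and the
general model by binomial maximum likelihood on the Rogers depletion
expectation, and selects among them by AICc with the
proportional-consumption diagnostic.
"""

from benthic_encounters import (HollingParams, fit_all_variants,
                                select_response)
from benthic_encounters.synthetic_data import generate_trials, geometric_levels

true = HollingParams(b=0.5, h=0.1, q=0.0)
trials = generate_trials(true, geometric_levels(6), replicates=25, T=1.0,
                         seed=42, pair_id="demo")

fits = fit_all_variants(trials, compute_se=False)
print(f"{'variant':>8} {'b':>8} {'h':>8} {'q':>5} {'AICc':>9}")
for name, fit in fits.items():
    p = fit.params
    print(f"{name:>8} {p.b:8.4f} {p.h:8.4f} {p.q:5.2f} {fit.AICc:9.2f}")

best = select_response(fits, trials)
print(f"\nselected: variant {best.variant} "
      f"(diagnostic trend: {best.diagnostic_trend})")
print(f"true parameters were b={true.b}, h={true.h}, q={true.q}")
# The selected variant should be II (or the general model with q ~ 0),
# with b and h within ~20% of the generating values; the lowest AICc row
# is the most parsimonious model the data support.
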