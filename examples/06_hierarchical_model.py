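"""Hierarchical Bayesian inference on a planted approach-vs-avoid effect.

Simulates theta power for 10 patients x 4 electrodes x 30 trials with a
true approach-minus-avoid coefficient of 0.24 (on the raw scale), fits the
nested mixed model (patient and patient:electrode random intercepts), and
reports the posterior summary with P+, the fraction of posterior draws
above zero.
"""

import numpy as np
import pandas as pd

from aaconflict import bayes

rng = np.random.default_rng(8)
rows = []
for p in range(10):
    u_p = rng.normal(0, 0.3)
    for e in range(4):
        u_e = rng.normal(0, 0.3)
        for t in range(30):
            approach = t % 2 == 1
            rows.append(
                dict(
                    theta_power=0.1 + 0.24 * approach + u_p + u_e + rng.normal(0, 1),
                    period="approach" if approach else "avoid",
                    patient=f"p{p}",
                    electrode=f"e{e}",
                    conflict=True,
                    attack=False,
                    dots_collected=3,
                )
            )
data = pd.DataFrame(rows)

spec = bayes.build_model("theta_approach_avoid", data)
fit = bayes.fit(spec, data, seed=8, chains=2, iterations=1500, warmup=500)
print(fit.summary_frame(convergence_ess=400).to_string(index=False))
print(
    "\nresponse is z-scored, so the planted coefficient on the model scale "
    f"is {0.24 / data.theta_power.std():.3f}; "
    "P+ near 1 says the approach elevation is credibly positive"
)
ppc = bayes.posterior_predictive_check(fit, seed=1)
print(f"posterior predictive tail probabilities: "
      f"mean {ppc['mean']['tail_prob']:.2f}, sd {ppc['sd']['tail_prob']:.2f}")
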