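"""Worst-case inference for one matched sample across a Γ grid.

Simulated matched pairs with a genuine treatment effect: the weighted
M-statistic is tested against its worst-case null distribution for
increasing amounts of permitted hidden bias Γ.  The smallest Γ at which
the test stops rejecting is the sensitivity value.
"""

import numpy as np

from hetsens import (ScoreConfig, SensitivityModel, pvalue_upper,
                     scores_from_outcomes, statistic, worstcase_moments)

rng = np.random.default_rng(3)
I = 150
outcomes = [np.array([rng.normal() + 0.45, rng.normal()]) for _ in range(I)]
scores = scores_from_outcomes(outcomes, ScoreConfig(inner=0, outer=3))
t = statistic(scores, range(I)).value
print(f"{I} matched pairs, true shift 0.45; T = {t:.2f} "
      f"(scale s = {scores.s:.3f})")

print("\n  Gamma  theta_G  sigma_G  p-value")
sens = None
for gamma in np.arange(1.0, 2.61, 0.2).round(1):
    null = worstcase_moments(scores, range(I), SensitivityModel(gamma))
    p = pvalue_upper(t, null)
    print(f"  {gamma:5.1f} {null.theta:8.2f} {null.sigma:8.2f} {p:9.4f}")
    if sens is None and p > 0.05:
        sens = gamma
print(f"\nSensitivity value ≈ {sens}: an unmeasured confounder must "
      "multiply the odds of treatment by at least this factor to explain "
      "the effect away; p-values rise monotonically with Γ.")
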