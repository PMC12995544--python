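"""Optimal matching on a synthetic observational cohort.

Builds a small cohort with mild confounding, imputes missing covariates
(mean/mode fill plus missingness indicators), and forms optimal pairs by
rank-based Mahalanobis distance with a soft propensity-score caliper.
The balance report shows standardized mean differences shrinking after
matching.
"""

from hetsens import (MatchConstraints, apply_caliper, generate_fixture,
                     impute_two_step, pair_match, propensity_scores,
                     rank_mahalanobis, standardized_differences)

table = impute_two_step(generate_fixture(n_treated=60, n_control=180, p=12,
                                         missing_rate=0.03, seed=11))
print(f"cohort: {table.n_treated} treated, {table.n_control} controls, "
      f"{len(table.covariate_names)} covariates (incl. missingness "
      "indicators)")

dist = rank_mahalanobis(table)
dist = apply_caliper(dist, propensity_scores(table), MatchConstraints())
sample = pair_match(dist, MatchConstraints(), table)

report = standardized_differences(table, sample)
print(f"matched {sample.I} pairs at total distance "
      f"{sample.provenance['total_distance']:.1f}")
print(f"mean |SMD| before matching: {report['smd_before'].abs().mean():.3f}")
print(f"mean |SMD| after matching:  {report['smd_after'].abs().mean():.3f}")
print("Reading: standardized mean differences (treated - control, in "
      "pooled-SD units) move toward 0, i.e. the matched controls resemble "
      "the treated group on observables.")
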