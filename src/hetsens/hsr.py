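"""HSR: CART-discovered subgroups with closed testing over a Γ grid.

The pipeline pair-matches treated to controls with almost-exact matching on
the candidate modifiers, fits a regression tree to the absolute within-pair
differences, re-pairs inexact pairs within the tree's leaf-defined
subgroups, and then, for each value of the sensitivity parameter Γ, tests
every intersection of subgroup sharp nulls with the truncated product of
the member subgroups' worst-case p-values.  Closed testing turns the
intersection tests into familywise-valid subgroup rejections, and scanning
the Γ grid yields each hypothesis's sensitivity value (the smallest Γ at
which rejection is lost).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import ObservationalTable
from .matching import (MatchConstraints, MatchedSample, apply_almost_exact,
                       apply_caliper, pair_match, propensity_scores,
                       rank_mahalanobis, rematch_inexact)
from .mscore import (ScoreConfig, SensitivityModel, SetScores, pvalue_upper,
                     set_scores, statistic, worstcase_moments)
from .subgrouping import (SubgroupPartition, TreeParams, fit_tree,
                          pair_differences, partition_from_tree)

__all__ = [
    "TruncatedProduct",
    "ClosedTestResult",
    "truncated_product",
    "truncated_product_pvalue",
    "subgroup_pvalues",
    "closed_testing",
    "hsr_pipeline",
    "HsrResult",
]


@dataclass(frozen=True)
class TruncatedProduct:
    W: float
    alpha_tilde: float
    pvalue: float
    n_tests: int


def truncated_product_pvalue(w: float, n_tests: int, alpha_tilde: float) -> float:
    """Null probability that the truncated product is <= w.

    Under independent uniform p-values, with truncation threshold tau, the
    product W of the p-values below tau satisfies (conditioning on the
    number k of p-values below tau)

        P(W <= w) = sum_k C(G,k) (1-tau)^(G-k)
                    * [ w * sum_{s<k} (k ln tau - ln w)^s / s!   if w <= tau^k
                        tau^k                                    otherwise ].

    W = 1 (no p-value below the threshold) has probability (1-tau)^G, so
    its p-value is exactly 1.
    """
    tau = alpha_tilde
    if not (0 < tau <= 1):
        raise ValueError("alpha_tilde must lie in (0, 1]")
    if w >= 1.0:
        return 1.0
    if w <= 0.0:  # product underflowed: beyond double-precision tail
        return 0.0
    logw = math.log(w)
    logtau = math.log(tau)
    total = 0.0
    for k in range(1, n_tests + 1):
        weight = math.comb(n_tests, k) * (1 - tau) ** (n_tests - k)
        if logw <= k * logtau:
            u = k * logtau - logw  # >= 0
            # w * sum_s u^s / s!  computed stably in logs
            terms = [s * math.log(u) - gammaln(s + 1) if u > 0 else
                     (0.0 if s == 0 else -math.inf)
                     for s in range(k)]
            mx = max(terms)
            inner = math.exp(logw + mx) * sum(math.exp(t - mx) for t in terms)
            total += weight * inner
        else:
            total += weight * tau**k
    return min(total, 1.0)


def truncated_product(pvals, alpha_tilde: float = 0.05) -> TruncatedProduct:
    """Truncated product of p-values and its exact null p-value."""
    pvals = np.asarray(list(pvals), dtype=float)
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    below = pvals[pvals <= alpha_tilde]
    w = float(np.prod(below)) if below.size else 1.0
    p = truncated_product_pvalue(w, len(pvals), alpha_tilde)
    return TruncatedProduct(W=w, alpha_tilde=alpha_tilde, pvalue=p,
                            n_tests=len(pvals))


def subgroup_pvalues(scores: SetScores, partition: SubgroupPartition,
                     gamma: float, side: str = "upper") -> dict:
    """Worst-case p-value per subgroup at the given Γ.

    ``side``: "upper" / "lower" one-sided, or "two" = doubled smaller
    one-sided p-value, capped at 1.
    """
    out = {}
    for label in partition.labels:
        members = partition.groups[label]
        t = statistic(scores, members)
        ps = {}
        for direction in ("upper", "lower"):
            if side not in (direction, "two"):
                continue
            model = SensitivityModel(gamma=gamma, direction=direction)
            null = worstcase_moments(scores, members, model)
            tval = t.value if direction == "upper" else -t.value
            ps[direction] = pvalue_upper(tval, null)
        out[label] = (min(1.0, 2 * min(ps.values())) if side == "two"
                      else ps[side])
    return out


@dataclass
class ClosedTestResult:
    """Closed testing over the lattice of subgroup intersections."""

    pvalues: dict          # frozenset -> intersection p-value
    local_reject: dict     # frozenset -> local test rejected
    reject: dict           # frozenset -> familywise-valid rejection (closure)
    singletons: dict       # group label/index -> rejected
    alpha: float


def closed_testing(intersection_p, G: int, alpha: float = 0.05,
                   labels=None) -> ClosedTestResult:
    """Marcus closed testing over all nonempty subsets of G hypotheses.

    ``intersection_p`` maps a frozenset of group positions (0..G-1) to the
    p-value of the corresponding intersection null.  A hypothesis set K is
    rejected familywise-validly iff every superset's local test rejects.
    """
    if G > 20:
        raise ValueError("closed testing over more than 20 groups is "
                         "infeasible; consider the submax procedure")
    labels = list(labels) if labels is not None else list(range(G))
    subsets = [frozenset(c) for r in range(1, G + 1)
               for c in itertools.combinations(range(G), r)]
    pvals = {s: float(intersection_p(s)) for s in subsets}
    local = {s: pvals[s] <= alpha for s in subsets}
    reject = {s: all(local[t] for t in subsets if t >= s) for s in subsets}
    singles = {labels[g]: reject[frozenset([g])] for g in range(G)}
    return ClosedTestResult(pvalues=pvals, local_reject=local, reject=reject,
                            singletons=singles, alpha=alpha)


def closed_testing_from_groups(group_pvalues: dict, alpha: float = 0.05,
                               alpha_tilde: float = 0.05) -> ClosedTestResult:
    """Closed testing with truncated-product intersection tests."""
    labels = list(group_pvalues)
    pv = [group_pvalues[lbl] for lbl in labels]

    def inter_p(subset):
        return truncated_product([pv[g] for g in subset], alpha_tilde).pvalue

    return closed_testing(inter_p, len(labels), alpha, labels=labels)


@dataclass
class HsrResult:
    sample: MatchedSample
    tree: object
    partition: SubgroupPartition
    table: pd.DataFrame               # rows Γ, columns intersections
    rejections: pd.DataFrame          # same shape, closed-testing rejections
    sensitivity_values: dict          # column -> smallest Γ losing rejection
    n_excluded_pairs: int = 0
    results_by_gamma: dict = field(default_factory=dict)


def _subset_label(labels, subset) -> str:
    return "&".join(labels[g] for g in sorted(subset))


def hsr_pipeline(table: ObservationalTable, pem_keys, gamma_grid,
                 config: ScoreConfig | None = None, alpha: float = 0.05,
                 alpha_tilde: float = 0.05, side: str = "two",
                 constraints: MatchConstraints | None = None,
                 tree_params: TreeParams | None = None,
                 sample: MatchedSample | None = None) -> HsrResult:
    """Run the full HSR analysis on an observational table.

    Steps: optimal pair match (rank-Mahalanobis + soft caliper +
    almost-exact on the candidate modifiers) -> within-pair differences ->
    regression tree on |Y| -> re-pair inexact pairs within leaf-defined
    subgroups -> for each Γ in the grid, subgroup worst-case p-values,
    truncated-product intersection tests and closed testing.  A
    pre-constructed ``sample`` (e.g. from the simulation generator)
    bypasses the matching step.
    """
    config = config or ScoreConfig()
    pem_keys = list(pem_keys)
    if sample is None:
        constraints = constraints or MatchConstraints(exact_keys=tuple(pem_keys))
        dist = rank_mahalanobis(table)
        scores_ps = propensity_scores(table)
        dist = apply_caliper(dist, scores_ps, constraints)
        dist = apply_almost_exact(dist, table, pem_keys,
                                  penalty=constraints.exact_penalty)
        sample = pair_match(dist, constraints, table)

    records = pair_differences(sample, table, pem_keys)
    tree = fit_tree(records, pem_keys, tree_params)

    if tree.L > 0:
        # exact agreement on the leaf assignment = exact on the selected
        # covariates as dichotomized by the tree
        leaf_col = tree.assign(table.covariates[pem_keys])
        aug = ObservationalTable(
            ids=table.ids.copy(), z=table.z.copy(), r=table.r.copy(),
            covariates=table.covariates.assign(__leaf__=leaf_col),
            covariate_types=dict(table.covariate_types, __leaf__="categorical"))
        sample = rematch_inexact(sample, aug, ["__leaf__"])
    partition = partition_from_tree(sample, table, tree)
    scores = set_scores(sample, table, config)
    pos = {s.set_index: i for i, s in enumerate(sample.sets)}
    partition = SubgroupPartition(
        groups={lbl: [pos[i] for i in partition.groups[lbl]]
                for lbl in partition.labels},
        labels=partition.labels)

    labels = partition.labels
    rows_p, rows_r, results = [], [], {}
    for gamma in gamma_grid:
        gp = subgroup_pvalues(scores, partition, gamma, side=side)
        res = closed_testing_from_groups(gp, alpha=alpha,
                                         alpha_tilde=alpha_tilde)
        results[gamma] = res
        rows_p.append({_subset_label(labels, s): res.pvalues[s]
                       for s in res.pvalues})
        rows_r.append({_subset_label(labels, s): res.reject[s]
                       for s in res.reject})
    ptab = pd.DataFrame(rows_p, index=pd.Index(list(gamma_grid), name="gamma"))
    rtab = pd.DataFrame(rows_r, index=ptab.index)
    sens = {}
    for col in rtab.columns:
        lost = rtab.index[~rtab[col]]
        sens[col] = float(lost[0]) if len(lost) else math.inf
    return HsrResult(sample=sample, tree=tree, partition=partition,
                     table=ptab, rejections=rtab, sensitivity_values=sens,
                     n_excluded_pairs=records.attrs.get("n_excluded", 0),
                     results_by_gamma=results)
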