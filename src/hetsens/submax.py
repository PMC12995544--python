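"""The subgroup-maximum (submax) family of sensitivity analyses.

Each of L binary effect modifiers splits the matched population into two
subpopulations, giving K = 2L + 1 comparisons: the overall population plus
both halves per modifier.  A matched set participates in a comparison only
if it is exactly matched on every covariate defining that comparison (the
overall comparison admits every set).  For each Γ, the studentized deviate
of comparison k is

    D_Γk = (T_k - θ_Γk) / σ_Γk,

where T_k sums the weighted treated-member scores over the comparison's
sets and (θ_Γk, σ_Γk) are the worst-case null moments.  Under the overall
sharp null the vector D_Γ is asymptotically normal with correlation ρ_Γ
determined by the shared sets between comparisons; the overall test refers
max_k D_Γk to κ_Γα, the 1-α quantile of the maximum of that correlated
normal vector.  Closed testing over subsets of comparisons then gives
familywise-valid rejections per subpopulation, and submax+ seeds the
modifiers from a regression tree fit to within-pair absolute differences.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtri

from ._mvn import rectangle_probability
from .io import ObservationalTable, ValidationError
from .matching import (MatchConstraints, MatchedSample, apply_almost_exact,
                       apply_caliper, pair_match, propensity_scores,
                       rank_mahalanobis, variable_ratio_match)
from .mscore import (ScoreConfig, SensitivityModel, SetScores,
                     set_scores, set_worstcase_components)
from .subgrouping import TreeParams, fit_tree, pair_differences

__all__ = [
    "ContrastFamily",
    "DeviateVector",
    "CriticalValue",
    "SubmaxClosedResult",
    "build_contrasts",
    "deviates",
    "correlation",
    "critical_value",
    "submax_test",
    "closed_testing_submax",
    "sensitivity_value",
    "submax_pipeline",
    "submax_plus_pipeline",
]

#: exhaustive closed testing is enumerated up to this many comparisons;
#: beyond it, singletons fall back to the conservative global-κ rule
_MAX_ENUM_K = 15


@dataclass
class ContrastFamily:
    """The K = 2L+1 comparisons with their set-level memberships."""

    labels: list                 # length K; labels[0] is the overall comparison
    members: list                # list of int arrays (positions in the sample)
    modifier_keys: list

    @property
    def K(self) -> int:  # noqa: E743
        return len(self.labels)

    @property
    def L(self) -> int:  # noqa: E743
        return len(self.modifier_keys)


@dataclass(frozen=True)
class DeviateVector:
    d: np.ndarray
    gamma: float
    labels: tuple

    @property
    def dmax(self) -> float:
        return float(self.d.max())


@dataclass(frozen=True)
class CriticalValue:
    kappa: float
    alpha: float
    dim: int


def build_contrasts(sample: MatchedSample, table: ObservationalTable,
                    modifier_keys) -> ContrastFamily:
    """Comparisons from L binary modifiers with partial set membership.

    A set is exactly matched on a key when all its members share the key's
    value; it joins a modifier's comparison only then, but always joins
    the overall comparison.  Keys must be binary 0/1.
    """
    modifier_keys = list(modifier_keys)
    idx = {uid: i for i, uid in enumerate(table.ids)}
    vals = table.covariates[modifier_keys] if modifier_keys else None

    matched_value = {}  # (set position, key) -> 0/1 or None when inexact
    for pos, s in enumerate(sample.sets):
        for key in modifier_keys:
            member_vals = pd.to_numeric(
                vals[key].iloc[[idx[m] for m in s.member_ids]], errors="coerce")
            if member_vals.isna().any() or not member_vals.isin([0, 1]).all():
                raise ValidationError(f"modifier {key!r} must be binary 0/1")
            uniq = member_vals.unique()
            matched_value[(pos, key)] = int(uniq[0]) if len(uniq) == 1 else None

    labels = ["overall"]
    members = [np.arange(len(sample.sets))]
    for key in modifier_keys:
        for level in (1, 0):
            labels.append(f"{key}={level}")
            members.append(np.array(
                [pos for pos in range(len(sample.sets))
                 if matched_value[(pos, key)] == level], dtype=int))
    return ContrastFamily(labels=labels, members=members,
                          modifier_keys=modifier_keys)


def _components(scores: SetScores, family: ContrastFamily,
                model: SensitivityModel):
    """Worst-case per-set mean/variance contributions, computed once."""
    all_sets = range(scores.I)
    means, variances = set_worstcase_components(scores, all_sets, model)
    sign = 1.0 if model.direction == "upper" else -1.0
    tq = sign * np.array([scores.w[i] * scores.q[i][0] for i in all_sets])
    return tq, means, variances


def deviates(scores: SetScores, family: ContrastFamily,
             model: SensitivityModel) -> DeviateVector:
    """Studentized worst-case deviates D_Γk for every comparison."""
    tq, means, variances = _components(scores, family, model)
    d = np.empty(family.K)
    for k, mem in enumerate(family.members):
        if mem.size == 0:
            raise ValidationError(f"comparison {family.labels[k]!r} is empty")
        var = variances[mem].sum()
        if var <= 0:
            raise ValidationError(
                f"degenerate comparison {family.labels[k]!r} (zero variance)")
        d[k] = (tq[mem].sum() - means[mem].sum()) / math.sqrt(var)
    return DeviateVector(d=d, gamma=model.gamma, labels=tuple(family.labels))


def correlation(scores: SetScores, family: ContrastFamily,
                model: SensitivityModel) -> np.ndarray:
    """Correlation ρ_Γ of the deviates via shared-set variance sums."""
    _, _, variances = _components(scores, family, model)
    K = family.K
    M = np.zeros((K, scores.I))
    for k, mem in enumerate(family.members):
        M[k, mem] = 1.0
    cov = (M * variances) @ M.T
    sd = np.sqrt(np.diag(cov))
    rho = cov / np.outer(sd, sd)
    np.fill_diagonal(rho, 1.0)
    return rho


def critical_value(rho: np.ndarray, alpha: float) -> CriticalValue:
    """κ_Γα: the 1-α quantile of max_k X_k for X ~ N(0, ρ).

    Solved by bracketing root search on the deterministic rectangle
    probability, to an absolute tolerance of 1e-4 on κ.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    K = rho.shape[0]
    if K == 1:
        return CriticalValue(kappa=float(ndtri(1 - alpha)), alpha=alpha, dim=1)
    smallest = float(np.linalg.eigvalsh(rho).min())
    if smallest < -1e-8:
        raise ValueError(f"correlation matrix is not PSD "
                         f"(smallest eigenvalue {smallest:.3e})")

    def fn(k):
        return rectangle_probability(np.full(K, k), rho) - (1 - alpha)

    lo = float(ndtri(1 - alpha)) - 1e-6
    hi = float(ndtri((1 - alpha) ** (1.0 / K))) + 0.25
    flo, fhi = fn(lo), fn(hi)
    while fhi < 0:  # widen for (unusual) negative-correlation families
        hi += 0.5
        fhi = fn(hi)
    if flo >= 0:
        return CriticalValue(kappa=lo, alpha=alpha, dim=K)
    kappa = brentq(fn, lo, hi, xtol=1e-5)
    return CriticalValue(kappa=float(kappa), alpha=alpha, dim=K)


def submax_test(dev: DeviateVector, rho: np.ndarray, alpha: float = 0.05):
    """Overall test: reject when D_Γmax >= κ_Γα; returns (reject, p-value)."""
    rho = np.atleast_2d(rho)
    if rho.shape[0] != dev.d.size:
        raise ValueError("correlation dimension does not match deviates")
    kappa = critical_value(rho, alpha).kappa
    p = 1.0 - rectangle_probability(np.full(dev.d.size, dev.dmax), rho)
    return dev.dmax >= kappa, float(p)


@dataclass
class SubmaxClosedResult:
    local_reject: dict     # frozenset of comparison positions -> local test
    reject: dict           # frozenset -> familywise-valid (closure)
    singletons: dict       # comparison label -> rejected
    kappa_full: float
    alpha: float
    exhaustive: bool = True


def closed_testing_submax(dev: DeviateVector, rho: np.ndarray,
                          alpha: float = 0.05) -> SubmaxClosedResult:
    """Closed testing over subsets of comparisons.

    H_J is locally rejected when max_{k in J} D_Γk >= κ from the |J|-dim
    correlation submatrix; the closure rejects H_J when every superset is
    locally rejected.  Because κ_J <= κ_full for any subfamily, a subset
    whose max deviate clears the full-family κ is rejected without
    recomputing κ (identical result, much faster).  Beyond _MAX_ENUM_K
    comparisons the exhaustive lattice is infeasible and singletons use
    the conservative global-κ rule D_k >= κ_full.
    """
    rho = np.atleast_2d(rho)
    K = dev.d.size
    kappa_full = critical_value(rho, alpha).kappa
    full = frozenset(range(K))
    labels = list(dev.labels)

    if dev.dmax < kappa_full:
        # nothing survives the closure
        return SubmaxClosedResult(local_reject={full: False},
                                  reject={full: False},
                                  singletons={lbl: False for lbl in labels},
                                  kappa_full=kappa_full, alpha=alpha)
    if K > _MAX_ENUM_K:
        singles = {labels[k]: bool(dev.d[k] >= kappa_full) for k in range(K)}
        return SubmaxClosedResult(local_reject={full: True},
                                  reject={full: True}, singletons=singles,
                                  kappa_full=kappa_full, alpha=alpha,
                                  exhaustive=False)

    local = {}
    for r in range(1, K + 1):
        for comb in itertools.combinations(range(K), r):
            J = frozenset(comb)
            maxd = float(dev.d[list(comb)].max())
            if maxd >= kappa_full:
                local[J] = True
            else:
                sub = rho[np.ix_(list(comb), list(comb))]
                local[J] = maxd >= critical_value(sub, alpha).kappa
    reject = {J: all(local[Jp] for Jp in local if Jp >= J) for J in local}
    singles = {labels[k]: reject[frozenset([k])] for k in range(K)}
    return SubmaxClosedResult(local_reject=local, reject=reject,
                              singletons=singles, kappa_full=kappa_full,
                              alpha=alpha)


def sensitivity_value(test_at_gamma, grid) -> float:
    """Smallest Γ on the grid at which the test fails to reject.

    Returns the grid's first non-rejecting Γ (monotone search; worst-case
    p-values are nondecreasing in Γ), 1 when never rejected, and +inf when
    rejection holds through the grid maximum (report as "> grid max").
    """
    grid = list(grid)
    if not grid or grid[0] < 1:
        raise ValueError("grid must be increasing from 1")
    for gamma in grid:
        if not test_at_gamma(gamma):
            return float(gamma)
    return math.inf


@dataclass
class SubmaxResult:
    sample: MatchedSample
    family: ContrastFamily
    table: pd.DataFrame            # rows Γ: deviates, Dmax, κ, p
    rejections: pd.DataFrame       # closed-testing singleton rejections
    sensitivity_values: dict
    tree: object | None = None
    results_by_gamma: dict = field(default_factory=dict)


def _run_submax_grid(scores: SetScores, family: ContrastFamily, gamma_grid,
                     alpha: float, two_sided: bool) -> tuple:
    level = alpha / 2 if two_sided else alpha
    rows, rej_rows, results = [], [], {}
    for gamma in gamma_grid:
        per_gamma = {}
        for direction in (("upper", "lower") if two_sided else ("upper",)):
            model = SensitivityModel(gamma=gamma, direction=direction)
            dev = deviates(scores, family, model)
            rho = correlation(scores, family, model)
            res = closed_testing_submax(dev, rho, level)
            pmax = 1.0 - rectangle_probability(np.full(dev.d.size, dev.dmax),
                                               rho)
            per_gamma[direction] = (dev, res, float(pmax))
        results[gamma] = per_gamma
        dev_u = per_gamma["upper"][0]
        row = {lbl: dev_u.d[k] for k, lbl in enumerate(family.labels)}
        row["Dmax"] = dev_u.dmax
        row["kappa"] = per_gamma["upper"][1].kappa_full
        row["pvalue"] = per_gamma["upper"][2]
        rows.append(row)
        rej_rows.append({lbl: any(pg[1].singletons[lbl]
                                  for pg in per_gamma.values())
                         for lbl in family.labels})
    idx = pd.Index(list(gamma_grid), name="gamma")
    tab = pd.DataFrame(rows, index=idx)
    rej = pd.DataFrame(rej_rows, index=idx)
    sens = {}
    for lbl in family.labels:
        lost = rej.index[~rej[lbl]]
        sens[lbl] = float(lost[0]) if len(lost) else math.inf
    return tab, rej, sens, results


def submax_pipeline(table: ObservationalTable, modifier_keys, gamma_grid,
                    config: ScoreConfig | None = None, alpha: float = 0.05,
                    two_sided: bool = False,
                    constraints: MatchConstraints | None = None,
                    sample: MatchedSample | None = None) -> SubmaxResult:
    """submax with prespecified binary modifiers.

    Variable-ratio matching with almost-exact matching on the modifiers,
    then the maximum-deviate test and closed testing per Γ.  Two-sided
    testing runs both tails at α/2 and rejects when either does.
    """
    config = config or ScoreConfig()
    modifier_keys = list(modifier_keys)
    if sample is None:
        constraints = constraints or MatchConstraints(
            exact_keys=tuple(modifier_keys), control_ratio=(1, 3))
        dist = rank_mahalanobis(table)
        ps = propensity_scores(table)
        dist = apply_caliper(dist, ps, constraints)
        if modifier_keys:
            dist = apply_almost_exact(dist, table, modifier_keys,
                                      penalty=constraints.exact_penalty)
        sample = (pair_match(dist, constraints, table)
                  if constraints.control_ratio == (1, 1)
                  else variable_ratio_match(dist, constraints, table))
    family = build_contrasts(sample, table, modifier_keys)
    scores = set_scores(sample, table, config)
    tab, rej, sens, results = _run_submax_grid(scores, family, gamma_grid,
                                               alpha, two_sided)
    return SubmaxResult(sample=sample, family=family, table=tab,
                        rejections=rej, sensitivity_values=sens,
                        results_by_gamma=results)


def submax_plus_pipeline(table: ObservationalTable, pem_keys, gamma_grid,
                         config: ScoreConfig | None = None,
                         alpha: float = 0.05, two_sided: bool = False,
                         constraints: MatchConstraints | None = None,
                         tree_params: TreeParams | None = None,
                         pair_sample: MatchedSample | None = None,
                         analysis_sample: MatchedSample | None = None) -> SubmaxResult:
    """submax+: modifiers seeded by a regression tree.

    A pair match on the candidate modifiers feeds the tree on |Y|; the
    tree's splitting variables, dichotomized at its split points, become
    the binary modifiers for a variable-ratio submax analysis.  When the
    tree selects no variable the procedure reduces to the overall-only
    submax (K = 1).
    """
    config = config or ScoreConfig()
    pem_keys = list(pem_keys)
    if pair_sample is None:
        pc = MatchConstraints(exact_keys=tuple(pem_keys))
        dist = rank_mahalanobis(table)
        ps = propensity_scores(table)
        dist = apply_caliper(dist, ps, pc)
        dist = apply_almost_exact(dist, table, pem_keys)
        pair_sample = pair_match(dist, pc, table)
    records = pair_differences(pair_sample, table, pem_keys)
    tree = fit_tree(records, pem_keys, tree_params)

    # dichotomize the selected variables at the tree's (first) split point
    split_points = {}
    for name, threshold in tree.splits:
        split_points.setdefault(name, threshold)
    derived = {}
    for name, threshold in split_points.items():
        col = pd.to_numeric(table.covariates[name], errors="coerce")
        derived[f"{name}>{threshold:g}"] = (col > threshold).astype(int)

    if derived:
        aug = ObservationalTable(
            ids=table.ids.copy(), z=table.z.copy(), r=table.r.copy(),
            covariates=table.covariates.assign(**derived),
            covariate_types={**table.covariate_types,
                             **{k: "numeric" for k in derived}})
    else:
        aug = table
    keys = list(derived)

    sample = analysis_sample
    if sample is None:
        constraints = constraints or MatchConstraints(
            exact_keys=tuple(keys), control_ratio=(1, 3))
        dist = rank_mahalanobis(aug)
        ps = propensity_scores(aug)
        dist = apply_caliper(dist, ps, constraints)
        if keys:
            dist = apply_almost_exact(dist, aug, keys)
        sample = variable_ratio_match(dist, constraints, aug)
    elif derived:
        pass  # caller-provided analysis sample reused with derived columns

    family = build_contrasts(sample, aug, keys)
    scores = set_scores(sample, aug, config)
    tab, rej, sens, results = _run_submax_grid(scores, family, gamma_grid,
                                               alpha, two_sided)
    return SubmaxResult(sample=sample, family=family, table=tab,
                        rejections=rej, sensitivity_values=sens, tree=tree,
                        results_by_gamma=results)
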