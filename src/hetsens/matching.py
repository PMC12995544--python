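"""Optimal matching of treated to control units.

Distances are rank-based Mahalanobis distances (squared form, as is
conventional for matching), optionally augmented by a soft propensity-score
caliper and almost-exact penalties.  Assignment is solved as a minimum-cost
flow problem, which covers optimal pair matching, optimal variable-ratio
matching, and near-fine balance through category-slot nodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .io import ObservationalTable, ValidationError, expand_categoricals

logger = logging.getLogger("hetsens.matching")

__all__ = [
    "DistanceMatrix",
    "MatchConstraints",
    "MatchedSet",
    "MatchedSample",
    "MatchingInfeasibleError",
    "rank_mahalanobis",
    "propensity_scores",
    "apply_caliper",
    "apply_almost_exact",
    "pair_match",
    "variable_ratio_match",
    "evaluate_fine_balance",
    "standardized_differences",
    "rematch_inexact",
]

#: integer cost resolution for the flow solver (relative to max finite cost)
_COST_RESOLUTION = 10**6


class MatchingInfeasibleError(RuntimeError):
    """No assignment satisfying the constraints has finite total cost."""


@dataclass
class DistanceMatrix:
    """Treated-by-control cost matrix; +inf forbids a pairing."""

    matrix: np.ndarray
    treated_ids: np.ndarray
    control_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.treated_ids), len(self.control_ids)):
            raise ValueError("distance matrix shape does not match unit counts")
        finite = self.matrix[np.isfinite(self.matrix)]
        if finite.size and finite.min() < 0:
            raise ValueError("distances must be nonnegative")

    def copy(self) -> "DistanceMatrix":
        return DistanceMatrix(self.matrix.copy(), self.treated_ids, self.control_ids)


@dataclass
class MatchConstraints:
    """Devices steering the optimal match.

    caliper_width is on the propensity-score scale (None = 0.2 SD of the
    scores); the caliper is soft: pairings beyond the width incur a penalty
    proportional to the excess gap.  exact_keys get dominant additive
    penalties (almost-exact matching).  balance_keys get near-fine balance
    through category slots.  control_ratio (min, max) is the allowed number
    of controls per treated unit; (1, 1) is pair matching.
    """

    caliper_width: float | None = None
    caliper_penalty: float = 1000.0
    exact_keys: tuple = ()
    balance_keys: tuple = ()
    control_ratio: tuple = (1, 1)
    total_controls: int | None = None
    balance_penalty: float | None = None
    exact_penalty: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.control_ratio
        if lo < 1 or hi < lo:
            raise ValueError("control_ratio must satisfy 1 <= min <= max")
        if self.caliper_width is not None and self.caliper_width <= 0:
            raise ValueError("caliper_width must be positive")


@dataclass
class MatchedSet:
    set_index: int
    treated_id: object
    control_ids: list

    def __post_init__(self) -> None:
        members = [self.treated_id, *self.control_ids]
        if len(self.control_ids) < 1:
            raise ValueError("a matched set needs at least one control")
        if len(set(map(str, members))) != len(members):
            raise ValueError("matched set members must be distinct")

    @property
    def n(self) -> int:
        return 1 + len(self.control_ids)

    @property
    def member_ids(self) -> list:
        return [self.treated_id, *self.control_ids]


@dataclass
class MatchedSample:
    sets: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for s in self.sets:
            for uid in s.member_ids:
                if uid in seen:
                    raise ValueError(f"unit {uid!r} appears in two matched sets")
                seen.add(uid)
        if len(self.sets) < 1:
            raise ValueError("a matched sample needs at least one set")

    @property
    def I(self) -> int:  # noqa: E743 - field-standard name
        return len(self.sets)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sets:
            rows.append({"set_index": s.set_index, "unit_id": s.treated_id,
                         "role": "treated"})
            rows.extend({"set_index": s.set_index, "unit_id": c, "role": "control"}
                        for c in s.control_ids)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distances


def rank_mahalanobis(table: ObservationalTable) -> DistanceMatrix:
    """Squared Mahalanobis distance on covariate ranks.

    Each covariate (categoricals expanded to level indicators) is replaced
    by its ranks over all units, with average ranks for ties; the distance
    uses the covariance matrix of the ranks, regularized on the diagonal if
    singular.  Ranks make the distance invariant to strictly monotone
    transforms of any covariate and resistant to outliers.
    """
    design = expand_categoricals(table)
    ranks = design.apply(lambda c: rankdata(c, method="average"), axis=0)
    keep = ranks.std(ddof=0) > 0
    dropped = list(ranks.columns[~keep])
    if dropped:
        warnings.warn(f"dropping zero-variance covariates from distance: {dropped}")
        ranks = ranks.loc[:, keep]
    if ranks.shape[1] == 0:
        raise ValidationError("no covariates with variation; cannot build distances")
    rk = ranks.to_numpy(float)
    cov = np.cov(rk, rowvar=False)
    cov = np.atleast_2d(cov)
    p = cov.shape[0]
    if np.linalg.matrix_rank(cov) < p:
        cov = cov + np.eye(p) * 1e-6 * np.trace(cov) / p
    vi = np.linalg.inv(cov)
    tmask = table.z == 1
    diff = cdist(rk[tmask], rk[~tmask], metric="mahalanobis", VI=vi)
    return DistanceMatrix(diff**2, table.ids[tmask], table.ids[~tmask])


def propensity_scores(table: ObservationalTable) -> pd.Series:
    """Estimated probability of treatment given covariates.

    Main-effects logistic fit on the (imputed, expanded) covariates.  Under
    perfect separation or non-convergence the fit falls back to a
    ridge-penalized logistic model, with a logged warning.
    """
    import statsmodels.api as sm

    design = expand_categoricals(table)
    design = design.loc[:, design.std(ddof=0) > 0]
    if design.shape[1]:
        # drop columns collinear with the intercept + earlier columns
        # (full one-hot expansions are otherwise rank deficient)
        from scipy.linalg import qr

        M = np.column_stack([np.ones(table.n),
                             design.to_numpy(float)])
        _, R, piv = qr(M, mode="economic", pivoting=True)
        tol = abs(R[0, 0]) * 1e-10
        rank = int((np.abs(np.diag(R)) > tol).sum())
        keep = sorted(j - 1 for j in piv[:rank] if j > 0)
        design = design.iloc[:, keep]
    z = table.z.astype(float)
    if design.shape[1] == 0:
        score = np.full(table.n, z.mean())
        return pd.Series(score, index=table.ids, name="propensity")
    X = sm.add_constant((design - design.mean()) / design.std(ddof=0))
    fitted = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(z, X).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and \
                    np.abs(res.params.to_numpy()).max() < 30:
                fitted = np.asarray(res.predict(X))
        except Exception:
            fitted = None
    if fitted is None:
        from sklearn.linear_model import LogisticRegression

        logger.warning("logistic fit separated or failed to converge; "
                       "falling back to ridge-penalized fit")
        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(design.to_numpy(float), table.z)
        fitted = clf.predict_proba(design.to_numpy(float))[:, 1]
    fitted = np.clip(fitted, 1e-9, 1 - 1e-9)
    return pd.Series(fitted, index=table.ids, name="propensity")


def apply_caliper(dist: DistanceMatrix, scores: pd.Series,
                  constraints: MatchConstraints) -> DistanceMatrix:
    """Soft propensity caliper: penalize pairings with large score gaps.

    Entries whose |score gap| exceeds the caliper width w gain
    ``penalty * (gap - w) / w``; entries within the width are unchanged.
    """
    out = dist.copy()
    st = scores.loc[dist.treated_ids].to_numpy(float)
    sc = scores.loc[dist.control_ids].to_numpy(float)
    width = constraints.caliper_width
    if width is None:
        width = 0.2 * float(np.std(scores.to_numpy(float)))
        if width <= 0:
            return out
    gap = np.abs(st[:, None] - sc[None, :])
    excess = np.maximum(gap - width, 0.0)
    out.matrix = out.matrix + constraints.caliper_penalty * excess / width
    return out


def apply_almost_exact(dist: DistanceMatrix, table: ObservationalTable,
                       exact_keys, penalty: float | None = None) -> DistanceMatrix:
    """Add a dominant penalty per exact-key disagreement.

    The default penalty, 1000 x the largest finite base distance, exceeds
    any possible total of base distances, so assignments with fewer
    disagreements are always preferred when feasible.
    """
    out = dist.copy()
    finite = out.matrix[np.isfinite(out.matrix)]
    if penalty is None:
        penalty = 1000.0 * (float(finite.max()) if finite.size else 1.0)
        penalty = max(penalty, 1.0)
    for key in exact_keys:
        if key not in table.covariates.columns:
            raise KeyError(f"exact key {key!r} not in table")
        vals = table.covariates[key].to_numpy()
        vt = vals[table.z == 1]
        vc = vals[table.z == 0]
        disagree = vt[:, None] != vc[None, :]
        out.matrix = out.matrix + penalty * disagree
    return out


# ---------------------------------------------------------------------------
# assignment via minimum-cost flow


def _integer_costs(matrix: np.ndarray) -> np.ndarray:
    finite = matrix[np.isfinite(matrix)]
    if finite.size == 0:
        return np.full(matrix.shape, -1, dtype=object)
    scale = _COST_RESOLUTION / max(1.0, float(finite.max()))
    out = np.where(np.isfinite(matrix), np.round(matrix * scale), -1.0)
    return out.astype(np.int64)


def _min_cost_match(dist: DistanceMatrix, lo: int, hi: int,
                    control_categories: np.ndarray | None = None,
                    slots: dict | None = None,
                    balance_penalty_int: int | None = None,
                    total: int | None = None) -> list:
    """Solve the assignment; returns a list of (treated_pos, [control_pos]).

    ``total`` fixes the number of controls used overall (between nt*lo and
    nt*hi); otherwise the cheapest admissible count is used.
    """
    nt, nc = dist.matrix.shape
    if nc < nt * lo:
        raise MatchingInfeasibleError(
            f"need at least {nt * lo} controls for {nt} treated units "
            f"at ratio >= {lo}; only {nc} available")
    if total is not None and not (nt * lo <= total <= min(nt * hi, nc)):
        raise MatchingInfeasibleError(
            f"total_controls={total} incompatible with {nt} treated at "
            f"ratio ({lo}, {hi}) and {nc} controls")
    cost = _integer_costs(dist.matrix)
    no_edge = ~np.isfinite(dist.matrix)
    dead = np.flatnonzero(no_edge.all(axis=1))
    if dead.size:
        raise MatchingInfeasibleError(
            "treated units with no admissible control: "
            f"{list(dist.treated_ids[dead])}")

    G = nx.DiGraph()
    extra = nt * (hi - lo)
    G.add_node("S", demand=-extra)
    G.add_node("T", demand=nt * hi)
    bypass = extra if total is None else nt * hi - total
    if bypass:
        # with a fixed total the bypass must be saturated at any optimum:
        # a tiny negative weight makes that strict without affecting which
        # control assignments are chosen
        G.add_edge("S", "T", capacity=bypass,
                   weight=0 if total is None else -1)
    for i in range(nt):
        G.add_node(("t", i), demand=-lo)
        if hi > lo:
            G.add_edge("S", ("t", i), capacity=hi - lo, weight=0)
    for j in range(nc):
        G.add_node(("c", j), demand=0)
    rows, cols = np.nonzero(~no_edge)
    for i, j in zip(rows.tolist(), cols.tolist()):
        G.add_edge(("t", int(i)), ("c", int(j)), capacity=1,
                   weight=int(cost[i, j]))
    if control_categories is None:
        for j in range(nc):
            G.add_edge(("c", j), "T", capacity=1, weight=0)
    else:
        G.add_node("OVF", demand=0)
        G.add_edge("OVF", "T", capacity=nt * hi, weight=0)
        for cat in np.unique(control_categories):
            G.add_node(("b", cat), demand=0)
            G.add_edge(("b", cat), "T", capacity=int(slots.get(cat, 0)), weight=0)
            G.add_edge(("b", cat), "OVF", capacity=nt * hi,
                       weight=int(balance_penalty_int))
        for j in range(nc):
            G.add_edge(("c", j), ("b", control_categories[j]), capacity=1, weight=0)
    try:
        flow = nx.min_cost_flow(G)
    except nx.NetworkXUnfeasible as exc:
        raise MatchingInfeasibleError(
            "no feasible assignment under the given constraints") from exc
    result = []
    for i in range(nt):
        chosen = [j for (_, j), f in
                  ((edge, f) for edge, f in flow[("t", i)].items())
                  if f > 0]
        result.append((i, sorted(chosen)))
    return result


def _balance_layout(table: ObservationalTable, dist: DistanceMatrix,
                    constraints: MatchConstraints):
    """Joint balance categories for controls plus treated-derived slots."""
    keys = list(constraints.balance_keys)
    if not keys:
        return None, None, None
    vals = table.covariates[keys].astype(str)
    joint = vals.agg("|".join, axis=1).to_numpy()
    cpos = {uid: table.index_of(uid) for uid in dist.control_ids}
    tpos = {uid: table.index_of(uid) for uid in dist.treated_ids}
    control_cats = np.array([joint[cpos[uid]] for uid in dist.control_ids])
    treated_cats = np.array([joint[tpos[uid]] for uid in dist.treated_ids])
    _, hi = constraints.control_ratio
    slots = {}
    for cat, cnt in zip(*np.unique(treated_cats, return_counts=True)):
        slots[cat] = int(np.ceil(cnt * hi))
    finite = dist.matrix[np.isfinite(dist.matrix)]
    pen = constraints.balance_penalty
    if pen is None:
        pen = 10.0 * (float(finite.max()) if finite.size else 1.0)
    scale = _COST_RESOLUTION / max(1.0, float(finite.max()) if finite.size else 1.0)
    return control_cats, slots, int(round(pen * scale))


def pair_match(dist: DistanceMatrix,
               constraints: MatchConstraints | None = None,
               table: ObservationalTable | None = None) -> MatchedSample:
    """Optimal pair matching: minimum total distance, one control each."""
    constraints = constraints or MatchConstraints()
    cats = slots = pen = None
    if constraints.balance_keys and table is not None:
        cats, slots, pen = _balance_layout(table, dist, constraints)
    assignment = _min_cost_match(dist, 1, 1, cats, slots, pen)
    sets = [MatchedSet(i, dist.treated_ids[ti], [dist.control_ids[cs[0]]])
            for i, (ti, cs) in enumerate(assignment)]
    total = sum(dist.matrix[ti, cs[0]] for ti, cs in assignment)
    return MatchedSample(sets, provenance={"kind": "pair", "total_distance": total,
                                           "constraints": constraints})


def variable_ratio_match(dist: DistanceMatrix,
                         constraints: MatchConstraints,
                         table: ObservationalTable | None = None) -> MatchedSample:
    """Optimal variable-ratio matching with optional near-fine balance."""
    lo, hi = constraints.control_ratio
    cats = slots = pen = None
    if constraints.balance_keys and table is not None:
        cats, slots, pen = _balance_layout(table, dist, constraints)
    assignment = _min_cost_match(dist, lo, hi, cats, slots, pen,
                                 total=constraints.total_controls)
    sets = [MatchedSet(i, dist.treated_ids[ti],
                       [dist.control_ids[j] for j in cs])
            for i, (ti, cs) in enumerate(assignment)]
    total = sum(dist.matrix[ti, j] for ti, cs in assignment for j in cs)
    return MatchedSample(sets, provenance={"kind": "variable_ratio",
                                           "total_distance": total,
                                           "constraints": constraints})


# ---------------------------------------------------------------------------
# balance diagnostics


def evaluate_fine_balance(sample: MatchedSample, table: ObservationalTable,
                          key: str) -> pd.Series:
    """Per-category |treated - control| count deviation after matching.

    Control counts are rescaled by the overall matching ratio so that pair
    and variable-ratio samples are on the same footing.
    """
    vals = table.covariates[key].astype(str)
    idx = {uid: i for i, uid in enumerate(table.ids)}
    tvals, cvals = [], []
    for s in sample.sets:
        tvals.append(vals.iloc[idx[s.treated_id]])
        cvals.extend(vals.iloc[idx[c]] for c in s.control_ids)
    tc = pd.Series(tvals).value_counts()
    cc = pd.Series(cvals).value_counts()
    ratio = len(cvals) / len(tvals)
    cats = sorted(set(tc.index) | set(cc.index))
    dev = {cat: abs(tc.get(cat, 0) - cc.get(cat, 0) / ratio) for cat in cats}
    return pd.Series(dev, name=key)


def standardized_differences(table: ObservationalTable,
                             sample: MatchedSample | None = None) -> pd.DataFrame:
    """Standardized mean differences (treated minus control) per covariate.

    The pooled SD comes from the before-matching groups, so before and
    after values share a scale.  For variable-ratio samples each matched
    set contributes equally: controls are weighted by 1/(n_i - 1).
    """
    design = expand_categoricals(table)
    X = design.to_numpy(float)
    t = table.z == 1
    mt, mc = X[t].mean(axis=0), X[~t].mean(axis=0)

    def _var(a):  # singleton groups contribute zero variance
        return a.var(axis=0, ddof=1) if a.shape[0] > 1 else np.zeros(a.shape[1])

    sd = np.sqrt((_var(X[t]) + _var(X[~t])) / 2)
    zero = sd == 0
    sd_safe = np.where(zero, 1.0, sd)
    out = pd.DataFrame({"smd_before": (mt - mc) / sd_safe,
                        "zero_sd": zero}, index=design.columns)
    out.loc[zero, "smd_before"] = 0.0
    if sample is not None:
        idx = {uid: i for i, uid in enumerate(table.ids)}
        tw = np.zeros(len(table.ids))
        cw = np.zeros(len(table.ids))
        for s in sample.sets:
            tw[idx[s.treated_id]] += 1.0
            for c in s.control_ids:
                cw[idx[c]] += 1.0 / len(s.control_ids)
        mt_a = (X * tw[:, None]).sum(axis=0) / tw.sum()
        mc_a = (X * cw[:, None]).sum(axis=0) / cw.sum()
        out["smd_after"] = (mt_a - mc_a) / sd_safe
        out.loc[zero, "smd_after"] = 0.0
    return out


# ---------------------------------------------------------------------------
# rematching after subgroup discovery


def rematch_inexact(sample: MatchedSample, table: ObservationalTable,
                    selected_keys) -> MatchedSample:
    """Re-pair inexactly matched pairs so they agree on the selected keys.

    Pairs already exact on every selected key are kept untouched.  The
    treated and control units of the remaining pairs are pooled and
    re-paired, at minimum rank-Mahalanobis distance, within identical
    key-profiles; units with no available partner are dropped (logged).
    The number of exactly matched pairs never decreases.
    """
    if any(s.n != 2 for s in sample.sets):
        raise ValueError("rematch_inexact requires a pair matching")
    vals = table.covariates[list(selected_keys)].astype(str)
    idx = {uid: i for i, uid in enumerate(table.ids)}

    def profile(uid):
        return tuple(vals.iloc[idx[uid]])

    exact, pool_t, pool_c = [], [], []
    for s in sample.sets:
        if profile(s.treated_id) == profile(s.control_ids[0]):
            exact.append(s)
        else:
            pool_t.append(s.treated_id)
            pool_c.append(s.control_ids[0])
    if not pool_t:
        return MatchedSample([MatchedSet(i, s.treated_id, list(s.control_ids))
                              for i, s in enumerate(exact)],
                             provenance=dict(sample.provenance, rematched=0))

    base = rank_mahalanobis(table)
    trow = {uid: k for k, uid in enumerate(base.treated_ids)}
    ccol = {uid: k for k, uid in enumerate(base.control_ids)}

    from scipy.optimize import linear_sum_assignment

    new_pairs = []
    profs = {profile(u) for u in pool_t} & {profile(u) for u in pool_c}
    for pr in sorted(profs):
        ts = [u for u in pool_t if profile(u) == pr]
        cs = [u for u in pool_c if profile(u) == pr]
        sub = np.array([[base.matrix[trow[a], ccol[b]] for b in cs] for a in ts])
        ri, ci = linear_sum_assignment(sub)
        new_pairs.extend((ts[a], cs[b]) for a, b in zip(ri, ci))
    dropped = (len(pool_t) - len(new_pairs)) + (len(pool_c) - len(new_pairs))
    if dropped:
        logger.info("rematch_inexact dropped %d unmatchable units", dropped)

    sets = [MatchedSet(i, s.treated_id, list(s.control_ids))
            for i, s in enumerate(exact)]
    sets.extend(MatchedSet(len(exact) + k, tuid, [cuid])
                for k, (tuid, cuid) in enumerate(new_pairs))
    return MatchedSample(sets, provenance=dict(sample.provenance,
                                               rematched=len(new_pairs)))
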