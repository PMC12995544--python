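"""Weighted M-statistics and their worst-case null distribution under Γ.

The test statistic for a subgroup s of matched sets is

    T = sum_{i in s} w_i * sum_j Z_ij q_ij,
    q_ij = sum_l psi((R_ij - R_il) / s_scale),

where psi is a monotone increasing odd ramp with inner/outer trimming, the
scale s_scale is a quantile of the pooled absolute treated-control outcome
differences, and w_i are nonnegative set weights.  With the identity psi
and constant weights, T is (up to scaling) the permutational t-statistic.

Under the sensitivity model, two units in the same matched set may differ
in their odds of treatment by at most a factor Γ >= 1.  For the sharp null
of no effect, the worst-case (largest) null distribution of T over all
configurations of the unobserved covariate is approximated by the standard
separable construction: within each set the adverse configuration puts
probability Γ/(aΓ + n_i - a) on each of the a largest q-values and
1/(aΓ + n_i - a) on the rest, with a chosen to maximize the set's null
mean (ties resolved toward the larger second moment, the conservative
choice).  The resulting worst-case mean θ_Γ and SD σ_Γ yield a normal
approximation to the worst-case p-value.  An exact enumeration oracle over
all binary configurations of the unobserved covariate is provided for
small instances.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .io import ObservationalTable
from .matching import MatchedSample

__all__ = [
    "ScoreConfig",
    "SetScores",
    "MStat",
    "SensitivityModel",
    "WorstCaseNull",
    "scale_s",
    "psi",
    "set_scores",
    "scores_from_outcomes",
    "statistic",
    "worstcase_moments",
    "pvalue_upper",
    "exact_worstcase_tail",
]


@dataclass(frozen=True)
class ScoreConfig:
    """Trimming, scale quantile and weighting for the M-statistic.

    inner/outer: the psi ramp is flat up to ``inner``, linear to ``outer``
    and capped beyond it; ``outer = inf`` recovers the identity psi.
    lam: the quantile of pooled |treated - control| differences used as the
    scale.  weight_scheme: ``"constant"`` (default) or ``"ustat"`` with
    parameters (m, m_lo, m_hi) for the U-statistic weighting that
    emphasizes sets whose absolute difference ranks in positions
    m_lo..m_hi of a size-m subset.
    """

    inner: float = 0.0
    outer: float = math.inf
    lam: float = 0.5
    weight_scheme: str = "constant"
    m: int | None = None
    m_lo: int | None = None
    m_hi: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.inner < self.outer):
            raise ValueError("need 0 <= inner < outer")
        if not (0 < self.lam < 1):
            raise ValueError("lambda must lie in (0, 1)")
        if self.weight_scheme not in ("constant", "ustat"):
            raise ValueError("weight_scheme must be 'constant' or 'ustat'")
        if self.weight_scheme == "ustat":
            if None in (self.m, self.m_lo, self.m_hi) or \
                    not (1 <= self.m_lo <= self.m_hi <= self.m):
                raise ValueError("ustat weights need 1 <= m_lo <= m_hi <= m")


@dataclass
class SetScores:
    """Per-set psi-scores and weights.

    q[i] is the score vector of set i with the treated member first;
    within a pair q[i][0] == -q[i][1].  w[i] >= 0 is the set weight and s
    the scale used.
    """

    q: list
    w: np.ndarray
    s: float

    @property
    def I(self) -> int:  # noqa: E743
        return len(self.q)

    def treated_q(self) -> np.ndarray:
        return np.array([qi[0] for qi in self.q])


@dataclass(frozen=True)
class MStat:
    value: float
    subgroup: tuple
    label: str = ""


@dataclass(frozen=True)
class SensitivityModel:
    """Odds-of-treatment bound Γ >= 1 and the tested tail."""

    gamma: float = 1.0
    direction: str = "upper"

    def __post_init__(self) -> None:
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.direction not in ("upper", "lower"):
            raise ValueError("direction must be 'upper' or 'lower'")


@dataclass(frozen=True)
class WorstCaseNull:
    theta: float
    sigma: float
    gamma: float


def psi(y, inner: float = 0.0, outer: float = math.inf):
    """Odd, nondecreasing ramp: sign(y) * min(max(|y|-inner, 0), outer-inner)."""
    y = np.asarray(y, dtype=float)
    mag = np.minimum(np.maximum(np.abs(y) - inner, 0.0), outer - inner)
    out = np.sign(y) * mag
    return float(out) if out.ndim == 0 else out


def _outcome_sets(sample: MatchedSample, table: ObservationalTable) -> list:
    """Outcome vector per set, treated member first."""
    idx = {uid: i for i, uid in enumerate(table.ids)}
    out = []
    for s in sample.sets:
        out.append(np.array([table.r[idx[s.treated_id]]]
                            + [table.r[idx[c]] for c in s.control_ids]))
    return out


def scale_s(sample: MatchedSample, table: ObservationalTable,
            lam: float = 0.5) -> float:
    """λ-quantile of pooled within-set |treated - control| differences.

    Computed once globally per matched sample (not per subgroup).  Linear
    interpolation between order statistics.  All-tied outcomes give scale
    zero, which is an error: the caller may fall back to s = 1.
    """
    diffs = []
    for r in _outcome_sets(sample, table):
        diffs.extend(abs(r[0] - rc) for rc in r[1:])
    s = float(np.quantile(np.asarray(diffs), lam))
    if s <= 0:
        raise ValueError("scale is zero (all within-set outcomes tied); "
                         "consider the identity fallback s = 1")
    return s


def _ustat_weights(r_sets: list, m: int, m_lo: int, m_hi: int) -> np.ndarray:
    """U-statistic set weights.

    Sets are ranked by the absolute difference between the treated outcome
    and the mean control outcome; the weight of the set with rank a is the
    probability that, in a random size-m subset of sets containing it, its
    rank falls in positions m_lo..m_hi (hypergeometric form).
    """
    I = len(r_sets)
    mags = np.array([abs(r[0] - r[1:].mean()) for r in r_sets])
    order = np.argsort(np.argsort(mags, kind="stable"), kind="stable")
    ranks = order + 1  # 1..I, ties broken by stable order
    m = min(m, I)
    m_hi = min(m_hi, m)
    m_lo = min(m_lo, m_hi)
    denom = math.comb(I - 1, m - 1)
    w = np.zeros(I)
    for i, a in enumerate(ranks):
        w[i] = sum(math.comb(a - 1, l - 1) * math.comb(I - a, m - l)
                   for l in range(m_lo, m_hi + 1)
                   if l - 1 <= a - 1 and m - l <= I - a) / denom
    return w


def scores_from_outcomes(r_sets: list, config: ScoreConfig) -> SetScores:
    """Build :class:`SetScores` from per-set outcome vectors (treated first)."""
    diffs = [abs(r[0] - rc) for r in r_sets for rc in r[1:]]
    s = float(np.quantile(np.asarray(diffs), config.lam))
    if s <= 0:
        s = 1.0  # identity fallback for degenerate (all-tied) outcomes
        warnings.warn("all within-set outcome differences are zero; using s=1")
    q = []
    for r in r_sets:
        qi = np.array([psi((rj - r) / s, config.inner, config.outer).sum()
                       for rj in r])
        q.append(qi)
    if config.weight_scheme == "constant":
        w = np.ones(len(r_sets))
    else:
        w = _ustat_weights(r_sets, config.m, config.m_lo, config.m_hi)
    return SetScores(q=q, w=w, s=s)


def set_scores(sample: MatchedSample, table: ObservationalTable,
               config: ScoreConfig | None = None) -> SetScores:
    """Compute psi-scores q_ij and weights w_i for a matched sample."""
    config = config or ScoreConfig()
    return scores_from_outcomes(_outcome_sets(sample, table), config)


def statistic(scores: SetScores, subgroup) -> MStat:
    """Weighted sum of treated-member scores over a subgroup of sets."""
    subgroup = tuple(subgroup)
    if len(subgroup) == 0:
        raise ValueError("subgroup must be nonempty")
    val = float(sum(scores.w[i] * scores.q[i][0] for i in subgroup))
    return MStat(value=val, subgroup=subgroup)


def _set_worstcase(q: np.ndarray, gamma: float) -> tuple:
    """Worst-case (mean, second moment) of the treated member's q in one set.

    The adverse unobserved-covariate configuration within a set of size n
    puts elevated probability Γ/(aΓ+n-a) on each of the a largest q-values;
    a is chosen to maximize the mean, ties toward the larger second moment.
    """
    n = q.size
    qs = np.sort(q)[::-1]
    cs = np.cumsum(qs)
    cs2 = np.cumsum(qs**2)
    best = (-np.inf, -np.inf)
    for a in range(1, n):
        denom = a * gamma + (n - a)
        mu = (gamma * cs[a - 1] + (cs[-1] - cs[a - 1])) / denom
        nu = (gamma * cs2[a - 1] + (cs2[-1] - cs2[a - 1])) / denom
        if mu > best[0] + 1e-12 or (abs(mu - best[0]) <= 1e-12 and nu > best[1]):
            best = (mu, nu)
    return best


def worstcase_moments(scores: SetScores, subgroup,
                      model: SensitivityModel) -> WorstCaseNull:
    """Worst-case null mean θ_Γ and SD σ_Γ of the M-statistic.

    θ_Γ = Σ w_i μ_i and σ_Γ² = Σ w_i² (ν_i - μ_i²) with (μ_i, ν_i) the
    per-set worst-case first and second moments.  The lower tail applies
    the same construction to -q.  At Γ=1 this reduces to the uniform
    within-set randomization moments.
    """
    subgroup = tuple(subgroup)
    if len(subgroup) == 0:
        raise ValueError("subgroup must be nonempty")
    sign = 1.0 if model.direction == "upper" else -1.0
    theta = 0.0
    var = 0.0
    for i in subgroup:
        mu, nu = _set_worstcase(sign * scores.q[i], model.gamma)
        theta += scores.w[i] * mu
        var += scores.w[i] ** 2 * (nu - mu**2)
    # for the lower tail the moments refer to -T (apply pvalue_upper to -T)
    return WorstCaseNull(theta=theta, sigma=math.sqrt(max(var, 0.0)),
                         gamma=model.gamma)


def set_worstcase_components(scores: SetScores, subgroup,
                             model: SensitivityModel):
    """Per-set worst-case contributions (w μ, w²(ν-μ²)); used by submax."""
    sign = 1.0 if model.direction == "upper" else -1.0
    means, variances = [], []
    for i in subgroup:
        mu, nu = _set_worstcase(sign * scores.q[i], model.gamma)
        means.append(scores.w[i] * mu)
        variances.append(scores.w[i] ** 2 * (nu - mu**2))
    return np.asarray(means), np.asarray(variances)


def pvalue_upper(T: MStat | float, null: WorstCaseNull) -> float:
    """Normal-approximation worst-case p-value P(T >= t)."""
    t = T.value if isinstance(T, MStat) else float(T)
    if null.sigma == 0:
        warnings.warn("degenerate worst-case null (sigma = 0)")
        return 1.0 if t <= null.theta else 0.0
    return float(1.0 - ndtr((t - null.theta) / null.sigma))


def exact_worstcase_tail(scores: SetScores, subgroup, model: SensitivityModel,
                         t: float, limit: int = 14) -> float:
    """Exact worst-case tail P(T >= t) by enumeration (test oracle).

    Maximizes over every binary configuration of the unobserved covariate;
    within each set the treated position has probability proportional to
    Γ^u over members.  Only feasible for a handful of small sets; raises
    when the total member count exceeds ``limit``.
    """
    subgroup = tuple(subgroup)
    sizes = [scores.q[i].size for i in subgroup]
    if sum(sizes) > limit:
        raise ValueError(f"instance too large for enumeration (> {limit} members)")
    sign = 1.0 if model.direction == "upper" else -1.0
    qs = [sign * scores.q[i] for i in subgroup]
    ws = [scores.w[i] for i in subgroup]
    tt = sign * t  # lower tail of T is the upper tail of -T at -t

    best = 0.0
    u_spaces = [list(itertools.product((0, 1), repeat=n)) for n in sizes]
    for u_config in itertools.product(*u_spaces):
        probs = []
        for u, q in zip(u_config, qs):
            g = model.gamma ** np.asarray(u, dtype=float)
            probs.append(g / g.sum())
        tail = 0.0
        for choice in itertools.product(*(range(n) for n in sizes)):
            val = sum(w * q[j] for w, q, j in zip(ws, qs, choice))
            if val >= tt - 1e-12:
                pr = 1.0
                for p, j in zip(probs, choice):
                    pr *= p[j]
                tail += pr
        best = max(best, tail)
    return best
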