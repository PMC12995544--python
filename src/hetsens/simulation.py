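"""Simulation study: power and effect-modifier identification.

The data-generating process draws I matched pairs.  Each pair shares one
vector of p Bernoulli(1/2) covariates; the first log2(G) covariates define
G subgroups with additive treatment effects β = (β_1, ..., β_G); control
responses are standard normal, the treated response adds the pair's
subgroup effect, and the treated position is randomized within the pair.
Because both members share the covariates, every pair is exactly matched
by construction and the matching step is bypassed.

Five analysis variants are compared: hsr (tree-based subgroups with
truncated-product closed testing), submax with all covariates as
modifiers, submax+ (tree-selected modifiers), submax (best) with the true
modifiers, and submax (worst) with only non-modifiers.  Performance is
summarized by F1 and the true-positive rate, both for hypothesis
rejections and for identified effect modifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hsr import closed_testing_from_groups, subgroup_pvalues
from .io import ObservationalTable
from .matching import MatchedSample, MatchedSet
from .mscore import ScoreConfig, SensitivityModel, set_scores
from .subgrouping import (TreeParams, fit_tree, pair_differences,
                          partition_from_tree)
from .submax import build_contrasts, closed_testing_submax, correlation, deviates

__all__ = [
    "SimConfig",
    "TruthSpec",
    "EvalMetrics",
    "VariantResult",
    "VARIANTS",
    "generate",
    "run_variant",
    "power_metrics",
    "modifier_metrics",
    "study",
]

VARIANTS = ("hsr", "submax", "submax_plus", "submax_best", "submax_worst")


@dataclass(frozen=True)
class SimConfig:
    """Design of one simulation setting.

    beta has one entry per subgroup; G = len(beta) must be a power of two,
    with log2(G) designated modifier covariates (x1 for G=2; x1, x2 for
    G=4).  The remaining covariates are noise.
    """

    I: int = 200  # noqa: E741
    p: int = 4
    beta: tuple = (0.0, 0.0, 0.0, 0.0)
    reps: int = 100
    alpha: float = 0.05
    gamma_grid: tuple = (1.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        G = len(self.beta)
        if G < 2 or (G & (G - 1)) != 0:
            raise ValueError("len(beta) must be a power of two >= 2")
        if self.p < int(math.log2(G)):
            raise ValueError("p must be at least log2(G)")

    @property
    def G(self) -> int:  # noqa: E743
        return len(self.beta)

    @property
    def n_modifiers(self) -> int:
        return int(math.log2(self.G))


@dataclass(frozen=True)
class TruthSpec:
    modifiers: tuple       # covariate names of the true effect modifiers
    nonnull: tuple         # per-subgroup flag: beta_g != 0
    beta: tuple


@dataclass(frozen=True)
class EvalMetrics:
    tp: int
    fp: int
    fn: int
    f1: float
    tpr: float
    f1_defined: bool = True
    tpr_defined: bool = True


@dataclass
class VariantResult:
    variant: str
    rejections: dict       # hypothesis label -> rejected
    false_null: dict       # hypothesis label -> hypothesis is a false null
    identified: set        # covariate names identified as modifiers
    candidates: list       # covariate names the variant could identify
    detail: object = None


def generate(config: SimConfig, seed: int | None = None):
    """Draw one replicate: (sample, table, truth)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    I, p, L = config.I, config.p, config.n_modifiers
    beta = np.asarray(config.beta, dtype=float)

    x = rng.integers(0, 2, size=(I, p))
    g = np.zeros(I, dtype=int)
    for l in range(L):
        g = (g << 1) | x[:, l]
    rc = rng.normal(0.0, 1.0, size=(I, 2))
    rt = rc + beta[g][:, None]
    treated_pos = rng.integers(0, 2, size=I)

    ids, z, r = [], [], []
    cov_rows = []
    sets = []
    for i in range(I):
        a, b = f"p{i}a", f"p{i}b"
        ta = treated_pos[i] == 0
        ids.extend([a, b])
        z.extend([int(ta), int(not ta)])
        r.extend([rt[i, 0] if ta else rc[i, 0],
                  rc[i, 1] if ta else rt[i, 1]])
        cov_rows.extend([x[i], x[i]])
        sets.append(MatchedSet(i, a if ta else b, [b if ta else a]))

    names = [f"x{k + 1}" for k in range(p)]
    table = ObservationalTable(
        ids=np.array(ids), z=np.array(z, int), r=np.array(r, float),
        covariates=pd.DataFrame(np.array(cov_rows), columns=names),
        covariate_types={n: "numeric" for n in names})
    sample = MatchedSample(sets, provenance={"kind": "simulated_pairs"})
    truth = TruthSpec(modifiers=tuple(names[:L]),
                      nonnull=tuple(bool(b != 0) for b in beta),
                      beta=tuple(beta))
    return sample, table, truth


def _set_nonnull_flags(table: ObservationalTable, sample: MatchedSample,
                       truth: TruthSpec) -> np.ndarray:
    """Per-set flag: does this set's subgroup carry a nonzero effect."""
    idx = {uid: i for i, uid in enumerate(table.ids)}
    L = int(math.log2(len(truth.beta)))
    flags = np.zeros(len(sample.sets), dtype=bool)
    for pos, s in enumerate(sample.sets):
        xv = table.covariates.iloc[idx[s.treated_id]]
        g = 0
        for l in range(L):
            g = (g << 1) | int(xv[truth.modifiers[l]])
        flags[pos] = truth.nonnull[g]
    return flags


def _run_submax_variant(keys, sample, table, truth, gamma, alpha,
                        config: ScoreConfig) -> VariantResult:
    family = build_contrasts(sample, table, keys)
    scores = set_scores(sample, table, config)
    model = SensitivityModel(gamma=gamma, direction="upper")
    dev = deviates(scores, family, model)
    rho = correlation(scores, family, model)
    res = closed_testing_submax(dev, rho, alpha)

    nonnull = _set_nonnull_flags(table, sample, truth)
    false_null = {lbl: bool(nonnull[family.members[k]].any())
                  for k, lbl in enumerate(family.labels)}
    rejections = dict(res.singletons)
    identified = {key for key in keys
                  if rejections.get(f"{key}=1", False)
                  or rejections.get(f"{key}=0", False)}
    return VariantResult(variant="submax", rejections=rejections,
                         false_null=false_null, identified=identified,
                         candidates=list(keys), detail=res)


def _run_hsr_variant(sample, table, truth, gamma, alpha,
                     config: ScoreConfig, tree_params) -> VariantResult:
    names = table.covariate_names
    records = pair_differences(sample, table, names)
    tree = fit_tree(records, names, tree_params)
    partition = partition_from_tree(sample, table, tree)
    pos = {s.set_index: i for i, s in enumerate(sample.sets)}
    groups = {lbl: [pos[i] for i in partition.groups[lbl]]
              for lbl in partition.labels}
    scores = set_scores(sample, table, config)

    from .subgrouping import SubgroupPartition

    part = SubgroupPartition(groups=groups, labels=partition.labels)
    gp = subgroup_pvalues(scores, part, gamma, side="upper")
    res = closed_testing_from_groups(gp, alpha=alpha)

    nonnull = _set_nonnull_flags(table, sample, truth)
    rejections, false_null = {}, {}
    for lbl in part.labels:
        rejections[lbl] = res.singletons[lbl]
        false_null[lbl] = bool(nonnull[groups[lbl]].any())
    if part.G > 1:
        # with a single leaf the overall IS the leaf hypothesis
        full = frozenset(range(part.G))
        rejections["overall"] = res.reject[full]
        false_null["overall"] = any(false_null[lbl] for lbl in part.labels)

    idx = {uid: i for i, uid in enumerate(table.ids)}
    x = table.covariates.iloc[[idx[s.treated_id] for s in sample.sets]]
    leaves_by_var = tree.leaves_under_splits(x.reset_index(drop=True))
    identified = set()
    for var, leaves in leaves_by_var.items():
        if any(rejections.get(f"leaf{int(l)}", False) for l in leaves):
            identified.add(var)
    return VariantResult(variant="hsr", rejections=rejections,
                         false_null=false_null, identified=identified,
                         candidates=list(names), detail=(tree, res))


def run_variant(variant: str, sample: MatchedSample, table: ObservationalTable,
                truth: TruthSpec, gamma: float = 1.0, alpha: float = 0.05,
                config: ScoreConfig | None = None,
                tree_params: TreeParams | None = None) -> VariantResult:
    """Run one analysis variant on one replicate at one Γ."""
    config = config or ScoreConfig()
    names = table.covariate_names
    if variant == "hsr":
        return _run_hsr_variant(sample, table, truth, gamma, alpha, config,
                                tree_params)
    if variant == "submax":
        keys = names
    elif variant == "submax_best":
        keys = list(truth.modifiers)
    elif variant == "submax_worst":
        keys = [n for n in names if n not in truth.modifiers]
    elif variant == "submax_plus":
        records = pair_differences(sample, table, names)
        tree = fit_tree(records, names, tree_params)
        keys = tree.selected_covariates  # binary covariates: no dichotomizing
    else:
        raise ValueError(f"unknown variant {variant!r}; "
                         f"choose one of {VARIANTS}")
    res = _run_submax_variant(keys, sample, table, truth, gamma, alpha, config)
    res.variant = variant
    return res


def power_metrics(result: VariantResult) -> EvalMetrics:
    """F1/TPR over the tested hypotheses (false null = should reject)."""
    tp = fp = fn = 0
    for lbl, rejected in result.rejections.items():
        false_null = result.false_null[lbl]
        if rejected and false_null:
            tp += 1
        elif rejected and not false_null:
            fp += 1
        elif not rejected and false_null:
            fn += 1
    return _metrics(tp, fp, fn)


def modifier_metrics(result: VariantResult, truth: TruthSpec) -> EvalMetrics:
    """F1/TPR over covariates for effect-modifier identification."""
    true_set = set(truth.modifiers)
    tp = len(result.identified & true_set)
    fp = len(result.identified - true_set)
    fn = len(true_set - result.identified)
    return _metrics(tp, fp, fn)


def _metrics(tp: int, fp: int, fn: int) -> EvalMetrics:
    f1_den = 2 * tp + fp + fn
    tpr_den = tp + fn
    return EvalMetrics(
        tp=tp, fp=fp, fn=fn,
        f1=(2 * tp / f1_den) if f1_den else 0.0,
        tpr=(tp / tpr_den) if tpr_den else 0.0,
        f1_defined=f1_den > 0, tpr_defined=tpr_den > 0)


def study(config: SimConfig, variants=VARIANTS,
          config_score: ScoreConfig | None = None,
          tree_params: TreeParams | None = None) -> pd.DataFrame:
    """Replicated comparison; returns a tidy frame of mean F1/TPR curves.

    Per-replicate seeds are config.seed + replicate index, giving
    independent, replayable streams.  Output columns: variant, gamma,
    metric, mean, mc_se, reps.
    """
    config_score = config_score or ScoreConfig()
    records = {}
    for rep in range(config.reps):
        sample, table, truth = generate(config, seed=config.seed + rep)
        for gamma in config.gamma_grid:
            for variant in variants:
                res = run_variant(variant, sample, table, truth, gamma,
                                  config.alpha, config_score, tree_params)
                pm = power_metrics(res)
                mm = modifier_metrics(res, truth)
                for metric, val in (("power_f1", pm.f1), ("power_tpr", pm.tpr),
                                    ("modifier_f1", mm.f1),
                                    ("modifier_tpr", mm.tpr)):
                    records.setdefault((variant, gamma, metric), []).append(val)
    rows = []
    for (variant, gamma, metric), vals in records.items():
        arr = np.asarray(vals)
        rows.append({"variant": variant, "gamma": gamma, "metric": metric,
                     "mean": arr.mean(),
                     "mc_se": arr.std(ddof=1) / math.sqrt(len(arr))
                     if len(arr) > 1 else 0.0,
                     "reps": len(arr)})
    return pd.DataFrame(rows)
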