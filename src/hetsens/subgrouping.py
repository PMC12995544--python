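"""Data-driven discovery of candidate effect modifiers.

Within-pair treated-minus-control differences Y_i are computed for pairs
exactly matched on the chosen potential effect modifiers.  A least-squares
regression tree fit to |Y_i| partitions the modifier space into leaves;
under the sharp null, |Y_i| is invariant to which member of the pair was
treated, so fitting the tree to |Y_i| does not bias subsequent inference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .io import ObservationalTable, ValidationError
from .matching import MatchedSample

logger = logging.getLogger("hetsens.subgrouping")

__all__ = [
    "TreeParams",
    "TreeSpec",
    "SubgroupPartition",
    "pair_differences",
    "fit_tree",
    "partition_from_tree",
    "partition_from_modifiers",
]


@dataclass(frozen=True)
class TreeParams:
    """Recursive-partitioning controls (conventional defaults).

    ``cp`` is the complexity parameter: a split must reduce the residual
    sum of squares by at least ``cp`` times the root sum of squares.
    """

    min_split: int = 20
    min_leaf: int = 7
    cp: float = 0.01
    max_depth: int = 30


@dataclass
class TreeSpec:
    """A fitted regression tree on |Y| with its covariate names."""

    tree: DecisionTreeRegressor
    feature_names: list

    @property
    def n_leaves(self) -> int:
        return int(self.tree.get_n_leaves())

    @property
    def splits(self) -> list:
        """(covariate, threshold) for every internal node, preorder."""
        t = self.tree.tree_
        return [(self.feature_names[t.feature[i]], float(t.threshold[i]))
                for i in range(t.node_count) if t.children_left[i] != -1]

    @property
    def selected_covariates(self) -> list:
        seen = []
        for name, _ in self.splits:
            if name not in seen:
                seen.append(name)
        return seen

    @property
    def L(self) -> int:  # noqa: E743
        return len(self.selected_covariates)

    def assign(self, x: pd.DataFrame) -> np.ndarray:
        """Leaf id for each row of modifier values."""
        xx = x[self.feature_names]
        if xx.isna().any().any():
            bad = list(xx.index[xx.isna().any(axis=1)])
            raise ValidationError(f"unroutable modifier values for rows {bad}")
        return self.tree.apply(xx.to_numpy(float))

    def leaf_means(self, x: pd.DataFrame, y: np.ndarray) -> dict:
        leaves = self.assign(x)
        return {int(l): float(np.mean(y[leaves == l])) for l in np.unique(leaves)}

    def leaves_under_splits(self, x: pd.DataFrame) -> dict:
        """Map each splitting covariate to the leaf ids below its splits."""
        t = self.tree.tree_
        out = {}

        def descend(node):
            if t.children_left[node] == -1:
                return {node}
            return descend(t.children_left[node]) | descend(t.children_right[node])

        for i in range(t.node_count):
            if t.children_left[i] != -1:
                name = self.feature_names[t.feature[i]]
                out.setdefault(name, set()).update(descend(i))
        return out

    def to_json(self) -> str:
        t = self.tree.tree_
        nodes = []
        for i in range(t.node_count):
            leaf = t.children_left[i] == -1
            nodes.append({
                "id": i, "leaf": bool(leaf),
                "feature": None if leaf else self.feature_names[t.feature[i]],
                "threshold": None if leaf else float(t.threshold[i]),
                "left": int(t.children_left[i]), "right": int(t.children_right[i]),
                "value": float(t.value[i].ravel()[0]), "n": int(t.n_node_samples[i]),
            })
        return json.dumps({"features": self.feature_names, "nodes": nodes})


@dataclass
class SubgroupPartition:
    """G mutually exclusive, exhaustive groups of matched-set indices."""

    groups: dict  # label -> list of set indices
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = list(self.groups)
        seen = set()
        for label in self.labels:
            members = self.groups[label]
            if len(members) == 0:
                raise ValueError(f"subgroup {label!r} is empty")
            if seen & set(members):
                raise ValueError("subgroups must be disjoint")
            seen |= set(members)
        self._covered = seen

    @property
    def G(self) -> int:  # noqa: E743
        return len(self.labels)

    @property
    def sizes(self) -> dict:
        return {label: len(self.groups[label]) for label in self.labels}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"set_index": i, "group_label": label}
                for label in self.labels for i in self.groups[label]]
        return pd.DataFrame(rows)


def pair_differences(sample: MatchedSample, table: ObservationalTable,
                     pem_keys) -> pd.DataFrame:
    """Treated-minus-control differences for pairs exact on the modifiers.

    Returns one record per exactly matched pair with columns ``set_index``,
    ``y``, ``abs_y`` and the shared modifier values; inexact pairs are
    excluded and counted in ``df.attrs["n_excluded"]``.
    """
    pem_keys = list(pem_keys)
    if any(s.n != 2 for s in sample.sets):
        raise ValueError("pair differences require a pair matching")
    idx = {uid: i for i, uid in enumerate(table.ids)}
    rows = []
    excluded = 0
    for s in sample.sets:
        ti, ci = idx[s.treated_id], idx[s.control_ids[0]]
        xt = table.covariates.iloc[ti][pem_keys]
        xc = table.covariates.iloc[ci][pem_keys]
        if not (xt.to_numpy() == xc.to_numpy()).all():
            excluded += 1
            continue
        y = float(table.r[ti] - table.r[ci])
        rows.append({"set_index": s.set_index, "y": y, "abs_y": abs(y),
                     **xt.to_dict()})
    if not rows:
        raise ValidationError("no pairs exactly matched on the modifiers")
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = excluded
    return df


def fit_tree(records: pd.DataFrame, pem_keys,
             params: TreeParams | None = None) -> TreeSpec:
    """Least-squares regression tree of |Y| on the potential modifiers.

    Deterministic for fixed inputs.  The complexity parameter is enforced
    as a minimum impurity decrease of cp * Var(|Y|) per split, matching
    the usual cost-complexity convention on the root-relative scale.
    """
    params = params or TreeParams()
    pem_keys = list(pem_keys)
    X = records[pem_keys].to_numpy(float)
    y = records["abs_y"].to_numpy(float)
    tree = DecisionTreeRegressor(
        criterion="squared_error",
        min_samples_split=params.min_split,
        min_samples_leaf=params.min_leaf,
        max_depth=params.max_depth,
        min_impurity_decrease=params.cp * float(np.var(y)),
        random_state=0,
    )
    tree.fit(X, y)
    return TreeSpec(tree=tree, feature_names=pem_keys)


def partition_from_tree(sample: MatchedSample, table: ObservationalTable,
                        tree: TreeSpec) -> SubgroupPartition:
    """Groups = tree leaves; each set routed by its treated member's values."""
    idx = {uid: i for i, uid in enumerate(table.ids)}
    x = table.covariates.iloc[[idx[s.treated_id] for s in sample.sets]]
    leaves = tree.assign(x.reset_index(drop=True))
    groups = {}
    for s, leaf in zip(sample.sets, leaves):
        groups.setdefault(f"leaf{int(leaf)}", []).append(s.set_index)
    labels = sorted(groups, key=lambda lbl: int(lbl[4:]))
    return SubgroupPartition(groups=groups, labels=labels)


def partition_from_modifiers(sample: MatchedSample, table: ObservationalTable,
                             modifier_keys) -> SubgroupPartition:
    """One group per observed combination of the L binary modifiers."""
    modifier_keys = list(modifier_keys)
    idx = {uid: i for i, uid in enumerate(table.ids)}
    groups = {}
    for s in sample.sets:
        vals = table.covariates.iloc[idx[s.treated_id]][modifier_keys]
        arr = pd.to_numeric(vals, errors="coerce")
        if not arr.isin([0, 1]).all():
            raise ValidationError(
                f"modifiers must be binary 0/1; dichotomize first (set "
                f"{s.set_index}: {vals.to_dict()})")
        label = ",".join(f"{k}={int(v)}" for k, v in zip(modifier_keys, arr)) \
            or "all"
        groups.setdefault(label, []).append(s.set_index)
    n_possible = 2 ** len(modifier_keys)
    if len(groups) < n_possible:
        logger.info("only %d of %d modifier combinations present",
                    len(groups), n_possible)
    return SubgroupPartition(groups=groups, labels=sorted(groups))
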