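"""Tabular study data: loading, missing-data handling, and synthetic fixtures.

The expected input is a rectangular table of study units: a unit identifier,
a binary treatment indicator, a continuous outcome, and covariates that may
be numeric or categorical and may contain missing entries.  Missing-data
handling follows the two-step recipe common in matched observational
studies: add a binary "was missing" indicator per affected covariate, then
fill numeric gaps with the observed mean (categorical gaps with the modal
level).  Matching on both the filled covariate and the indicator balances
the observed values and the missingness pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "Unit",
    "ObservationalTable",
    "load_table",
    "impute_two_step",
    "generate_fixture",
    "expand_categoricals",
]

#: strings that denote a missing cell in the CSV dialect
NA_VALUES = ("", "NA")


class SchemaError(ValueError):
    """A mandatory column is absent from the input file."""


class ValidationError(ValueError):
    """The input violates a structural requirement (e.g. non-binary treatment)."""


@dataclass(frozen=True)
class Unit:
    """A single study unit: id, treatment arm, outcome, covariate vector."""

    unit_id: str
    z: int
    r: float
    x: dict


@dataclass
class ObservationalTable:
    """A typed table of study units.

    Attributes
    ----------
    ids : array of unit identifiers (unique).
    z : int array, 1 = treated, 0 = control.
    r : float array of observed outcomes.
    covariates : DataFrame, one row per unit, mixed numeric/categorical.
    covariate_types : mapping covariate name -> "numeric" | "categorical".
    missing : boolean DataFrame marking originally missing cells.
    """

    ids: np.ndarray
    z: np.ndarray
    r: np.ndarray
    covariates: pd.DataFrame
    covariate_types: dict = field(default_factory=dict)
    missing: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("unit ids must be unique")
        if not np.isin(self.z, [0, 1]).all():
            raise ValidationError("treatment indicator must be binary 0/1")
        if self.z.sum() == 0 or self.z.sum() == len(self.z):
            raise ValidationError("need at least one treated and one control unit")
        if self.missing is None:
            self.missing = self.covariates.isna()

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_treated(self) -> int:
        return int(self.z.sum())

    @property
    def n_control(self) -> int:
        return int(self.n - self.z.sum())

    @property
    def covariate_names(self) -> list:
        return list(self.covariates.columns)

    @property
    def units(self) -> list:
        return [
            Unit(str(self.ids[i]), int(self.z[i]), float(self.r[i]),
                 self.covariates.iloc[i].to_dict())
            for i in range(self.n)
        ]

    def index_of(self, unit_id) -> int:
        pos = np.flatnonzero(self.ids == unit_id)
        if pos.size == 0:
            raise KeyError(unit_id)
        return int(pos[0])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": self.ids, "treatment": self.z, "outcome": self.r})
        return pd.concat([out, self.covariates.reset_index(drop=True)], axis=1)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _infer_type(col: pd.Series) -> str:
    return "numeric" if pd.api.types.is_numeric_dtype(col) else "categorical"


def load_table(path, schema: Mapping[str, object]) -> ObservationalTable:
    """Read a comma-separated file into an :class:`ObservationalTable`.

    Parameters
    ----------
    path : file path or buffer.
    schema : mapping with keys ``"id"``, ``"treatment"``, ``"outcome"`` and
        optionally ``"covariates"`` (a list of column names; defaults to all
        remaining columns).

    Empty strings and ``"NA"`` denote missing cells.  The treatment column
    must contain only 0 and 1.
    """
    df = pd.read_csv(path, na_values=list(NA_VALUES), keep_default_na=False)
    for role in ("id", "treatment", "outcome"):
        colname = schema.get(role)
        if colname is None or colname not in df.columns:
            raise SchemaError(f"schema must name an existing {role!r} column")
    cov_cols = schema.get("covariates")
    if cov_cols is None:
        cov_cols = [c for c in df.columns
                    if c not in {schema["id"], schema["treatment"], schema["outcome"]}]
    if len(cov_cols) == 0:
        raise SchemaError("schema must include at least one covariate column")
    missing_cov = [c for c in cov_cols if c not in df.columns]
    if missing_cov:
        raise SchemaError(f"covariate columns not found: {missing_cov}")

    ztry = pd.to_numeric(df[schema["treatment"]], errors="coerce")
    if ztry.isna().any() or not ztry.isin([0, 1]).all():
        raise ValidationError("treatment column must be binary 0/1")

    cov = df[cov_cols].copy()
    types = {c: _infer_type(cov[c]) for c in cov_cols}
    return ObservationalTable(
        ids=df[schema["id"]].to_numpy(),
        z=ztry.to_numpy(dtype=int),
        r=pd.to_numeric(df[schema["outcome"]]).to_numpy(dtype=float),
        covariates=cov,
        covariate_types=types,
    )


def impute_two_step(table: ObservationalTable) -> ObservationalTable:
    """Two-step missing-data handling.

    For every covariate with at least one missing entry, append a binary
    ``<name>_missing`` indicator (1 where the value was missing) and fill
    the gaps: numeric covariates with the mean of the non-missing entries,
    categorical ones with the modal level (ties broken by sorted order, for
    determinism).  Covariates without missingness are untouched.  The
    operation is idempotent.
    """
    cov = table.covariates.copy()
    types = dict(table.covariate_types)
    indicators = {}
    for name in table.covariate_names:
        col = cov[name]
        mask = col.isna()
        if not mask.any():
            continue
        if mask.all():
            raise ValidationError(f"covariate {name!r} has all entries missing")
        indicators[f"{name}_missing"] = mask.astype(int)
        if types.get(name, _infer_type(col)) == "numeric":
            cov[name] = col.fillna(col.mean())
        else:
            mode = sorted(col.dropna().mode())[0]
            cov[name] = col.fillna(mode)
    for iname, ind in indicators.items():
        cov[iname] = ind
        types[iname] = "numeric"
    return ObservationalTable(
        ids=table.ids.copy(), z=table.z.copy(), r=table.r.copy(),
        covariates=cov, covariate_types=types,
        missing=pd.DataFrame(False, index=cov.index, columns=cov.columns),
    )


_CAT_LEVELS = ["house", "condo", "apartment", "community", "mobile", "assisted"]


def generate_fixture(n_treated: int, n_control: int, p: int,
                     missing_rate: float, seed: int) -> ObservationalTable:
    """Generate a synthetic observational table.

    The fixture emulates the shape of a cognitive-aging cohort: roughly 1
    treated per 3 controls, ~30 mixed-type covariates (binary, categorical
    and continuous), and sparse missingness confined to a few covariates.
    Treatment is mildly confounded with a handful of covariates so that
    matching has work to do.  A pure function of its arguments: the same
    seed yields a byte-identical table.
    """
    if n_treated < 1 or n_control < 1 or p < 1:
        raise ValidationError("counts must be positive")
    if not (0 <= missing_rate < 1):
        raise ValidationError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = n_treated + n_control
    z = np.concatenate([np.ones(n_treated, int), np.zeros(n_control, int)])

    cov = {}
    types = {}
    for k in range(p):
        name = f"x{k + 1}"
        kind = k % 3
        # mild treated/control shift on every third covariate: confounding
        shift = 0.25 * z if k % 4 == 0 else 0.0
        if kind == 0:  # continuous
            cov[name] = rng.normal(0.0, 1.0, n) + shift
            types[name] = "numeric"
        elif kind == 1:  # binary
            pr = np.clip(0.4 + 0.3 * (shift != 0) * z * 0.3, 0.05, 0.95)
            cov[name] = (rng.random(n) < pr).astype(int)
            types[name] = "numeric"
        else:  # categorical with 3-6 levels
            levels = _CAT_LEVELS[: 3 + (k % 4)]
            probs = np.arange(len(levels), 0, -1, dtype=float)
            probs /= probs.sum()
            cov[name] = rng.choice(levels, size=n, p=probs)
            types[name] = "categorical"
    cov = pd.DataFrame(cov)

    # outcome: linear in the first continuous covariate, heterogeneous effect
    x1 = pd.to_numeric(cov["x1"], errors="coerce").fillna(0).to_numpy(float)
    mod = cov["x2"].to_numpy(float) if p >= 2 and types.get("x2") == "numeric" else 0.0
    r = 0.3 * x1 + z * (0.2 + 0.3 * np.asarray(mod)) + rng.normal(0, 1, n)

    if missing_rate > 0:
        # confine missingness to a few covariates (~1 in 8, at least one)
        eligible = [f"x{k + 1}" for k in range(p) if k % 8 == 3] or ["x1"]
        for name in eligible:
            mask = rng.random(n) < missing_rate
            if mask.any():
                col = cov[name].astype(object if types[name] == "categorical" else float)
                col[mask] = np.nan
                cov[name] = col

    ids = np.array([f"u{i:05d}" for i in range(n)])
    return ObservationalTable(ids=ids, z=z, r=np.asarray(r, float),
                              covariates=cov, covariate_types=types)


def expand_categoricals(table: ObservationalTable) -> pd.DataFrame:
    """Numeric design matrix with one indicator column per categorical level.

    Requires an imputed table (no missing cells).  Numeric covariates pass
    through unchanged; each categorical covariate is replaced by one 0/1
    indicator per observed level, named ``<covariate>=<level>``.
    """
    if table.covariates.isna().any().any():
        raise ValidationError("impute the table before building a design matrix")
    pieces = []
    for name in table.covariate_names:
        col = table.covariates[name]
        if table.covariate_types.get(name, _infer_type(col)) == "numeric":
            pieces.append(col.astype(float).rename(name))
        else:
            for level in sorted(col.astype(str).unique()):
                pieces.append((col.astype(str) == level).astype(float)
                              .rename(f"{name}={level}"))
    return pd.concat(pieces, axis=1)
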