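import io

import numpy as np
import pandas as pd
import pytest

from hetsens.io import ObservationalTable
from hetsens.matching import MatchedSample, MatchedSet
from hetsens.mscore import ScoreConfig, scores_from_outcomes


def make_table(z, r, cov: dict, types=None) -> ObservationalTable:
    z = np.asarray(z, int)
    cov = pd.DataFrame(cov)
    return ObservationalTable(
        ids=np.array([f"u{i}" for i in range(len(z))]),
        z=z, r=np.asarray(r, float), covariates=cov,
        covariate_types=types or {c: "numeric" for c in cov.columns})


def make_pairs(outcomes, cov: dict | None = None):
    """Paired sample + table from a list of (treated R, control R)."""
    n = len(outcomes)
    ids, z, r = [], [], []
    sets = []
    rows = []
    for i, (rt, rc) in enumerate(outcomes):
        ids += [f"p{i}t", f"p{i}c"]
        z += [1, 0]
        r += [rt, rc]
        sets.append(MatchedSet(i, f"p{i}t", [f"p{i}c"]))
        if cov:
            rows.append(i)
    covframe = (pd.DataFrame({k: np.repeat(v, 2) for k, v in cov.items()})
                if cov else pd.DataFrame({"x1": np.zeros(2 * n)}))
    table = ObservationalTable(
        ids=np.array(ids), z=np.array(z), r=np.array(r, float),
        covariates=covframe,
        covariate_types={c: "numeric" for c in covframe.columns})
    return MatchedSample(sets), table


def random_paired_scores(rng, I, shift=0.0, config=None):
    """SetScores from random paired outcomes (treated first)."""
    outcomes = [np.array([rng.normal() + shift, rng.normal()])
                for _ in range(I)]
    return scores_from_outcomes(outcomes, config or ScoreConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def csv_buffer(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")
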