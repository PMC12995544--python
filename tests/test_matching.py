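import itertools

import numpy as np
import pandas as pd
import pytest

from hetsens.io import generate_fixture, impute_two_step
from hetsens.matching import (DistanceMatrix, MatchConstraints,
                              MatchingInfeasibleError, apply_almost_exact,
                              apply_caliper, evaluate_fine_balance, pair_match,
                              propensity_scores, rank_mahalanobis,
                              rematch_inexact, standardized_differences,
                              variable_ratio_match)

from conftest import make_pairs, make_table


def dm(matrix):
    matrix = np.asarray(matrix, float)
    nt, nc = matrix.shape
    return DistanceMatrix(matrix,
                          np.array([f"t{i}" for i in range(nt)]),
                          np.array([f"c{j}" for j in range(nc)]))


class TestRankMahalanobis:
    def test_identical_covariates_distance_zero(self):
        t = make_table([1, 0, 1, 0], [0, 0, 0, 0],
                       {"a": [1.0, 1.0, 5.0, 5.0], "b": [2.0, 2.0, 7.0, 7.0]})
        d = rank_mahalanobis(t)
        assert d.matrix[0, 0] == pytest.approx(0.0, abs=1e-10)
        assert d.matrix[1, 1] == pytest.approx(0.0, abs=1e-10)

    def test_single_covariate_proportional_to_squared_rank_difference(self):
        # ranks of (1, 2, 3, 10) are (1, 2, 3, 4); squared Mahalanobis in
        # one dimension is (rank difference)^2 / rank variance
        t = make_table([1, 1, 0, 0], [0, 0, 0, 0], {"a": [1.0, 2.0, 3.0, 10.0]})
        d = rank_mahalanobis(t)
        var = np.var([1, 2, 3, 4], ddof=1)
        expect = np.array([[(1 - 3) ** 2, (1 - 4) ** 2],
                           [(2 - 3) ** 2, (2 - 4) ** 2]]) / var
        np.testing.assert_allclose(d.matrix, expect)

    def test_invariant_to_monotone_transform(self):
        base = {"a": [1.0, 2.0, 3.0, 2.5], "b": [0.0, 1.0, 0.0, 1.0]}
        trans = {"a": [1.0, 10.0, 100.0, 50.0], "b": base["b"]}
        z, r = [1, 0, 1, 0], [0, 0, 0, 0]
        d1 = rank_mahalanobis(make_table(z, r, base))
        d2 = rank_mahalanobis(make_table(z, r, trans))
        np.testing.assert_allclose(d1.matrix, d2.matrix)

    def test_zero_variance_covariate_dropped_with_warning(self):
        t = make_table([1, 0, 1, 0], [0, 0, 0, 0],
                       {"a": [1.0, 2.0, 3.0, 4.0], "flat": [7.0] * 4})
        with pytest.warns(UserWarning, match="zero-variance"):
            d = rank_mahalanobis(t)
        assert np.isfinite(d.matrix).all()


class TestPropensityScores:
    def test_independent_covariates_give_treated_fraction(self):
        n = 2000
        local = np.random.default_rng(7)
        z = (local.random(n) < 0.3).astype(int)
        z[:2] = [1, 0]
        t = make_table(z, np.zeros(n), {"a": local.normal(size=n),
                                        "b": local.integers(0, 2, n) * 1.0})
        ps = propensity_scores(t)
        assert np.abs(ps.to_numpy() - z.mean()).max() < 0.05

    def test_constant_covariate_scores_exactly_treated_fraction(self):
        t = make_table([1, 0, 0, 0], np.zeros(4), {"a": [3.0] * 4})
        ps = propensity_scores(t)
        np.testing.assert_allclose(ps.to_numpy(), 0.25)

    def test_separation_falls_back_to_ridge(self):
        z = [1, 1, 1, 0, 0, 0]
        t = make_table(z, np.zeros(6), {"a": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]})
        ps = propensity_scores(t)  # must not blow up to 0/1
        assert ((ps > 0) & (ps < 1)).all()


class TestCaliper:
    def setup_method(self):
        self.d = dm([[1.0, 2.0], [3.0, 4.0]])
        self.scores = pd.Series([0.5, 0.5, 0.5, 0.9],
                                index=["t0", "t1", "c0", "c1"])

    def test_gap_within_width_unchanged(self):
        c = MatchConstraints(caliper_width=0.5, caliper_penalty=1000)
        out = apply_caliper(self.d, self.scores, c)
        np.testing.assert_allclose(out.matrix[:, 0], self.d.matrix[:, 0])

    def test_double_width_gap_adds_full_penalty(self):
        c = MatchConstraints(caliper_width=0.2, caliper_penalty=1000)
        out = apply_caliper(self.d, self.scores, c)  # gap 0.4 = 2 x width
        np.testing.assert_allclose(out.matrix[:, 1],
                                   self.d.matrix[:, 1] + 1000.0)

    def test_zero_penalty_is_identity(self):
        c = MatchConstraints(caliper_width=0.01, caliper_penalty=0.0)
        out = apply_caliper(self.d, self.scores, c)
        np.testing.assert_allclose(out.matrix, self.d.matrix)


class TestAlmostExact:
    def test_agreement_unchanged_disagreement_additive(self):
        t = make_table([1, 1, 0, 0], np.zeros(4),
                       {"k1": [0, 1, 0, 1], "k2": [0, 0, 0, 1],
                        "k3": [1, 1, 1, 1]})
        d = dm([[1.0, 1.0], [1.0, 1.0]])
        out = apply_almost_exact(d, t, ["k1", "k2", "k3"], penalty=100.0)
        assert out.matrix[0, 0] == 1.0                 # agree on all keys
        assert out.matrix[0, 1] == 1.0 + 2 * 100.0     # disagrees on k1, k2
        assert out.matrix[1, 1] == 1.0 + 100.0

    def test_exact_assignment_beats_any_mismatch(self):
        # brute force over all 3x3 assignments: with the default dominant
        # penalty, every all-exact assignment costs less than any with a
        # single mismatch
        t = make_table([1, 1, 1, 0, 0, 0], np.zeros(6),
                       {"k": [0, 1, 0, 1, 0, 0]})
        base = np.array([[5.0, 1.0, 9.0], [1.0, 8.0, 2.0], [4.0, 3.0, 7.0]])
        out = apply_almost_exact(dm(base), t, ["k"])
        key = np.array([0, 1, 0]), np.array([1, 0, 0])
        costs = {}
        for perm in itertools.permutations(range(3)):
            mism = sum(key[0][i] != key[1][j] for i, j in enumerate(perm))
            costs.setdefault(mism, []).append(
                sum(out.matrix[i, j] for i, j in enumerate(perm)))
        worst_exact = max(costs.pop(0))
        best_inexact = min(min(v) for v in costs.values())
        assert worst_exact < best_inexact


class TestPairMatch:
    def test_diagonal_is_optimal(self):
        s = pair_match(dm([[1.0, 10.0], [10.0, 1.0]]))
        got = {(x.treated_id, x.control_ids[0]) for x in s.sets}
        assert got == {("t0", "c0"), ("t1", "c1")}
        assert s.provenance["total_distance"] == pytest.approx(2.0)

    def test_greedy_is_suboptimal_here(self):
        # enumerating both assignments: cross pairing totals 3 < 101
        s = pair_match(dm([[1.0, 2.0], [1.0, 100.0]]))
        got = {(x.treated_id, x.control_ids[0]) for x in s.sets}
        assert got == {("t0", "c1"), ("t1", "c0")}

    def test_all_infinite_raises_listing_units(self):
        with pytest.raises(MatchingInfeasibleError, match="t0"):
            pair_match(dm([[np.inf, np.inf], [np.inf, np.inf]]))

    def test_matches_brute_force_minimum(self, rng):
        # exhaustive oracle over all control subsets/permutations, <= 6 treated
        for trial in range(12):
            nt = int(rng.integers(2, 6))
            nc = int(rng.integers(nt, nt + 3))
            mat = rng.random((nt, nc)) * 10
            best = min(sum(mat[i, p[i]] for i in range(nt))
                       for p in itertools.permutations(range(nc), nt))
            s = pair_match(dm(mat))
            assert s.provenance["total_distance"] == pytest.approx(best)


class TestVariableRatio:
    def test_two_nearest_controls_selected(self):
        # enumerate all 3-choose-2 subsets: {c0, c2} is cheapest
        d = dm([[1.0, 5.0, 2.0]])
        c = MatchConstraints(control_ratio=(2, 2))
        s = variable_ratio_match(d, c)
        assert sorted(s.sets[0].control_ids) == ["c0", "c2"]

    def test_ratio_one_reduces_to_pair_match(self, rng):
        mat = rng.random((4, 6)) * 5
        c = MatchConstraints(control_ratio=(1, 1))
        a = variable_ratio_match(dm(mat), c)
        b = pair_match(dm(mat))
        assert a.to_frame().drop(columns="set_index").equals(
            b.to_frame().drop(columns="set_index"))
        assert a.provenance["total_distance"] == pytest.approx(
            b.provenance["total_distance"])

    def test_controls_cannot_be_shared(self):
        d = dm([[1.0, 1.0], [1.0, 1.0]])
        c = MatchConstraints(control_ratio=(1, 2))
        s = variable_ratio_match(d, c)
        used = [cid for st in s.sets for cid in st.control_ids]
        assert len(used) == len(set(used)) == 2

    def test_fixed_total_controls(self, rng):
        mat = rng.random((3, 9))
        c = MatchConstraints(control_ratio=(1, 3), total_controls=7)
        s = variable_ratio_match(dm(mat), c)
        assert sum(x.n - 1 for x in s.sets) == 7

    def test_insufficient_supply_raises_with_counts(self):
        d = dm([[1.0, 1.0], [1.0, 1.0]])
        c = MatchConstraints(control_ratio=(2, 2))
        with pytest.raises(MatchingInfeasibleError, match="only 2 available"):
            variable_ratio_match(d, c)


class TestFineBalance:
    def test_balanced_pairs_zero_deviation(self):
        sample, table = make_pairs([(1.0, 0.0), (2.0, 0.0)],
                                   cov={"g": ["A", "B"]})
        dev = evaluate_fine_balance(sample, table, "g")
        assert (dev == 0).all()

    def test_counting_example(self):
        # treated levels (A, A), controls (A, B): deviation 1 for each
        from hetsens.matching import MatchedSample, MatchedSet
        table = make_table([1, 0, 1, 0], np.zeros(4),
                           {"g": ["A", "A", "A", "B"]},
                           types={"g": "categorical"})
        sample = MatchedSample([MatchedSet(0, "u0", ["u1"]),
                                MatchedSet(1, "u2", ["u3"])])
        dev = evaluate_fine_balance(sample, table, "g")
        assert dev["A"] == 1 and dev["B"] == 1

    def test_invariant_to_relabeling(self):
        from hetsens.matching import MatchedSample, MatchedSet
        for labels in (["A", "A", "A", "B"], ["B", "B", "B", "A"]):
            table = make_table([1, 0, 1, 0], np.zeros(4), {"g": labels},
                               types={"g": "categorical"})
            sample = MatchedSample([MatchedSet(0, "u0", ["u1"]),
                                    MatchedSet(1, "u2", ["u3"])])
            dev = evaluate_fine_balance(sample, table, "g")
            assert sorted(dev.to_numpy()) == [1, 1]

    def test_near_fine_balance_steers_control_choice(self):
        # two interchangeable-by-distance controls per category; balance
        # slots push the match toward the treated marginal
        z = [1, 1, 0, 0, 0, 0]
        g = ["A", "B", "A", "A", "B", "B"]
        table = make_table(z, np.zeros(6), {"g": g}, types={"g": "categorical"})
        mat = np.zeros((2, 4))
        c = MatchConstraints(balance_keys=("g",))
        d = DistanceMatrix(mat, table.ids[:2], table.ids[2:])
        s = pair_match(d, c, table)
        picked = sorted(g[table.index_of(x.control_ids[0])] for x in s.sets)
        assert picked == ["A", "B"]


class TestStandardizedDifferences:
    def test_formula_and_zero_cases(self):
        t = make_table([1, 1, 0, 0], np.zeros(4),
                       {"a": [3.0, 1.0, 1.0, 1.0], "same": [1.0, 2.0, 1.0, 2.0]})
        rep = standardized_differences(t)
        pooled = np.sqrt((np.var([3, 1], ddof=1) + np.var([1, 1], ddof=1)) / 2)
        assert rep.loc["a", "smd_before"] == pytest.approx(1.0 / pooled)
        assert rep.loc["same", "smd_before"] == 0.0

    def test_zero_pooled_sd_flagged(self):
        t = make_table([1, 0], np.zeros(2), {"a": [2.0, 2.0]})
        rep = standardized_differences(t)
        assert bool(rep.loc["a", "zero_sd"]) and rep.loc["a", "smd_before"] == 0

    def test_matching_exactly_on_covariate_zeroes_after(self):
        sample, table = make_pairs([(1.0, 0.0), (2.0, 0.0)],
                                   cov={"x1": [0.0, 1.0], "x2": [1.0, 0.0]})
        rep = standardized_differences(table, sample)
        assert np.allclose(rep["smd_after"], 0.0)


class TestRematchInexact:
    @staticmethod
    def _pairs(profiles_t, profiles_c):
        from hetsens.matching import MatchedSample, MatchedSet
        n = len(profiles_t)
        ids, z, prof = [], [], []
        sets = []
        for i, (pt, pc) in enumerate(zip(profiles_t, profiles_c)):
            ids += [f"t{i}", f"c{i}"]
            z += [1, 0]
            prof += [pt, pc]
            sets.append(MatchedSet(i, f"t{i}", [f"c{i}"]))
        table = make_table(z, np.zeros(2 * n),
                           {"k": prof, "noise": np.arange(2 * n, dtype=float)},
                           types={"k": "categorical", "noise": "numeric"})
        table.ids = np.array(ids)
        return MatchedSample(sets), table

    def test_crossed_profiles_both_become_exact(self):
        sample, table = self._pairs(["A", "B"], ["B", "A"])
        out = rematch_inexact(sample, table, ["k"])
        assert out.I == 2
        vals = table.covariates["k"]
        for s in out.sets:
            assert (vals.iloc[table.index_of(s.treated_id)]
                    == vals.iloc[table.index_of(s.control_ids[0])])

    def test_all_exact_is_identity(self):
        sample, table = self._pairs(["A", "B"], ["A", "B"])
        out = rematch_inexact(sample, table, ["k"])
        assert out.to_frame().equals(sample.to_frame())

    def test_partial_recovery_drops_unmatchable(self):
        # 3 exact pairs; 3 inexact pairs admit exactly 2 cross-exact
        # re-pairings, so 5 pairs remain
        sample, table = self._pairs(["A", "A", "B", "A", "B", "C"],
                                    ["A", "A", "B", "B", "A", "D"])
        out = rematch_inexact(sample, table, ["k"])
        assert out.I == 5

    def test_never_fewer_exact_pairs(self, rng):
        for trial in range(10):
            pt = rng.choice(["A", "B", "C"], size=6).tolist()
            pc = rng.choice(["A", "B", "C"], size=6).tolist()
            sample, table = self._pairs(pt, pc)
            before = sum(a == b for a, b in zip(pt, pc))
            out = rematch_inexact(sample, table, ["k"])
            vals = table.covariates["k"]
            after = sum(vals.iloc[table.index_of(s.treated_id)]
                        == vals.iloc[table.index_of(s.control_ids[0])]
                        for s in out.sets)
            assert after >= before


def test_fixture_matching_improves_balance():
    table = impute_two_step(generate_fixture(40, 120, 8, 0.03, seed=8))
    dist = rank_mahalanobis(table)
    dist = apply_caliper(dist, propensity_scores(table), MatchConstraints())
    sample = pair_match(dist, MatchConstraints(), table)
    rep = standardized_differences(table, sample)
    assert rep["smd_after"].abs().mean() <= rep["smd_before"].abs().mean()
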