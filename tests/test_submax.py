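import math

import numpy as np
import pytest
from scipy.special import ndtri

from hetsens.io import ValidationError
from hetsens.matching import MatchedSample, MatchedSet
from hetsens.mscore import SensitivityModel, SetScores
from hetsens.simulation import SimConfig, generate
from hetsens.submax import (DeviateVector, build_contrasts,
                            closed_testing_submax, correlation,
                            critical_value, deviates, sensitivity_value,
                            submax_plus_pipeline, submax_test)

from conftest import make_pairs, random_paired_scores


def paired_family(rng, I, keys=("x1",), shift=0.0):
    cov = {k: rng.integers(0, 2, I).astype(float) for k in ("x1", "x2")}
    outcomes = [(rng.normal() + shift, rng.normal()) for _ in range(I)]
    sample, table = make_pairs(outcomes, cov=cov)
    family = build_contrasts(sample, table, list(keys))
    from hetsens.mscore import ScoreConfig, set_scores
    scores = set_scores(sample, table, ScoreConfig())
    return sample, table, family, scores


class TestBuildContrasts:
    def test_two_modifiers_give_five_comparisons(self, rng):
        _, _, family, _ = paired_family(rng, 30, keys=("x1", "x2"))
        assert family.K == 5 and family.L == 2
        assert family.labels[0] == "overall"

    def test_no_modifiers_overall_only(self, rng):
        _, _, family, _ = paired_family(rng, 10, keys=())
        assert family.K == 1

    def test_membership_partition_semantics(self, rng):
        sample, table, family, _ = paired_family(rng, 40, keys=("x1", "x2"))
        overall = family.members[0]
        assert len(overall) == 40
        for key in ("x1", "x2"):
            one = family.members[family.labels.index(f"{key}=1")]
            zero = family.members[family.labels.index(f"{key}=0")]
            assert set(one) & set(zero) == set()
            assert set(one) | set(zero) == set(overall)  # pairs share values

    def test_inexactly_matched_set_excluded_from_modifier_comparisons(self):
        # a variable-ratio set whose members disagree on x1 joins only the
        # overall comparison
        import pandas as pd

        from hetsens.io import ObservationalTable
        ids = np.array(["t0", "c0", "c1"])
        table = ObservationalTable(
            ids=ids, z=np.array([1, 0, 0]), r=np.zeros(3),
            covariates=pd.DataFrame({"x1": [1.0, 1.0, 0.0]}),
            covariate_types={"x1": "numeric"})
        sample = MatchedSample([MatchedSet(0, "t0", ["c0", "c1"])])
        family = build_contrasts(sample, table, ["x1"])
        assert list(family.members[0]) == [0]
        assert list(family.members[1]) == []  # x1=1
        assert list(family.members[2]) == []  # x1=0

    def test_non_binary_modifier_rejected(self, rng):
        sample, table, _, _ = paired_family(rng, 10)
        table.covariates["x1"] = 2.0
        with pytest.raises(ValidationError):
            build_contrasts(sample, table, ["x1"])


class TestDeviates:
    def test_unit_deviate_by_construction(self, rng):
        _, _, family, scores = paired_family(rng, 25)
        model = SensitivityModel(1.0)
        from hetsens.mscore import statistic, worstcase_moments
        null = worstcase_moments(scores, range(25), model)
        t = statistic(scores, range(25)).value
        dev = deviates(scores, family, model)
        assert dev.d[0] == pytest.approx((t - null.theta) / null.sigma)

    def test_null_deviates_centered(self, rng):
        vals = []
        for _ in range(300):
            sc = random_paired_scores(rng, 40)
            family = _overall_family(40)
            vals.append(deviates(sc, family, SensitivityModel(1.0)).d[0])
        assert abs(np.mean(vals)) < 0.1

    def test_weight_scaling_invariance(self, rng):
        _, _, family, scores = paired_family(rng, 30, keys=("x1",))
        model = SensitivityModel(1.4)
        d1 = deviates(scores, family, model).d
        doubled = SetScores(q=scores.q, w=2 * scores.w, s=scores.s)
        d2 = deviates(doubled, family, model).d
        np.testing.assert_allclose(d1, d2)


def _overall_family(I):
    from hetsens.submax import ContrastFamily
    return ContrastFamily(labels=["overall"], members=[np.arange(I)],
                          modifier_keys=[])


class TestCorrelation:
    def test_disjoint_comparisons_uncorrelated(self, rng):
        _, _, family, scores = paired_family(rng, 40, keys=("x1",))
        rho = correlation(scores, family, SensitivityModel(1.0))
        i, j = family.labels.index("x1=1"), family.labels.index("x1=0")
        assert rho[i, j] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_overall_vs_half_with_equal_variances(self):
        # equal per-set variances, equal halves: correlation 1/sqrt(2)
        from hetsens.submax import ContrastFamily
        qs = [np.array([1.0, -1.0])] * 8
        sc = SetScores(q=qs, w=np.ones(8), s=1.0)
        fam = ContrastFamily(labels=["overall", "half"],
                             members=[np.arange(8), np.arange(4)],
                             modifier_keys=[])
        rho = correlation(sc, fam, SensitivityModel(1.0))
        assert rho[0, 1] == pytest.approx(1 / math.sqrt(2))

    def test_identical_comparisons_fully_correlated(self, rng):
        sc = random_paired_scores(rng, 10)
        from hetsens.submax import ContrastFamily
        fam = ContrastFamily(labels=["a", "b"],
                             members=[np.arange(10), np.arange(10)],
                             modifier_keys=[])
        rho = correlation(sc, fam, SensitivityModel(1.3))
        assert rho[0, 1] == pytest.approx(1.0)


class TestCriticalValue:
    def test_univariate_is_normal_quantile(self):
        assert critical_value(np.eye(1), 0.05).kappa == pytest.approx(
            1.645, abs=1e-3)

    def test_two_independent(self):
        # kappa solves Phi(k)^2 = 0.95
        expect = float(ndtri(math.sqrt(0.95)))
        got = critical_value(np.eye(2), 0.05).kappa
        assert got == pytest.approx(expect, abs=2e-3)

    def test_perfect_dependence_collapses_to_univariate(self):
        rho = np.ones((4, 4))
        assert critical_value(rho, 0.05).kappa == pytest.approx(1.645,
                                                                abs=2e-3)

    def test_nonincreasing_in_alpha(self):
        rho = np.eye(3)
        k1 = critical_value(rho, 0.01).kappa
        k2 = critical_value(rho, 0.10).kappa
        assert k1 > k2

    def test_slepian_ordering_kappa_shrinks_with_correlation(self):
        def equi(r, K=4):
            m = np.full((K, K), r)
            np.fill_diagonal(m, 1.0)
            return m
        kappas = [critical_value(equi(r), 0.05).kappa
                  for r in (0.0, 0.3, 0.6, 0.9)]
        assert (np.diff(kappas) <= 1e-4).all()

    def test_non_psd_rejected(self):
        rho = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            critical_value(rho, 0.05)


class TestSubmaxTest:
    def test_pvalue_at_kappa_equals_alpha(self):
        rho = np.eye(3) * 0.0 + 0.4
        np.fill_diagonal(rho, 1.0)
        kappa = critical_value(rho, 0.05).kappa
        dev = DeviateVector(d=np.array([kappa, -1.0, 0.0]), gamma=1.0,
                            labels=("a", "b", "c"))
        reject, p = submax_test(dev, rho, 0.05)
        assert reject and p == pytest.approx(0.05, abs=2e-3)

    def test_huge_deviate_tiny_pvalue(self):
        dev = DeviateVector(d=np.array([7.0, 0.0]), gamma=1.0,
                            labels=("a", "b"))
        _, p = submax_test(dev, np.eye(2), 0.05)
        assert p < 1e-4

    def test_pvalue_matches_monte_carlo_exceedance(self, rng):
        rho = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        dmax = 1.7
        dev = DeviateVector(d=np.array([dmax, 0.0, 0.3]), gamma=1.0,
                            labels=("a", "b", "c"))
        _, p = submax_test(dev, rho, 0.05)
        L = np.linalg.cholesky(rho)
        draws = rng.standard_normal((10**5, 3)) @ L.T
        mc = float(np.mean(draws.max(axis=1) > dmax))
        se = math.sqrt(mc * (1 - mc) / 10**5)
        assert abs(p - mc) <= 3 * se


class TestClosedTestingSubmax:
    def test_all_large_deviates_reject_everything(self):
        dev = DeviateVector(d=np.full(5, 9.0), gamma=1.0,
                            labels=tuple("abcde"))
        res = closed_testing_submax(dev, np.eye(5), 0.05)
        assert all(res.singletons.values())

    def test_null_deviates_reject_nothing(self):
        dev = DeviateVector(d=np.zeros(5), gamma=1.0, labels=tuple("abcde"))
        res = closed_testing_submax(dev, np.eye(5), 0.05)
        assert not any(res.singletons.values())

    def test_closure_property_random_instances(self, rng):
        for _ in range(5):
            K = 4
            A = rng.normal(size=(K, K))
            rho = A @ A.T
            d = np.sqrt(np.diag(rho))
            rho = np.abs(rho / np.outer(d, d))
            np.fill_diagonal(rho, 1.0)
            # project to nearest PSD just in case
            w, V = np.linalg.eigh(rho)
            rho = (V * np.clip(w, 1e-6, None)) @ V.T
            d = np.sqrt(np.diag(rho))
            rho = rho / np.outer(d, d)
            dev = DeviateVector(d=rng.normal(1.5, 1.0, K), gamma=1.0,
                                labels=tuple("abcd"))
            res = closed_testing_submax(dev, rho, 0.05)
            for J, rej in res.reject.items():
                if rej:
                    assert all(res.reject[Jp] for Jp in res.reject
                               if Jp >= J)
            # singleton rejections imply the unadjusted per-comparison test
            for k, lbl in enumerate(dev.labels):
                if res.singletons[lbl]:
                    assert dev.d[k] >= critical_value(np.eye(1), 0.05).kappa


class TestSensitivityValue:
    def test_never_rejected_returns_grid_start(self):
        assert sensitivity_value(lambda g: False, [1.0, 1.1]) == 1.0

    def test_crossing_located_on_grid(self):
        # rejection holds through 1.81 and fails from 1.82 onward
        val = sensitivity_value(lambda g: g <= 1.815,
                                np.arange(1.0, 2.01, 0.01).round(2))
        assert val == pytest.approx(1.82)

    def test_grid_coarsening_never_decreases_value(self):
        fine = np.arange(1.0, 3.01, 0.01).round(2)
        coarse = np.arange(1.0, 3.1, 0.1).round(1)
        test = lambda g: g <= 1.77  # noqa: E731
        assert (sensitivity_value(test, coarse)
                >= sensitivity_value(test, fine))

    def test_rejected_everywhere_reports_above_grid(self):
        assert sensitivity_value(lambda g: True, [1.0, 1.5]) == math.inf


class TestSubmaxPlus:
    def test_no_tree_split_reduces_to_overall_only(self, rng):
        sample, table, truth = generate(
            SimConfig(I=80, p=2, beta=(0.0, 0.0), seed=5), seed=5)
        res = submax_plus_pipeline(table, table.covariate_names, [1.0],
                                   pair_sample=sample,
                                   analysis_sample=sample)
        assert res.family.K == 1

    def test_two_sided_runs_both_tails(self, rng):
        sample, table, truth = generate(
            SimConfig(I=150, p=2, beta=(-2.0, -2.0), seed=8), seed=8)
        res = submax_plus_pipeline(table, table.covariate_names, [1.0],
                                   pair_sample=sample, analysis_sample=sample,
                                   two_sided=True)
        # strongly negative effects only reject through the lower tail
        assert res.rejections.loc[1.0].any()
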