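from itertools import combinations

import numpy as np
import pytest

import ke4dflow as k
from ke4dflow.errors import AnalysisError, DegenerateDataError
from ke4dflow.stats import SubjectRecord, SuppressionNotice


def brute_force_mw_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    u_obs = sum(1 for a in x for b in y if a > b)
    us = []
    for comb in combinations(range(n1 + n2), n1):
        cs = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(n1 + n2) if i not in cs]
        us.append(sum(1 for a in xs for b in ys if a > b))
    us = np.asarray(us)
    p_lo = np.mean(us <= u_obs)
    p_hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_lo, p_hi))


class TestMannWhitney:
    def test_complete_separation_five_vs_five(self):
        res = k.mann_whitney([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert res.exact
        assert res.p_value == pytest.approx(2 / 252, rel=1e-12)

    def test_symmetric_samples_give_p_one(self):
        res = k.mann_whitney([1, 4], [2, 3])
        assert res.p_value == 1.0

    def test_single_inversion_from_separation(self):
        res = k.mann_whitney([1, 2, 3, 4, 6], [5, 7, 8, 9, 10])
        assert res.p_value == pytest.approx(4 / 252, rel=1e-12)

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 12)
                                       for n2 in range(1, 12)
                                       if n1 + n2 <= 12])
    def test_exact_p_equals_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        data = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        x, y = data[:n1], data[n1:]
        res = k.mann_whitney(x, y, mode="exact")
        assert res.p_value == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=6)
        y = rng.normal(1.0, size=5)
        p_raw = k.mann_whitney(x, y).p_value
        p_exp = k.mann_whitney(np.exp(x), np.exp(y)).p_value
        assert p_raw == pytest.approx(p_exp, rel=1e-12)

    def test_exact_mode_refuses_ties(self):
        with pytest.raises(AnalysisError, match="tie"):
            k.mann_whitney([1, 2, 2], [3, 4], mode="exact")

    def test_tied_data_falls_back_to_corrected_approximation(self):
        res = k.mann_whitney([1, 2, 2, 3], [2, 4, 5, 6], mode="auto")
        assert not res.exact
        assert 0 <= res.p_value <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(DegenerateDataError):
            k.mann_whitney([], [1, 2])


class TestPearson:
    def test_perfect_positive_linearity(self):
        x = np.arange(10.0)
        res = k.pearson_correlation(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(5.0)
        assert k.pearson_correlation(x, -x).statistic == pytest.approx(-1.0)

    def test_fixture_against_formula_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (
            x.std() * y.std())
        res = k.pearson_correlation(x, y)
        assert res.statistic == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            k.pearson_correlation([1, 1, 1], [1, 2, 3])


# 11-subject single-ventricle cohort: subjects 1, 2, 9, 10 have a left
# ventricle with a short outflow tract (predicting the diastolic-dominant
# pattern); 3-8 a right ventricle and 11 an LV with a long outflow tract
# (predicting systolic-dominant).  Observed KE patterns agree perfectly.
MORPHOLOGY = ["short_outflow", "short_outflow", "long_outflow", "long_outflow",
              "long_outflow", "long_outflow", "long_outflow", "long_outflow",
              "short_outflow", "short_outflow", "long_outflow"]
PREDICTED_PATTERN = {"short_outflow": "diastolic_dominant",
                     "long_outflow": "systolic_dominant"}
KE_PATTERN = ["diastolic_dominant", "diastolic_dominant", "systolic_dominant",
              "systolic_dominant", "systolic_dominant", "systolic_dominant",
              "systolic_dominant", "systolic_dominant", "diastolic_dominant",
              "diastolic_dominant", "systolic_dominant"]


class TestCohensKappa:
    def test_identical_vectors(self):
        res = k.cohens_kappa(["a", "b", "a"], ["a", "b", "a"])
        assert res.kappa == 1.0 and res.observed_agreement == 1.0

    def test_cohort_morphology_vs_pattern_agreement(self):
        predicted = [PREDICTED_PATTERN[m] for m in MORPHOLOGY]
        res = k.cohens_kappa(predicted, KE_PATTERN)
        assert res.kappa == pytest.approx(1.0)
        assert res.n == 11

    def test_independent_labels_give_near_zero_kappa(self):
        rng = np.random.default_rng(0)
        kappas = []
        for _ in range(300):
            a = rng.integers(0, 2, size=40)
            b = rng.integers(0, 2, size=40)
            kappas.append(k.cohens_kappa(a.tolist(), b.tolist()).kappa)
        assert abs(np.mean(kappas)) < 0.03

    def test_invariant_under_label_renaming(self):
        a = ["x", "y", "x", "z", "y"]
        b = ["x", "x", "x", "z", "y"]
        ren = {"x": 1, "y": 2, "z": 3}
        base = k.cohens_kappa(a, b)
        renamed = k.cohens_kappa([ren[v] for v in a], [ren[v] for v in b])
        assert base.kappa == pytest.approx(renamed.kappa, abs=1e-12)

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, size=30).tolist()
        b = rng.integers(0, 3, size=30).tolist()
        assert k.cohens_kappa(a, b).kappa == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(AnalysisError, match="length"):
            k.cohens_kappa(["a"], ["a", "b"])


class TestInterobserverVariability:
    def test_identical_observers(self):
        mean, sd = k.interobserver_variability([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (mean, sd) == (0.0, 0.0)

    def test_constant_ten_percent_offset(self):
        b = np.array([1.0, 2.0, 3.0, 4.0])
        mean, sd = k.interobserver_variability(1.1 * b, b)
        assert mean == pytest.approx(100 * 0.1 / 1.05, rel=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetric_in_arguments(self):
        a = [1.2, 2.1, 2.9]
        b = [1.0, 2.0, 3.0]
        m1, _ = k.interobserver_variability(a, b)
        m2, _ = k.interobserver_variability(b, a)
        assert m1 == pytest.approx(-m2)

    def test_nonpositive_pair_mean_rejected(self):
        with pytest.raises(AnalysisError, match="pair mean"):
            k.interobserver_variability([1.0, -2.0], [1.0, 1.0])


class TestGroupComparison:
    def test_small_subgroups_are_suppressed(self):
        res = k.compare_groups([1, 2, 3], [4, 5, 6, 7, 8])
        assert isinstance(res, SuppressionNotice)
        assert "suppressed" in res.reason

    def test_large_enough_groups_are_tested(self):
        res = k.compare_groups([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert not isinstance(res, SuppressionNotice)
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)


def _record(i, group, morph, **kw):
    return SubjectRecord(subject_id=f"s{i}", group=group, morphology=morph, **kw)


class TestCohortTable:
    def test_single_record_mean_with_n_flag(self):
        table = k.cohort_table([_record(0, "fontan", "left", ef=43.0)])
        row = table[table.metric == "ef"].iloc[0]
        assert row["mean"] == 43.0 and row["sd"] == 0.0 and row["n"] == 1

    def test_groups_by_morphology(self):
        recs = [
            _record(0, "fontan", "left", ef=40.0),
            _record(1, "fontan", "left", ef=46.0),
            _record(2, "control", "left", ef=57.0),
        ]
        table = k.cohort_table(recs)
        f = table[(table.group == "fontan") & (table.metric == "ef")].iloc[0]
        assert f["mean"] == pytest.approx(43.0)
        assert f["sd"] == pytest.approx(np.std([40, 46], ddof=1))

    def test_empty_metric_cells_are_omitted(self):
        table = k.cohort_table([_record(0, "fontan", "left", ef=43.0)])
        assert "co" not in set(table.metric)
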