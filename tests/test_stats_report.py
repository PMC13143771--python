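import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vogain.errors import (DataError, InsufficientDataError, ParameterError)
from vogain.stats_report import (bonferroni_adjust, fit_cohort_model,
                                 friedman_test, midrank, reliability_report,
                                 spearman_rho, wilcoxon_signed_rank)

# -- independent brute-force oracles ---------------------------------------


def naive_midrank(values):
    """Quadratic-time midranks computed independently of the implementation."""
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(less + (equal + 1) / 2.0)
    return np.array(out)


def pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2)))


small_vectors = st.lists(st.integers(0, 4), min_size=3, max_size=8)


class TestSpearman:
    def test_monotone_transform_gives_unity(self):
        x = np.arange(1, 8, dtype=float)
        assert spearman_rho(x, x ** 2) == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(6, dtype=float)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_tied_example_matches_midrank_oracle(self):
        x, y = [1, 1, 2, 2], [1, 2, 3, 4]
        assert spearman_rho(x, y) == pytest.approx(
            pearson(naive_midrank(x), naive_midrank(y)), abs=1e-12)

    @given(x=small_vectors, y=small_vectors)
    def test_matches_brute_force_on_all_small_tied_inputs(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if len(set(x)) < 2 or len(set(y)) < 2:
            with pytest.raises(DataError):
                spearman_rho(x, y)
            return
        assert spearman_rho(x, y) == pytest.approx(
            pearson(naive_midrank(x), naive_midrank(y)), abs=1e-12)

    def test_matches_scipy_cross_check(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 5, 10)
            y = rng.integers(0, 5, 10)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert spearman_rho(x, y) == pytest.approx(
                spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_input_is_an_error(self):
        with pytest.raises(DataError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestFriedman:
    def test_identical_columns_give_zero_statistic(self):
        m = np.tile([[3.0], [1.0], [2.0]], (1, 4))
        res = friedman_test(m)
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_five_conditions_have_four_degrees_of_freedom(self):
        m = np.random.default_rng(0).normal(size=(6, 5))
        assert friedman_test(m).df == 4

    @given(st.lists(st.lists(st.integers(0, 4), min_size=3, max_size=3),
                    min_size=3, max_size=6))
    def test_matches_scipy_on_small_tied_matrices(self, rows):
        from scipy.stats import friedmanchisquare
        m = np.array(rows, dtype=float)
        try:
            mine = friedman_test(m)
        except DataError:
            return
        if mine.chi_square == 0.0:
            return  # scipy divides by zero on fully tied data
        ref = friedmanchisquare(*m.T)
        assert mine.chi_square == pytest.approx(ref.statistic, abs=1e-10)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_statistic_matches_direct_rank_computation(self):
        # independent evaluation of the tie-corrected formula on a small case
        m = np.array([[1, 2, 3], [2, 2, 3], [1, 3, 2]], dtype=float)
        ranks = np.array([naive_midrank(row) for row in m])
        n, k = m.shape
        rj = ranks.sum(axis=0)
        stat = 12 / (n * k * (k + 1)) * np.sum(rj ** 2) - 3 * n * (k + 1)
        ties = sum(np.sum(c ** 3 - c)
                   for row in m
                   for c in [np.unique(row, return_counts=True)[1]])
        stat /= 1 - ties / (n * k * (k * k - 1))
        assert friedman_test(m).chi_square == pytest.approx(stat, abs=1e-12)

    def test_incomplete_blocks_rejected(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(DataError):
            friedman_test(m)


class TestWilcoxon:
    def test_equal_samples_are_degenerate(self):
        with pytest.raises(DataError):
            wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])

    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)),
                    min_size=5, max_size=8))
    def test_exact_p_matches_sign_enumeration(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        d = np.array(a, float) - np.array(b, float)
        d = d[d != 0]
        if len(d) < 5:
            return
        res = wilcoxon_signed_rank(a, b)
        ranks = naive_midrank(np.abs(d))
        w_obs = float(ranks[d > 0].sum())
        dist = [sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([0, 1], repeat=len(d))]
        lower = sum(w <= w_obs + 1e-9 for w in dist) / len(dist)
        upper = sum(w >= w_obs - 1e-9 for w in dist) / len(dist)
        assert res.p_value == pytest.approx(
            min(1.0, 2 * min(lower, upper)), abs=1e-9)
        assert res.statistic == pytest.approx(
            min(w_obs, float(ranks.sum()) - w_obs))

    def test_large_shift_reaches_enumeration_floor(self):
        a = np.arange(8, dtype=float)
        res = wilcoxon_signed_rank(a + 100, a)
        assert res.statistic == 0
        assert res.p_value == pytest.approx(2 * 0.5 ** 8)

    def test_normal_approximation_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.4, 1.0, 25)
        b = np.zeros(25)
        exact = wilcoxon_signed_rank(a, b, exact_max_n=25)
        approx = wilcoxon_signed_rank(a, b, exact_max_n=10)
        assert approx.p_value == pytest.approx(exact.p_value, rel=0.2, abs=0.005)


class TestBonferroni:
    def test_simple_scaling_and_capping(self):
        out = bonferroni_adjust([0.01, 0.5], m=4)
        assert out[0] == pytest.approx(0.04)
        assert out[1] == 1.0

    def test_ordering_preserved(self):
        p = np.array([0.2, 0.01, 0.04, 0.8])
        out = bonferroni_adjust(p)
        assert list(np.argsort(out)) == list(np.argsort(p))

    def test_m_smaller_than_inputs_rejected(self):
        with pytest.raises(ParameterError):
            bonferroni_adjust([0.1, 0.2, 0.3], m=2)


class TestCohortModel:
    @staticmethod
    def _toy_table(n_participants=12, noise_sd=0.0, direction_effect=0.0,
                   age_slope_per_decade=0.0, seed=0):
        import pandas as pd
        rng = np.random.default_rng(seed)
        rows = []
        ages = np.linspace(20, 79, n_participants)
        for p in range(n_participants):
            for f in (0.25, 0.5, 0.75, 1.0, 1.25):
                for d in ("left", "right"):
                    g = 0.5 + age_slope_per_decade * (ages[p] - ages.mean()) / 10
                    if d == "right":
                        g += direction_effect
                    g += rng.normal(0, noise_sd)
                    rows.append({"participant_id": f"P{p}", "age_years": ages[p],
                                 "test_type": "VORS",
                                 "intended_frequency_hz": f,
                                 "direction": d, "gain": g})
        return pd.DataFrame(rows)

    def test_zero_noise_zero_effect_gives_zero_estimates(self):
        table = self._toy_table()
        res = fit_cohort_model(table, "VORS")
        assert abs(res.direction_effect["estimate"]) < 1e-6
        assert abs(res.age_slope_per_decade["estimate"]) < 1e-6
        assert np.allclose(res.frequency_contrasts["estimate"], 0.0, atol=1e-6)

    def test_known_effects_recovered_exactly_without_noise(self):
        table = self._toy_table(direction_effect=0.08,
                                age_slope_per_decade=0.008)
        res = fit_cohort_model(table, "VORS")
        assert res.direction_effect["estimate"] == pytest.approx(0.08, abs=1e-6)
        assert res.age_slope_per_decade["estimate"] == pytest.approx(0.008,
                                                                     abs=1e-6)

    def test_contrasts_are_against_the_half_hz_reference(self):
        table = self._toy_table(noise_sd=0.01)
        res = fit_cohort_model(table, "VORS")
        assert res.reference_frequency_hz == 0.5
        assert set(res.frequency_contrasts["frequency_hz"]) == {0.25, 0.75, 1.0, 1.25}
        assert "p_bonferroni" in res.frequency_contrasts

    def test_missing_reference_level_rejected(self):
        table = self._toy_table()
        table = table[table["intended_frequency_hz"] != 0.5]
        with pytest.raises(ParameterError):
            fit_cohort_model(table, "VORS")


class TestReliabilityReport:
    @staticmethod
    def _table():
        from vogain.pipeline import cohort_table
        from vogain.simulate import SimCohortParams, simulate_cohort
        sim = simulate_cohort(SimCohortParams(
            n_participants=4, frequency_levels_hz=(0.5, 1.0),
            duration_s=16.0, blink_rate_per_min=0.0, seed=0))
        table, failures = cohort_table([r for r, _ in sim.recordings])
        assert not failures
        return table

    def test_report_is_pure_function_of_table(self):
        table = self._table()
        r1 = reliability_report(table)
        r2 = reliability_report(table.copy())
        for tt in r1.by_test_type:
            a, b = r1.by_test_type[tt], r2.by_test_type[tt]
            assert a.rho_intended_vs_actual_frequency == \
                b.rho_intended_vs_actual_frequency
            assert a.per_level.equals(b.per_level)

    def test_intended_vs_actual_rho_matches_oracle(self):
        table = self._table()
        rep = reliability_report(table).by_test_type["VVOR"]
        per_rec = table[table.test_type == "VVOR"].drop_duplicates(
            subset=["participant_id", "intended_frequency_hz"])
        oracle = pearson(naive_midrank(per_rec["intended_frequency_hz"]),
                         naive_midrank(per_rec["actual_frequency_hz"]))
        assert rep.rho_intended_vs_actual_frequency == pytest.approx(
            oracle, abs=1e-12)

    def test_single_frequency_level_flags_correlation_not_computable(self):
        table = self._table()
        sub = table[table["intended_frequency_hz"] == 0.5]
        rep = reliability_report(sub).by_test_type["VVOR"]
        assert rep.rho_intended_vs_actual_frequency is None
        assert any("not_computable" in f for f in rep.flags)

    def test_descriptives_contain_expected_columns(self):
        rep = reliability_report(self._table()).by_test_type["VORS"]
        assert {"mean", "ci95_low", "ci95_high", "median", "min", "max"} <= \
            set(rep.gain_descriptives.columns)
        assert {"median", "min", "max"} <= set(rep.saccade_descriptives.columns)
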