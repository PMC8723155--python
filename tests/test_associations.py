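"""Outcome typing, the three built-in tests, orchestration and Bonferroni."""

import numpy as np
import pandas as pd
import pytest

from sgi import (
    OutcomeTable,
    bonferroni_adjust,
    fisher_exact,
    infer_outcome_type,
    logrank_test,
    results_to_frame,
    run_associations,
    t_test,
)
from sgi.associations import SkipTest, _fisher_r2_exact
from oracles import fisher_2x2_p, logrank_chi2, welch_t


def _col(left_vals, right_vals, name="y"):
    """Build (left_ids, right_ids, column) from two value lists."""
    ids_l = [f"L{i}" for i in range(len(left_vals))]
    ids_r = [f"R{i}" for i in range(len(right_vals))]
    col = pd.Series(list(left_vals) + list(right_vals), index=ids_l + ids_r, name=name)
    return frozenset(ids_l), frozenset(ids_r), col


class TestInference:
    def test_text_column_is_categorical(self):
        assert infer_outcome_type(pd.Series(["F", "M", "F"])) == "categorical"

    def test_real_valued_column_is_continuous(self):
        assert infer_outcome_type(pd.Series(np.linspace(18.0, 42.0, 30))) == "continuous"

    def test_low_cardinality_numeric_is_categorical(self):
        assert infer_outcome_type(pd.Series([0, 1, 2] * 10)) == "categorical"

    def test_declared_pair_is_survival(self):
        out = OutcomeTable(
            pd.DataFrame({"t": [1.0, 2.0], "e": [1, 0]}, index=["a", "b"]),
            survival={"os": ("t", "e")},
        )
        assert out.types["os"] == "survival"
        assert out.outcome_names == ["os"]
        assert list(out.column("os").columns) == ["time", "event"]

    def test_declaration_overrides_inference(self):
        out = OutcomeTable(
            pd.DataFrame({"dose": [1, 2, 3, 1, 2, 3]}, index=list("abcdef")),
            types={"dose": "continuous"},
        )
        assert out.types["dose"] == "continuous"

    def test_all_missing_column_is_an_error(self):
        with pytest.raises(ValueError, match="no observed values"):
            infer_outcome_type(pd.Series([np.nan, np.nan], name="x"))

    def test_negative_survival_time_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            OutcomeTable(
                pd.DataFrame({"t": [-1.0], "e": [1]}, index=["a"]), survival={"os": ("t", "e")}
            )


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected_p",
        [
            ([[1, 1], [1, 1]], 1.0),
            ([[2, 0], [0, 2]], 1 / 3),
            ([[5, 0], [0, 5]], 2 / 252),
        ],
    )
    def test_known_tables(self, table, expected_p):
        left = ["A"] * table[0][0] + ["B"] * table[1][0]
        right = ["A"] * table[0][1] + ["B"] * table[1][1]
        l, r, col = _col(left, right)
        _, p, test = fisher_exact(l, r, col)
        assert test == "fisher"
        assert p == pytest.approx(expected_p, rel=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_2x2_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 9, size=(2, 2))
        while table.sum() > 30 or table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            table = rng.integers(0, 9, size=(2, 2))
        left = ["A"] * table[0][0] + ["B"] * table[1][0]
        right = ["A"] * table[0][1] + ["B"] * table[1][1]
        l, r, col = _col(left, right)
        _, p, _ = fisher_exact(l, r, col)
        assert p == pytest.approx(fisher_2x2_p(table), abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_r2_enumeration_agrees_with_2x2_route(self, seed):
        # the r x 2 enumeration, run on 2 x 2 tables, must match scipy's exact p
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 8, size=(2, 2))
        assert _fisher_r2_exact(np.array(table)) == pytest.approx(
            fisher_2x2_p(table), abs=1e-10
        )

    def test_three_level_exact(self):
        # perfectly separated 3 x 2 table: p = 2 / multinomial(6; 2,2,2) = 1/45... computed by the
        # independent enumeration below
        l, r, col = _col(["A", "A", "B"], ["B", "C", "C"])
        _, p, test = fisher_exact(l, r, col)
        assert test == "fisher"
        # brute force over all 3x2 tables with these margins
        from itertools import product
        from math import comb

        rows, n_left = [2, 2, 2], 3
        p_obs = None
        probs = []
        denom = comb(6, 3)
        for ks in product(range(3), range(3), range(3)):
            if sum(ks) != n_left:
                continue
            pr = np.prod([comb(rv, k) for rv, k in zip(rows, ks)]) / denom
            probs.append((ks, pr))
            if list(ks) == [2, 1, 0]:
                p_obs = pr
        expected = sum(pr for _, pr in probs if pr <= p_obs + 1e-12)
        assert p == pytest.approx(expected, abs=1e-10)

    def test_unobserved_level_dropped_single_level_skipped(self):
        l, r, col = _col(["A", "A"], ["A", None])
        with pytest.raises(SkipTest, match="fewer than 2"):
            fisher_exact(l, r, col)

    def test_montecarlo_fallback_reports_seed(self, monkeypatch):
        import sgi.associations as assoc

        monkeypatch.setattr(assoc, "_FISHER_ENUM_LIMIT", 1)
        rng = np.random.default_rng(0)
        l, r, col = _col(rng.integers(0, 6, 40), rng.integers(0, 6, 40))
        col = col.astype(str)
        _, p, test = fisher_exact(l, r, col)
        assert "fisher-mc(seed=" in test
        assert 0 < p <= 1


class TestTTest:
    def test_identical_groups_t_zero_p_one(self):
        l, r, col = _col([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        t, p, _ = t_test(l, r, col)
        assert t == 0.0 and p == 1.0

    def test_closed_form_example(self):
        l, r, col = _col([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        t, p, name = t_test(l, r, col)
        assert name == "t-welch"
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=1e-3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_welch_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, rng.integers(3, 20))
        y = rng.normal(0.5, 2, rng.integers(3, 20))
        l, r, col = _col(x, y)
        t, p, _ = t_test(l, r, col)
        t0, _, p0 = welch_t(x, y)
        assert t == pytest.approx(t0, rel=1e-10)
        assert p == pytest.approx(p0, rel=1e-10)

    def test_shift_moves_t_monotonically(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        ts = []
        for c in (0.0, 1.0, 2.0, 4.0):
            l, r, col = _col(x, y + c)
            ts.append(t_test(l, r, col)[0])
        assert ts == sorted(ts, reverse=True)

    def test_small_side_skipped(self):
        l, r, col = _col([1.0], [2.0, 3.0, 4.0])
        with pytest.raises(SkipTest, match="fewer than 2"):
            t_test(l, r, col)

    def test_degenerate_constant_groups_skipped(self):
        l, r, col = _col([2.0, 2.0, 2.0], [2.0, 2.0])
        with pytest.raises(SkipTest, match="zero variance"):
            t_test(l, r, col)

    def test_pooled_option(self):
        from scipy import stats

        x, y = [1.0, 2.0, 5.0], [2.0, 4.0, 9.0, 3.0]
        l, r, col = _col(x, y)
        t, p, name = t_test(l, r, col, kind="pooled")
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert name == "t-pooled"
        assert t == pytest.approx(ref.statistic)


def _surv_col(ta, ea, tb, eb):
    ids_l = [f"L{i}" for i in range(len(ta))]
    ids_r = [f"R{i}" for i in range(len(tb))]
    col = pd.DataFrame(
        {"time": list(ta) + list(tb), "event": list(ea) + list(eb)}, index=ids_l + ids_r
    )
    return frozenset(ids_l), frozenset(ids_r), col


class TestLogrank:
    def test_identical_survival_chi2_zero(self):
        l, r, col = _surv_col([1, 2, 3], [1, 1, 0], [1, 2, 3], [1, 1, 0])
        chi2, p, _ = logrank_test(l, r, col)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # events at 1,2 vs 3,4 with no censoring: chi2 = (2 - 5/6)^2 / (17/36) = 49/17
        l, r, col = _surv_col([1, 2], [1, 1], [3, 4], [1, 1])
        chi2, p, _ = logrank_test(l, r, col)
        assert chi2 == pytest.approx(49 / 17, rel=1e-9)
        assert p == pytest.approx(0.0896, abs=1e-3)

    def test_early_censoring_shrinks_risk_sets(self):
        # right side fully censored before the first left event: only left
        # subjects remain at risk, so O - E = 0 at every event time
        l, r, col = _surv_col([5, 6, 7], [1, 1, 1], [1, 2, 3], [0, 0, 0])
        chi2, _, _ = logrank_test(l, r, col)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert chi2 == pytest.approx(logrank_chi2([5, 6, 7], [1, 1, 1], [1, 2, 3], [0, 0, 0]))

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_oev_accumulator(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(4, 21, size=2)
        ta = np.round(rng.exponential(5, na), 1) + 0.1
        tb = np.round(rng.exponential(8, nb), 1) + 0.1
        ea = rng.integers(0, 2, na)
        eb = rng.integers(0, 2, nb)
        if ea.sum() + eb.sum() == 0:
            ea[0] = 1
        l, r, col = _surv_col(ta, ea, tb, eb)
        chi2, _, _ = logrank_test(l, r, col)
        assert chi2 == pytest.approx(logrank_chi2(ta, ea, tb, eb), rel=1e-6, abs=1e-9)

    def test_no_events_skipped(self):
        l, r, col = _surv_col([1, 2], [0, 0], [3, 4], [0, 0])
        with pytest.raises(SkipTest, match="no events"):
            logrank_test(l, r, col)


class TestRunAssociations:
    def test_one_result_per_pair_outcome_combination(self, fitted):
        valid = [p for p in fitted.splits_ if p.is_valid]
        n_outcomes = len(fitted.outcomes_.outcome_names)
        assert len(fitted.results_) == len(valid) * n_outcomes
        keys = {(r.cid_left, r.outcome) for r in fitted.results_}
        assert len(keys) == len(fitted.results_)

    def test_missing_side_skips_only_that_result(self, fitted):
        data_outcomes = fitted.outcomes_.data.copy()
        top = fitted.splits_[0]
        data_outcomes.loc[list(top.members_left), "bmi"] = np.nan
        from sgi import OutcomeTable

        out = OutcomeTable(data_outcomes, survival=fitted.outcomes_.survival)
        results = run_associations(fitted.splits_, out)
        top_bmi = [r for r in results if r.cid_left == 2 and r.outcome == "bmi"]
        assert len(top_bmi) == 1 and top_bmi[0].status.startswith("skipped")
        # every other outcome is unaffected everywhere
        assert all(r.status == "ok" for r in results if r.outcome != "bmi")
        # bmi is still testable at splits entirely inside the untouched side
        right_side = [
            r for r in results
            if r.outcome == "bmi" and fitted.membership(r.cid_left) <= top.members_right
        ]
        assert right_side and all(r.status == "ok" for r in right_side)

    def test_custom_test_is_used(self, fitted):
        calls = []

        def my_test(left, right, column):
            calls.append((len(left), len(right)))
            return 1.23, 0.5

        results = run_associations(
            fitted.splits_, fitted.outcomes_, custom_tests={"bmi": my_test}
        )
        bmi = [r for r in results if r.outcome == "bmi"]
        assert calls and all(r.test == "custom" and r.p_raw == 0.5 for r in bmi)

    def test_custom_test_bad_p_is_an_error(self, fitted):
        with pytest.raises(ValueError, match="bmi.*outside"):
            run_associations(
                fitted.splits_, fitted.outcomes_, custom_tests={"bmi": lambda l, r, c: (0.0, 1.5)}
            )

    def test_no_valid_pairs_warns_and_returns_empty(self, fitted):
        import copy

        splits = copy.deepcopy(fitted.splits_)
        for p in splits:
            p.is_valid = False
        with pytest.warns(UserWarning, match="no valid cluster pairs"):
            assert run_associations(splits, fitted.outcomes_) == []

    def test_planted_outcome_smallest_p_at_top_split(self):
        from sgi import PlantedDesign, PlantedSplit, OutcomeEffect, SubgroupIdentification, generate_planted

        hits = 0
        for seed in range(20):
            design = PlantedDesign(
                n_samples=100,
                n_features=50,
                splits=[PlantedSplit(delta_x=2.0, features=tuple(range(15)))],
                outcomes=[OutcomeEffect("y", "continuous", "", 1.5)],
                seed=seed,
            )
            data, out, _ = generate_planted(design)
            model = SubgroupIdentification().fit(data, out)
            ok = [r for r in model.results_ if r.status == "ok"]
            best = min(ok, key=lambda r: r.p_raw)
            hits += best.cid_left == 2
        assert hits >= 18  # >= 90% of seeds


class TestBonferroni:
    @pytest.mark.parametrize(
        "p_raw, m, expected",
        [(0.01, 5, 0.05), (0.5, 3, 1.0), (0.2, 1, 0.2)],
    )
    def test_adjustment_formula(self, p_raw, m, expected, fitted):
        r = fitted.results_[0].__class__(
            cid_left=2, cid_right=3, outcome="y", test="t-welch", statistic=0.0,
            p_raw=p_raw, p_adj=None, n_left=5, n_right=5,
            summary_left="", summary_right="",
        )
        bonferroni_adjust([r], m)
        assert r.p_adj == pytest.approx(expected)

    def test_factor_is_valid_pairs_not_outcomes(self, fitted):
        m = fitted.n_valid_pairs_
        for r in fitted.results_:
            if np.isfinite(r.p_raw):
                assert r.p_adj == pytest.approx(min(1.0, r.p_raw * m))
                assert r.p_adj >= r.p_raw

    def test_optional_outcome_factor(self, fitted):
        import copy

        results = copy.deepcopy(fitted.results_)
        bonferroni_adjust(results, 2, across_outcomes=True, n_outcomes=3)
        for r in results:
            if np.isfinite(r.p_raw):
                assert r.p_adj == pytest.approx(min(1.0, r.p_raw * 6))

    def test_m_below_one_rejected(self, fitted):
        with pytest.raises(ValueError):
            bonferroni_adjust([], 0)


def test_results_frame_columns(fitted):
    df = results_to_frame(fitted.results_)
    assert list(df.columns)[:9] == [
        "cid_left", "cid_right", "outcome", "test", "statistic",
        "p_raw", "p_adj", "n_left", "n_right",
    ]
    assert len(df) == len(fitted.results_)
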