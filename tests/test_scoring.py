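import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prtf.containers import EnrichmentResult, GeneSet
from prtf.errors import DataError, UsageError
from prtf.scoring import (
    build_null,
    classify_sample,
    classify_samples,
    running_enrichment,
    score_signature,
    signature_pvalues,
)
from .conftest import brute_force_null


def expr_with_member_ranks(n, member_ranks):
    """Expression column whose i-th largest value sits at gene g{i}."""
    genes = [f"g{i}" for i in range(1, n + 1)]
    values = pd.Series(np.arange(n, 0, -1, dtype=float), index=genes)
    members = frozenset(f"g{r}" for r in member_ranks)
    return values, GeneSet("set", members)


class TestRunningEnrichment:
    @pytest.mark.parametrize(
        "n,ranks,expected",
        [
            (5, (1, 2), (0.0, 1.0)),  # members at the top
            (5, (4, 5), (-1.0, 0.0)),  # mirror case, members at the bottom
            (4, (2, 4), (-0.5, 0.0)),  # prefix sums -0.5, 0, -0.5, 0
        ],
    )
    def test_hand_computed_extrema(self, n, ranks, expected):
        expr, gs = expr_with_member_ranks(n, ranks)
        assert running_enrichment(expr, gs) == pytest.approx(expected)

    def test_missing_members_dropped_with_warning(self):
        expr, _ = expr_with_member_ranks(5, (1,))
        gs = GeneSet("set", frozenset({"g1", "absent"}))
        with pytest.warns(UserWarning):
            e_minus, e_plus = running_enrichment(expr, gs)
        # effective m = 1, member at the top rank
        assert e_plus == pytest.approx(1.0)

    def test_degenerate_sets_error(self):
        expr, _ = expr_with_member_ranks(4, (1,))
        with pytest.warns(UserWarning), pytest.raises(DataError):
            running_enrichment(expr, GeneSet("set", frozenset({"zzz"})))
        with pytest.raises(DataError):
            running_enrichment(expr, GeneSet("all", frozenset(expr.index)))

    def test_ties_broken_by_gene_id(self):
        genes = ["b", "a", "c"]
        expr = pd.Series([1.0, 1.0, 0.0], index=genes)
        gs = GeneSet("set", frozenset({"a"}))
        # tie between a and b resolved in id order: a takes rank 1
        _, e_plus = running_enrichment(expr, gs)
        assert e_plus == pytest.approx(1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_bounds_and_rank_invariance(self, data):
        n = data.draw(st.integers(5, 40))
        m = data.draw(st.integers(1, n - 1))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
        values = pd.Series(
            rng.normal(size=n), index=[f"g{i}" for i in range(n)]
        )
        members = frozenset(rng.choice(values.index, size=m, replace=False))
        gs = GeneSet("set", members)
        e_minus, e_plus = running_enrichment(values, gs)
        assert -1.0 <= e_minus <= 0.0 <= e_plus <= 1.0
        # any strictly monotone transform leaves the rank-only score unchanged
        transformed = 3.0 * np.exp(values) + 1.0
        assert running_enrichment(transformed, gs) == pytest.approx((e_minus, e_plus))

    def test_prefix_sum_vector_ends_at_zero(self):
        rng = np.random.default_rng(5)
        n, m = 30, 7
        values = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        members = set(rng.choice(values.index, size=m, replace=False))
        h = np.where(values.sort_values(ascending=False).index.isin(members), 1 / m, -1 / (n - m))
        assert abs(np.cumsum(h)[-1]) < 1e-12


class TestBuildNull:
    def test_exhaustive_matches_brute_force_enumeration(self):
        for n, m in [(4, 2), (6, 3), (7, 2)]:
            null = build_null(n, m, 0, seed=0, exhaustive=True)
            oracle_minus, oracle_plus = brute_force_null(n, m)
            np.testing.assert_allclose(
                np.sort(null.scores_minus), np.sort(oracle_minus), atol=1e-12
            )
            np.testing.assert_allclose(
                np.sort(null.scores_plus), np.sort(oracle_plus), atol=1e-12
            )

    def test_bounds_hold_for_random_draws(self):
        null = build_null(50, 6, 500, seed=1)
        assert (null.scores_minus >= -1).all() and (null.scores_minus <= 0).all()
        assert (null.scores_plus >= 0).all() and (null.scores_plus <= 1).all()

    def test_same_seed_reproduces(self):
        a = build_null(30, 4, 200, seed=9)
        b = build_null(30, 4, 200, seed=9)
        np.testing.assert_array_equal(a.scores_plus, b.scores_plus)
        np.testing.assert_array_equal(a.scores_minus, b.scores_minus)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(DataError):
            build_null(5, 5, 10, seed=0)
        with pytest.raises(DataError):
            build_null(5, 2, 0, seed=0)


class TestSignaturePvalues:
    def test_observed_beyond_all_null_hits_floor(self):
        null = build_null(20, 3, 999, seed=0)
        res = signature_pvalues((0.0, 1.0 + 1e-12), null)
        assert res.p_plus == pytest.approx(1 / 1000)

    def test_minimum_possible_score_hits_floor(self):
        null = build_null(20, 3, 99, seed=0)
        null.scores_minus = np.clip(null.scores_minus, -0.99, 0)  # ensure no -1 draws
        res = signature_pvalues((-1.0, 0.0), null)
        assert res.p_minus == pytest.approx(1 / 100)

    def test_exhaustive_null_pvalue_matches_enumeration(self):
        null = build_null(4, 2, 0, seed=0, exhaustive=True)
        # observed: members at ranks 1,2 -> E+ = 1; only that placement reaches 1
        res = signature_pvalues((0.0, 1.0), null)
        assert res.p_plus == pytest.approx((1 + 1) / (1 + 6))

    def test_reported_score_follows_smaller_pvalue(self):
        res = EnrichmentResult("s", -0.8, 0.2, 0.01, 0.7)
        assert res.tail == "low" and res.e_reported == -0.8
        res = EnrichmentResult("s", -0.2, 0.9, 0.5, 0.001)
        assert res.tail == "high" and res.e_reported == 0.9


class TestClassification:
    def make(self, sample, p_minus, p_plus):
        return EnrichmentResult(sample, -0.5, 0.5, p_minus, p_plus)

    def test_rule_application(self):
        p = self.make("s", 0.9, 0.001)
        r = self.make("s", 0.5, 0.4)
        assert classify_sample(p, r) == "P+/R-"

    def test_double_positive(self):
        p = self.make("s", 0.9, 0.001)
        r = self.make("s", 0.9, 0.01)
        assert classify_sample(p, r) == "P+/R+"

    def test_downregulation_is_not_positive(self):
        p = self.make("s", 0.001, 0.99)  # significant low tail only
        r = self.make("s", 0.5, 0.4)
        assert classify_sample(p, r) == "P-/R-"

    def test_mismatched_samples_rejected(self):
        with pytest.raises(UsageError):
            classify_sample(self.make("a", 0.5, 0.5), self.make("b", 0.5, 0.5))

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.normal(size=(30, 8)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(8)],
        )
        gs_p = GeneSet("P", frozenset([f"g{i}" for i in range(5)]))
        gs_r = GeneSet("R", frozenset([f"g{i}" for i in range(5, 11)]))
        tp = score_signature(expr, gs_p, n_perm=200, seed=1)
        tr = score_signature(expr, gs_r, n_perm=200, seed=2)
        calls = classify_samples(tp, tr)
        for s in expr.columns:
            pr = EnrichmentResult(s, *tp.loc[s, ["e_minus", "e_plus", "p_minus", "p_plus"]])
            rr = EnrichmentResult(s, *tr.loc[s, ["e_minus", "e_plus", "p_minus", "p_plus"]])
            assert classify_sample(pr, rr) == calls.loc[s, "pr_label"]

    def test_score_signature_rejects_mismatched_null(self):
        expr = pd.DataFrame(
            np.arange(12, dtype=float).reshape(6, 2),
            index=[f"g{i}" for i in range(6)],
        )
        gs = GeneSet("P", frozenset({"g0", "g1"}))
        wrong = build_null(10, 2, 50, seed=0)
        with pytest.raises(UsageError):
            score_signature(expr, gs, null=wrong)
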