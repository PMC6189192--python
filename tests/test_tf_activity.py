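import numpy as np
import pandas as pd
import pytest

from prtf.containers import ActivityMatrix, ExpressionMatrix, RegulatoryNetwork, TernaryMatrix
from prtf.errors import DataError, ParseError, UsageError
from prtf.tf_activity import (
    build_ternary_matrix,
    build_tf_null,
    filter_constant_tfs,
    infer_activities,
    parse_trrust,
    tf_pvalues_and_calls,
)
from .conftest import random_full_rank_ternary


def write_trrust(tmp_path, lines):
    path = tmp_path / "net.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


class TestParseTrrust:
    def test_direct_mapping(self, tmp_path):
        net = parse_trrust(write_trrust(tmp_path, ["KLF4\tIL1B\tActivation\t123"]))
        row = net.edges.iloc[0]
        assert (row["tf"], row["target"], row["mode"]) == ("KLF4", "IL1B", 1)

    def test_unknown_mode_dropped(self, tmp_path):
        net = parse_trrust(
            tmp_path / "net.tsv"
            if False
            else write_trrust(
                tmp_path,
                ["TP53\tX\tUnknown\t456", "TP53\tY\tRepression\t457"],
            )
        )
        assert len(net.edges) == 1
        assert net.edges.iloc[0]["mode"] == -1

    def test_conflicting_modes_excluded(self, tmp_path):
        net = parse_trrust(
            write_trrust(
                tmp_path,
                [
                    "A\tB\tActivation\t1",
                    "A\tB\tRepression\t2",
                    "A\tC\tActivation\t3",
                ],
            )
        )
        assert list(net.edges["target"]) == ["C"]

    def test_identical_duplicates_collapse(self, tmp_path):
        net = parse_trrust(
            write_trrust(tmp_path, ["A\tB\tActivation\t1", "A\tB\tActivation\t99"])
        )
        assert len(net.edges) == 1

    def test_malformed_line_reports_line_number(self, tmp_path):
        with pytest.raises(ParseError, match="line 2"):
            parse_trrust(write_trrust(tmp_path, ["A\tB\tActivation\t1", "bad line"]))


class TestBuildTernaryMatrix:
    def net(self, rows):
        return RegulatoryNetwork(pd.DataFrame(rows, columns=["tf", "target", "mode"]))

    def test_two_activated_targets(self):
        T = build_ternary_matrix(self.net([("t", "a", 1), ("t", "b", 1)]), {"a", "b"})
        assert T.values.shape == (2, 1)
        assert (T.values["t"] == 1).all()

    def test_absent_target_row_dropped(self):
        T = build_ternary_matrix(self.net([("t", "a", 1), ("t", "b", -1)]), {"a"})
        assert list(T.values.index) == ["a"]

    def test_tf_without_expressed_targets_dropped(self):
        T = build_ternary_matrix(
            self.net([("t1", "a", 1), ("t2", "z", 1)]), {"a"}
        )
        assert list(T.values.columns) == ["t1"]

    def test_empty_intersection_is_error(self):
        with pytest.raises(DataError):
            build_ternary_matrix(self.net([("t", "a", 1)]), {"zzz"})


def expr_from_array(arr, genes, samples=None):
    samples = samples or [f"s{i}" for i in range(np.atleast_2d(arr).shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


class TestInferActivities:
    def test_exact_fit_with_intercept(self):
        T = TernaryMatrix(pd.DataFrame({"t": [1, -1]}, index=["a", "b"]))
        G = expr_from_array([[3.0], [-3.0]], ["a", "b"])
        A = infer_activities(G, T, intercept=True)
        assert A.values.loc["t"].iloc[0] == pytest.approx(3.0)

    def test_identity_design_returns_data(self):
        T = TernaryMatrix(
            pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"], columns=["t1", "t2"])
        )
        G = expr_from_array([[5.0], [-2.0]], ["a", "b"])
        A = infer_activities(G, T, intercept=False)
        assert A.values["s0"].tolist() == pytest.approx([5.0, -2.0])

    def test_normal_equations_hand_example(self):
        # T = [1, 1, -1]^T, G = [1, 3, -2]: normal equation 3a = 6 -> a = 2
        T = TernaryMatrix(pd.DataFrame({"t": [1, 1, -1]}, index=["a", "b", "c"]))
        G = expr_from_array([[1.0], [3.0], [-2.0]], ["a", "b", "c"])
        A = infer_activities(G, T, intercept=False)
        assert A.values.loc["t"].iloc[0] == pytest.approx(2.0)

    def test_matches_pseudoinverse_on_random_full_rank_designs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_genes = rng.integers(8, 31)
            n_tfs = rng.integers(2, 9)
            X = random_full_rank_ternary(rng, n_genes, n_tfs)
            G = rng.normal(size=(n_genes, 4))
            T = TernaryMatrix(
                pd.DataFrame(
                    X,
                    index=[f"g{i}" for i in range(n_genes)],
                    columns=[f"t{j}" for j in range(n_tfs)],
                )
            )
            A = infer_activities(expr_from_array(G, list(T.values.index)), T, intercept=False)
            expected = np.linalg.pinv(X) @ G
            np.testing.assert_allclose(A.values.to_numpy(), expected, atol=1e-8)
            # residual orthogonal to every design column
            resid = G - X @ A.values.to_numpy()
            np.testing.assert_allclose(X.T @ resid, 0.0, atol=1e-8)

    def test_collinear_column_marked_non_identifiable(self):
        # t2 duplicates t1: only one of the pair is identifiable
        T = TernaryMatrix(
            pd.DataFrame(
                [[1, 1], [1, 1], [-1, -1]],
                index=["a", "b", "c"],
                columns=["t1", "t2"],
            )
        )
        G = expr_from_array([[1.0], [3.0], [-2.0]], ["a", "b", "c"])
        A = infer_activities(G, T, intercept=False)
        assert A.values.isna().sum().sum() == 1
        assert len(A.dropped_tfs) == 1

    def test_parameter_recovery_under_small_noise(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(500)]
        from prtf.synthetic import generate_regulatory_network

        net = generate_regulatory_network(20, 10, 0.3, genes, seed=5)
        T = build_ternary_matrix(net, set(genes))
        A_true = rng.normal(size=(T.values.shape[1], 100))
        G = T.values.to_numpy() @ A_true + rng.normal(0, 0.1, size=(len(T.values), 100))
        expr = expr_from_array(G, list(T.values.index))
        A = infer_activities(expr, T, intercept=True)
        for i, tf in enumerate(T.values.columns):
            r = np.corrcoef(A_true[i], A.values.loc[tf])[0, 1]
            assert r > 0.95


class TestFilterAndCalls:
    def test_constant_and_varying_rows(self):
        A = ActivityMatrix(
            pd.DataFrame(
                {"s1": [0.0, 1.0], "s2": [0.0, 2.0], "s3": [0.0, 3.0]},
                index=["flat", "varying"],
            )
        )
        out = filter_constant_tfs(A)
        assert list(out.values.index) == ["varying"]
        assert ("flat", "zero standard deviation") in out.dropped_tfs

    def test_all_missing_row_dropped_as_non_identifiable(self):
        A = ActivityMatrix(
            pd.DataFrame(
                {"s1": [np.nan, 1.0], "s2": [np.nan, 2.0]}, index=["gone", "ok"]
            )
        )
        out = filter_constant_tfs(A)
        assert ("gone", "non-identifiable") in out.dropped_tfs

    def test_all_dropped_is_error(self):
        A = ActivityMatrix(pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["flat"]))
        with pytest.raises(DataError):
            filter_constant_tfs(A)

    def test_null_pooling_length(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(40)]
        T = TernaryMatrix(
            pd.DataFrame(
                random_full_rank_ternary(rng, 40, 3),
                index=genes,
                columns=["t1", "t2", "t3"],
            )
        )
        expr = expr_from_array(rng.normal(size=(40, 10)), genes)
        null = build_tf_null(expr, T, n_perm=100, seed=0)
        assert null.scores.shape[1] == 100 * 10

    def test_null_mean_near_zero_on_centered_input(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(60)]
        T = TernaryMatrix(
            pd.DataFrame(
                random_full_rank_ternary(rng, 60, 4),
                index=genes,
                columns=[f"t{j}" for j in range(4)],
            )
        )
        vals = rng.normal(size=(60, 20))
        vals -= vals.mean(axis=1, keepdims=True)
        expr = expr_from_array(vals, genes)
        null = build_tf_null(expr, T, n_perm=200, seed=3)
        for tf in null.scores.index:
            ref = null.scores.loc[tf].dropna().to_numpy()
            se = ref.std(ddof=1) / np.sqrt(len(ref))
            assert abs(ref.mean()) < 3 * se + 1e-12

    def test_pvalue_formula_and_strict_threshold(self):
        from prtf.containers import TFNull

        null = TFNull(
            scores=pd.DataFrame([np.sort(np.linspace(-1, 1, 999))], index=["t"]),
            n_perm=999,
        )
        A = ActivityMatrix(pd.DataFrame({"s1": [2.0]}, index=["t"]))
        out, calls = tf_pvalues_and_calls(A, null, alpha=0.05, designated_tf="t")
        assert out.pvalues.loc["t", "s1"] == pytest.approx(1 / 1000)
        assert bool(calls["s1"])

    def test_p_exactly_alpha_is_negative(self):
        from prtf.containers import TFNull

        # 19 null values above the observation -> p = 20/400 = 0.05 exactly
        ref = np.sort(np.concatenate([np.full(380, -1.0), np.full(19, 5.0)]))
        null = TFNull(scores=pd.DataFrame([ref], index=["t"]), n_perm=399)
        A = ActivityMatrix(pd.DataFrame({"s1": [2.0]}, index=["t"]))
        out, calls = tf_pvalues_and_calls(A, null, alpha=0.05, designated_tf="t")
        assert out.pvalues.loc["t", "s1"] == pytest.approx(0.05)
        assert not bool(calls["s1"])

    def test_missing_tf_in_null_rejected(self):
        from prtf.containers import TFNull

        null = TFNull(scores=pd.DataFrame([np.zeros(10)], index=["other"]), n_perm=10)
        A = ActivityMatrix(pd.DataFrame({"s1": [1.0]}, index=["t"]))
        with pytest.raises(UsageError):
            tf_pvalues_and_calls(A, null, designated_tf="t")

    def test_permuting_constant_column_leaves_activities_unchanged(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(30)]
        T = TernaryMatrix(
            pd.DataFrame(
                random_full_rank_ternary(rng, 30, 3),
                index=genes,
                columns=["t1", "t2", "t3"],
            )
        )
        expr = expr_from_array(np.full((30, 2), 7.0), genes)
        A = infer_activities(expr, T, intercept=True)
        null = build_tf_null(expr, T, n_perm=20, seed=5)
        for tf in A.values.index:
            ref = null.scores.loc[tf].dropna().unique()
            np.testing.assert_allclose(ref, A.values.loc[tf].iloc[0], atol=1e-10)
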