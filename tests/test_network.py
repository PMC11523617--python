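"""Robust binarization, Zhang's score, binomial edge test, graph rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from habitatlink.network import (
    DEFAULT_Z_THRESHOLD,
    MadZeroError,
    binarize,
    binomial_edge_test,
    build_network,
    edge_table,
    exceptionality_matrix,
    modified_zscore,
    precision_recall,
    zhang_score,
)


class TestModifiedZscore:
    def test_hand_computed_example(self):
        z = modified_zscore([1, 2, 3, 4, 100])
        assert z.tolist() == [-2.0, -1.0, 0.0, 1.0, 97.0]

    def test_median_maps_to_zero(self, rng):
        x = rng.normal(size=21)
        z = modified_zscore(x)
        assert z[np.argsort(x)[10]] == pytest.approx(0.0)

    def test_affine_equivariance(self, rng):
        x = rng.normal(size=15)
        assert np.allclose(modified_zscore(x + 7.3), modified_zscore(x))
        assert np.allclose(modified_zscore(2.5 * x), modified_zscore(x))

    def test_mad_zero_raises(self):
        with pytest.raises(MadZeroError):
            modified_zscore([1.0, 1.0, 1.0, 9.0])  # MAD 0 despite an outlier


class TestBinarize:
    def test_threshold_example(self):
        z = np.array([-2.0, -1.0, 0.0, 1.0, 97.0])
        assert binarize(z, 3.5).tolist() == [0, 0, 0, 0, 1]

    def test_all_below_gives_zeros(self):
        assert binarize(np.array([0.1, -5.0, 3.0]), 3.5).sum() == 0

    @given(st.floats(0.5, 10.0), st.floats(0.1, 5.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_raising_threshold_is_monotone(self, t, dt):
        z = np.linspace(-5, 15, 41)
        low, high = binarize(z, t), binarize(z, t + dt)
        assert (high <= low).all()

    def test_one_sided(self):
        # exceptionally LOW values are never flagged
        assert binarize(np.array([-100.0, 0.0, 100.0]), 3.5).tolist() == [0, 0, 1]


class TestZhangScore:
    def test_analytic_cases(self):
        a = np.array([1, 1, 0, 0, 1, 0, 0, 0, 1, 0], dtype=float)
        assert zhang_score(a, a) == pytest.approx(1.0)
        assert zhang_score(a, 1 - a) == pytest.approx(-1.0)
        # exact independence: P(AB) = P(A) P(B)
        ind_a = np.array([1, 1, 0, 0], dtype=float)
        ind_b = np.array([1, 0, 1, 0], dtype=float)
        assert zhang_score(ind_a, ind_b) == pytest.approx(0.0)

    def test_worked_formula_example(self):
        # n=10: joint in 4, A in 5, B in 6 -> (0.4-0.3)/max(0.2, 0.1) = 0.5
        a = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=float)
        b = np.array([1, 1, 1, 1, 0, 1, 1, 0, 0, 0], dtype=float)
        assert zhang_score(a, b, direction="ab") == pytest.approx(0.5)

    @given(st.integers(0, 2**16 - 1))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_bounded_for_random_vectors(self, bits):
        a = np.array([(bits >> i) & 1 for i in range(8)], dtype=float)
        b = np.array([(bits >> (i + 8)) & 1 for i in range(8)], dtype=float)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            with pytest.raises(ValueError):
                zhang_score(a, b)
        else:
            assert -1.0 <= zhang_score(a, b) <= 1.0

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            zhang_score(np.ones(5), np.array([1, 0, 1, 0, 1.0]))


class TestBinomialEdgeTest:
    def test_zero_cooccurrence_gives_one(self):
        a = np.array([1, 0, 0, 0, 0], dtype=float)
        b = np.array([0, 1, 0, 0, 0], dtype=float)
        assert binomial_edge_test(a, b) == pytest.approx(1.0)

    def test_matches_exact_tail_sum(self):
        # n=10, p0=0.25, k=8 -> sum_{k=8}^{10} C(10,k) 0.25^k 0.75^(10-k)
        from math import comb

        expected = sum(comb(10, k) * 0.25**k * 0.75 ** (10 - k) for k in range(8, 11))
        a = np.array([1] * 8 + [1, 1], dtype=float)  # support 1 -> pass p0 explicitly
        b = np.array([1] * 8 + [0, 0], dtype=float)
        assert binomial_edge_test(a, b, p0=0.25) == pytest.approx(expected)

    def test_matches_scipy_binomtest(self, rng):
        from scipy.stats import binomtest

        a = (rng.random(30) < 0.4).astype(float)
        b = (rng.random(30) < 0.5).astype(float)
        if np.ptp(a) and np.ptp(b):
            k = int((a * b).sum())
            ours = binomial_edge_test(a, b)
            ref = binomtest(k, 30, a.mean() * b.mean(), alternative="greater").pvalue
            assert ours == pytest.approx(ref)

    def test_nonincreasing_in_cooccurrence(self):
        n, p0 = 20, 0.2
        ps = [binomial_edge_test(np.zeros(n), np.zeros(n), p0=p0)]
        for k in range(1, n + 1):
            a = np.array([1.0] * k + [0.0] * (n - k))
            ps.append(binomial_edge_test(a, a, p0=p0))
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_degenerate_support_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            p = binomial_edge_test(np.ones(6), np.array([1, 0, 1, 0, 1, 0.0]))
        assert p == 1.0


class TestExceptionalityMatrix:
    def test_values_binary_and_mad_zero_dropped(self, rng):
        df = pd.DataFrame(
            {
                "ok": rng.normal(size=30),
                "spiky": np.concatenate([np.zeros(28), [50.0, 60.0]]),
            }
        )
        df["flat"] = 1.0
        with pytest.warns(UserWarning, match="non-binarizable"):
            binary, audit = exceptionality_matrix(df)
        assert "flat" not in binary.columns
        assert set(np.unique(binary.to_numpy())) <= {0.0, 1.0}
        assert not audit.loc["flat", "kept"] and audit.loc["ok", "kept"]
        assert audit.loc["ok", "threshold"] == pytest.approx(DEFAULT_Z_THRESHOLD)


class TestBuildNetwork:
    def test_planted_duplicate_edge(self, rng):
        n = 100
        pattern = np.zeros(n)
        pattern[rng.choice(n, 20, replace=False)] = 1.0
        binary = pd.DataFrame({"a": pattern, "b": pattern.copy(),
                               "noise": (rng.random(n) < 0.1).astype(float)})
        g = build_network(binary)
        assert g.has_edge("a", "b")
        assert g.edges["a", "b"]["zhang"] == pytest.approx(1.0)

    def test_empty_edge_set_is_valid(self):
        binary = pd.DataFrame({"a": [1, 0, 0, 0.0], "b": [0, 1, 0, 0.0]})
        g = build_network(binary)
        assert g.number_of_edges() == 0
        assert edge_table(g).empty

    def test_relaxing_thresholds_never_removes_edges(self, rng):
        binary = pd.DataFrame(
            (rng.random((60, 12)) < 0.25).astype(float),
            columns=[f"v{i}" for i in range(12)],
        )
        strict = build_network(binary, zhang_min=0.5, alpha=0.01)
        loose = build_network(binary, zhang_min=0.25, alpha=0.05)
        assert set(map(frozenset, strict.edges())) <= set(map(frozenset, loose.edges()))

    def test_deterministic_for_fixed_input(self, rng):
        binary = pd.DataFrame((rng.random((40, 8)) < 0.3).astype(float))
        binary.columns = [f"v{i}" for i in range(8)]
        a, b = build_network(binary), build_network(binary)
        assert edge_table(a).equals(edge_table(b))

    def test_edge_attributes_and_invariants(self, rng):
        binary = pd.DataFrame((rng.random((80, 10)) < 0.3).astype(float))
        binary.columns = [f"v{i}" for i in range(10)]
        g = build_network(binary, zhang_min=0.0, alpha=0.5)
        for _, _, attrs in g.edges(data=True):
            assert attrs["support_ab"] <= min(attrs["support_a"], attrs["support_b"]) + 1e-12
            assert -1.0 <= attrs["zhang"] <= 1.0
            assert 0.0 < attrs["binom_p"] <= 1.0
            assert attrs["n"] == 80

    def test_pairwise_complete_cases(self):
        binary = pd.DataFrame(
            {
                "a": [1, 1, 0, 0, 1, 0, np.nan, 0],
                "b": [1, 1, 0, 0, 1, 0, 0, np.nan],
                "c": [0, 1, 1, 0, 0, 1, 0, 0.0],
            }
        )
        g = build_network(binary, zhang_min=0.1, alpha=0.5)
        assert g.edges["a", "b"]["n"] == 6  # both NaN rows excluded


class TestPrecisionRecall:
    def test_exact_set_comparison(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("c", "d"), ("x", "y")])
        p, r = precision_recall(g, [("b", "a"), ("c", "d"), ("u", "v")])
        assert p == pytest.approx(2 / 3)
        assert r == pytest.approx(2 / 3)
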