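"""PCA, PERMANOVA, dbRDA, Spearman screen and the Procrustes test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from habitatlink.ordination import (
    dbrda,
    gradient_analysis,
    pca,
    permanova,
    procrustes_test,
    spearman_screen,
)


def _euclid(points):
    return squareform(pdist(points))


class TestPca:
    def test_collinear_points_load_on_one_axis(self):
        t = np.linspace(0, 1, 10)
        df = pd.DataFrame({"x": t, "y": 2 * t})
        res = pca(df, standardize=False)
        assert res.proportion_explained["PC1"] == pytest.approx(1.0)

    def test_trace_conservation_standardized(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        res = pca(df, standardize=True)
        assert res.eigenvalues.sum() == pytest.approx(5.0)

    def test_reconstruction(self, rng):
        df = pd.DataFrame(rng.normal(size=(12, 4)))
        res = pca(df, standardize=False)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + res.means.to_numpy()
        assert np.allclose(recon, df.to_numpy())

    def test_scores_centered_loadings_orthonormal(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 4)))
        res = pca(df)
        assert np.allclose(res.scores.mean(axis=0), 0, atol=1e-10)
        l = res.loadings.to_numpy()
        assert np.allclose(l.T @ l, np.eye(l.shape[1]), atol=1e-10)
        assert (np.diff(res.eigenvalues.to_numpy()) <= 1e-12).all()

    def test_constant_variable_dropped_with_warning(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        df["c"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = pca(df, standardize=True)
        assert "c" not in res.loadings.index


class TestPermanova:
    def test_two_clusters_explain_everything(self):
        d = np.ones((8, 8))
        d[:4, :4] = 0
        d[4:, 4:] = 0
        np.fill_diagonal(d, 0)
        res = permanova(d, np.repeat([0.0, 1.0], 4), n_perm=99, seed=0)
        assert res.r2("x1") == pytest.approx(1.0, abs=1e-10)

    def test_exhaustive_matches_brute_force(self, rng):
        pts = rng.normal(size=(6, 3))
        d = _euclid(pts)
        cov = rng.normal(size=6)

        def brute_f(dmat, v):
            n = len(v)
            g = (np.eye(n) - 1 / n) @ (-0.5 * dmat**2) @ (np.eye(n) - 1 / n)
            x = np.column_stack([np.ones(n), v])
            h = x @ np.linalg.pinv(x.T @ x) @ x.T
            ss_x = np.trace(h @ g)
            ss_r = np.trace(g) - ss_x
            return ss_x / (ss_r / (n - 2))

        f0 = brute_f(d, cov)
        hits = sum(
            brute_f(d[np.ix_(p, p)], cov) >= f0 - 1e-12
            for p in itertools.permutations(range(6))
        )
        res = permanova(d, cov, exhaustive=True)
        assert res.p("x1") == pytest.approx(hits / 720)

    def test_matches_skbio_two_group_pseudo_f(self, rng):
        # independent reference implementation for the categorical case
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        pts = rng.normal(size=(12, 4))
        pts[:6] += 1.0
        d = _euclid(pts)
        grouping = ["g1"] * 6 + ["g2"] * 6
        ours = permanova(d, np.repeat([0.0, 1.0], 6), n_perm=99, seed=0)
        theirs = skbio_permanova(DistanceMatrix(d), grouping, permutations=99)
        assert ours.table.loc["x1", "F"] == pytest.approx(theirs["test statistic"])

    def test_sequential_r2_sums_to_one(self, rng):
        d = _euclid(rng.normal(size=(15, 4)))
        cov = pd.DataFrame(rng.normal(size=(15, 2)), columns=["PC1", "PC2"])
        res = permanova(d, cov, n_perm=99, seed=1)
        assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0)
        assert ((res.table["p"].dropna() >= 1 / 100) & (res.table["p"].dropna() <= 1)).all()

    def test_bit_reproducible(self, rng):
        d = _euclid(rng.normal(size=(10, 3)))
        cov = rng.normal(size=10)
        a = permanova(d, cov, n_perm=199, seed=42)
        b = permanova(d, cov, n_perm=199, seed=42)
        assert a.table.equals(b.table)

    def test_constant_covariate_and_size_mismatch(self, rng):
        d = _euclid(rng.normal(size=(8, 3)))
        with pytest.raises(ValueError):
            permanova(d, np.ones(8), n_perm=99)
        with pytest.raises(ValueError):
            permanova(d, np.arange(7.0), n_perm=99)


class TestDbrda:
    def test_orthogonal_constraint_explains_nothing(self):
        n = 12
        y = np.zeros((n, 2))
        y[: n // 2, 0] = 1.0  # community varies only along a block structure
        d = _euclid(y)
        constraint = np.tile([1.0, -1.0], n // 2)  # orthogonal to the blocks
        res = dbrda(d, constraint, sqrt_transform=False)
        assert res.proportion_constrained == pytest.approx(0.0, abs=1e-10)

    def test_inertia_equals_permanova_r2(self, rng):
        d = _euclid(rng.normal(size=(14, 5)))
        cov = rng.normal(size=14)
        r2 = permanova(d, cov, n_perm=99, seed=0).r2("x1")
        res = dbrda(d, cov, sqrt_transform=False)
        assert res.proportion_constrained == pytest.approx(r2, abs=1e-10)

    def test_euclidean_equals_rda_on_raw_coordinates(self, rng):
        y = rng.normal(size=(10, 4))
        yc = y - y.mean(axis=0)
        x = rng.normal(size=(10, 2))
        res = dbrda(_euclid(yc), x, sqrt_transform=False)
        # reference RDA: eigen-analysis of the fitted values of Y ~ X
        design = np.column_stack([np.ones(10), x])
        h = design @ np.linalg.pinv(design.T @ design) @ design.T
        s = np.linalg.svd(h @ yc, compute_uv=False)
        assert np.allclose(res.eigenvalues.to_numpy(), (s**2)[: len(res.eigenvalues)])

    def test_negative_eigenvalue_mass_reported(self, default_study):
        from habitatlink.otu import bray_curtis

        table, _ = default_study["otu_tables"]["16S"]
        d = bray_curtis(table)
        cov = np.linspace(0, 1, len(d.ids))
        res = dbrda(d, cov)  # sqrt transform on
        assert res.negative_eigenvalue_mass >= 0.0
        assert 0.0 <= res.proportion_constrained <= 1.0


class TestSpearmanScreen:
    def test_monotone_and_reversed(self):
        axis = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        ab = pd.DataFrame(
            {"up": np.exp(axis.to_numpy()), "down": -axis.to_numpy()}, index=axis.index
        )
        res = spearman_screen(ab, axis)
        assert res.loc["up", "rho"] == pytest.approx(1.0)
        assert res.loc["down", "rho"] == pytest.approx(-1.0)

    def test_ties_match_direct_rank_formula(self):
        # oracle: Pearson correlation of average ranks
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0])
        from scipy.stats import rankdata

        expected = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
        ab = pd.DataFrame({"v": x})
        res = spearman_screen(ab, pd.Series(y), alpha=0.05)
        assert res.loc["v", "rho"] == pytest.approx(expected)

    def test_constant_reported_missing(self):
        ab = pd.DataFrame({"flat": np.ones(6), "ok": np.arange(6.0)})
        res = spearman_screen(ab, pd.Series(np.arange(6.0)))
        assert np.isnan(res.loc["flat", "rho"]) and not res.loc["flat", "significant"]


class TestProcrustes:
    def test_rigid_rotation_gives_unit_statistic(self, rng):
        x = rng.normal(size=(9, 2))
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        res = procrustes_test(x, x @ rot, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_invariant_to_orthogonal_rotation(self, rng):
        x, y = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
        q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        a = procrustes_test(x, y, n_perm=99, seed=3).statistic
        b = procrustes_test(x @ q, y, n_perm=99, seed=3).statistic
        assert a == pytest.approx(b)

    def test_matches_scipy_disparity_relation(self, rng):
        # scipy's standardized disparity is 1 - statistic^2
        from scipy.spatial import procrustes as scipy_procrustes

        x, y = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        stat = procrustes_test(x, y, n_perm=99, seed=0).statistic
        _, _, disparity = scipy_procrustes(x, y)
        assert disparity == pytest.approx(1 - stat**2)

    def test_null_p_is_calibrated(self, rng):
        # independent configurations: p roughly uniform, mean near 1/2
        ps = []
        for _ in range(100):
            x, y = rng.normal(size=(10, 2)), rng.normal(size=(10, 2))
            ps.append(procrustes_test(x, y, n_perm=49, seed=1).p)
        assert 0.35 < np.mean(ps) < 0.65

    def test_rank_zero_errors(self):
        with pytest.raises(ValueError):
            procrustes_test(np.ones((5, 2)), np.ones((5, 2)))


class TestGradientAnalysis:
    def test_report_contract_with_empty_screen(self, rng):
        # pure noise: every report field exists even with nothing significant
        d = _euclid(rng.normal(size=(12, 6)))
        abiotic = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        table = pd.DataFrame(rng.integers(0, 30, size=(12, 8)).astype(float))
        rep = gradient_analysis(d, abiotic, table, n_perm=99, seed=0)
        assert set(rep) == {"pca", "axes", "permanova", "dbrda", "otu_screen"}
        assert set(rep["otu_screen"]) == set(rep["axes"])
        for scr in rep["otu_screen"].values():
            assert list(scr.columns) == ["rho", "p", "significant"] or scr.empty

    def test_stage_name_in_errors(self, rng):
        d = _euclid(rng.normal(size=(4, 2)))
        abiotic = pd.DataFrame(rng.normal(size=(3, 3)))  # wrong length
        with pytest.raises(RuntimeError, match="stage"):
            gradient_analysis(d, abiotic, None, n_perm=99, seed=0)
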