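"""Attribution battery: VPA, LMG, partial correlation, Mantel, random forest."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from emfkit.attribution import (
    lmg_importance,
    mantel,
    partial_correlation,
    partial_correlation_table,
    rf_importance,
    unique_fractions,
    variance_partition,
)


def _exact_gram(corr: np.ndarray, n: int, rng) -> np.ndarray:
    """Columns with mean 0 and *sample* correlation exactly `corr`."""
    p = corr.shape[0]
    raw = rng.normal(size=(n, p + 1))
    raw[:, 0] = 1.0
    q, _ = np.linalg.qr(raw)
    basis = q[:, 1 : p + 1]  # orthonormal, orthogonal to the constant
    chol = np.linalg.cholesky(corr)
    return basis @ chol.T * np.sqrt(n - 1)


class TestVariancePartition:
    def test_duplicated_information_has_no_unique_part(self, rng):
        x = rng.normal(size=100)
        y = pd.Series(x + rng.normal(scale=0.3, size=100))
        X = pd.DataFrame({"a1": x, "b1": x.copy()})
        with pytest.warns(UserWarning, match="collinear"):
            vpa = variance_partition(y, X, {"A": ["a1"], "B": ["b1"]})
        u = unique_fractions(vpa)
        assert u["A"] == pytest.approx(0.0, abs=1e-10)
        assert u["B"] == pytest.approx(0.0, abs=1e-10)
        assert vpa["components"][("A", "B")] == pytest.approx(vpa["full_adj_r2"])

    def test_null_predictors_give_near_zero_components(self, rng):
        y = pd.Series(rng.normal(size=2000))
        X = pd.DataFrame(rng.normal(size=(2000, 4)), columns=list("abcd"))
        vpa = variance_partition(y, X, {"A": ["a", "b"], "B": ["c", "d"]})
        assert all(abs(v) < 0.02 for v in vpa["components"].values())

    def test_orthogonal_predictors_recover_variance_shares(self, rng):
        n = 200
        corr = np.eye(2)
        xm = _exact_gram(corr, n, rng)
        y = pd.Series(xm[:, 0] + xm[:, 1] + rng.normal(size=n))
        X = pd.DataFrame(xm, columns=["x1", "x2"])
        vpa = variance_partition(y, X, {"A": ["x1"], "B": ["x2"]})
        u = unique_fractions(vpa)
        r2 = vpa["full_adj_r2"]
        assert u["A"] == pytest.approx(r2 / 2, abs=0.05)
        assert u["B"] == pytest.approx(r2 / 2, abs=0.05)
        assert abs(vpa["components"][("A", "B")]) < 0.05

    def test_inclusion_exclusion_identity_exact(self, rng):
        y = pd.Series(rng.normal(size=40))
        X = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("abcdef"))
        vpa = variance_partition(
            y, X, {"A": ["a", "b"], "B": ["c"], "C": ["d", "e"], "D": ["f"]}
        )
        assert sum(vpa["components"].values()) == pytest.approx(
            vpa["full_adj_r2"], abs=1e-8
        )

    def test_overlapping_groups_rejected(self, rng):
        y = pd.Series(rng.normal(size=20))
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="disjoint"):
            variance_partition(y, X, {"A": ["a"], "B": ["a", "b"]})


class TestLMG:
    def test_single_predictor_share_equals_r2(self, rng):
        x = rng.normal(size=50)
        y = pd.Series(2 * x + rng.normal(size=50))
        share = lmg_importance(y, pd.DataFrame({"x": x}))
        r = np.corrcoef(x, y)[0, 1]
        assert share["x"] == pytest.approx(r**2, abs=1e-10)

    def test_orthogonal_equal_betas_share_equally(self, rng):
        xm = _exact_gram(np.eye(2), 64, rng)
        y = pd.Series(xm[:, 0] + xm[:, 1])
        shares = lmg_importance(y, pd.DataFrame(xm, columns=["a", "b"]))
        assert shares["a"] == pytest.approx(shares["b"], abs=1e-10)

    def test_correlated_pair_matches_analytic_sequential_r2(self, rng):
        """x1, x2 correlated 0.5, y = x1 + e with e ⟂ {x1,x2} and matched
        variance: the two-ordering average gives shares 0.4375 / 0.0625
        of the total y variance (hand covariance algebra)."""
        corr = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        m = _exact_gram(corr, 32, rng)  # x1, x2, e — exact sample correlations
        y = pd.Series(m[:, 0] + m[:, 2])
        shares = lmg_importance(y, pd.DataFrame(m[:, :2], columns=["x1", "x2"]))
        assert shares["x1"] == pytest.approx(0.4375, abs=1e-10)
        assert shares["x2"] == pytest.approx(0.0625, abs=1e-10)

    def test_shares_always_sum_to_full_r2(self, rng):
        from emfkit.attribution import _r2

        y = pd.Series(rng.normal(size=30))
        X = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        shares = lmg_importance(y, X)
        assert shares.sum() == pytest.approx(
            _r2(y.to_numpy(), X.to_numpy()), abs=1e-10
        )

    def test_large_p_requires_sampling_mode(self, rng):
        y = pd.Series(rng.normal(size=40))
        X = pd.DataFrame(rng.normal(size=(40, 9)))
        X.columns = [f"v{i}" for i in range(9)]
        with pytest.raises(ValueError, match="sample_orderings"):
            lmg_importance(y, X)
        shares = lmg_importance(y, X, sample_orderings=50, seed=0)
        assert len(shares) == 9


class TestPartialCorrelation:
    def test_no_controls_equals_pearson(self, rng):
        x = pd.Series(rng.normal(size=30), name="x")
        y = pd.Series(x + rng.normal(size=30), name="y")
        r, p = partial_correlation(y, x)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_identity_gives_unit_partial_r(self, rng):
        x = pd.Series(rng.normal(size=25), name="x")
        z = pd.DataFrame({"z": rng.normal(size=25)})
        r, _ = partial_correlation(x.rename("y"), x, z)
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_closed_form_three_variable_system(self, rng):
        """corr(y,x)=.6, corr(y,z)=.5, corr(x,z)=.4 →
        r_yx·z = (.6 − .5·.4)/sqrt((1−.25)(1−.16))."""
        corr = np.array([[1.0, 0.6, 0.5], [0.6, 1.0, 0.4], [0.5, 0.4, 1.0]])
        m = _exact_gram(corr, 24, rng)
        y = pd.Series(m[:, 0], name="y")
        x = pd.Series(m[:, 1], name="x")
        z = pd.DataFrame({"z": m[:, 2]})
        r, _ = partial_correlation(y, x, z)
        expected = (0.6 - 0.5 * 0.4) / np.sqrt((1 - 0.25) * (1 - 0.16))
        assert r == pytest.approx(expected, abs=1e-10)

    def test_residual_and_precision_matrix_routes_agree(self, rng):
        data = pd.DataFrame(rng.normal(size=(40, 4)), columns=["y", "x", "a", "b"])
        r, _ = partial_correlation(data["y"], data["x"], data[["a", "b"]])
        prec = np.linalg.inv(np.corrcoef(data.T))
        r_prec = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert r == pytest.approx(r_prec, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        data = pd.DataFrame(rng.normal(size=(30, 3)), columns=["y", "x", "z"])
        r, p = partial_correlation(data["y"], data["x"], data[["z"]])
        ref = pingouin.partial_corr(data, x="x", y="y", covar=["z"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_control_collision_rejected(self, rng):
        x = pd.Series(rng.normal(size=20), name="x")
        with pytest.raises(ValueError):
            partial_correlation(x.rename("y"), x, pd.DataFrame({"x": x}))

    def test_table_controls_each_other(self, rng):
        y = pd.Series(rng.normal(size=30))
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        tab = partial_correlation_table(y, X)
        assert list(tab.index) == ["a", "b", "c"]
        assert ((tab["p"] >= 0) & (tab["p"] <= 1)).all()


class TestMantel:
    @staticmethod
    def _dist(rng, n=7):
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return d

    def test_identical_matrices_r_one(self, rng):
        d = self._dist(rng)
        r, p = mantel(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_hand_spearman_on_upper_triangles(self):
        d1 = np.zeros((4, 4))
        d2 = np.zeros((4, 4))
        v1 = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        v2 = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        iu = np.triu_indices(4, k=1)
        d1[iu], d2[iu] = v1, v2
        d1, d2 = d1 + d1.T, d2 + d2.T
        r, _ = mantel(d1, d2, n_perm=9, seed=0)
        assert r == pytest.approx(sps.spearmanr(v1, v2).statistic, abs=1e-12)

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            mantel(self._dist(rng, 5), self._dist(rng, 6))

    def test_agrees_with_skbio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        d1, d2 = self._dist(rng, 8), self._dist(rng, 8)
        r, p = mantel(d1, d2, n_perm=999, seed=1)
        r_ref, p_ref, _ = skbio_stats.mantel(
            d1, d2, method="spearman", permutations=999, alternative="greater"
        )
        assert r == pytest.approx(r_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=0.06)  # independent permutation draws


class TestRandomForest:
    def test_true_signal_ranked_first_across_seeds(self, rng):
        wins = 0
        for s in range(50):
            r = np.random.default_rng(s)
            X = pd.DataFrame(r.normal(size=(100, 3)), columns=["x1", "x2", "x3"])
            y = pd.Series(np.sin(X["x1"] * 2) + 0.3 * r.normal(size=100))
            imp = rf_importance(y, X, n_trees=60, n_perm=0, seed=s)
            wins += imp["importance"].idxmax() == "x1"
        assert wins >= 48  # >= 95% of 50 runs

    def test_duplicated_signal_beats_noise(self):
        r = np.random.default_rng(4)
        x1 = r.normal(size=120)
        X = pd.DataFrame({"x1": x1, "dup": x1 + 0.01 * r.normal(size=120), "noise": r.normal(size=120)})
        y = pd.Series(x1 + 0.2 * r.normal(size=120))
        imp = rf_importance(y, X, n_trees=80, n_perm=0, seed=0)["importance"]
        assert imp["x1"] + imp["dup"] > imp["noise"]

    def test_constant_response_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(12, 2)))
        X.columns = ["a", "b"]
        with pytest.raises(ValueError):
            rf_importance(pd.Series(np.ones(12)), X)

    def test_null_importances_rarely_significant(self):
        r = np.random.default_rng(9)
        X = pd.DataFrame(r.normal(size=(40, 3)), columns=["a", "b", "c"])
        y = pd.Series(r.normal(size=40))
        imp = rf_importance(y, X, n_trees=40, n_perm=49, seed=1)
        assert (imp["p"] > 0.05).sum() >= 2
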