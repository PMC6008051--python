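"""PCA scores/variance, per-transcript correlations, bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest

from muscletx import (
    bootstrap_pca,
    correlate_with_pc,
    expressed_mask,
    rank_by_pc_correlation,
    run_pca,
)
from muscletx.data_model import DataModelError
from muscletx.pca_axis import fisher_z_ci


def _frame(X, prefix="s"):
    return pd.DataFrame(
        X, index=[f"T{i}" for i in range(X.shape[0])],
        columns=[f"{prefix}{j}" for j in range(X.shape[1])],
    )


class TestRunPca:
    def test_rank_one_gives_full_first_component(self):
        t = np.linspace(-1, 1, 8)
        X = np.outer(np.array([3.0, -1.0, 0.5, 2.0]), t) + 5.0
        res = run_pca(_frame(X))
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_orthogonal_equal_variance_directions(self):
        # samples at (+-1, 0) and (0, +-1) in a 2-transcript space
        X = np.array([[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]])
        res = run_pca(_frame(X))
        assert res.variance_explained[0] == pytest.approx(0.5, abs=1e-12)

    def test_sign_canonicalized_and_deterministic(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 10))
        r1, r2 = run_pca(_frame(X)), run_pca(_frame(X))
        assert np.allclose(r1.scores, r2.scores)
        for c in r1.loadings.columns:
            col = r1.loadings[c].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 12))
        res = run_pca(_frame(X))
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 9))
        res = run_pca(_frame(X))
        M = X.T - X.T.mean(axis=0, keepdims=True)
        evals = np.sort(np.linalg.eigvalsh(M @ M.T))[::-1]  # Gram-matrix oracle
        assert np.allclose(res.variance_explained, evals / evals.sum(), atol=1e-10)

    def test_constant_matrix_rejected(self):
        with pytest.raises(DataModelError):
            run_pca(_frame(np.full((4, 6), 3.0)))


class TestCorrelations:
    def test_rank_one_driver_r2_one(self):
        t = np.linspace(-1, 1, 10)
        X = np.vstack([2 * t + 3, -t + 1, 0.5 * t])
        res = run_pca(_frame(X))
        corr = correlate_with_pc(_frame(X), res.scores, 1)
        assert np.allclose(corr["r2"], 1.0, atol=1e-10)

    def test_null_transcripts_mean_r2_near_one_over_n_minus_one(self):
        rng = np.random.default_rng(3)
        n = 66
        X = rng.normal(size=(1000, n))
        res = run_pca(_frame(X))
        corr = correlate_with_pc(_frame(X), res.scores, 1)
        # under the null E[R^2] ~= 1/(n-1); PC1 is fit to these data so
        # allow generous slack above the analytic null expectation
        assert corr["r2"].mean() == pytest.approx(1.0 / (n - 1), rel=0.8)

    def test_affine_invariance_and_constant_rows_missing(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 8))
        res = run_pca(_frame(X))
        base = correlate_with_pc(_frame(X), res.scores, 1)
        X2 = X * 7.0 - 11.0
        again = correlate_with_pc(_frame(X2), res.scores, 1)
        assert np.allclose(base["r2"], again["r2"], atol=1e-12)
        Xc = X.copy()
        Xc[0] = 2.0
        assert np.isnan(correlate_with_pc(_frame(Xc), res.scores, 1).loc["T0", "r"])

    def test_ranking_size_ties_and_sign(self):
        corr = pd.DataFrame(
            {"r": [0.9, -0.9, 0.5, np.nan], "r2": [0.81, 0.81, 0.25, np.nan]},
            index=["Tb", "Ta", "Tc", "Td"],
        )
        top = rank_by_pc_correlation(corr, top_n=2)
        assert list(top.index) == ["Ta", "Tb"]  # tie broken by id
        assert list(top["sign"]) == [-1, 1]


class TestBootstrap:
    def _design(self, noise_sd, seed=0, reps=4, tissues=5, p=12):
        rng = np.random.default_rng(seed)
        cols = [f"t{t}_r{r}" for t in range(tissues) for r in range(reps)]
        axis = np.repeat(rng.normal(size=tissues), reps)
        X = np.outer(rng.normal(size=p), axis) + rng.normal(size=(p, len(cols))) * noise_sd
        expr = pd.DataFrame(X, index=[f"T{i}" for i in range(p)], columns=cols)
        meta = pd.DataFrame({"tissue": [c.split("_")[0] for c in cols]},
                            index=pd.Index(cols, name="sample_id"))
        return expr, meta

    def test_zero_within_tissue_variance_gives_zero_width_ci(self):
        expr, meta = self._design(noise_sd=0.0)
        res = bootstrap_pca(expr, meta, n_boot=50, seed=1)
        lo, hi = res.variance_ci
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical_cis(self):
        expr, meta = self._design(noise_sd=0.3)
        a = bootstrap_pca(expr, meta, n_boot=100, seed=5, transcripts=["T0", "T1"])
        b = bootstrap_pca(expr, meta, n_boot=100, seed=5, transcripts=["T0", "T1"])
        assert a.variance_ci == b.variance_ci
        assert np.allclose(a.ci99, b.ci99)

    def test_ci_contains_point_estimate(self):
        expr, meta = self._design(noise_sd=0.3, seed=2)
        res = bootstrap_pca(expr, meta, n_boot=200, seed=7, transcripts=["T0"])
        lo, hi = res.variance_ci
        assert lo <= res.variance_explained[0] <= hi
        r2 = res.transcript_correlations.loc["T0", "r2"]
        assert res.ci99.loc["T0", "lo"] - 1e-9 <= r2 <= res.ci99.loc["T0", "hi"] + 1e-9

    def test_single_replicate_tissue_excluded(self):
        expr, meta = self._design(noise_sd=0.3, seed=3)
        meta2 = meta.drop(index=[c for c in meta.index if c.startswith("t0_")][1:])
        expr2 = expr[meta2.index]
        res = bootstrap_pca(expr2, meta2, n_boot=20, seed=9)
        assert res.excluded_tissues == ["t0"]
        assert all(not c.startswith("t0_") for c in res.scores.index)

    def test_seed_mandatory(self):
        expr, meta = self._design(noise_sd=0.3)
        with pytest.raises(DataModelError):
            bootstrap_pca(expr, meta, n_boot=10)


class TestExpressedMaskAndFisher:
    def test_mask_uses_tissue_mean_log(self):
        cols = ["a_r1", "a_r2", "b_r1", "b_r2"]
        log_expr = pd.DataFrame(
            {"a_r1": [0.4, 2.0], "a_r2": [0.4, 2.0], "b_r1": [0.9, 0.1], "b_r2": [0.9, 0.1]},
            index=["low", "high"],
        )[cols]
        meta = pd.DataFrame({"tissue": ["a", "a", "b", "b"]},
                            index=pd.Index(cols, name="sample_id"))
        mask = expressed_mask(log_expr, meta, threshold=1.0)
        assert not mask.loc["low"] and mask.loc["high"]

    def test_fisher_z_interval_brackets_r(self):
        lo, hi = fisher_z_ci(0.56, n=11)
        assert lo < 0.56 < hi and -1 < lo and hi < 1
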