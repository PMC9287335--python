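"""The voom / weighted-fit / empirical-Bayes chain.

Includes a frozen golden comparison against limma 3.58.1 + edgeR 4.0.16
run on the identical fixture (finite- and infinite-prior branches).
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mirlink as ml
from mirlink.diffexpr import ebayes_moderate, fit_variance_prior
from mirlink.preprocess import NormalizationResult

from conftest import counts_frame


def _design(columns):
    return ml.DesignSpec(
        groups={s: s.split("_")[0] for s in columns}, contrast=("mimic", "ctrl")
    )


SIX = ["mimic_1", "mimic_2", "mimic_3", "ctrl_1", "ctrl_2", "ctrl_3"]


class TestFilterCounts:
    @pytest.mark.parametrize(
        "row,kept",
        [
            ([2, 2, 0, 0, 0, 0], True),   # 2 samples > 1 meets ceil(6/4) = 2
            ([0, 0, 0, 0, 0, 0], False),
            ([1, 1, 1, 1, 1, 1], False),  # strict: 1 > 1 is false
        ],
    )
    def test_code_mode_rule(self, row, kept):
        m = counts_frame([row, [9] * 6], samples=SIX)
        out = ml.filter_counts_de(m)
        assert ("g0" in out.index) is kept

    def test_text_mode_differs_on_exact_quarter(self):
        # 4 samples: count >= 1 in exactly 25% of samples fails the strict
        # "more than 25%" text reading but passes with 1 sample under code
        # mode only if > min_count
        m = counts_frame([[1, 0, 0, 0], [5, 5, 5, 5]])
        out_text = ml.filter_counts_de(m, mode="text")
        assert "g0" not in out_text.index


class TestVoom:
    def _identity_norm(self, counts):
        lib = counts.sum(axis=0).astype(float)
        return NormalizationResult(
            tmm_factors=pd.Series(1.0, index=counts.columns),
            effective_libsizes=lib,
            log2cpm=np.log2((counts + 0.5).div(lib + 1.0, axis=1) * 1e6),
        )

    def test_log2cpm_offset_formula(self, rng):
        counts = counts_frame(
            rng.integers(100, 2000, size=(60, 6)), samples=SIX
        )
        counts.iloc[0, :] = 0
        counts.iloc[1:, :] = (
            counts.iloc[1:, :].div(counts.iloc[1:, :].sum(axis=0), axis=1) * 1e6
        ).round()
        lib = counts.sum(axis=0)
        y, _w = ml.voom_transform(counts, _design(SIX), self._identity_norm(counts))
        expected = np.log2(0.5 / (lib.iloc[0] + 1.0) * 1e6)
        assert y.iloc[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_weights_positive_and_finite(self, rng):
        counts = counts_frame(rng.integers(0, 500, size=(80, 6)), samples=SIX)
        counts = ml.filter_counts_de(counts)
        _y, w = ml.voom_transform(counts, _design(SIX), self._identity_norm(counts))
        assert (w.to_numpy() > 0).all() and np.isfinite(w.to_numpy()).all()

    def test_flat_mean_variance_trend_gives_flat_weights(self, rng):
        # constant log-scale variance across a wide abundance range
        mu = rng.uniform(4, 12, size=150)
        y = mu[:, None] + rng.normal(0, 0.4, size=(150, 6))
        counts = counts_frame(np.rint(2.0**y), samples=SIX)
        _y, w = ml.voom_transform(counts, _design(SIX), self._identity_norm(counts))
        ratio = w.to_numpy().max() / w.to_numpy().min()
        assert ratio < 1.5**4  # sd within 1.5x flat => weights within 1.5^4


class TestFitContrast:
    def test_identical_groups_give_zero_coef(self):
        y = counts_frame([[3.0, 3.0, 3.0, 3.0]], samples=["mimic_1", "mimic_2", "ctrl_1", "ctrl_2"])
        fit = ml.fit_contrast(y, None, _design(y.columns))
        assert fit.coef[0] == pytest.approx(0.0)

    def test_group_mean_difference(self):
        y = counts_frame([[2.0, 4.0, 1.0, 1.0]], samples=["mimic_1", "mimic_2", "ctrl_1", "ctrl_2"])
        fit = ml.fit_contrast(y, None, _design(y.columns))
        assert fit.coef[0] == pytest.approx(2.0)

    def test_matches_normal_equations_oracle(self, rng):
        samples = ["mimic_1", "mimic_2", "mimic_3", "ctrl_1", "ctrl_2", "ctrl_3"]
        y = counts_frame(rng.normal(size=(20, 6)), samples=samples)
        fit = ml.fit_contrast(y, None, _design(samples))
        X = np.zeros((6, 2))
        X[:3, 1] = 1.0  # mimic column (levels sorted: ctrl, mimic)
        X[3:, 0] = 1.0
        c = np.array([-1.0, 1.0])
        for g in range(20):
            beta = np.linalg.solve(X.T @ X, X.T @ y.iloc[g].to_numpy())
            resid = y.iloc[g].to_numpy() - X @ beta
            sigma = math.sqrt(resid @ resid / 4)
            assert fit.coef[g] == pytest.approx(c @ beta, abs=1e-10)
            assert fit.sigma[g] == pytest.approx(sigma, abs=1e-10)
            se_unscaled = math.sqrt(c @ np.linalg.inv(X.T @ X) @ c)
            assert fit.stdev_unscaled[g] == pytest.approx(se_unscaled, abs=1e-12)

    def test_small_group_rejected(self):
        y = counts_frame([[1.0, 2.0, 3.0]], samples=["mimic_1", "ctrl_1", "ctrl_2"])
        with pytest.raises(ValueError):
            ml.fit_contrast(y, None, _design(y.columns))


class TestEbayes:
    def _fit(self, rng, n_feat=200, sigma=None):
        samples = SIX
        y = rng.normal(size=(n_feat, 6))
        if sigma is not None:
            y *= sigma[:, None]
        frame = counts_frame(y, samples=samples)
        return ml.fit_contrast(frame, None, _design(samples))

    def test_identical_variances_take_infinite_prior_branch(self):
        # crafted responses with exactly equal residual variance per feature
        base = np.array([1.0, -1.0, 0.0, 1.0, -1.0, 0.0])
        y = counts_frame(np.vstack([base + k for k in range(12)]), samples=SIX)
        fit = ml.fit_contrast(y, None, _design(SIX))
        table = ebayes_moderate(fit)
        assert np.isinf(table["prior_df"]).all()
        # moderated t then equals ordinary t with the pooled common variance
        pooled = float(np.mean(fit.sigma**2))
        t_exp = fit.coef / (fit.stdev_unscaled * math.sqrt(pooled))
        assert np.allclose(table["t"], t_exp)

    def test_posterior_variance_is_convex_combination(self, rng):
        sigma = np.sqrt(stats.invgamma.rvs(2, scale=0.1, size=300, random_state=1))
        fit = self._fit(rng, n_feat=300, sigma=sigma)
        table = ebayes_moderate(fit)
        d0 = table["prior_df"].iloc[0]
        s02 = table["prior_var"].iloc[0]
        assert np.isfinite(d0)
        s2 = fit.sigma**2
        post = (d0 * s02 + fit.df_residual * s2) / (d0 + fit.df_residual)
        lo = np.minimum(s2, s02)
        hi = np.maximum(s2, s02)
        inner = ~np.isclose(s2, s02)
        assert ((post >= lo) & (post <= hi)).all()
        assert ((post > lo) & (post < hi))[inner].all()

    def test_vanishing_prior_reproduces_ordinary_t(self, rng):
        fit = self._fit(rng)
        table = ebayes_moderate(fit, prior_df=1e-8, prior_var=1.0)
        t_ord = fit.coef / (fit.stdev_unscaled * fit.sigma)
        assert np.allclose(table["t"], t_ord, rtol=1e-6)

    def test_moment_recovery_of_known_prior(self):
        """Scaled-F simulated variances recover (d0, s0^2)."""
        d0_true, s02_true, df = 4.0, 0.05, 4
        d0_est, s02_est = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            var_g = s02_true * d0_true / rng.chisquare(d0_true, size=2000)
            s2 = var_g * rng.chisquare(df, size=2000) / df
            d0, s02 = fit_variance_prior(s2, df)
            d0_est.append(d0)
            s02_est.append(s02)
        assert abs(np.mean(d0_est) - d0_true) / d0_true < 0.3
        assert abs(np.mean(s02_est) - s02_true) / s02_true < 0.2


class TestGoldenLimma:
    """Fixed NB fixture frozen against the reference R implementation."""

    def _fixture(self):
        rng = np.random.default_rng(5)
        p, n = 400, 8
        mu = rng.lognormal(6, 1.2, p)
        counts = np.vstack([rng.poisson(rng.gamma(1 / 0.3, mu * 0.3)) for _ in range(n)]).T
        cols = [f"mimic_{i}" for i in range(1, 5)] + [f"ctrl_{i}" for i in range(1, 5)]
        return counts_frame(counts.astype(int), features=[f"g{i:03d}" for i in range(p)], samples=cols)

    def test_matches_limma_voom_chain(self):
        counts = self._fixture()
        de = ml.run_de_pipeline(counts, _design(counts.columns))
        # frozen from limma 3.58.1 (voom+lmFit+contrasts.fit+eBayes)
        assert de["prior_df"].iloc[0] == pytest.approx(52.5207178834091, rel=1e-8)
        assert de["prior_var"].iloc[0] == pytest.approx(1.1126176354678, rel=1e-8)
        expected = {
            "g000": (-0.464178092509894, -0.748268393448534, 0.457295032144616),
            "g123": (-0.0122510416867367, -0.0218906818381112, 0.982609628441384),
            "g399": (-0.112273434370362, -0.188899909239459, 0.850824859777378),
        }
        for gene, (lfc, t, p) in expected.items():
            assert de.loc[gene, "logFC"] == pytest.approx(lfc, abs=1e-8)
            assert de.loc[gene, "t"] == pytest.approx(t, abs=1e-7)
            assert de.loc[gene, "p"] == pytest.approx(p, abs=1e-8)

    def test_pipeline_is_deterministic(self):
        counts = self._fixture()
        a = ml.run_de_pipeline(counts, _design(counts.columns))
        b = ml.run_de_pipeline(counts, _design(counts.columns))
        pd.testing.assert_frame_equal(a, b)


class TestSummarize:
    def _table(self, logfc, p_adj):
        return pd.DataFrame({
            "logFC": logfc,
            "p": np.asarray(p_adj) / 2,
            "p_adj": p_adj,
        })

    def test_no_significant_features(self):
        s = ml.summarize_de(self._table([1.0, -2.0], [0.5, 0.9]))
        assert (s.n_sig, s.n_up, s.n_down) == (0, 0, 0)
        assert math.isnan(s.asymmetry_p)

    def test_asymmetry_chi2_closed_form(self):
        logfc = [-2.0] * 69 + [2.0] * 20
        s = ml.summarize_de(self._table(logfc, [0.01] * 89))
        expected = (69 - 44.5) ** 2 / 44.5 + (20 - 44.5) ** 2 / 44.5
        assert s.asymmetry_chi2 == pytest.approx(expected, abs=1e-10)
        assert s.asymmetry_p == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-12)
        assert (s.n_down_lfc, s.n_up_lfc) == (69, 20)

    def test_lfc_cut_applied_on_top_of_significance(self):
        s = ml.summarize_de(self._table([-0.5, -1.5, 1.2], [0.01, 0.01, 0.01]), lfc_cut=1.0)
        assert (s.n_sig, s.n_down, s.n_down_lfc, s.n_up_lfc) == (3, 2, 1, 1)
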