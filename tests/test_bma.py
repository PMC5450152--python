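import numpy as np
import pandas as pd
import pytest

from pgxsig import bma
from pgxsig._gibbs import pg_sample
from pgxsig.datatypes import ConfigError, DataError


def _logistic_data(rng, n, betas, maf=0.3, intercept=0.0):
    X = rng.binomial(2, maf, size=(n, len(betas))).astype(float)
    lp = intercept + X @ np.asarray(betas)
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    design = pd.DataFrame(X, columns=[f"x{j}" for j in range(len(betas))])
    return design, y


class TestPolyaGamma:
    def test_moments_at_zero(self):
        d = pg_sample(np.zeros(100_000), 7)
        assert d.mean() == pytest.approx(0.25, abs=0.003)
        assert d.var() == pytest.approx(1 / 24, rel=0.05)

    @pytest.mark.parametrize("z", [0.3, 1.0, 2.5, 6.0])
    def test_mean_formula(self, z):
        # E[PG(1,z)] = tanh(z/2) / (2z)
        d = pg_sample(np.full(60_000, z), 11)
        assert d.mean() == pytest.approx(np.tanh(z / 2) / (2 * z), rel=0.02)

    def test_positive_support(self):
        d = pg_sample(np.linspace(-4, 4, 10_000), 3)
        assert (d > 0).all()

    def test_seed_determinism(self):
        z = np.linspace(0, 2, 100)
        assert np.array_equal(pg_sample(z, 5), pg_sample(z, 5))


class TestSpikeSlabConfig:
    def test_validation(self):
        with pytest.raises(ConfigError):
            bma.SpikeSlabConfig(n_iterations=0)
        with pytest.raises(ConfigError):
            bma.SpikeSlabConfig(burn_in_fraction=1.0)
        with pytest.raises(ConfigError):
            bma.SpikeSlabConfig(prior_inclusion_probability=1.5)

    def test_burn_in(self):
        cfg = bma.SpikeSlabConfig(n_iterations=1000, burn_in_fraction=0.2)
        assert cfg.burn_in == 200


class TestFitSpikeSlab:
    def test_prior_recovery_with_no_data(self):
        # likelihood off (n = 0): PIPs equal the prior inclusion probability
        design = pd.DataFrame({"x1": [], "x2": []})
        cfg = bma.SpikeSlabConfig(
            n_iterations=20_000, prior_inclusion_probability=0.3, seed=2
        )
        post = bma.fit_spike_slab(design, np.array([]), cfg)
        assert post.pip["x1"] == pytest.approx(0.3, abs=0.02)
        assert post.pip["x2"] == pytest.approx(0.3, abs=0.02)
        assert post.pip[bma.INTERCEPT] == 1.0

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(0)
        design, y = _logistic_data(rng, 2000, [-2.0, 0.0], intercept=1.0)
        post = bma.fit_spike_slab(
            design, y, bma.SpikeSlabConfig(n_iterations=6000, seed=3)
        )
        assert post.pip["x0"] > 0.95
        ci = post.credible_interval().loc["x0"]
        assert ci["upper"] < 0.0
        assert -2.5 < post.posterior_mean["x0"] < -1.5
        assert post.pip["x1"] < 0.6

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        design, y = _logistic_data(rng, 300, [-1.0, 0.0])
        cfg = bma.SpikeSlabConfig(n_iterations=2000, seed=9)
        p1 = bma.fit_spike_slab(design, y, cfg)
        p2 = bma.fit_spike_slab(design, y, cfg)
        assert np.array_equal(p1.beta_draws, p2.beta_draws)
        assert p1.pip.equals(p2.pip)

    def test_enumeration_oracle_p2(self):
        # PIPs on an enumerable 2-predictor problem match exhaustive
        # model-by-model evidence weights within 0.05
        rng = np.random.default_rng(3)
        n = 60
        x1 = rng.binomial(2, 0.3, n).astype(float)
        x2 = rng.binomial(2, 0.4, n).astype(float)
        lp = 0.3 - 1.0 * x1
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        design = pd.DataFrame({"x1": x1, "x2": x2})
        cfg = bma.SpikeSlabConfig(n_iterations=30_000, seed=5)
        post = bma.fit_spike_slab(design, y, cfg)
        oracle = bma.enumerate_model_pips(design, y, cfg)
        for term in ("x1", "x2"):
            assert post.pip[term] == pytest.approx(oracle[term], abs=0.05)

    def test_slab_shrinkage_monotone(self):
        # posterior mean shrinks toward 0 as the slab variance shrinks
        rng = np.random.default_rng(4)
        design, y = _logistic_data(rng, 500, [-1.0])
        means = []
        for weight in (1.0, 400.0):  # larger weight = tighter slab
            cfg = bma.SpikeSlabConfig(
                n_iterations=4000,
                information_weight=weight,
                prior_inclusion_probability=0.5,
                seed=6,
            )
            post = bma.fit_spike_slab(design, y, cfg)
            means.append(abs(post.posterior_mean["x0"]))
        assert means[1] < means[0]

    def test_degenerate_column_rejected(self):
        design = pd.DataFrame({"x0": np.zeros(50)})
        y = np.r_[np.ones(25), np.zeros(25)]
        with pytest.raises(DataError):
            bma.fit_spike_slab(design, y)

    def test_single_class_rejected(self):
        design = pd.DataFrame({"x0": np.arange(20, dtype=float)})
        with pytest.raises(DataError):
            bma.fit_spike_slab(design, np.ones(20))


class TestSelectSignature:
    @staticmethod
    def _posterior(pips, cis, terms=None, n=1000):
        terms = terms or [f"s{i}" for i in range(len(pips))]
        all_terms = [bma.INTERCEPT] + terms
        rng = np.random.default_rng(0)
        gamma = np.ones((n, len(all_terms)), dtype=bool)
        beta = np.zeros((n, len(all_terms)))
        for j, (pip, (lo, hi)) in enumerate(zip(pips, cis), start=1):
            inc = rng.random(n) < pip
            gamma[:, j] = inc
            # uniform draws spanning the CI so quantiles land inside (lo, hi)
            width = hi - lo
            beta[inc, j] = np.linspace(lo + 0.01 * width, hi - 0.01 * width, inc.sum())
        return bma.SpikeSlabPosterior(
            terms=all_terms,
            beta_draws=beta,
            gamma_draws=gamma,
            config=bma.SpikeSlabConfig(n_iterations=n, burn_in_fraction=0.0),
        )

    def test_ci_containing_zero_not_selected(self):
        post = self._posterior([0.85], [(-0.2, 0.1)])
        assert bma.select_signature(post, post) == []

    def test_high_pip_zero_excluding_selected(self):
        post = self._posterior([0.9], [(-1.0, -0.3)])
        assert bma.select_signature(post, post) == ["s0"]

    def test_must_hold_in_both_fits(self):
        good = self._posterior([0.9], [(-1.0, -0.3)])
        bad = self._posterior([0.9], [(-0.5, 0.5)])
        assert bma.select_signature(good, bad) == []
        assert bma.select_signature(bad, good) == []

    def test_low_pip_not_selected(self):
        post = self._posterior([0.5], [(-1.0, -0.3)])
        assert bma.select_signature(post, post) == []


class TestScreenInteractions:
    def test_single_snp_empty(self):
        design = pd.DataFrame({"a": np.arange(10, dtype=float)})
        assert bma.screen_interactions(["a"], design, np.zeros(10)).empty

    def test_no_planted_interaction_low_pips(self):
        rng = np.random.default_rng(5)
        design, y = _logistic_data(rng, 1500, [-1.0, -1.0], intercept=1.0)
        cfg = bma.SpikeSlabConfig(n_iterations=4000, seed=8)
        pips = bma.screen_interactions(["x0", "x1"], design, y, cfg)
        assert list(pips.index) == ["x0:x1"]
        main = bma.fit_spike_slab(design, y, cfg)
        assert pips["x0:x1"] < min(main.pip["x0"], main.pip["x1"])

    def test_planted_product_effect_detected(self):
        rng = np.random.default_rng(6)
        n = 2000
        X = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
        lp = -0.5 + 1.5 * X[:, 0] * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        design = pd.DataFrame(X, columns=["x0", "x1"])
        cfg = bma.SpikeSlabConfig(n_iterations=4000, seed=9)
        pips = bma.screen_interactions(["x0", "x1"], design, y, cfg)
        assert pips["x0:x1"] > 0.8


class TestRefitFinal:
    def test_paper_style_or_from_coefficient(self):
        # exponentiation consistency on printed-style values
        model_or = float(np.exp(-0.52))
        assert round(model_or, 2) == 0.59
        assert round(float(np.exp(-1.46)), 2) == 0.23
        lo, hi = np.exp(-2.31), np.exp(-0.63)
        assert (round(lo, 2), round(hi, 2)) == (0.10, 0.53)

    def test_zero_coefficient_unit_or(self):
        rng = np.random.default_rng(7)
        design, y = _logistic_data(rng, 4000, [0.0])
        model = bma.refit_final(design, y)
        assert model.odds_ratios[0] == pytest.approx(1.0, abs=0.15)

    def test_model_artifact_roundtrip(self, tmp_path):
        rng = np.random.default_rng(8)
        design, y = _logistic_data(rng, 500, [-0.8, 0.4])
        model = bma.refit_final(design, y, codings={"x0": "dominant"})
        path = tmp_path / "model.json"
        model.to_json(path)
        back = bma.SignatureModel.from_json(path)
        assert back.coefficients == model.coefficients
        assert back.codings == ["dominant", "additive"]
        for orr, beta in zip(back.odds_ratios, back.coefficients):
            assert orr == pytest.approx(np.exp(beta), rel=1e-9)

    def test_empty_selection_rejected(self):
        with pytest.raises(DataError):
            bma.refit_final(pd.DataFrame(index=range(5)), np.zeros(5))

    def test_separation_flagged(self):
        x = np.r_[np.ones(20), np.zeros(20)]
        y = np.r_[np.ones(20), np.zeros(20)]
        model = bma.refit_final(pd.DataFrame({"x": x}), y)
        assert model.separated


class TestDiagnostics:
    def test_iid_rhat_near_one(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(20_000)
        assert bma.split_rhat(x) == pytest.approx(1.0, abs=0.01)

    def test_stuck_chain_warns(self):
        terms = [bma.INTERCEPT, "x"]
        beta = np.zeros((1000, 2))
        beta[:, 0] = 1.23  # constant: stuck
        gamma = np.ones((1000, 2), dtype=bool)
        post = bma.SpikeSlabPosterior(
            terms=terms,
            beta_draws=beta,
            gamma_draws=gamma,
            config=bma.SpikeSlabConfig(n_iterations=1000),
        )
        report = bma.diagnostics(post)
        assert report.loc[bma.INTERCEPT, "verdict"] == "warn"

    def test_ar1_ess_closed_form(self):
        rho = 0.9
        n = 200_000
        rng = np.random.default_rng(11)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert bma.effective_sample_size(x) == pytest.approx(expected, rel=0.2)

    def test_iid_ess_near_n(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(10_000)
        assert bma.effective_sample_size(x) > 0.8 * 10_000

    def test_too_few_draws(self):
        with pytest.raises(DataError):
            bma.effective_sample_size(np.array([1.0, 2.0]))
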