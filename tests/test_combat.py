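import subprocess
import sys
import textwrap

import numpy as np
import pytest
from scipy import stats

from radcombat import (
    FeatureTable, SimulationConfig, simulate_features, fit_standardize,
    eb_hyperpriors, eb_adjust, harmonize,
)
from radcombat.combat import ConfoundingError, CombatModel

from reference_combat import reference_harmonize


def _model_for(table, covariates=("class",)):
    model, Z = fit_standardize(table, covariates)
    return eb_hyperpriors(model), Z


class TestFitStandardize:
    def test_confounded_design_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (20, 5))
        batches = np.r_[np.zeros(10), np.ones(10)].astype(int)
        table = FeatureTable(X, [f"f{i}" for i in range(5)],
                             batches.astype(str), batches)
        with pytest.raises(ConfoundingError):
            fit_standardize(table, ("class",))

    def test_zero_variance_feature_named(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (20, 3))
        X[:, 1] = 7.0
        y = np.tile([0, 1], 10)
        table = FeatureTable(X, ["a", "dead", "c"],
                             np.repeat(["p", "q"], 10), y)
        with pytest.raises(ValueError, match="dead"):
            fit_standardize(table)

    def test_null_limit_gamma_zero_delta_one(self):
        cfg = SimulationConfig(n_per_batch=[4000, 4000], n_features=20,
                               additive_effect_scale=0.0,
                               multiplicative_effect_range=(1.0, 1.0),
                               seed=1)
        table, _ = simulate_features(cfg)
        model, _ = fit_standardize(table)
        assert np.all(np.abs(model.gamma_hat) < 0.1)
        assert np.all(np.abs(model.delta2_hat - 1.0) < 0.1)

    def test_beta_recovery_within_3se(self):
        cfg = SimulationConfig(n_per_batch=[500, 500], n_features=50,
                               class_effect_scale=1.0,
                               additive_effect_scale=0.0,
                               multiplicative_effect_range=(1.0, 1.0),
                               noise_sd=1.0, seed=2)
        table, truth = simulate_features(cfg)
        model, _ = fit_standardize(table)
        # balanced two-group design: SE(beta) ~ sd * sqrt(4/n)
        se = cfg.noise_sd * np.sqrt(4.0 / table.n_samples)
        assert np.all(np.abs(model.beta_hat[0] - truth.beta) < 3 * se)

    def test_gamma_hat_weighted_mean_zero(self, small_fixture_table):
        model, _ = fit_standardize(small_fixture_table)
        w = model.n_per_batch / model.n_per_batch.sum()
        assert np.allclose(w @ model.gamma_hat, 0.0, atol=1e-10)


class TestHyperpriors:
    def test_identical_gammas_give_zero_variance(self):
        model = CombatModel(
            batch_levels=["a"], design_columns=[], n_per_batch=np.array([5]),
            alpha_hat=np.zeros(4), beta_hat=np.zeros((0, 4)),
            sigma2_hat=np.ones(4),
            gamma_hat=np.full((1, 4), 0.7),
            delta2_hat=np.array([[1.0, 2.0, 3.0, 4.0]]),
        )
        eb_hyperpriors(model)
        assert model.hyper_gamma_mean[0] == pytest.approx(0.7)
        assert model.hyper_gamma_var[0] == 0.0

    def test_too_few_features_rejected(self):
        model = CombatModel(
            batch_levels=["a"], design_columns=[], n_per_batch=np.array([5]),
            alpha_hat=np.zeros(2), beta_hat=np.zeros((0, 2)),
            sigma2_hat=np.ones(2), gamma_hat=np.zeros((1, 2)),
            delta2_hat=np.ones((1, 2)),
        )
        with pytest.raises(ValueError):
            eb_hyperpriors(model)

    def test_inverse_gamma_moment_recovery(self):
        # delta2 drawn from a known inverse-gamma: moments recover the
        # parameters within 5% at G = 10^4
        lam_true, theta_true = 8.0, 12.0  # finite 4th moment (lambda > 4)
        rng = np.random.default_rng(3)
        d2 = theta_true / rng.gamma(lam_true, 1.0, 10_000)
        model = CombatModel(
            batch_levels=["a"], design_columns=[],
            n_per_batch=np.array([5]),
            alpha_hat=np.zeros(d2.size), beta_hat=np.zeros((0, d2.size)),
            sigma2_hat=np.ones(d2.size),
            gamma_hat=np.zeros((1, d2.size)),
            delta2_hat=d2[None, :],
        )
        eb_hyperpriors(model)
        assert model.hyper_delta_lambda[0] == pytest.approx(lam_true,
                                                            rel=0.05)
        assert model.hyper_delta_theta[0] == pytest.approx(theta_true,
                                                           rel=0.05)

    def test_feature_permutation_invariance(self, small_fixture_table):
        model, _ = _model_for(small_fixture_table)
        perm = np.random.default_rng(0).permutation(
            small_fixture_table.n_features
        )
        names = [small_fixture_table.feature_names[g] for g in perm]
        shuffled = small_fixture_table.subset_features(names)
        model2, _ = _model_for(shuffled)
        assert np.allclose(model.hyper_gamma_mean, model2.hyper_gamma_mean)
        assert np.allclose(model.hyper_gamma_var, model2.hyper_gamma_var)
        assert np.allclose(model.hyper_delta_lambda,
                           model2.hyper_delta_lambda)


class TestEbAdjust:
    def test_diffuse_prior_no_shrinkage(self, small_fixture_table):
        model, Z = _model_for(small_fixture_table)
        model.hyper_gamma_var = np.full(len(model.batch_levels), np.inf)
        eb_adjust(model, Z, small_fixture_table.batch_labels)
        assert np.allclose(model.gamma_star, model.gamma_hat)

    def test_degenerate_prior_full_shrinkage(self, small_fixture_table):
        model, Z = _model_for(small_fixture_table)
        model.hyper_gamma_var = np.zeros(len(model.batch_levels))
        eb_adjust(model, Z, small_fixture_table.batch_labels)
        for i in range(len(model.batch_levels)):
            assert np.allclose(model.gamma_star[i],
                               model.hyper_gamma_mean[i])

    def test_fixed_point_satisfies_updates(self, small_fixture_table):
        model, Z = _model_for(small_fixture_table)
        tol = 1e-10
        eb_adjust(model, Z, small_fixture_table.batch_labels, tol=tol,
                  max_iter=10_000)
        from radcombat.combat import _postmean, _postvar
        for i, b in enumerate(model.batch_levels):
            zi = Z[small_fixture_table.batch_labels == b]
            n = zi.shape[0]
            g = _postmean(model.gamma_hat[i], model.hyper_gamma_mean[i], n,
                          model.delta2_star[i], model.hyper_gamma_var[i])
            assert np.allclose(g, model.gamma_star[i], atol=1e-6)
            ss = ((zi - g[None, :]) ** 2).sum(axis=0)
            d2 = _postvar(ss, n, model.hyper_delta_lambda[i],
                          model.hyper_delta_theta[i])
            assert np.allclose(d2, model.delta2_star[i], atol=1e-6)

    def test_shrinkage_ordering(self, study_table):
        table, _ = study_table
        _, model = harmonize(table)
        for i in range(len(model.batch_levels)):
            assert np.all(
                np.abs(model.gamma_star[i] - model.hyper_gamma_mean[i])
                <= np.abs(model.gamma_hat[i] - model.hyper_gamma_mean[i])
                + 1e-12
            )


class TestHarmonize:
    def test_single_batch_identity(self):
        rng = np.random.default_rng(0)
        table = FeatureTable(rng.normal(0, 1, (10, 4)),
                             list("abcd"), np.full(10, "only"),
                             np.tile([0, 1], 5))
        with pytest.warns(RuntimeWarning):
            out, model = harmonize(table)
        assert model is None
        assert np.allclose(out.values, table.values, atol=1e-10)

    def test_labels_and_order_preserved(self, study_table):
        table, _ = study_table
        out, _ = harmonize(table)
        assert out.sample_ids == table.sample_ids
        assert np.array_equal(out.batch_labels, table.batch_labels)
        assert np.array_equal(out.class_labels, table.class_labels)

    def test_known_shifts_removed_within_3se(self):
        # strong additive shifts, delta = 1: per-batch means must agree
        # across batches after harmonization
        n = 2000
        cfg = SimulationConfig(n_per_batch=[n, n, n], n_features=500,
                               additive_effect_scale=2.0,
                               multiplicative_effect_range=(1.0, 1.0),
                               noise_sd=1.0, seed=4)
        table, truth = simulate_features(cfg)
        out, _ = harmonize(table)
        means = np.stack([
            out.values[out.batch_labels == b].mean(axis=0)
            for b in out.batch_levels
        ])
        se = cfg.noise_sd * np.sqrt(2.0 / n)  # SE of a mean difference
        assert np.max(np.abs(means - means.mean(axis=0))) < 3 * se

    def test_class_effect_preserved(self):
        # beta fitted on harmonized data matches beta fitted on an
        # effect-free simulation of the same size, within sampling error
        cfg = SimulationConfig(n_per_batch=[300, 300, 300], n_features=50,
                               class_effect_scale=1.0,
                               additive_effect_scale=1.5,
                               multiplicative_effect_range=(0.5, 2.0),
                               seed=5)
        table, truth = simulate_features(cfg)
        out, _ = harmonize(table)
        x = out.class_labels.astype(float)
        xc = x - x.mean()
        beta_fit = xc @ (out.values - out.values.mean(axis=0)) / (xc @ xc)
        resid_sd = 1.25  # approx average delta * noise_sd
        se = resid_sd * np.sqrt(4.0 / out.n_samples)
        assert np.mean(np.abs(beta_fit - truth.beta) < 3 * se) > 0.95

    def test_repeated_harmonization_contracts(self, small_fixture_table):
        # EB shrinkage is not a projection, so a second pass still moves
        # the data slightly; the changes must shrink pass over pass and
        # stay small relative to the first adjustment
        x = small_fixture_table
        h1, _ = harmonize(x, tol=1e-8, max_iter=2000)
        h2, _ = harmonize(h1, tol=1e-8, max_iter=2000)
        h3, _ = harmonize(h2, tol=1e-8, max_iter=2000)
        d01 = np.abs(h1.values - x.values).max()
        d12 = np.abs(h2.values - h1.values).max()
        d23 = np.abs(h3.values - h2.values).max()
        assert d12 < 0.5 * d01
        assert d23 < d12

    def test_matches_equation_reference(self, small_fixture_table):
        ours, _ = harmonize(small_fixture_table, tol=1e-12, max_iter=20_000)
        ref = reference_harmonize(
            small_fixture_table.values,
            small_fixture_table.batch_labels,
            small_fixture_table.class_labels,
        )
        assert np.allclose(ours.values, ref, atol=1e-6)

    def test_anova_rejection_pattern(self, study_table):
        # strong simulated batch effects: ANOVA flips from rejecting on
        # nearly all features to rejecting on none
        from radcombat.assessment import anova_by_batch, rejection_rate
        table, _ = study_table
        out, _ = harmonize(table)
        assert rejection_rate(anova_by_batch(table)) > 0.9
        assert rejection_rate(anova_by_batch(out)) < 0.05


class TestAgainstSva:
    def test_matches_bioconductor_combat(self, small_fixture_table, tmp_path):
        """Cross-check the full harmonization against the reference
        parametric ComBat in Bioconductor's sva package."""
        t = small_fixture_table
        np.savetxt(tmp_path / "dat.csv", t.values.T, delimiter=",")
        np.savetxt(tmp_path / "batch.csv",
                   np.array([t.batch_levels.index(b)
                             for b in t.batch_labels]), delimiter=",")
        np.savetxt(tmp_path / "mod.csv", t.class_labels, delimiter=",")
        rscript = textwrap.dedent("""
            suppressMessages(library(sva))
            dat <- as.matrix(read.csv("dat.csv", header=FALSE))
            batch <- factor(read.csv("batch.csv", header=FALSE)[[1]])
            mod <- model.matrix(~ read.csv("mod.csv", header=FALSE)[[1]])
            out <- ComBat(dat=dat, batch=batch, mod=mod, par.prior=TRUE)
            write.table(out, "out.csv", sep=",", row.names=FALSE,
                        col.names=FALSE)
        """)
        (tmp_path / "run.R").write_text(rscript)
        proc = subprocess.run(
            ["Rscript", "run.R"], cwd=tmp_path, capture_output=True,
            text=True, timeout=300,
        )
        assert proc.returncode == 0, proc.stderr
        ref = np.loadtxt(tmp_path / "out.csv", delimiter=",").T
        ours, _ = harmonize(t, tol=1e-8, max_iter=5000)
        assert np.allclose(ours.values, ref, atol=1e-3)
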