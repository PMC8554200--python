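"""Joint longitudinal likelihood and maximum-likelihood fitting."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from hollimap.covariance import SADParams, build_sad1_covariance
from hollimap.dynamics import HollingLVParams
from hollimap.likelihood import (
    FitConfig,
    FitError,
    GenotypeModel,
    fit_parameters,
    genotype_mean_curves,
    joint_log_likelihood,
)


@pytest.fixture
def two_class_model(times16):
    thA = HollingLVParams(0.30, 24.0, -0.05, 0.26, 21.6, -0.08)
    thB = HollingLVParams(0.24, 20.0, -0.10, 0.22, 18.0, -0.15)
    sad = SADParams(0.6, 0.6, 0.8, 0.8, 0.3)
    return GenotypeModel(
        thetas={"A": thA, "B": thB},
        sad=sad,
        inits={"A": (1.2, 1.1), "B": (1.0, 1.0)},
    )


def _draw(model, labels, times, rng):
    mus = genotype_mean_curves(model, times)
    sigma = build_sad1_covariance(model.sad, len(times))
    return np.stack([rng.multivariate_normal(mus[l], sigma) for l in labels])


class TestJointLogLikelihood:
    def test_equals_dense_mvn_oracle(self, two_class_model, times16):
        """The structured computation must agree with a generic dense MVN
        log-density summed over individuals."""
        rng = np.random.default_rng(0)
        labels = np.array(["A", "B", "A", "B"])
        t = times16[:3]
        Y = _draw(two_class_model, labels, t, rng)
        mus = genotype_mean_curves(two_class_model, t)
        sigma = build_sad1_covariance(two_class_model.sad, 3)
        oracle = sum(
            multivariate_normal.logpdf(Y[i], mus[l], sigma)
            for i, l in enumerate(labels)
        )
        ours = joint_log_likelihood(Y, labels, two_class_model, t)
        assert ours == pytest.approx(oracle, rel=1e-10)

    def test_duplicating_individual_adds_its_density(self, two_class_model, times16):
        rng = np.random.default_rng(1)
        labels = np.array(["A", "B", "B"])
        Y = _draw(two_class_model, labels, times16, rng)
        base = joint_log_likelihood(Y, labels, two_class_model, times16)
        dup = joint_log_likelihood(
            np.vstack([Y, Y[:1]]), np.append(labels, "A"), two_class_model, times16
        )
        single = joint_log_likelihood(Y[:1], labels[:1], two_class_model, times16)
        total_const = 0.0  # additivity is exact, no fudge
        assert dup == pytest.approx(base + single + total_const, rel=1e-10)

    def test_unassigned_combination_rejected(self, two_class_model, times16):
        Y = np.ones((2, 32))
        with pytest.raises(ValueError, match="undeclared"):
            joint_log_likelihood(Y, ["A", "C"], two_class_model, times16)


class TestMeanCurves:
    def test_identical_theta_identical_mu(self, times16):
        th = HollingLVParams(0.3, 24.0, -0.05, 0.25, 21.0, -0.08)
        model = GenotypeModel(
            thetas={"X": th, "Y": th}, sad=SADParams(0.5, 0.5, 1, 1, 0),
            inits={"X": (1.0, 1.0), "Y": (1.0, 1.0)},
        )
        mus = genotype_mean_curves(model, times16)
        np.testing.assert_array_equal(mus["X"], mus["Y"])

    def test_monoculture_ignores_interaction_scalars(self, times16):
        th1 = HollingLVParams(0.3, 24.0, -0.5, 0.25, 21.0, -0.9)
        th2 = HollingLVParams(0.3, 24.0, 0.0, 0.25, 21.0, 0.0)
        sad = SADParams(0.5, 0.5, 1, 1, 0)
        m1 = GenotypeModel({"X": th1}, sad, {"X": (1.0, 1.0)},
                           culture="monoculture", species="E")
        m2 = GenotypeModel({"X": th2}, sad, {"X": (1.0, 1.0)},
                           culture="monoculture", species="E")
        np.testing.assert_array_equal(
            genotype_mean_curves(m1, times16)["X"],
            genotype_mean_curves(m2, times16)["X"],
        )

    def test_antagonism_lowers_own_species_curve(self, times16):
        sad = SADParams(0.5, 0.5, 1, 1, 0)
        harmed = GenotypeModel(
            {"X": HollingLVParams(0.3, 24.0, -0.2, 0.25, 21.0, 0.0)},
            sad, {"X": (1.0, 1.0)},
        )
        neutral = GenotypeModel(
            {"X": HollingLVParams(0.3, 24.0, 0.0, 0.25, 21.0, 0.0)},
            sad, {"X": (1.0, 1.0)},
        )
        mu_h = genotype_mean_curves(harmed, times16)["X"][:16]
        mu_n = genotype_mean_curves(neutral, times16)["X"][:16]
        assert np.all(mu_h[1:] < mu_n[1:])


class TestFitParameters:
    def test_noiseless_self_consistency(self, times16):
        """Data equal to exact model curves: fitted growth parameters must
        come back essentially exactly."""
        th = HollingLVParams(0.30, 24.0, -0.08, 0.25, 21.0, -0.12)
        model = GenotypeModel(
            thetas={"g": th}, sad=SADParams(0.5, 0.5, 1, 1, 0),
            inits={"g": (1.2, 1.0)},
        )
        mu = genotype_mean_curves(model, times16, step=0.02)["g"]
        Y = np.tile(mu, (4, 1))
        # tiny jitter keeps the residual covariance estimable while leaving
        # the mean curve essentially exact
        rng = np.random.default_rng(3)
        Y = Y + 1e-5 * rng.standard_normal(Y.shape)
        fit = fit_parameters(
            Y, ["g"] * 4, times16, mode="by_combination",
            config=FitConfig(step=0.02, n_restarts=1, max_cycles=8, tol=1e-10,
                             xatol=1e-9, fatol=1e-12),
        )
        est = fit.thetas["g"].as_array()
        np.testing.assert_allclose(est, th.as_array(), rtol=1e-3)

    def test_nested_loglik_ordering(self, strong_dataset, fast_fit):
        Y = strong_dataset.Y_coculture()
        labels = np.where(
            strong_dataset.genome_alleles("A", "M0002") == 1, "A", "a"
        )
        null = fit_parameters(Y, labels, strong_dataset.times, mode="null", config=fast_fit)
        alt = fit_parameters(
            Y, labels, strong_dataset.times, mode="by_combination",
            config=fast_fit, warm_start=null,
        )
        assert alt.loglik >= null.loglik - 1e-6

    def test_all_zero_abundance_rejected(self, times16):
        with pytest.raises(FitError):
            fit_parameters(np.zeros((4, 32)), ["g"] * 4, times16)

    def test_small_combination_rejected(self, times16):
        Y = np.ones((3, 32))
        with pytest.raises(FitError, match="'b'"):
            fit_parameters(np.asarray(Y), ["a", "a", "b"], times16)

    def test_serialisation_roundtrip(self, two_class_model):
        restored = GenotypeModel.from_json(two_class_model.to_json())
        for lab in two_class_model.thetas:
            np.testing.assert_allclose(
                restored.thetas[lab].as_array(),
                two_class_model.thetas[lab].as_array(),
            )
        assert restored.sad == two_class_model.sad
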