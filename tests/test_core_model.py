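"""Core generative model: risk-shift helper, standardization, log density."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrope import (
    ModelParameters,
    MRDataset,
    PriorConfig,
    log_joint,
    risk_shift,
    standardize,
)


class TestRiskShift:
    @pytest.mark.parametrize(
        "baseline, expected",
        [(0.993, 0.994), (0.524, 0.549), (0.109, 0.119)],
    )
    def test_one_sd_exposure_shift_examples(self, baseline, expected):
        """A log-odds shift of 0.1 moves these baseline risks as printed."""
        assert round(risk_shift(baseline, 0.1), 3) == expected

    @given(p=st.floats(0.001, 0.999))
    @settings(deadline=None)
    def test_zero_effect_is_identity(self, p):
        assert risk_shift(p, 0.0) == pytest.approx(p, abs=1e-12)

    @given(p=st.floats(0.01, 0.99), b=st.floats(-3, 3))
    @settings(deadline=None)
    def test_logit_scale_additivity(self, p, b):
        """Shifting by b then by -b returns the baseline (additivity on logits)."""
        assert risk_shift(risk_shift(p, b), -b) == pytest.approx(p, rel=1e-9)

    @given(p=st.floats(0.05, 0.95), b1=st.floats(-2, 2), b2=st.floats(-2, 2))
    @settings(deadline=None)
    def test_strictly_increasing_in_beta(self, p, b1, b2):
        lo, hi = sorted((b1, b2))
        if hi - lo < 1e-9:  # below float resolution of the logit shift
            return
        assert risk_shift(p, lo) < risk_shift(p, hi)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_rejects_degenerate_baseline(self, bad):
        with pytest.raises(ValueError):
            risk_shift(bad, 0.1)


class TestStandardize:
    def test_columns_and_exposure_scaled_to_unit(self, tiny_dataset):
        std = standardize(tiny_dataset)
        obs = ~std.exposure_missing_mask
        np.testing.assert_allclose(std.genotypes.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(std.genotypes.std(axis=0, ddof=1), 1.0, atol=1e-12)
        assert std.exposure[obs].mean() == pytest.approx(0.0, abs=1e-12)
        assert std.exposure[obs].std(ddof=1) == pytest.approx(1.0)
        # outcome untouched, masked entries still masked
        np.testing.assert_array_equal(std.outcome, tiny_dataset.outcome)
        assert np.isnan(std.exposure[std.exposure_missing_mask]).all()

    def test_idempotent(self, tiny_dataset):
        once = standardize(tiny_dataset)
        twice = standardize(once)
        np.testing.assert_allclose(twice.genotypes, once.genotypes, atol=1e-12)
        obs = ~once.exposure_missing_mask
        np.testing.assert_allclose(twice.exposure[obs], once.exposure[obs], atol=1e-12)

    def test_only_observed_entries_enter_exposure_moments(self):
        """Hand computation on a 6-value exposure with 3 masked entries."""
        x = np.array([2.0, np.nan, 4.0, np.nan, 6.0, np.nan])
        mask = np.isnan(x)
        ds = MRDataset(
            genotypes=np.tile(np.array([[0.0], [1.0], [2.0], [1.0], [0.0], [2.0]]), (1, 1)),
            exposure=x,
            exposure_missing_mask=mask,
            outcome=np.zeros(6, dtype=int),
        )
        std = standardize(ds)
        # observed values (2, 4, 6): mean 4, sample SD 2 -> (-1, 0, 1)
        np.testing.assert_allclose(std.exposure[~mask], [-1.0, 0.0, 1.0], atol=1e-12)
        assert std.standardization.exposure_mean == pytest.approx(4.0)
        assert std.standardization.exposure_sd == pytest.approx(2.0)

    def test_monomorphic_column_named_in_error(self):
        ds = MRDataset(
            genotypes=np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]]),
            exposure=np.array([0.1, 0.2, 0.3]),
            exposure_missing_mask=np.zeros(3, dtype=bool),
            outcome=np.array([0, 1, 0]),
        )
        with pytest.raises(ValueError, match=r"monomorphic.*\[0\]"):
            standardize(ds)


def _oracle_log_joint(ds, params, prior):
    """Independent term-by-term summation with explicit density formulas."""

    def ln_norm(v, mean, sd):
        return -0.5 * math.log(2 * math.pi) - math.log(sd) - (v - mean) ** 2 / (2 * sd**2)

    def ln_invgamma(v, shape, scale):
        return (
            shape * math.log(scale)
            - math.lgamma(shape)
            - (shape + 1) * math.log(v)
            - scale / v
        )

    x = []
    k = 0
    for i in range(ds.n):
        if ds.exposure_missing_mask[i]:
            x.append(params.x_missing[k])
            k += 1
        else:
            x.append(ds.exposure[i])
    total = 0.0
    for i in range(ds.n):
        mean_x = sum(ds.genotypes[i, j] * params.alpha[j] for j in range(ds.n_instruments))
        mean_x += params.delta_x * params.u[i]
        total += ln_norm(x[i], mean_x, params.sigma_x)
        eta = params.intercept + params.beta * x[i] + params.delta_y * params.u[i]
        p = 1.0 / (1.0 + math.exp(-eta))
        total += math.log(p) if ds.outcome[i] == 1 else math.log(1.0 - p)
        total += ln_norm(params.u[i], 0.0, math.sqrt(prior.u_variance))
    for j in range(ds.n_instruments):
        total += ln_norm(params.alpha[j], prior.alpha_prior_mean, prior.alpha_prior_sd)
    total += ln_norm(params.beta, prior.used_prior_mean, prior.used_prior_sd)
    total += ln_norm(params.delta_x, 0.0, prior.delta_prior_sd)
    total += ln_norm(params.delta_y, 0.0, prior.delta_prior_sd)
    total += ln_norm(params.intercept, 0.0, prior.intercept_prior_sd)
    total += ln_invgamma(params.sigma_x, prior.sigma_x_prior_shape, prior.sigma_x_prior_scale)
    return total


def _tiny_params():
    return ModelParameters(
        alpha=np.array([0.4, 0.6]),
        beta=0.25,
        delta_x=0.8,
        delta_y=-0.3,
        sigma_x=1.3,
        intercept=0.1,
        u=np.array([0.2, -0.1, 0.05, 0.3, -0.25]),
        x_missing=np.array([0.7]),
    )


class TestLogJoint:
    def test_matches_independent_summation(self, tiny_dataset, default_prior):
        params = _tiny_params()
        assert log_joint(tiny_dataset, params, default_prior) == pytest.approx(
            _oracle_log_joint(tiny_dataset, params, default_prior), rel=1e-12
        )

    def test_all_zero_dataset_closed_form(self, default_prior):
        """Zero data, zero parameters: density is priors + Gaussian(0 resid) + n log 1/2."""
        n, J = 4, 3
        ds = MRDataset(
            genotypes=np.zeros((n, J)),
            exposure=np.zeros(n),
            exposure_missing_mask=np.zeros(n, dtype=bool),
            outcome=np.zeros(n, dtype=int),
        )
        params = ModelParameters(
            alpha=np.zeros(J), beta=0.0, delta_x=0.0, delta_y=0.0,
            sigma_x=1.0, intercept=0.0, u=np.zeros(n),
        )
        from scipy.stats import invgamma, norm

        expected = (
            n * norm.logpdf(0.0, 0.0, 1.0)  # exposure residuals
            + n * math.log(0.5)  # Bernoulli at expit(0)
            + J * norm.logpdf(0.0, 0.5, 0.2)  # alpha prior at 0
            + norm.logpdf(0.0, 0.0, 10.0)  # used beta prior
            + 3 * norm.logpdf(0.0, 0.0, 1.0)  # delta_x, delta_y, intercept priors
            + invgamma.logpdf(1.0, 3.0, scale=2.0)
            + n * norm.logpdf(0.0, 0.0, math.sqrt(0.1))  # latent confounders
        )
        assert log_joint(ds, params, default_prior) == pytest.approx(expected, rel=1e-12)

    def test_beta_perturbation_leaves_exposure_term_unchanged(
        self, tiny_dataset, default_prior
    ):
        """The density factorizes: beta touches only outcome + beta-prior terms."""
        from dataclasses import replace
        from scipy.stats import norm

        from mrope.core_model import bernoulli_loglik

        params = _tiny_params()
        shifted = replace(params, beta=params.beta + 0.37)
        x = tiny_dataset.exposure.copy()
        x[tiny_dataset.exposure_missing_mask] = params.x_missing

        def outcome_and_prior(p):
            eta = p.intercept + p.beta * x + p.delta_y * p.u
            return bernoulli_loglik(tiny_dataset.outcome, eta) + norm.logpdf(
                p.beta, default_prior.used_prior_mean, default_prior.used_prior_sd
            )

        diff_full = log_joint(tiny_dataset, shifted, default_prior) - log_joint(
            tiny_dataset, params, default_prior
        )
        diff_partial = outcome_and_prior(shifted) - outcome_and_prior(params)
        assert diff_full == pytest.approx(diff_partial, rel=1e-12)

    def test_dimension_and_domain_errors(self, tiny_dataset, default_prior):
        params = _tiny_params()
        from dataclasses import replace

        with pytest.raises(ValueError, match="alpha"):
            log_joint(tiny_dataset, replace(params, alpha=np.zeros(3)), default_prior)
        with pytest.raises(ValueError, match="x_missing"):
            log_joint(tiny_dataset, replace(params, x_missing=np.zeros(2)), default_prior)
        with pytest.raises(ValueError, match="sigma_x"):
            replace(params, sigma_x=-1.0)


class TestMRDatasetInvariants:
    def test_counts_partition_sample(self, tiny_dataset):
        assert tiny_dataset.n_complete + tiny_dataset.n_missing == tiny_dataset.n
        assert tiny_dataset.n_missing == int(tiny_dataset.exposure_missing_mask.sum())

    def test_rejects_nonbinary_outcome(self):
        with pytest.raises(ValueError, match="outcome"):
            MRDataset(
                genotypes=np.zeros((2, 1)),
                exposure=np.zeros(2),
                exposure_missing_mask=np.zeros(2, dtype=bool),
                outcome=np.array([0, 2]),
            )

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="first-dimension"):
            MRDataset(
                genotypes=np.zeros((3, 1)),
                exposure=np.zeros(2),
                exposure_missing_mask=np.zeros(2, dtype=bool),
                outcome=np.zeros(2, dtype=int),
            )

    def test_prior_config_validation(self):
        with pytest.raises(ValueError):
            PriorConfig(pi0=1.2)
        with pytest.raises(ValueError):
            PriorConfig(rope_T=0.0)
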