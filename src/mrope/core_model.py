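"""Generative model for individual-level Mendelian randomization.

The model ties J genetic instruments Z (standardized minor-allele counts),
a continuous exposure X (standardized), a binary outcome Y, and a scalar
latent confounder U together as

    U   ~ N(0, u_variance)                       (confounder)
    X   | Z, U ~ N(sum_k alpha_k Z_k + delta_x U, sigma_x^2)
    Y   | X, U ~ Bernoulli(expit(omega + beta X + delta_y U))

where ``N(m, v)`` is parametrized by mean and *variance*.  ``beta`` is the
causal effect of interest; ``delta_x`` and ``delta_y`` carry confounding and
are identified only through their product.  Missing exposure values are
ordinary unknowns of the model and are imputed during posterior sampling.

This module holds the data container, the parameter and prior containers,
the unnormalized log posterior density under the convenience ("used")
continuous prior for beta, and the risk-shift helper used to elicit the
half-width T of the region of practical equivalence (ROPE).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit as _expit, logit as _logit
from scipy.stats import invgamma, norm

__all__ = [
    "MRDataset",
    "ModelParameters",
    "PriorConfig",
    "StandardizationInfo",
    "log_joint",
    "risk_shift",
    "standardize",
]


@dataclass(frozen=True)
class StandardizationInfo:
    """Centering/scaling constants applied by :func:`standardize`.

    Kept with the dataset so that effect estimates remain interpretable on
    the original measurement scale.
    """

    genotype_means: np.ndarray
    genotype_sds: np.ndarray
    exposure_mean: float
    exposure_sd: float


@dataclass
class MRDataset:
    """One-sample MR data: genotypes, exposure (possibly missing), outcome.

    Parameters
    ----------
    genotypes
        ``(n, J)`` matrix of per-individual minor-allele counts; values in
        {0, 1, 2} before standardization, real-valued after.
    exposure
        ``(n,)`` exposure vector; entries at masked positions are NaN.
    exposure_missing_mask
        ``(n,)`` boolean vector, True where the exposure is unobserved.
    outcome
        ``(n,)`` binary vector with entries in {0, 1}.
    exposure_oracle
        Optional hidden copy of the pre-masking exposure values (simulation
        bookkeeping only; never used by inference).
    standardization
        Constants recorded by :func:`standardize`, if it was applied.
    """

    genotypes: np.ndarray
    exposure: np.ndarray
    exposure_missing_mask: np.ndarray
    outcome: np.ndarray
    exposure_oracle: Optional[np.ndarray] = None
    standardization: Optional[StandardizationInfo] = None

    def __post_init__(self) -> None:
        self.genotypes = np.atleast_2d(np.asarray(self.genotypes, dtype=float))
        self.exposure = np.asarray(self.exposure, dtype=float)
        self.exposure_missing_mask = np.asarray(self.exposure_missing_mask, dtype=bool)
        self.outcome = np.asarray(self.outcome)
        n = self.genotypes.shape[0]
        if not (self.exposure.shape == (n,) == self.outcome.shape == self.exposure_missing_mask.shape):
            raise ValueError(
                "genotypes, exposure, mask and outcome must share first-dimension "
                f"length; got n={n}, exposure {self.exposure.shape}, "
                f"mask {self.exposure_missing_mask.shape}, outcome {self.outcome.shape}"
            )
        if not np.isin(self.outcome, (0, 1)).all():
            raise ValueError("outcome entries must be exactly 0 or 1")
        self.outcome = self.outcome.astype(np.int8)
        if np.isnan(self.exposure[~self.exposure_missing_mask]).any():
            raise ValueError("NaN exposure at a position not flagged missing")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_instruments(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_complete(self) -> int:
        """n_A: individuals with observed exposure."""
        return int((~self.exposure_missing_mask).sum())

    @property
    def n_missing(self) -> int:
        """n_B: individuals with masked exposure."""
        return int(self.exposure_missing_mask.sum())


@dataclass
class ModelParameters:
    """One point in the space of model unknowns.

    ``u`` holds the per-individual latent confounder scores; ``x_missing``
    holds imputed values for the masked exposures (ordered as the True
    entries of the dataset mask), empty when there is no missingness.
    """

    alpha: np.ndarray
    beta: float
    delta_x: float
    delta_y: float
    sigma_x: float
    intercept: float
    u: np.ndarray
    x_missing: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.x_missing = np.asarray(self.x_missing, dtype=float)
        if not self.sigma_x > 0:
            raise ValueError(f"sigma_x must be positive, got {self.sigma_x}")

    @property
    def delta_product(self) -> float:
        """delta_x * delta_y — the identified confounding quantity."""
        return self.delta_x * self.delta_y


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the priors and of the causal-null mixture.

    ``pi0`` is the prior mass on the interval null |beta| <= ``rope_T``;
    the "used" prior is the continuous normal actually sampled under, to be
    corrected to the spike-free mixture by importance weighting downstream.
    ``N(m, v)`` convention: ``u_variance`` is a variance; all ``*_sd`` are
    standard deviations; sigma_x has an inverse-gamma prior on the SD scale.
    """

    pi0: float = 0.5
    rope_T: float = 0.1
    used_prior_mean: float = 0.0
    used_prior_sd: float = 10.0
    alpha_prior_mean: float = 0.5
    alpha_prior_sd: float = 0.2
    sigma_x_prior_shape: float = 3.0
    sigma_x_prior_scale: float = 2.0
    u_variance: float = 0.1
    intercept_prior_sd: float = 1.0
    delta_prior_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError(f"pi0 must lie in [0, 1], got {self.pi0}")
        for name in (
            "rope_T",
            "used_prior_sd",
            "alpha_prior_sd",
            "sigma_x_prior_shape",
            "sigma_x_prior_scale",
            "u_variance",
            "intercept_prior_sd",
            "delta_prior_sd",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


def risk_shift(baseline_prob: float, beta: float) -> float:
    """Absolute risk after adding ``beta`` on the log-odds scale.

    Translates a candidate causal-effect magnitude into the change it
    implies for an event probability, the quantity a subject-matter expert
    can judge negligible or not when eliciting the ROPE half-width T: with
    a logistic outcome model, a one-SD change in the exposure moves a
    baseline risk ``p`` to ``expit(logit(p) + beta)``.
    """
    p = float(baseline_prob)
    if not 0.0 < p < 1.0:
        raise ValueError(f"baseline_prob must lie strictly in (0, 1), got {p}")
    return float(_expit(_logit(p) + beta))


def standardize(dataset: MRDataset, ddof: int = 1) -> MRDataset:
    """Rescale genotype columns and the observed exposure to mean 0, SD 1.

    Missing exposure entries stay NaN; the outcome is untouched.  The
    mean/SD pairs used are the *observed-data* sample statistics (all a
    real analysis has) and are recorded on the returned dataset so that
    imputations and effects can be mapped back to the original scale.

    Raises
    ------
    ValueError
        If any genotype column, or the observed exposure, has zero
        variance (a monomorphic SNP carries no instrument information).
    """
    Z = dataset.genotypes
    g_means = Z.mean(axis=0)
    g_sds = Z.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(g_sds == 0)
    if zero.size:
        raise ValueError(
            f"monomorphic instrument: genotype column(s) {zero.tolist()} have zero variance"
        )
    obs = ~dataset.exposure_missing_mask
    x_obs = dataset.exposure[obs]
    if x_obs.size < 2:
        raise ValueError("need at least 2 observed exposure values to standardize")
    x_mean = float(x_obs.mean())
    x_sd = float(x_obs.std(ddof=ddof))
    if x_sd == 0:
        raise ValueError("observed exposure has zero variance")
    exposure = dataset.exposure.copy()
    exposure[obs] = (x_obs - x_mean) / x_sd
    oracle = dataset.exposure_oracle
    if oracle is not None:
        oracle = (oracle - x_mean) / x_sd
    return replace(
        dataset,
        genotypes=(Z - g_means) / g_sds,
        exposure=exposure,
        exposure_oracle=oracle,
        standardization=StandardizationInfo(g_means, g_sds, x_mean, x_sd),
    )


def _complete_exposure(dataset: MRDataset, params: ModelParameters) -> np.ndarray:
    """Exposure vector with imputed values substituted at masked positions."""
    mask = dataset.exposure_missing_mask
    if params.x_missing.shape != (dataset.n_missing,):
        raise ValueError(
            f"x_missing has length {params.x_missing.size}, dataset has "
            f"{dataset.n_missing} masked exposures"
        )
    x = dataset.exposure.copy()
    x[mask] = params.x_missing
    return x


def bernoulli_loglik(outcome: np.ndarray, eta: np.ndarray) -> float:
    """Sum of Bernoulli log-probabilities on the logit scale (numerically safe)."""
    return float(np.sum(outcome * eta - np.logaddexp(0.0, eta)))


def log_joint(dataset: MRDataset, params: ModelParameters, prior: PriorConfig) -> float:
    """Unnormalized log posterior density under the used (continuous) beta prior.

    Sums the exposure and outcome log-likelihood terms with the log prior
    densities of every unknown, including the per-individual latent
    confounders and any imputed exposures.  Finite for all finite
    parameter values with ``sigma_x > 0``.
    """
    if params.alpha.shape != (dataset.n_instruments,):
        raise ValueError(
            f"alpha has length {params.alpha.size}, dataset has {dataset.n_instruments} instruments"
        )
    if params.u.shape != (dataset.n,):
        raise ValueError(f"u has length {params.u.size}, dataset has n={dataset.n}")
    x = _complete_exposure(dataset, params)
    mean_x = dataset.genotypes @ params.alpha + params.delta_x * params.u
    ll_x = float(norm.logpdf(x, mean_x, params.sigma_x).sum())
    eta = params.intercept + params.beta * x + params.delta_y * params.u
    ll_y = bernoulli_loglik(dataset.outcome, eta)
    lp = float(
        norm.logpdf(params.alpha, prior.alpha_prior_mean, prior.alpha_prior_sd).sum()
        + norm.logpdf(params.beta, prior.used_prior_mean, prior.used_prior_sd)
        + norm.logpdf(params.delta_x, 0.0, prior.delta_prior_sd)
        + norm.logpdf(params.delta_y, 0.0, prior.delta_prior_sd)
        + norm.logpdf(params.intercept, 0.0, prior.intercept_prior_sd)
        + invgamma.logpdf(params.sigma_x, prior.sigma_x_prior_shape, scale=prior.sigma_x_prior_scale)
        + norm.logpdf(params.u, 0.0, np.sqrt(prior.u_variance)).sum()
    )
    return ll_x + ll_y + lp
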