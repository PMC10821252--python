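"""Posterior sampling under the convenience ("used") prior for beta.

The target density is the one evaluated by :func:`mrope.core_model.log_joint`:
all model parameters, the per-individual latent confounders U, and any
missing exposures are sampled jointly.  The sampler is a
Metropolis-within-Gibbs scheme exploiting the model's structure:

* ``alpha`` and ``delta_x`` have exact conjugate Gaussian full
  conditionals (the exposure equation is linear with Gaussian noise);
* ``sigma_x`` takes a random-walk Metropolis step on the log scale
  (its inverse-gamma prior sits on the SD, not the variance, so the
  conditional is not a standard family);
* the logistic-block parameters ``intercept``, ``beta``, ``delta_y`` take
  scalar adaptive random-walk Metropolis steps;
* the latent ``u_i`` are conditionally independent given the global
  parameters, so a vectorized per-individual random-walk step updates
  all of them at once;
* missing exposures are conditionally independent as well and are
  proposed from their Gaussian full-conditional prior
  ``N(alpha'Z_i + delta_x u_i, sigma_x^2)``, accepted on the Bernoulli
  term alone (an independence sampler with high acceptance).

Proposal scales adapt during warmup (Robbins–Monro toward 44%
acceptance for scalar moves) and are frozen afterwards, so the retained
draws target the exact posterior.  Any sampler producing asymptotically
correct draws from the same density is interchangeable with this one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .core_model import MRDataset, PriorConfig

__all__ = ["PosteriorDraws", "Diagnostics", "sample_used_posterior", "compute_rhat"]

_TARGET_ACCEPT = 0.44  # optimal-ish for scalar random-walk moves


@dataclass
class PosteriorDraws:
    """Retained MCMC draws (all chains concatenated, chain-major order)."""

    beta: np.ndarray
    alpha: np.ndarray
    delta_x: np.ndarray
    delta_y: np.ndarray
    sigma_x: np.ndarray
    intercept: np.ndarray
    u: np.ndarray
    x_missing: np.ndarray
    chains: int
    iterations: int
    warmup: int
    seed: int
    acceptance: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.beta.size

    @property
    def delta_product(self) -> np.ndarray:
        """Draws of delta_x * delta_y, the identified confounding quantity."""
        return self.delta_x * self.delta_y

    def beta_by_chain(self) -> np.ndarray:
        """Beta draws reshaped to (chains, draws_per_chain)."""
        return self.beta.reshape(self.chains, -1)


@dataclass(frozen=True)
class Diagnostics:
    """Convergence summary for the causal-effect chain."""

    rhat_beta: float
    effective_sample_size: float


class _ChainState:
    __slots__ = ("alpha", "beta", "delta_x", "delta_y", "sigma_x", "intercept", "u", "x_miss")


def _init_state(dataset: MRDataset, prior: PriorConfig, rng: np.random.Generator) -> _ChainState:
    # mildly overdispersed starts so that R-hat can detect non-convergence
    s = _ChainState()
    J, n = dataset.n_instruments, dataset.n
    s.alpha = rng.normal(prior.alpha_prior_mean, prior.alpha_prior_sd, size=J)
    s.beta = rng.normal(0.0, 1.0)
    s.delta_x = rng.normal(0.0, 0.5)
    s.delta_y = rng.normal(0.0, 0.5)
    s.sigma_x = float(np.clip(rng.lognormal(0.0, 0.3), 0.2, 5.0))
    s.intercept = rng.normal(0.0, 0.5)
    s.u = rng.normal(0.0, math.sqrt(prior.u_variance), size=n)
    mean_x = dataset.genotypes @ s.alpha + s.delta_x * s.u
    s.x_miss = mean_x[dataset.exposure_missing_mask] + rng.normal(
        0.0, s.sigma_x, size=dataset.n_missing
    )
    return s


def _bern_loglik_terms(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return y * eta - np.logaddexp(0.0, eta)


def _run_chain(
    dataset: MRDataset,
    prior: PriorConfig,
    iterations: int,
    warmup: int,
    thin: int,
    rng: np.random.Generator,
):
    Z = dataset.genotypes
    y = dataset.outcome.astype(float)
    mask = dataset.exposure_missing_mask
    n, J = dataset.n, dataset.n_instruments
    n_miss = dataset.n_missing

    ZtZ = Z.T @ Z
    a_prec0 = 1.0 / prior.alpha_prior_sd**2
    a_mean0 = prior.alpha_prior_mean
    dx_prec0 = 1.0 / prior.delta_prior_sd**2
    ig_shape, ig_scale = prior.sigma_x_prior_shape, prior.sigma_x_prior_scale
    u_var = prior.u_variance
    beta_mu, beta_sd = prior.used_prior_mean, prior.used_prior_sd

    st = _init_state(dataset, prior, rng)
    x = dataset.exposure.copy()
    x[mask] = st.x_miss

    # adaptive log proposal scales
    steps = {"sigma_x": -1.0, "intercept": -1.0, "beta": -1.0, "delta_y": -1.0, "u": -1.0}
    acc_counts = {k: 0 for k in steps}
    n_kept = (iterations - warmup) // thin
    out = {
        "beta": np.empty(n_kept),
        "alpha": np.empty((n_kept, J)),
        "delta_x": np.empty(n_kept),
        "delta_y": np.empty(n_kept),
        "sigma_x": np.empty(n_kept),
        "intercept": np.empty(n_kept),
        "u": np.empty((n_kept, n)),
        "x_missing": np.empty((n_kept, n_miss)),
    }
    kept = 0

    def logistic_ll(intercept: float, beta: float, delta_y: float) -> float:
        eta = intercept + beta * x + delta_y * st.u
        return float(np.sum(_bern_loglik_terms(y, eta)))

    for it in range(iterations):
        adapting = it < warmup
        sig2 = st.sigma_x**2

        # --- alpha: conjugate multivariate normal
        r = x - st.delta_x * st.u
        prec = ZtZ / sig2 + a_prec0 * np.eye(J)
        b = Z.T @ r / sig2 + a_prec0 * a_mean0
        cf = cho_factor(prec, lower=True)
        mean = cho_solve(cf, b)
        st.alpha = mean + solve_triangular(cf[0].T, rng.standard_normal(J), lower=False)
        Za = Z @ st.alpha

        # --- delta_x: conjugate scalar normal
        r2 = x - Za
        prec_dx = float(st.u @ st.u) / sig2 + dx_prec0
        mean_dx = float(st.u @ r2) / sig2 / prec_dx
        st.delta_x = mean_dx + rng.standard_normal() / math.sqrt(prec_dx)

        # --- sigma_x: log-scale random walk (prior is InvGamma on the SD)
        resid = x - Za - st.delta_x * st.u
        ssr = float(resid @ resid)

        def sigma_logpost(s: float) -> float:
            return (
                -n * math.log(s)
                - ssr / (2.0 * s * s)
                - (ig_shape + 1.0) * math.log(s)
                - ig_scale / s
            )

        prop = st.sigma_x * math.exp(math.exp(steps["sigma_x"]) * rng.standard_normal())
        lr = sigma_logpost(prop) - sigma_logpost(st.sigma_x) + math.log(prop / st.sigma_x)
        acc = math.log(rng.uniform()) < lr
        if acc:
            st.sigma_x = prop
        _adapt(steps, acc_counts, "sigma_x", float(acc), it, adapting)
        sig2 = st.sigma_x**2

        # --- logistic block: intercept, beta, delta_y (scalar RW-MH each)
        ll_cur = logistic_ll(st.intercept, st.beta, st.delta_y)
        for name, prior_prec, prior_mu in (
            ("intercept", 1.0 / prior.intercept_prior_sd**2, 0.0),
            ("beta", 1.0 / beta_sd**2, beta_mu),
            ("delta_y", dx_prec0, 0.0),
        ):
            cur = getattr(st, name)
            prop = cur + math.exp(steps[name]) * rng.standard_normal()
            trial = {
                "intercept": st.intercept,
                "beta": st.beta,
                "delta_y": st.delta_y,
            }
            trial[name] = prop
            ll_prop = logistic_ll(**trial)
            lr = (
                ll_prop
                - ll_cur
                - 0.5 * prior_prec * ((prop - prior_mu) ** 2 - (cur - prior_mu) ** 2)
            )
            acc = math.log(rng.uniform()) < lr
            if acc:
                setattr(st, name, prop)
                ll_cur = ll_prop
            _adapt(steps, acc_counts, name, float(acc), it, adapting)

        # --- latent u: vectorized per-individual random walk
        if n:
            step_u = math.exp(steps["u"])
            u_prop = st.u + step_u * rng.standard_normal(n)
            mu_x_cur = Za + st.delta_x * st.u
            mu_x_prop = Za + st.delta_x * u_prop
            eta_cur = st.intercept + st.beta * x + st.delta_y * st.u
            eta_prop = st.intercept + st.beta * x + st.delta_y * u_prop
            lr_vec = (
                ((x - mu_x_cur) ** 2 - (x - mu_x_prop) ** 2) / (2.0 * sig2)
                + _bern_loglik_terms(y, eta_prop)
                - _bern_loglik_terms(y, eta_cur)
                + (st.u**2 - u_prop**2) / (2.0 * u_var)
            )
            acc_vec = np.log(rng.uniform(size=n)) < lr_vec
            st.u = np.where(acc_vec, u_prop, st.u)
            _adapt(steps, acc_counts, "u", float(acc_vec.mean()), it, adapting)

        # --- missing exposures: independence proposal from the Gaussian part
        if n_miss:
            mu_m = (Za + st.delta_x * st.u)[mask]
            x_prop = mu_m + st.sigma_x * rng.standard_normal(n_miss)
            u_m = st.u[mask]
            y_m = y[mask]
            eta_cur = st.intercept + st.beta * st.x_miss + st.delta_y * u_m
            eta_prop = st.intercept + st.beta * x_prop + st.delta_y * u_m
            lr_vec = _bern_loglik_terms(y_m, eta_prop) - _bern_loglik_terms(y_m, eta_cur)
            acc_vec = np.log(rng.uniform(size=n_miss)) < lr_vec
            st.x_miss = np.where(acc_vec, x_prop, st.x_miss)
            x[mask] = st.x_miss

        if not adapting and (it - warmup) % thin == 0 and kept < n_kept:
            out["beta"][kept] = st.beta
            out["alpha"][kept] = st.alpha
            out["delta_x"][kept] = st.delta_x
            out["delta_y"][kept] = st.delta_y
            out["sigma_x"][kept] = st.sigma_x
            out["intercept"][kept] = st.intercept
            out["u"][kept] = st.u
            out["x_missing"][kept] = st.x_miss
            kept += 1

    rates = {k: acc_counts[k] / max(iterations, 1) for k in acc_counts}
    return out, rates


def _adapt(steps, counts, name, acc, it, adapting):
    counts[name] += acc
    if adapting:
        steps[name] += (acc - _TARGET_ACCEPT) / math.sqrt(it + 1.0)


def sample_used_posterior(
    dataset: MRDataset,
    prior: Optional[PriorConfig] = None,
    iterations: int = 2000,
    warmup: Optional[int] = None,
    chains: int = 4,
    seed: int = 0,
    thin: int = 1,
) -> PosteriorDraws:
    """Draw from the posterior with beta under its continuous used prior.

    Missing exposures are imputed as part of the sampling (imputation and
    effect estimation happen simultaneously).  Draws are deterministic
    given ``seed``.

    Parameters
    ----------
    dataset
        Data on the model's standardized scale.
    prior
        Hyperparameters; defaults to :class:`PriorConfig` defaults.
    iterations, warmup
        Per-chain iteration count and warmup length (default: half).
    chains
        Number of independent chains (>= 2 recommended for diagnostics).
    seed
        Root seed; per-chain streams are spawned from it.
    thin
        Keep every ``thin``-th post-warmup draw.
    """
    if prior is None:
        prior = PriorConfig()
    if warmup is None:
        warmup = iterations // 2
    if warmup >= iterations:
        raise ValueError(f"warmup ({warmup}) must be smaller than iterations ({iterations})")
    if chains < 1:
        raise ValueError("need at least one chain")

    chain_seeds = np.random.SeedSequence(seed).spawn(chains)
    pieces = []
    rates_all: dict[str, float] = {}
    for cs in chain_seeds:
        out, rates = _run_chain(
            dataset, prior, iterations, warmup, thin, np.random.default_rng(cs)
        )
        pieces.append(out)
        for k, v in rates.items():
            rates_all[k] = rates_all.get(k, 0.0) + v / chains

    cat = {k: np.concatenate([p[k] for p in pieces]) for k in pieces[0]}
    return PosteriorDraws(
        beta=cat["beta"],
        alpha=cat["alpha"],
        delta_x=cat["delta_x"],
        delta_y=cat["delta_y"],
        sigma_x=cat["sigma_x"],
        intercept=cat["intercept"],
        u=cat["u"],
        x_missing=cat["x_missing"],
        chains=chains,
        iterations=iterations,
        warmup=warmup,
        seed=seed,
        acceptance=rates_all,
    )


def _split_chains(chains: np.ndarray) -> np.ndarray:
    c, m = chains.shape
    half = m // 2
    return np.vstack([chains[:, :half], chains[:, half : 2 * half]])


def compute_rhat(chains: np.ndarray | PosteriorDraws) -> Diagnostics:
    """Split-R̂ and effective sample size for the causal-effect draws.

    Accepts a ``(chains, draws)`` array or a :class:`PosteriorDraws`
    (whose beta draws are used).  Each chain is split in half; R̂ is the
    usual sqrt of (pooled variance estimate / mean within-chain variance).
    ESS uses Geyer's initial-monotone-positive-sequence truncation of the
    chain autocorrelations.  Values near 1 (R̂) and large (ESS) indicate
    good mixing; constant chains give NaN (flagged, not an error).
    """
    if isinstance(chains, PosteriorDraws):
        chains = chains.beta_by_chain()
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if chains.shape[0] < 2:
        raise ValueError(
            "need draws from >= 2 chains for split-R̂; run more chains or split manually"
        )
    if chains.shape[1] < 4:
        raise ValueError("chains too short for split-R̂")
    split = _split_chains(chains)
    c, m = split.shape
    w = split.var(axis=1, ddof=1).mean()
    if w == 0.0:
        return Diagnostics(rhat_beta=float("nan"), effective_sample_size=float("nan"))
    b = m * split.mean(axis=1).var(ddof=1)
    var_plus = (m - 1) / m * w + b / m
    rhat = math.sqrt(var_plus / w)

    # ESS: mean autocorrelation over split chains, Geyer truncation
    acov = np.zeros(m)
    for row in split:
        d = row - row.mean()
        fft = np.fft.rfft(d, n=2 * m)
        ac = np.fft.irfft(fft * np.conj(fft))[:m] / m
        acov += ac / c
    rho = 1.0 - (w - acov) / var_plus
    # sum consecutive pairs while positive and non-increasing
    tau = 1.0
    prev = float("inf")
    t = 1
    while t + 1 < m:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        tau += 2.0 * pair
        prev = pair
        t += 2
    ess = c * m / tau
    return Diagnostics(rhat_beta=float(rhat), effective_sample_size=float(ess))
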