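"""Mixture-prior importance resampling, ROPE posterior odds, and the CDDR.

Sampling is carried out under a convenience continuous prior for the
causal effect, ``p_used(beta) = N(used_prior_mean, used_prior_sd^2)``.
The intended ("true") prior is the two-component mixture

    p_true(beta) = (1 - pi0) * N(beta | m, s^2) + pi0 * Unif(beta | -T, T)

whose null component puts mass ``pi0`` uniformly on the region of
practical equivalence [-T, T].  Reweighting each draw by

    w(beta) = p_true(beta) / p_used(beta)

turns used-posterior draws into (weighted) true-posterior draws; a
weighted resampling with replacement yields plain draws from the true
posterior.  The posterior odds V0/V1 of beta lying inside versus outside
the ROPE then drive the ternary causal discovery decision rule (CDDR):
odds above 10 accept the no-effect hypothesis, odds below 0.1 claim a
discovery, anything in between is declared uncertain.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.stats import norm

from .core_model import PriorConfig
from .fit import PosteriorDraws

__all__ = [
    "WeightedDraws",
    "OddsResult",
    "Decision",
    "importance_weight",
    "resample",
    "posterior_odds",
    "cddr",
]


class Decision(enum.Enum):
    """Ternary outcome of the causal discovery decision rule."""

    ACCEPT_NULL = "accept_null"
    DISCOVERY = "discovery"
    UNCERTAIN = "uncertain"


@dataclass
class WeightedDraws:
    """Used-posterior draws with importance weights and a resampled set.

    ``weights[k]`` is w(beta[k]); outside the ROPE every weight equals
    ``1 - pi0`` exactly.  ``resampled_beta`` are causal-effect values drawn
    with replacement with probability proportional to the weights — a
    sample from the true (mixture-prior) posterior.  ``resampled_indices``
    index the original draws so that the remaining unknowns can be carried
    along for true-posterior inference on them too.
    """

    draws: PosteriorDraws
    weights: np.ndarray
    resampled_beta: np.ndarray
    resampled_indices: np.ndarray


@dataclass(frozen=True)
class OddsResult:
    """Posterior mass inside (V0) / outside (V1) the ROPE and their ratio."""

    V0: float
    V1: float
    odds: float
    n_resampled: int


def importance_weight(
    beta_value: Union[float, np.ndarray], prior: PriorConfig
) -> Union[float, np.ndarray]:
    """Importance weight w(beta) = p_true(beta) / p_used(beta).

    Evaluates ``((1 - pi0) * N(beta | m, s^2) + pi0 * Unif(beta | -T, T))
    / N(beta | m, s^2)`` with the uniform density equal to 1/(2T) inside
    [-T, T] and 0 outside.  Hence the weight is exactly ``1 - pi0``
    outside the ROPE and exceeds it inside; with pi0 = 0.5 the outside
    weight is 0.5.  Vectorized over ``beta_value``.
    """
    beta = np.asarray(beta_value, dtype=float)
    dens = norm.pdf(beta, prior.used_prior_mean, prior.used_prior_sd)
    inside = np.abs(beta) <= prior.rope_T
    w = (1.0 - prior.pi0) + prior.pi0 * inside / (2.0 * prior.rope_T * dens)
    if np.isscalar(beta_value) or np.ndim(beta_value) == 0:
        return float(w)
    return w


def resample(
    draws: PosteriorDraws,
    prior: PriorConfig,
    n_out: Optional[int] = None,
    seed: int = 0,
) -> WeightedDraws:
    """Weighted resampling of used-posterior draws into true-posterior draws.

    Each of the K input draws receives weight w(beta[k]); ``n_out``
    (default K) indices are then drawn with replacement with probability
    proportional to the weights.  Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If all weights vanish, which can only happen when pi0 = 1 and no
        draw fell inside the ROPE (the true prior then has no overlap
        with the sampled values).
    """
    if draws.K < 1:
        raise ValueError("need at least one posterior draw")
    if n_out is None:
        n_out = draws.K
    weights = np.asarray(importance_weight(draws.beta, prior), dtype=float)
    total = weights.sum()
    if total <= 0.0:
        raise ValueError(
            "all importance weights are zero: pi0 = 1 with no draw inside the "
            "ROPE leaves the true posterior unrepresented; lower pi0 or run longer"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(draws.K, size=n_out, replace=True, p=weights / total)
    return WeightedDraws(
        draws=draws,
        weights=weights,
        resampled_beta=draws.beta[idx],
        resampled_indices=idx,
    )


def posterior_odds(
    weighted: WeightedDraws, prior: PriorConfig, method: str = "weights"
) -> OddsResult:
    """Simulation-consistent posterior odds of beta lying in the ROPE.

    ``method="weights"`` (default) estimates V0 as the normalized
    importance-weight mass inside [-T, T] — same expectation as counting
    resampled draws but without resampling noise.  ``method="resample"``
    counts the resampled draws instead, reproducing the literal
    proportion-of-samples estimate.  ``odds = V0 / V1`` is +inf when no
    mass falls outside the ROPE and 0 when none falls inside.
    """
    T = prior.rope_T
    if method == "weights":
        inside = np.abs(weighted.draws.beta) <= T
        mass = weighted.weights.sum()
        v0 = float(weighted.weights[inside].sum() / mass)
    elif method == "resample":
        if weighted.resampled_beta.size < 1:
            raise ValueError("no resampled draws")
        v0 = float(np.mean(np.abs(weighted.resampled_beta) <= T))
    else:
        raise ValueError(f"unknown method {method!r}; use 'weights' or 'resample'")
    v1 = 1.0 - v0
    odds = math.inf if v1 == 0.0 else v0 / v1
    return OddsResult(V0=v0, V1=v1, odds=odds, n_resampled=int(weighted.resampled_beta.size))


def cddr(
    odds: Union[OddsResult, float], upper: float = 10.0, lower: float = 0.1
) -> Decision:
    """Ternary causal discovery decision rule on the ROPE posterior odds.

    Odds above ``upper`` accept the no-effect hypothesis with confidence;
    odds below ``lower`` claim a causal discovery; the closed interval
    [lower, upper] — boundaries included — yields an uncertain outcome.
    """
    if not lower < upper:
        raise ValueError(f"lower ({lower}) must be below upper ({upper})")
    value = odds.odds if isinstance(odds, OddsResult) else float(odds)
    if value > upper:
        return Decision.ACCEPT_NULL
    if value < lower:
        return Decision.DISCOVERY
    return Decision.UNCERTAIN
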