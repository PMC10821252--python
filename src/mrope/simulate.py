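"""Synthetic data generation for the MR simulation experiment.

A full factorial experiment crosses three exposure missingness rates
(80%, 40%, 0%), three instrument strengths (all alpha_k equal to 0.3, 0.1
or 0.05) and two causal-effect magnitudes (beta = 0.3 or 0), giving 18
scenarios.  Each simulated dataset starts from a pool of 1000 individuals
with independent Hardy–Weinberg SNP genotypes, from which an analysis
sample of 400 is drawn and split into a complete-data part A and a part B
whose exposures are masked.

Genotype realism is limited to independent biallelic SNPs with per-SNP
minor-allele frequency drawn from Uniform(0.1, 0.5); linkage
disequilibrium, sample overlap between A and B and pleiotropic
instruments are deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import invgamma

from .core_model import MRDataset

__all__ = [
    "ScenarioConfig",
    "ScenarioGrid",
    "MISSING_RATES",
    "ALPHA_STRENGTHS",
    "BETA_VALUES",
    "simulate_pool",
    "split_and_mask",
    "build_grid",
]

# factorial levels of the experiment design
MISSING_RATES: tuple[float, ...] = (0.8, 0.4, 0.0)
ALPHA_STRENGTHS: tuple[float, ...] = (0.3, 0.1, 0.05)
BETA_VALUES: tuple[float, ...] = (0.3, 0.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation design.

    ``alpha_strength`` is applied to every one of the ``J`` instruments.
    ``sigma_x_true`` is the exposure residual SD used in generation, fixed
    at 1 by default (the mean of its Inv-Gamma(3, 2) prior, and the
    natural companion to the fixed unit confounding coefficients); set it
    to None to draw it per dataset from that prior instead.  ``maf_range``
    bounds the per-SNP minor-allele frequency, drawn once per dataset.
    """

    missing_rate: float = 0.0
    alpha_strength: float = 0.3
    beta_true: float = 0.0
    n_pool: int = 1000
    n_analysis: int = 400
    J: int = 15
    delta_x: float = 1.0
    delta_y: float = 1.0
    intercept: float = 0.0
    replicates: int = 200
    seed: int = 0
    sigma_x_true: Optional[float] = 1.0
    maf_range: tuple[float, float] = (0.1, 0.5)

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        if self.n_analysis > self.n_pool:
            raise ValueError(
                f"n_analysis ({self.n_analysis}) exceeds pool size ({self.n_pool})"
            )
        if self.J < 1:
            raise ValueError("need at least one instrument")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class ScenarioGrid:
    """Ordered full-factorial collection of scenarios."""

    scenarios: tuple[ScenarioConfig, ...]

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self):
        return iter(self.scenarios)

    def n_datasets(self, replicates: Optional[int] = None) -> int:
        """Total dataset count across the grid."""
        if replicates is not None:
            return len(self.scenarios) * replicates
        return sum(s.replicates for s in self.scenarios)


def simulate_pool(config: ScenarioConfig, rng_seed: int) -> MRDataset:
    """Generate the fully observed pool H of ``config.n_pool`` individuals.

    Genotypes are Binomial(2, MAF) counts per SNP, standardized at pool
    level; U, X and Y then follow the generative model with all
    instrument strengths equal to ``alpha_strength``.  Deterministic given
    ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    n, J = config.n_pool, config.J
    maf = rng.uniform(*config.maf_range, size=J)
    counts = rng.binomial(2, maf, size=(n, J)).astype(float)
    sds = counts.std(axis=0, ddof=1)
    if (sds == 0).any():
        raise RuntimeError("monomorphic SNP in simulated pool; increase n_pool or MAF")
    Z = (counts - counts.mean(axis=0)) / sds

    sigma_x = (
        config.sigma_x_true
        if config.sigma_x_true is not None
        else float(invgamma.rvs(3.0, scale=2.0, random_state=rng))
    )
    alpha = np.full(J, config.alpha_strength)
    u = rng.normal(0.0, math.sqrt(0.1), size=n)
    x = Z @ alpha + config.delta_x * u + rng.normal(0.0, sigma_x, size=n)
    p = expit(config.intercept + config.beta_true * x + config.delta_y * u)
    y = rng.binomial(1, p)
    return MRDataset(
        genotypes=Z,
        exposure=x,
        exposure_missing_mask=np.zeros(n, dtype=bool),
        outcome=y,
    )


def _round_half_away(value: float) -> int:
    """round-half-away-from-zero; only the positive branch is ever used here."""
    return int(math.floor(value + 0.5)) if value >= 0 else int(math.ceil(value - 0.5))


def split_and_mask(pool: MRDataset, config: ScenarioConfig, rng_seed: int) -> MRDataset:
    """Draw the analysis sample D1 = A ∪ B and mask the exposures of B.

    A (size ``n_A = round(n_analysis * (1 - missing_rate))``) keeps complete
    records; B (size ``n_B = n_analysis - n_A``) has its exposure values set
    to missing.  Sampling is without replacement, so no individual appears
    twice.  The pre-masking exposures are retained in the hidden
    ``exposure_oracle`` field for simulation bookkeeping.
    """
    if config.n_analysis > pool.n:
        raise ValueError(f"n_analysis ({config.n_analysis}) exceeds pool size ({pool.n})")
    rng = np.random.default_rng(rng_seed)
    n_a = _round_half_away(config.n_analysis * (1.0 - config.missing_rate))
    n_b = config.n_analysis - n_a
    idx = rng.choice(pool.n, size=config.n_analysis, replace=False)
    mask = np.zeros(config.n_analysis, dtype=bool)
    mask[n_a:] = True  # the last n_b selected form dataset B
    exposure = pool.exposure[idx].copy()
    oracle = exposure.copy()
    exposure[mask] = np.nan
    assert int(mask.sum()) == n_b
    return MRDataset(
        genotypes=pool.genotypes[idx],
        exposure=exposure,
        exposure_missing_mask=mask,
        outcome=pool.outcome[idx],
        exposure_oracle=oracle,
    )


def build_grid(
    defaults: Optional[ScenarioConfig] = None,
    missing_rates: Sequence[float] = MISSING_RATES,
    alpha_strengths: Sequence[float] = ALPHA_STRENGTHS,
    beta_values: Sequence[float] = BETA_VALUES,
) -> ScenarioGrid:
    """Enumerate the factorial scenario grid (18 cells at the defaults)."""
    if defaults is None:
        defaults = ScenarioConfig()
    cells = tuple(
        replace(defaults, missing_rate=m, alpha_strength=a, beta_true=b)
        for m in missing_rates
        for a in alpha_strengths
        for b in beta_values
    )
    return ScenarioGrid(cells)
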