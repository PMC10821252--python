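import numpy as np
import pytest

from mrope import (
    MRDataset,
    PosteriorDraws,
    PriorConfig,
    ScenarioConfig,
    simulate_pool,
    split_and_mask,
)


def draws_from_beta(beta: np.ndarray, chains: int = 1) -> PosteriorDraws:
    """Wrap a bare beta sample in a PosteriorDraws container (tests only)."""
    beta = np.asarray(beta, dtype=float)
    K = beta.size
    return PosteriorDraws(
        beta=beta,
        alpha=np.zeros((K, 0)),
        delta_x=np.zeros(K),
        delta_y=np.zeros(K),
        sigma_x=np.ones(K),
        intercept=np.zeros(K),
        u=np.zeros((K, 0)),
        x_missing=np.zeros((K, 0)),
        chains=chains,
        iterations=K,
        warmup=0,
        seed=0,
    )


@pytest.fixture
def tiny_dataset() -> MRDataset:
    """5 individuals, 2 instruments, one masked exposure; hand-listed values."""
    return MRDataset(
        genotypes=np.array(
            [[0.5, -1.2], [1.1, 0.3], [-0.7, 0.9], [0.0, -0.4], [-0.9, 0.4]]
        ),
        exposure=np.array([0.8, -0.5, 1.2, np.nan, -1.5]),
        exposure_missing_mask=np.array([False, False, False, True, False]),
        outcome=np.array([1, 0, 1, 1, 0]),
    )


@pytest.fixture
def default_prior() -> PriorConfig:
    return PriorConfig()


@pytest.fixture(scope="session")
def strong_dataset() -> MRDataset:
    """Simulated strong-instrument dataset: beta=0.3, alpha=0.3, n=400, complete."""
    cfg = ScenarioConfig(missing_rate=0.0, alpha_strength=0.3, beta_true=0.3)
    pool = simulate_pool(cfg, rng_seed=11)
    return split_and_mask(pool, cfg, rng_seed=12)
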