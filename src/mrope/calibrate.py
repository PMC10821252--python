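"""Loss-based calibration and the Bayesian-vs-frequentist experiment.

A ternary decision (accept no-effect / claim discovery / uncertain) is
scored against the truth with a six-entry loss table: a correct confident
decision costs 0, a wrong confident decision costs 1, and an uncertain
outcome costs ``a`` (0 <= a <= 1) regardless of the truth.  The expected
loss of a procedure under a given truth is estimated by simulation.

The frequentist comparator is two-sample inverse-variance weighted (IVW)
estimation: per-instrument exposure associations come from the
complete-data part A, per-instrument outcome associations from part B
(whose Y values are all it contributes — the Y values of A are discarded
to respect the two-sample mechanism), and the per-instrument ratio
estimates are pooled with fixed-effect first-order weights.  Its decision
rule is binary: accept the null iff the 95% confidence interval covers 0.

``run_experiment`` ties everything together across a scenario grid,
drawing the ROPE half-width T ~ Unif(0.01, 0.1) and the uncertainty cost
a ~ Unif(0, 0.6) afresh for each simulated dataset so that loss surfaces
over (T, a) can be mapped out.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_model import MRDataset, PriorConfig, standardize
from .fit import sample_used_posterior
from .rope_decision import Decision, cddr, posterior_odds, resample
from .simulate import ScenarioConfig, ScenarioGrid, simulate_pool, split_and_mask

__all__ = [
    "LossSpec",
    "DecisionRecord",
    "IVWResult",
    "ExperimentResult",
    "loss",
    "expected_loss",
    "ivw_fit",
    "ivw_decide",
    "split_for_ivw",
    "run_experiment",
]

logger = logging.getLogger(__name__)

TRUTH_NULL = "null"
TRUTH_ALTERNATIVE = "alternative"


@dataclass(frozen=True)
class LossSpec:
    """Cost of an uncertain outcome (a) and the nonzero truth value beta_star."""

    a: float
    beta_star: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"a must lie in [0, 1], got {self.a}")


@dataclass(frozen=True)
class DecisionRecord:
    """One method's decision on one simulated dataset, with its loss."""

    scenario_id: int
    replicate: int
    method: str  # "bayes" or "ivw"
    decision: Decision
    truth: str  # TRUTH_NULL or TRUTH_ALTERNATIVE
    loss: float
    T_used: float
    a_used: float
    seed: int
    missing_rate: float = math.nan
    alpha_strength: float = math.nan
    beta_true: float = math.nan
    odds: float = math.nan
    estimate: float = math.nan


@dataclass(frozen=True)
class IVWResult:
    """Fixed-effect IVW pooled causal estimate with per-instrument parts."""

    estimate: float
    std_error: float
    ci_lower: float
    ci_upper: float
    gamma_hat: np.ndarray  # instrument–exposure associations (dataset A)
    gamma_se: np.ndarray
    Gamma_hat: np.ndarray  # instrument–outcome log-odds associations (dataset B)
    Gamma_se: np.ndarray


def loss(decision: Decision, truth: str, spec: LossSpec) -> float:
    """Six-entry loss table lookup.

    Correct confident decision -> 0; wrong confident decision -> 1;
    uncertain outcome -> ``spec.a`` whatever the truth.
    """
    if truth not in (TRUTH_NULL, TRUTH_ALTERNATIVE):
        raise ValueError(f"truth must be '{TRUTH_NULL}' or '{TRUTH_ALTERNATIVE}'")
    if decision is Decision.UNCERTAIN:
        return spec.a
    correct = (decision is Decision.ACCEPT_NULL) == (truth == TRUTH_NULL)
    return 0.0 if correct else 1.0


def expected_loss(
    records: Sequence[DecisionRecord], spec: Optional[LossSpec] = None
) -> float:
    """Empirical mean loss over records sharing one truth condition.

    Equivalent to the four-term formula (uncertain and wrong-confident
    probabilities weighted by a and 1) with the probabilities replaced by
    empirical frequencies; records from a binary (frequentist) rule can
    only contribute the two confident-error terms.  When ``spec`` is
    given, losses are recomputed with its ``a``; otherwise the recorded
    per-record losses (each at its own a) are averaged.
    """
    records = list(records)
    if not records:
        raise ValueError("expected_loss of an empty record list is undefined")
    truths = {r.truth for r in records}
    if len(truths) > 1:
        raise ValueError(
            f"records mix truth conditions {sorted(truths)}; split them first"
        )
    if spec is None:
        return float(np.mean([r.loss for r in records]))
    return float(np.mean([loss(r.decision, r.truth, spec) for r in records]))


def _assoc_exposure(dataset: MRDataset) -> Tuple[np.ndarray, np.ndarray]:
    obs = ~dataset.exposure_missing_mask
    x = dataset.exposure[obs]
    est = np.empty(dataset.n_instruments)
    se = np.empty(dataset.n_instruments)
    for j in range(dataset.n_instruments):
        zj = dataset.genotypes[obs, j]
        res = sm.OLS(x, sm.add_constant(zj)).fit()
        est[j], se[j] = res.params[1], res.bse[1]
    return est, se


def _assoc_outcome(dataset: MRDataset) -> Tuple[np.ndarray, np.ndarray]:
    y = dataset.outcome
    est = np.empty(dataset.n_instruments)
    se = np.empty(dataset.n_instruments)
    for j in range(dataset.n_instruments):
        zj = dataset.genotypes[:, j]
        res = sm.Logit(y, sm.add_constant(zj)).fit(disp=0)
        est[j], se[j] = res.params[1], res.bse[1]
    return est, se


def ivw_fit(dataset_a: MRDataset, dataset_b: MRDataset) -> IVWResult:
    """Two-sample fixed-effect IVW estimate of the causal effect.

    Per instrument j: gamma_j from a linear regression of X on Z_j in
    dataset A, Gamma_j from a logistic regression of Y on Z_j in dataset
    B.  The ratio estimates Gamma_j / gamma_j are pooled with first-order
    weights w_j = gamma_j^2 / se(Gamma_j)^2, i.e.

        estimate = sum_j gamma_j Gamma_j / se_j^2  /  sum_j gamma_j^2 / se_j^2

    which is free of ratio blow-ups when some gamma_j ~ 0 (such
    instruments simply get ~0 weight).  SE = (sum_j w_j)^(-1/2); the 95%
    CI is estimate ± 1.96 SE under the normal approximation.
    """
    if dataset_a.n_instruments != dataset_b.n_instruments:
        raise ValueError("datasets A and B disagree on the number of instruments")
    gamma, gamma_se = _assoc_exposure(dataset_a)
    Gamma, Gamma_se = _assoc_outcome(dataset_b)
    inv_var = 1.0 / Gamma_se**2
    denom = float(np.sum(gamma**2 * inv_var))
    if denom <= 0.0:
        raise ValueError("all instruments have zero exposure association; IVW undefined")
    estimate = float(np.sum(gamma * Gamma * inv_var)) / denom
    se = 1.0 / math.sqrt(denom)
    return IVWResult(
        estimate=estimate,
        std_error=se,
        ci_lower=estimate - 1.96 * se,
        ci_upper=estimate + 1.96 * se,
        gamma_hat=gamma,
        gamma_se=gamma_se,
        Gamma_hat=Gamma,
        Gamma_se=Gamma_se,
    )


def ivw_decide(result: IVWResult) -> Decision:
    """Binary rule: accept the null iff the 95% CI contains 0 (closed interval)."""
    if result.ci_lower <= 0.0 <= result.ci_upper:
        return Decision.ACCEPT_NULL
    return Decision.DISCOVERY


def _subset(dataset: MRDataset, idx: np.ndarray) -> MRDataset:
    return MRDataset(
        genotypes=dataset.genotypes[idx],
        exposure=dataset.exposure[idx],
        exposure_missing_mask=dataset.exposure_missing_mask[idx],
        outcome=dataset.outcome[idx],
    )


def split_for_ivw(dataset: MRDataset, rng_seed: int = 0) -> Tuple[MRDataset, MRDataset]:
    """Carve the two-sample (A: Z–X, B: Z–Y) structure out of one dataset.

    With masked exposures present, A is the complete-data part and B the
    masked part.  With no missingness there is no natural B, so the
    sample is split at random into two equal halves — one supplying the
    exposure associations, the other the outcome associations.
    """
    mask = dataset.exposure_missing_mask
    if mask.any():
        return _subset(dataset, np.flatnonzero(~mask)), _subset(dataset, np.flatnonzero(mask))
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(dataset.n)
    half = dataset.n // 2
    return _subset(dataset, perm[:half]), _subset(dataset, perm[half:])


@dataclass
class ExperimentResult:
    """All decision records of an experiment plus failure bookkeeping."""

    records: List[DecisionRecord] = field(default_factory=list)
    failures: List[Tuple[int, int, str]] = field(default_factory=list)  # scenario, rep, msg

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "scenario_id": r.scenario_id,
                "replicate": r.replicate,
                "method": r.method,
                "decision": r.decision.value,
                "truth": r.truth,
                "loss": r.loss,
                "T_used": r.T_used,
                "a_used": r.a_used,
                "seed": r.seed,
                "missing_rate": r.missing_rate,
                "alpha_strength": r.alpha_strength,
                "beta_true": r.beta_true,
                "odds": r.odds,
                "estimate": r.estimate,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def summarize(self) -> pd.DataFrame:
        """Per-scenario, per-method mean loss and decision frequencies."""
        df = self.to_dataframe()
        if df.empty:
            return df
        out = (
            df.groupby(["scenario_id", "missing_rate", "alpha_strength", "beta_true", "method"])
            .agg(
                mean_loss=("loss", "mean"),
                discovery_rate=("decision", lambda d: float((d == "discovery").mean())),
                accept_null_rate=("decision", lambda d: float((d == "accept_null").mean())),
                uncertain_rate=("decision", lambda d: float((d == "uncertain").mean())),
                n=("loss", "size"),
            )
            .reset_index()
        )
        return out

    def loss_surface(
        self, scenario_id: int, method: str = "bayes", bins: int = 3
    ) -> pd.DataFrame:
        """Mean loss binned over the (T, a) plane for one scenario."""
        df = self.to_dataframe()
        df = df[(df.scenario_id == scenario_id) & (df.method == method)].copy()
        if df.empty:
            return df
        df["T_bin"] = pd.cut(df.T_used, bins)
        df["a_bin"] = pd.cut(df.a_used, bins)
        return (
            df.groupby(["T_bin", "a_bin"], observed=True)["loss"].mean().reset_index()
        )

    def plot_loss_surface(self, scenario_id: int, bins: int = 3, ax=None):
        """Scatter the per-replicate losses of both methods over (T, a).

        Requires matplotlib (optional dependency).
        """
        import matplotlib.pyplot as plt

        df = self.to_dataframe()
        df = df[df.scenario_id == scenario_id]
        if ax is None:
            _, ax = plt.subplots()
        for method, marker in (("bayes", "o"), ("ivw", "^")):
            sub = df[df.method == method]
            ax.scatter(sub.T_used, sub.a_used, c=sub.loss, vmin=0, vmax=1,
                       marker=marker, label=method, cmap="viridis")
        ax.set_xlabel("ROPE half-width T")
        ax.set_ylabel("uncertainty cost a")
        ax.legend()
        return ax


def run_experiment(
    grid: ScenarioGrid,
    replicates: int = 20,
    T_dist: Tuple[float, float] = (1e-2, 1e-1),
    a_dist: Tuple[float, float] = (0.0, 0.6),
    seed: int = 0,
    iterations: int = 1200,
    warmup: Optional[int] = None,
    chains: int = 2,
    pi0: float = 0.5,
    methods: Iterable[str] = ("bayes", "ivw"),
) -> ExperimentResult:
    """Run the full simulation comparison over a scenario grid.

    For every scenario x replicate: simulate a pool, draw the analysis
    sample with masking, draw (T, a) afresh, run the Bayesian pipeline
    (fit -> importance reweighting -> posterior odds -> CDDR) and the IVW
    pipeline on the appropriate splits, and record each method's decision
    and loss.  Replicate failures are logged and collected in
    ``result.failures``, never silently skipped.  Deterministic given
    ``seed`` (per-replicate substreams are spawned from it).

    Defaults are desk-scale (20 replicates, short chains); pass
    ``replicates=200`` and longer chains for a full-size run.
    """
    methods = tuple(methods)
    result = ExperimentResult()
    root = np.random.SeedSequence(seed)
    scen_seeds = root.spawn(len(grid))
    for sid, (scenario, scen_ss) in enumerate(zip(grid, scen_seeds)):
        rep_seeds = scen_ss.spawn(replicates)
        for rep, rep_ss in enumerate(rep_seeds):
            subs = rep_ss.spawn(5)
            sub_ints = [int(s.generate_state(1)[0] % (2**31)) for s in subs]
            try:
                records = _run_one(
                    scenario, sid, rep, sub_ints, T_dist, a_dist,
                    iterations, warmup, chains, pi0, methods,
                )
                result.records.extend(records)
            except Exception as exc:  # noqa: BLE001 - collected, not swallowed
                logger.error("scenario %d replicate %d failed: %s", sid, rep, exc)
                result.failures.append((sid, rep, str(exc)))
    return result


def _run_one(
    scenario: ScenarioConfig,
    sid: int,
    rep: int,
    seeds: Sequence[int],
    T_dist: Tuple[float, float],
    a_dist: Tuple[float, float],
    iterations: int,
    warmup: Optional[int],
    chains: int,
    pi0: float,
    methods: Tuple[str, ...],
) -> List[DecisionRecord]:
    s_pool, s_split, s_fit, s_resample, s_hyper = seeds
    pool = simulate_pool(scenario, s_pool)
    d1 = split_and_mask(pool, scenario, s_split)
    hyper_rng = np.random.default_rng(s_hyper)
    T = float(hyper_rng.uniform(*T_dist))
    a = float(hyper_rng.uniform(*a_dist))
    truth = TRUTH_ALTERNATIVE if abs(scenario.beta_true) > T else TRUTH_NULL
    spec = LossSpec(a=a, beta_star=scenario.beta_true if truth == TRUTH_ALTERNATIVE else 0.3)
    common = dict(
        scenario_id=sid,
        replicate=rep,
        truth=truth,
        T_used=T,
        a_used=a,
        seed=s_pool,
        missing_rate=scenario.missing_rate,
        alpha_strength=scenario.alpha_strength,
        beta_true=scenario.beta_true,
    )
    records: List[DecisionRecord] = []
    if "bayes" in methods:
        prior = PriorConfig(pi0=pi0, rope_T=T)
        # the model assumes standardized (Z, X); the ROPE lives on that scale
        draws = sample_used_posterior(
            standardize(d1), prior,
            iterations=iterations, warmup=warmup, chains=chains, seed=s_fit,
        )
        weighted = resample(draws, prior, seed=s_resample)
        odds = posterior_odds(weighted, prior)
        decision = cddr(odds)
        records.append(
            DecisionRecord(
                method="bayes",
                decision=decision,
                loss=loss(decision, truth, spec),
                odds=odds.odds,
                estimate=float(np.mean(weighted.resampled_beta)),
                **common,
            )
        )
    if "ivw" in methods:
        ds_a, ds_b = split_for_ivw(d1, rng_seed=s_split)
        res = ivw_fit(ds_a, ds_b)
        decision = ivw_decide(res)
        records.append(
            DecisionRecord(
                method="ivw",
                decision=decision,
                loss=loss(decision, truth, spec),
                estimate=res.estimate,
                **common,
            )
        )
    return records
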