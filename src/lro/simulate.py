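"""Individual-based Monte-Carlo simulation of life trajectories.

Each simulated individual starts in a designated stage, moves at every
time step according to the columns of the full transition matrix ``P``,
and draws a random reproductive reward from its current stage's fertility
distribution (including the step on which it dies, unless reproduction
requires parental survival).  Totals at absorption are the sampled
lifetime reproductive outputs.

Besides the LRO and lifespan of every individual, the sampler records the
*path-conditional* mean and variance of LRO — the expected output and its
fertility noise given the exact sequence of stages the individual visited,
computed exactly from visit counts times the stage moments.  Their sample
variance and sample mean estimate the between- and within-pathway
components of the variance decomposition without nested simulation.

The sampler exists to cross-check the closed-form moment recursion and is
bit-reproducible given a seed (NumPy PCG64 generator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lifecycle import LifeCycleModel, build_markov_chain
from .moments import VariancePartition
from .rewards import FertilitySchedule

__all__ = ["TrajectorySample", "simulate_trajectories", "sample_partition"]


@dataclass
class TrajectorySample:
    """Per-individual outcomes of a cohort of simulated lives."""

    lro: np.ndarray
    lifespan: np.ndarray
    visits: np.ndarray
    path_mean: np.ndarray
    path_var: np.ndarray
    seed: int
    start_stage: int

    @property
    def n(self) -> int:
        return self.lro.size

    def raw_moment(self, k: int) -> float:
        """k-th sample raw moment of LRO."""
        return float(np.mean(self.lro.astype(float) ** k))

    def raw_moment_se(self, k: int) -> float:
        """Monte-Carlo standard error of the k-th sample raw moment."""
        x = self.lro.astype(float) ** k
        return float(np.std(x, ddof=1) / np.sqrt(self.n))


def _draw_rewards(
    rng: np.random.Generator, fert: FertilitySchedule, stage: int, size: int
) -> np.ndarray:
    f1 = fert.f1[stage]
    if fert.model == "bernoulli":
        return (rng.random(size) < f1).astype(float)
    if fert.model == "poisson":
        return rng.poisson(f1, size).astype(float)
    if fert.model == "fixed":
        return np.full(size, f1)
    # empirical: two-point distribution {0, c} matching the first two moments
    f2 = fert.second_moment()[stage]
    if f1 <= 0:
        return np.zeros(size)
    if f2 < f1 * f1:
        raise ValueError("cannot sample: inconsistent empirical moments")
    c = f2 / f1
    q = f1 * f1 / f2
    return c * (rng.random(size) < q).astype(float)


def simulate_trajectories(
    model: LifeCycleModel,
    fertility: FertilitySchedule | None = None,
    n: int = 10_000,
    seed: int = 0,
    start_stage: int = 1,
    max_steps: int = 1_000_000,
) -> TrajectorySample:
    """Simulate ``n`` independent life trajectories with stochastic rewards.

    ``start_stage`` is 1-based.  Rewards are drawn on every step from the
    departure stage's distribution; with ``require_parental_survival`` set
    on the fertility schedule the reward of the dying step is zero, and
    that step is likewise excluded from the path-conditional moments.
    """
    fert = fertility if fertility is not None else model.fertility
    if fert is None:
        raise ValueError("cannot sample: supply a fertility schedule")
    if fert.model not in ("bernoulli", "poisson", "fixed", "empirical"):
        raise ValueError("cannot sample: supply a sampler for this reward model")
    if not 1 <= start_stage <= model.tau:
        raise ValueError(f"start stage must be in 1..{model.tau}")
    chain = build_markov_chain(model)
    tau, s = chain.tau, chain.s
    cumP = np.cumsum(chain.P, axis=0)
    f1 = fert.f1
    v = fert.variance
    flag = fert.require_parental_survival

    rng = np.random.default_rng(seed)
    state = np.full(n, start_stage - 1, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    lro = np.zeros(n)
    lifespan = np.zeros(n, dtype=np.int64)
    visits = np.zeros((n, tau), dtype=np.int64)
    path_mean = np.zeros(n)
    path_var = np.zeros(n)

    steps = 0
    while alive.any():
        steps += 1
        if steps > max_steps:
            raise RuntimeError("simulation exceeded max_steps before absorption")
        alive_idx = np.flatnonzero(alive)
        cur = state[alive_idx]
        for j in np.unique(cur):
            idx = alive_idx[cur == j]
            k = idx.size
            u = rng.random(k)
            nxt = np.searchsorted(cumP[:, j], u, side="right")
            nxt = np.minimum(nxt, s - 1)
            rewards = _draw_rewards(rng, fert, j, k)
            died = nxt >= tau
            if flag:
                rewards = np.where(died, 0.0, rewards)
                surv = (~died).astype(float)
                path_mean[idx] += f1[j] * surv
                path_var[idx] += v[j] * surv
            else:
                path_mean[idx] += f1[j]
                path_var[idx] += v[j]
            lro[idx] += rewards
            visits[idx, j] += 1
            lifespan[idx] += 1
            state[idx] = nxt
            alive[idx[died]] = False
    return TrajectorySample(
        lro=lro,
        lifespan=lifespan,
        visits=visits,
        path_mean=path_mean,
        path_var=path_var,
        seed=seed,
        start_stage=start_stage,
    )


def sample_partition(sample: TrajectorySample) -> VariancePartition:
    """Estimate the variance partition from a trajectory sample.

    The between-pathway component is the sample variance of the
    path-conditional means; the within-pathway component is the sample
    mean of the path-conditional variances.  Their sum matches the sample
    variance of LRO up to estimator noise (law of total variance).
    """
    v_between = np.atleast_1d(np.var(sample.path_mean, ddof=1))
    v_within = np.atleast_1d(np.mean(sample.path_var))
    return VariancePartition(
        v_total=v_between + v_within, v_between=v_between, v_within=v_within
    )
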