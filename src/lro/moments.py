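"""Moments and statistics of lifetime reproductive output (LRO).

Let ``rho_k`` be the vector whose i-th entry is the k-th raw moment of the
remaining LRO of an individual currently in state i.  The dead do not
reproduce, so only the transient part ``rho~_k`` (length tau) is needed.
The moments satisfy the closed-form recursion

    rho~_m = N' Z (P ∘ R_m)' 1_s
             + sum_{k=1}^{m-1} C(m, k) N' (U ∘ R~_{m-k})' rho~_k

where ``N = (I - U)^{-1}`` is the fundamental matrix, ``Z = (I | 0)``
selects transient states, and ``R~_k = Z R_k Z'`` is the transient
submatrix of the reward moments.  The first term accumulates the reward of
the current step (including a possible dying step); the cross terms couple
lower-order moments of the future to reward moments of the present.

From the first two or three moments follow the variance, SD, CV, Crow's
opportunity-for-selection index ``I = V/E^2 = CV^2``, skewness, and the
within/between-pathway variance decomposition (law of total variance):
recomputing the variance under the *fixed* reward model removes all
within-pathway fertility noise and leaves the between-pathway component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

from .lifecycle import LifeCycleModel, MarkovChain, build_markov_chain, life_expectancy
from .rewards import FertilitySchedule, RewardMoments

__all__ = [
    "MomentVectors",
    "LROStatistics",
    "VariancePartition",
    "lro_moment_vectors",
    "lro_statistics",
    "partition_variance",
    "skewness",
]


@dataclass(frozen=True)
class MomentVectors:
    """Raw moments ``rho~_1 ... rho~_m`` of remaining LRO by starting stage."""

    rho: tuple[np.ndarray, ...]

    @property
    def order(self) -> int:
        return len(self.rho)

    @property
    def tau(self) -> int:
        return self.rho[0].size

    def raw(self, k: int) -> np.ndarray:
        """k-th raw moment vector (1-based)."""
        return self.rho[k - 1]

    def padded(self, k: int, alpha: int = 1) -> np.ndarray:
        """Full-state vector ``rho_k = Z' rho~_k`` (zeros for the dead)."""
        return np.concatenate([self.rho[k - 1], np.zeros(alpha)])


def lro_moment_vectors(
    chain: MarkovChain, rewards: RewardMoments, m: int | None = None
) -> MomentVectors:
    """All raw moments of LRO up to order ``m`` via the closed-form recursion.

    Each order is obtained by a linear solve against ``(I - U)'`` rather
    than forming ``N`` explicitly.
    """
    if rewards.tau != chain.tau or rewards.s != chain.s:
        raise ValueError(
            f"shape error: rewards are for (tau={rewards.tau}, s={rewards.s}), "
            f"chain has (tau={chain.tau}, s={chain.s})"
        )
    m = rewards.order if m is None else m
    if m > rewards.order:
        raise ValueError(f"shape error: order {m} requested, rewards supply {rewards.order}")
    tau = chain.tau
    U, P = chain.U, chain.P
    A = (np.eye(tau) - U).T
    rhos: list[np.ndarray] = []
    for order in range(1, m + 1):
        Rk = rewards.R(order)
        y = (P * Rk).T.sum(axis=1)[:tau]  # Z (P∘R_m)' 1_s
        for k in range(1, order):
            y = y + comb(order, k, exact=True) * (
                (U * rewards.Rtilde(order - k)).T @ rhos[k - 1]
            )
        rhos.append(np.linalg.solve(A, y))
    return MomentVectors(tuple(rhos))


@dataclass(frozen=True)
class LROStatistics:
    """Per-starting-stage summary statistics of LRO.

    ``cv`` and ``crow_i`` are NaN (undefined) where the mean is zero;
    ``crow_i`` equals ``cv**2`` exactly elsewhere.
    """

    mean: np.ndarray
    variance: np.ndarray
    sd: np.ndarray
    cv: np.ndarray
    crow_i: np.ndarray
    life_expectancy: np.ndarray | None = None

    @property
    def tau(self) -> int:
        return self.mean.size

    def to_frame(self) -> pd.DataFrame:
        """Tidy table, one row per starting stage (1-based labels)."""
        data = {
            "stage": np.arange(1, self.tau + 1),
            "mean": self.mean,
            "variance": self.variance,
            "sd": self.sd,
            "cv": self.cv,
            "crow_i": self.crow_i,
        }
        if self.life_expectancy is not None:
            data["life_expectancy"] = self.life_expectancy
        return pd.DataFrame(data)


def lro_statistics(
    moments: MomentVectors, life_expectancy: np.ndarray | None = None
) -> LROStatistics:
    """Mean, variance, SD, CV, and Crow's index from the raw moments."""
    if moments.order < 2:
        raise ValueError("statistics require moments up to order 2")
    mean = moments.raw(1)
    variance = moments.raw(2) - mean * mean
    # clip roundoff-negative variance; anything materially negative is a bug
    scale = np.maximum(1.0, mean * mean)
    if np.any(variance < -1e-9 * scale):
        raise ValueError("moment inconsistency: negative variance")
    variance = np.maximum(variance, 0.0)
    sd = np.sqrt(variance)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    crow_i = cv * cv
    return LROStatistics(mean, variance, sd, cv, crow_i, life_expectancy)


def skewness(moments: MomentVectors) -> np.ndarray:
    """Standardized third central moment of LRO per starting stage.

    ``(rho~_3 - 3 rho~_1∘rho~_2 + 2 rho~_1^3) / sd^3``; NaN where sd = 0.
    """
    if moments.order < 3:
        raise ValueError("skewness requires moments up to order 3")
    m1, m2, m3 = moments.raw(1), moments.raw(2), moments.raw(3)
    var = np.maximum(m2 - m1 * m1, 0.0)
    central3 = m3 - 3.0 * m1 * m2 + 2.0 * m1 ** 3
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(var > 0, central3 / var ** 1.5, np.nan)


@dataclass(frozen=True)
class VariancePartition:
    """Within/between-pathway decomposition of LRO variance.

    ``v_between`` is the variance under fixed (zero-variance) rewards —
    the spread caused purely by individuals taking different pathways.
    ``v_within = v_total - v_between`` is the stochastic-fertility noise
    accumulated along pathways.  Shares are percentages of ``v_total``.
    """

    v_total: np.ndarray
    v_between: np.ndarray
    v_within: np.ndarray

    def _shares(self) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(divide="ignore", invalid="ignore"):
            between = np.where(self.v_total > 0, 100.0 * self.v_between / self.v_total, np.nan)
            within = np.where(self.v_total > 0, 100.0 * self.v_within / self.v_total, np.nan)
        return between, within

    @property
    def between_pct(self) -> np.ndarray:
        return self._shares()[0]

    @property
    def within_pct(self) -> np.ndarray:
        return self._shares()[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": np.arange(1, self.v_total.size + 1),
                "v_total": self.v_total,
                "v_between": self.v_between,
                "v_within": self.v_within,
                "between_pct": self.between_pct,
                "within_pct": self.within_pct,
            }
        )


def partition_variance(
    model: LifeCycleModel,
    fertility: FertilitySchedule | None = None,
    chain: MarkovChain | None = None,
) -> VariancePartition:
    """Partition LRO variance into within- and between-pathway components.

    The total uses the fertility schedule's own reward model; the
    between-pathway component substitutes the fixed reward model for the
    same mean fertilities, which silences within-pathway noise.
    """
    fert = fertility if fertility is not None else model.fertility
    if fert is None:
        raise ValueError("partition requires a fertility schedule")
    chain = chain if chain is not None else build_markov_chain(model)
    total = lro_statistics(lro_moment_vectors(chain, fert.reward_moments(model.alpha, m=2)))
    fixed = lro_statistics(
        lro_moment_vectors(chain, fert.as_fixed().reward_moments(model.alpha, m=2))
    )
    v_total, v_between = total.variance, fixed.variance
    v_within = v_total - v_between
    scale = np.maximum(1.0, v_total)
    if np.any(v_within < -1e-9 * scale):
        raise ValueError("moment inconsistency: negative within-pathway variance")
    v_within = np.maximum(v_within, 0.0)
    return VariancePartition(v_total, v_between, v_within)
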