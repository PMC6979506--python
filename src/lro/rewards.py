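"""Reward-moment matrices for per-transition reproductive output.

In a Markov chain with rewards, every transition ``j -> i`` of the life
cycle carries a random reproductive reward.  The matrix ``R_k`` (dimension
``s x s``, where ``s = tau + alpha`` counts transient plus absorbing
states) holds the k-th raw moment of that reward for every transition.

In most demographic models mean fertility is stage-specific: an individual
in stage ``j`` produces on average ``f_j`` offspring per time step
regardless of the transition it makes.  ``R_1`` then has identical rows,
each equal to the fertility vector padded with zeros for the absorbing
states.  Higher moments come either from empirical raw moments or from a
parametric family:

* **Bernoulli** — at most one offspring per step, so all raw moments equal
  the first: ``R_3 = R_2 = R_1``.
* **Poisson** — clutch sizes with equal chances for everyone:
  ``R_2 = R_1 + R_1∘R_1`` and ``R_3 = R_1 + 3 R_1∘R_1 + R_1∘R_1∘R_1``.
* **Fixed** — every individual produces exactly the stage mean (a
  zero-variance reward): ``R_k = R_1∘...∘R_1`` (k factors).  Used to
  isolate the between-pathway component of variance.

By default the reward is collected on every transition, including the one
into death.  If reproduction requires parental survival, the rows of
``R_1`` corresponding to absorbing destinations are set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FertilitySchedule",
    "RewardMoments",
    "rewards_from_fertility_vector",
    "bernoulli_moments",
    "poisson_moments",
    "fixed_moments",
    "empirical_moments",
]

_MODELS = ("bernoulli", "poisson", "fixed", "empirical")

#: tolerance for Jensen consistency f2 >= f1^2 and for probability bounds
_TOL = 1e-12


def rewards_from_fertility_vector(
    f1: np.ndarray, s: int, require_parental_survival: bool = False
) -> np.ndarray:
    """First-moment reward matrix from a stage-specific fertility vector.

    Every row of the returned ``s x s`` matrix equals ``(f1^T, 0_alpha)``;
    entry ``(i, j)`` is the mean reward collected on the transition
    ``j -> i``.  With ``require_parental_survival`` the last
    ``alpha = s - tau`` rows (transitions into death) are zeroed.
    """
    f1 = np.atleast_1d(np.asarray(f1, dtype=float))
    if np.any(f1 < 0):
        raise ValueError("invalid fertility: negative entries in f1")
    tau = f1.size
    alpha = s - tau
    if alpha < 1:
        raise ValueError(f"invalid fertility: s={s} must exceed tau={tau}")
    row = np.concatenate([f1, np.zeros(alpha)])
    R1 = np.tile(row, (s, 1))
    if require_parental_survival:
        R1[tau:, :] = 0.0
    return R1


def bernoulli_moments(R1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Second and third raw moments under Bernoulli (0/1 offspring) rewards.

    All raw moments of a Bernoulli variable equal its mean, so
    ``R_3 = R_2 = R_1``.
    """
    R1 = np.asarray(R1, dtype=float)
    if np.any(R1 < -_TOL) or np.any(R1 > 1 + _TOL):
        raise ValueError("Bernoulli requires probabilities: entries of R1 in [0, 1]")
    return R1.copy(), R1.copy()


def poisson_moments(R1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Second and third raw moments under Poisson rewards with mean R1."""
    R1 = np.asarray(R1, dtype=float)
    if np.any(R1 < -_TOL):
        raise ValueError("invalid fertility: negative Poisson means")
    R2 = R1 + R1 * R1
    R3 = R1 + 3.0 * R1 * R1 + R1 * R1 * R1
    return R2, R3


def fixed_moments(R1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw moments of a degenerate reward equal to its mean with certainty.

    ``R_2 = R_1∘R_1`` and ``R_3 = R_1∘R_1∘R_1`` — a zero-variance reward
    used to remove the within-pathway component of LRO variance.
    """
    R1 = np.asarray(R1, dtype=float)
    if np.any(R1 < -_TOL):
        raise ValueError("invalid fertility: negative means")
    return R1 * R1, R1 * R1 * R1


@dataclass(frozen=True)
class RewardMoments:
    """Ordered collection of reward-moment matrices ``R_1 ... R_m``.

    Attributes
    ----------
    matrices
        Tuple of ``s x s`` arrays; ``matrices[k-1]`` is ``R_k``.
    tau
        Number of transient states; ``alpha = s - tau`` absorbing states.
    """

    matrices: tuple[np.ndarray, ...]
    tau: int

    def __post_init__(self) -> None:
        s = self.matrices[0].shape[0]
        for k, Rk in enumerate(self.matrices, start=1):
            if Rk.shape != (s, s):
                raise ValueError(f"shape error: R_{k} is {Rk.shape}, expected {(s, s)}")
            if np.any(Rk < -_TOL):
                raise ValueError(f"invalid reward moments: negative entries in R_{k}")
        if self.order >= 2:
            R1, R2 = self.matrices[0], self.matrices[1]
            if np.any(R2 - R1 * R1 < -1e-9 * np.maximum(1.0, R1 * R1)):
                raise ValueError("inconsistent moments: R_2 < R_1∘R_1 (negative variance)")

    @property
    def s(self) -> int:
        return self.matrices[0].shape[0]

    @property
    def alpha(self) -> int:
        return self.s - self.tau

    @property
    def order(self) -> int:
        return len(self.matrices)

    def R(self, k: int) -> np.ndarray:
        """k-th moment matrix (1-based)."""
        return self.matrices[k - 1]

    def Rtilde(self, k: int) -> np.ndarray:
        """Transient ``tau x tau`` submatrix of ``R_k``."""
        return self.matrices[k - 1][: self.tau, : self.tau]


def empirical_moments(
    f1: np.ndarray,
    f2: np.ndarray,
    f3: np.ndarray | None = None,
    alpha: int = 1,
    require_parental_survival: bool = False,
) -> RewardMoments:
    """Reward moments from empirical stage-specific raw moments.

    Each ``R_k`` broadcasts the stage's k-th raw moment across its column,
    following the same row-constant pattern as the first-moment matrix.
    """
    f1 = np.atleast_1d(np.asarray(f1, dtype=float))
    f2 = np.atleast_1d(np.asarray(f2, dtype=float))
    if f1.shape != f2.shape:
        raise ValueError("ragged schedule: f1 and f2 lengths differ")
    if np.any(f2 - f1 * f1 < -1e-9 * np.maximum(1.0, f1 * f1)):
        raise ValueError("inconsistent moments: f2 < f1^2 at some stage")
    s = f1.size + alpha
    mats = [
        rewards_from_fertility_vector(f1, s, require_parental_survival),
        rewards_from_fertility_vector(f2, s, require_parental_survival),
    ]
    if f3 is not None:
        f3 = np.atleast_1d(np.asarray(f3, dtype=float))
        if f3.shape != f1.shape:
            raise ValueError("ragged schedule: f3 length differs")
        mats.append(rewards_from_fertility_vector(f3, s, require_parental_survival))
    return RewardMoments(tuple(mats), tau=f1.size)


@dataclass(frozen=True)
class FertilitySchedule:
    """Stage-specific fertility with a model for its higher moments.

    Parameters
    ----------
    f1
        Mean offspring per stage per time step (length ``tau``).
    model
        One of ``bernoulli``, ``poisson``, ``fixed``, ``empirical``.
    f2, f3
        Raw moments for the ``empirical`` model (ignored otherwise).
    require_parental_survival
        If True, no reward is collected on the transition into death.
    """

    f1: np.ndarray
    model: str = "poisson"
    f2: np.ndarray | None = None
    f3: np.ndarray | None = None
    require_parental_survival: bool = False

    def __post_init__(self) -> None:
        f1 = np.atleast_1d(np.asarray(self.f1, dtype=float))
        object.__setattr__(self, "f1", f1)
        if self.model not in _MODELS:
            raise ValueError(f"unknown reward model {self.model!r}; choose from {_MODELS}")
        if np.any(f1 < 0):
            raise ValueError("invalid fertility: negative entries in f1")
        if self.model == "bernoulli" and np.any(f1 > 1 + _TOL):
            raise ValueError("Bernoulli requires probabilities: f1 entries must be <= 1")
        if self.model == "empirical":
            if self.f2 is None:
                raise ValueError("empirical model requires f2")
            f2 = np.atleast_1d(np.asarray(self.f2, dtype=float))
            object.__setattr__(self, "f2", f2)
            if f2.shape != f1.shape:
                raise ValueError("ragged schedule: f1 and f2 lengths differ")
            if np.any(f2 - f1 * f1 < -1e-9 * np.maximum(1.0, f1 * f1)):
                raise ValueError("inconsistent moments: f2 < f1^2 at some stage")
            if self.f3 is not None:
                object.__setattr__(
                    self, "f3", np.atleast_1d(np.asarray(self.f3, dtype=float))
                )

    @property
    def tau(self) -> int:
        return self.f1.size

    @property
    def variance(self) -> np.ndarray:
        """Per-stage reward variance v = f2 - f1∘f1 implied by the model."""
        f1 = self.f1
        if self.model == "bernoulli":
            return f1 * (1.0 - f1)
        if self.model == "poisson":
            return f1.copy()
        if self.model == "fixed":
            return np.zeros_like(f1)
        return self.f2 - f1 * f1

    def second_moment(self) -> np.ndarray:
        """Per-stage second raw moment f2 implied by the model."""
        return self.variance + self.f1 * self.f1

    def reward_moments(self, alpha: int = 1, m: int = 3) -> RewardMoments:
        """Build the reward-moment matrices ``R_1 ... R_m`` (m <= 3)."""
        if not 1 <= m <= 3:
            raise ValueError("moment order m must be 1, 2, or 3")
        s = self.tau + alpha
        R1 = rewards_from_fertility_vector(self.f1, s, self.require_parental_survival)
        if m == 1:
            return RewardMoments((R1,), tau=self.tau)
        if self.model == "bernoulli":
            R2, R3 = bernoulli_moments(R1)
        elif self.model == "poisson":
            R2, R3 = poisson_moments(R1)
        elif self.model == "fixed":
            R2, R3 = fixed_moments(R1)
        else:
            R2 = rewards_from_fertility_vector(self.f2, s, self.require_parental_survival)
            if m == 3:
                if self.f3 is None:
                    raise ValueError("empirical model requires f3 for third moments")
                R3 = rewards_from_fertility_vector(
                    self.f3, s, self.require_parental_survival
                )
            else:
                R3 = None
        mats = (R1, R2) if m == 2 else (R1, R2, R3)
        return RewardMoments(mats, tau=self.tau)

    def as_fixed(self) -> "FertilitySchedule":
        """Same mean fertility with the degenerate (fixed) reward model."""
        return FertilitySchedule(
            self.f1.copy(),
            model="fixed",
            require_parental_survival=self.require_parental_survival,
        )
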