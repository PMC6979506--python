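"""Life cycles as absorbing Markov chains.

The individual life cycle is a finite-state, discrete-time absorbing
Markov chain.  The ``tau x tau`` transient matrix ``U`` holds the
per-time-step transition probabilities among the living stages; the
``alpha`` absorbing states represent death.  The full column-stochastic
transition matrix is

    P = [[U, 0],
         [M, I_alpha]]

where the mortality matrix ``M`` holds the probabilities of dying from
each transient state.  We require the spectral radius of ``U`` to be
strictly below 1, so every individual is eventually absorbed (dies) with
probability 1.  The fundamental matrix ``N = (I - U)^{-1}`` gives expected
occupancy times; its column sums are the life expectancies.

Stage labels shown to users are 1-based (stage 1 ... tau); arrays are
0-indexed internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .rewards import FertilitySchedule

__all__ = [
    "LifeCycleModel",
    "MarkovChain",
    "StageDecomposition",
    "AgeClassifiedSchedule",
    "build_markov_chain",
    "fundamental_matrix",
    "life_expectancy",
    "build_age_classified",
    "decompose_stage_model",
]

_PROB_TOL = 1e-9
_RADIUS_TOL = 1e-10


def spectral_radius(U: np.ndarray) -> float:
    """Magnitude of the dominant eigenvalue of U."""
    return float(np.max(np.abs(np.linalg.eigvals(U)))) if U.size else 0.0


@dataclass
class LifeCycleModel:
    """A transient transition matrix plus a fertility specification.

    Parameters
    ----------
    U
        ``tau x tau`` matrix of transition probabilities among living
        stages, columns = departure stage.
    fertility
        Optional :class:`~lro.rewards.FertilitySchedule`.
    alpha
        Number of absorbing (death) states, default 1.
    M
        ``alpha x tau`` mortality matrix; required when ``alpha > 1``,
        derived from the column deficits of ``U`` when ``alpha == 1``.
    stage_labels
        Optional names for the transient stages (1-based ordering).
    """

    U: np.ndarray
    fertility: FertilitySchedule | None = None
    alpha: int = 1
    M: np.ndarray | None = None
    stage_labels: list[str] | None = None

    def __post_init__(self) -> None:
        U = np.atleast_2d(np.asarray(self.U, dtype=float))
        if U.shape[0] != U.shape[1]:
            raise ValueError(f"invalid transition matrix: U is not square {U.shape}")
        if np.any(U < -_PROB_TOL) or np.any(U > 1 + _PROB_TOL):
            raise ValueError("invalid transition matrix: entries outside [0, 1]")
        if np.any(U.sum(axis=0) > 1 + _PROB_TOL):
            raise ValueError("invalid transition matrix: column sums exceed 1")
        if self.alpha < 1:
            raise ValueError("invalid transition matrix: alpha must be >= 1")
        rho = spectral_radius(U)
        if rho >= 1 - _RADIUS_TOL:
            raise ValueError(
                f"non-absorbing chain: spectral radius of U is {rho:.12g} >= 1"
            )
        self.U = U
        if self.alpha > 1:
            if self.M is None:
                raise ValueError("mortality matrix M is required when alpha > 1")
            M = np.atleast_2d(np.asarray(self.M, dtype=float))
            if M.shape != (self.alpha, self.tau):
                raise ValueError(
                    f"invalid transition matrix: M is {M.shape}, "
                    f"expected {(self.alpha, self.tau)}"
                )
            if np.any(np.abs(U.sum(axis=0) + M.sum(axis=0) - 1.0) > _PROB_TOL):
                raise ValueError(
                    "invalid transition matrix: columns of [U; M] do not sum to 1"
                )
            self.M = M
        if self.fertility is not None and self.fertility.tau != self.tau:
            raise ValueError(
                f"shape error: fertility has {self.fertility.tau} stages, U has {self.tau}"
            )
        if self.stage_labels is not None and len(self.stage_labels) != self.tau:
            raise ValueError("ragged schedule: stage_labels length differs from tau")

    @property
    def tau(self) -> int:
        return self.U.shape[0]

    @property
    def s(self) -> int:
        return self.tau + self.alpha


@dataclass
class MarkovChain:
    """Assembled absorbing chain (P, U, M, Z, N) for a life-cycle model."""

    U: np.ndarray
    M: np.ndarray
    alpha: int = 1

    @property
    def tau(self) -> int:
        return self.U.shape[0]

    @property
    def s(self) -> int:
        return self.tau + self.alpha

    @cached_property
    def P(self) -> np.ndarray:
        """Full ``s x s`` column-stochastic transition matrix."""
        tau, alpha, s = self.tau, self.alpha, self.s
        P = np.zeros((s, s))
        P[:tau, :tau] = self.U
        P[tau:, :tau] = self.M
        P[tau:, tau:] = np.eye(alpha)
        return P

    @cached_property
    def Z(self) -> np.ndarray:
        """Selection matrix ``Z = (I_tau | 0)`` picking transient entries."""
        return np.hstack([np.eye(self.tau), np.zeros((self.tau, self.alpha))])

    @cached_property
    def N(self) -> np.ndarray:
        """Fundamental matrix ``(I - U)^{-1}`` via LU solves."""
        return _fundamental(self.U)


def _fundamental(U: np.ndarray) -> np.ndarray:
    tau = U.shape[0]
    A = np.eye(tau) - U
    try:
        N = np.linalg.solve(A, np.eye(tau))
    except np.linalg.LinAlgError as exc:
        raise ValueError("chain not absorbing within tolerance: I - U singular") from exc
    if not np.all(np.isfinite(N)) or np.any(N < -1e-8):
        raise ValueError("chain not absorbing within tolerance: ill-conditioned I - U")
    return N


def build_markov_chain(model: LifeCycleModel) -> MarkovChain:
    """Assemble the absorbing chain in block form ``[[U, 0], [M, I]]``.

    With a single absorbing state the mortality row is the column deficit
    ``M = 1' - 1'U``; with several absorbing states ``M`` must be supplied
    on the model.
    """
    if model.alpha == 1:
        M = (1.0 - model.U.sum(axis=0)).reshape(1, -1)
    else:
        M = model.M
    return MarkovChain(U=model.U, M=M, alpha=model.alpha)


def fundamental_matrix(model: LifeCycleModel | MarkovChain | np.ndarray) -> np.ndarray:
    """Fundamental matrix ``N = (I - U)^{-1}``.

    Entry ``(i, j)`` is the expected number of time steps spent in stage
    ``i`` by an individual starting in stage ``j``.
    """
    if isinstance(model, MarkovChain):
        return model.N
    U = model.U if isinstance(model, LifeCycleModel) else np.atleast_2d(np.asarray(model))
    return _fundamental(U)


def life_expectancy(model: LifeCycleModel | MarkovChain | np.ndarray) -> np.ndarray:
    """Expected remaining lifetime by starting stage: column sums of N."""
    return fundamental_matrix(model).sum(axis=0)


# ---------------------------------------------------------------------------
# age-classified construction


@dataclass
class AgeClassifiedSchedule:
    """Age-specific mortality hazards and mean fertilities.

    The transient matrix built from this schedule has survival
    probabilities ``p_x = exp(-mu_x)`` on the subdiagonal and zeros
    elsewhere; the final age class has no survival, so death is certain at
    the end of the table.  Set ``open_final_class`` to close the table with
    an open-ended last interval instead (a self-loop with survival
    ``exp(-mu_omega)``).
    """

    mu: np.ndarray
    f: np.ndarray
    open_final_class: bool = False

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        f = np.atleast_1d(np.asarray(self.f, dtype=float))
        if mu.shape != f.shape:
            raise ValueError("ragged schedule: mu and f lengths differ")
        if np.any(mu < 0):
            raise ValueError("invalid mortality: negative hazard")
        if np.any(f < 0):
            raise ValueError("invalid fertility: negative entries")
        self.mu, self.f = mu, f

    @property
    def omega(self) -> int:
        return self.mu.size

    @property
    def p(self) -> np.ndarray:
        """Survival probabilities ``p = exp(-mu)``."""
        with np.errstate(over="ignore"):
            return np.exp(-self.mu)

    @property
    def Y(self) -> np.ndarray:
        """Indicator matrix of the (sub)diagonal structure of U."""
        omega = self.omega
        Y = np.zeros((omega, omega))
        idx = np.arange(omega - 1)
        Y[idx + 1, idx] = 1.0
        if self.open_final_class:
            Y[omega - 1, omega - 1] = 1.0
        return Y


def build_age_classified(
    schedule: AgeClassifiedSchedule, model: str = "bernoulli"
) -> LifeCycleModel:
    """Life-cycle model from an age-classified mortality/fertility schedule.

    ``U`` has ``exp(-mu_x)`` at entry ``(x+1, x)`` and zeros elsewhere;
    fertility follows the given reward model (Bernoulli by default, with
    ``f_x`` read as the probability of a single offspring).
    """
    U = schedule.Y * schedule.p[np.newaxis, :]
    fert = FertilitySchedule(schedule.f, model=model)
    return LifeCycleModel(U=U, fertility=fert)


# ---------------------------------------------------------------------------
# stage-classified decomposition U = G Sigma


@dataclass
class StageDecomposition:
    """Factorization ``U = G Sigma`` into survival and conditional growth.

    ``Sigma = diag(sigma)`` holds stage survival probabilities and ``G``
    the transition probabilities conditional on survival (columns sum
    to 1).  The stage mortality hazard is ``mu = -log(sigma)``.
    """

    G: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        G = np.atleast_2d(np.asarray(self.G, dtype=float))
        sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if G.shape[0] != G.shape[1] or sigma.size != G.shape[0]:
            raise ValueError("shape error: G must be square with matching sigma")
        if np.any(np.abs(G.sum(axis=0) - 1.0) > 1e-8):
            raise ValueError("inconsistent survival vector: columns of G do not sum to 1")
        if np.any(sigma < 0) or np.any(sigma > 1 + _PROB_TOL):
            raise ValueError("invalid survival: sigma entries outside [0, 1]")
        self.G, self.sigma = G, sigma

    @property
    def tau(self) -> int:
        return self.G.shape[0]

    @property
    def Sigma(self) -> np.ndarray:
        return np.diag(self.sigma)

    @property
    def mu(self) -> np.ndarray:
        """Stage mortality hazards ``mu = -log(sigma)``."""
        with np.errstate(divide="ignore"):
            return -np.log(self.sigma)

    @property
    def U(self) -> np.ndarray:
        return self.G * self.sigma[np.newaxis, :]


def decompose_stage_model(
    U: np.ndarray, sigma: np.ndarray | None = None
) -> StageDecomposition:
    """Decompose a transient matrix into ``U = G Sigma``.

    The factorization is non-unique; when no survival vector is supplied,
    ``sigma`` defaults to the column sums of ``U`` (so all column deficit
    is attributed to mortality and ``G`` is column-stochastic by
    construction).  Columns of ``U`` that are entirely zero get
    ``sigma_j = 0`` and a degenerate unit column in ``G``.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    tau = U.shape[0]
    colsum = U.sum(axis=0)
    if sigma is None:
        sigma = colsum.copy()
    else:
        sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
        if sigma.size != tau:
            raise ValueError("ragged schedule: sigma length differs from tau")
        if np.any((sigma <= 0) & (colsum > _PROB_TOL)):
            raise ValueError(
                "inconsistent survival vector: sigma is zero where U has mass"
            )
    G = np.zeros_like(U)
    for j in range(tau):
        if sigma[j] > 0:
            G[:, j] = U[:, j] / sigma[j]
            if abs(G[:, j].sum() - 1.0) > 1e-8:
                raise ValueError(
                    "inconsistent survival vector: U column / sigma not stochastic"
                )
        else:
            G[j, j] = 1.0  # dead column; arbitrary since Sigma_jj = 0
    return StageDecomposition(G=G, sigma=sigma)
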