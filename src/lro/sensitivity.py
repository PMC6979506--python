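"""Analytic sensitivity and elasticity of LRO moments and statistics.

For a parameter vector ``theta`` (length p) the sensitivity of the m-th
moment vector of remaining LRO is the ``tau x p`` derivative matrix

    d rho~_m / d theta' = N' [ V_m + sum_{k=1}^{m-1} C(m,k) W_{k,m-k} + X_m ]

with auxiliary blocks (K is the vec-permutation matrix)

    V_i   = (1_s' ⊗ Z) K_ss [ D(vec R_i) dvecP + D(vec P) dvec R_i ]
    W_i,j = (rho~_i' ⊗ I) K_tt [ D(vec R~_j) dvecU + D(vec U) dvec R~_j ]
            + (U ∘ R~_j)' d rho~_i / d theta'
    X_i   = (rho~_i' ⊗ I) K_tt dvecU.

``V`` differentiates the current-step reward term, ``W`` the cross terms,
and ``X`` the fundamental matrix itself (via dN = N dU N).  All Kronecker
products with identity or one-vector factors are applied implicitly by
reshaping, so no tau^2 x tau^2 operator is materialized; the dense
vec-permutation matrix is exposed separately for small-scale checks.

Derivatives of the statistics follow by the chain rule:

    dV  = drho~_2 - 2 D(rho~_1) drho~_1
    dSD = (1/2) D(SD)^{-1} dV
    dCV = D(rho~_1)^{-1} dSD - D(SD) D(rho~_1)^{-2} drho~_1
    dI  = 2 D(CV) dCV

and elasticities are ``D(xi)^{-1} (dxi/dtheta') D(theta)``, defined only
where the statistic is positive; columns with ``theta_j = 0`` are set to
zero (the limiting value).

The module also builds the perturbation maps of common interest:
age-classified mortality and fertility, stage-classified survival and
mortality via ``U = G Sigma``, compensated (column-sum-preserving)
perturbations of the growth matrix ``G``, and fertility means/variances
either held independent or linked through a parametric reward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb

from .lifecycle import AgeClassifiedSchedule, MarkovChain, StageDecomposition
from .moments import MomentVectors, lro_moment_vectors
from .rewards import FertilitySchedule, RewardMoments, rewards_from_fertility_vector

__all__ = [
    "PerturbationMap",
    "SensitivityResult",
    "vec_permutation",
    "dP_from_dU",
    "moment_sensitivity",
    "statistic_sensitivity",
    "elasticity",
    "age_classified_pmap",
    "stage_classified_pmap",
    "compensated_growth_pmap",
    "fertility_pmap",
]


def vec_permutation(m: int, n: int) -> np.ndarray:
    """Vec-permutation matrix ``K_{m,n}`` with ``K vec X = vec X'``.

    ``X`` is ``m x n``; ``K_{m,n}`` is the ``mn x mn`` permutation sending
    column-stacking order to the column-stacking order of the transpose.
    ``K_{m,n} K_{n,m} = I`` and ``K_{1,n} = I_n``.
    """
    if m < 1 or n < 1:
        raise ValueError("vec_permutation requires m, n >= 1")
    K = np.zeros((m * n, m * n))
    for i in range(m):
        for j in range(n):
            K[j + i * n, i + j * m] = 1.0
    return K


def _unvec(A: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Reshape a stack of vec'd matrices (rows*cols, p) to (rows, cols, p)."""
    return np.asarray(A).reshape(rows, cols, -1, order="F")


def dP_from_dU(dU: np.ndarray, tau: int) -> np.ndarray:
    """Derivative of vec P induced by a derivative of vec U (alpha = 1).

    With one absorbing state the mortality row is the column deficit of
    ``U``, so every perturbation of ``U`` maps to ``P`` as the same block
    change plus the compensating change of the death row.  Applied
    implicitly, column by column, rather than through the dense
    ``s^2 x tau^2`` operator.
    """
    dU3 = _unvec(dU, tau, tau)
    p = dU3.shape[2]
    s = tau + 1
    dP3 = np.zeros((s, s, p))
    dP3[:tau, :tau, :] = dU3
    dP3[tau, :tau, :] = -dU3.sum(axis=0)
    return dP3.reshape(s * s, p, order="F")


@dataclass
class PerturbationMap:
    """Derivatives of the model matrices with respect to parameters theta.

    Attributes
    ----------
    theta
        Parameter values (length p), used for elasticities and for
        finite-difference validation.
    dU
        ``tau^2 x p`` matrix ``d vec U / d theta'``.
    dR
        Mapping ``order -> s^2 x p`` matrix ``d vec R_order / d theta'``;
        missing orders are treated as zero.
    dP
        Optional ``s^2 x p`` matrix; derived from ``dU`` when the chain
        has a single absorbing state, required otherwise.
    labels
        Optional parameter names.
    """

    theta: np.ndarray
    dU: np.ndarray
    dR: dict[int, np.ndarray] = field(default_factory=dict)
    dP: np.ndarray | None = None
    labels: list[str] | None = None
    tau: int = 0
    alpha: int = 1

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.dU = np.asarray(self.dU, dtype=float)
        if self.tau == 0:
            self.tau = int(round(np.sqrt(self.dU.shape[0])))
        if self.dU.shape != (self.tau * self.tau, self.p):
            raise ValueError(
                f"shape error: dU is {self.dU.shape}, expected "
                f"{(self.tau * self.tau, self.p)}"
            )
        s = self.s
        for k, dRk in self.dR.items():
            if np.asarray(dRk).shape != (s * s, self.p):
                raise ValueError(
                    f"shape error: dR[{k}] is {np.asarray(dRk).shape}, "
                    f"expected {(s * s, self.p)}"
                )

    @property
    def p(self) -> int:
        return self.theta.size

    @property
    def s(self) -> int:
        return self.tau + self.alpha

    def dR_matrix(self, order: int) -> np.ndarray:
        s = self.s
        return np.asarray(
            self.dR.get(order, np.zeros((s * s, self.p))), dtype=float
        )

    def dRtilde_matrix(self, order: int) -> np.ndarray:
        """``d vec R~_order / d theta'`` = (Z ⊗ Z) d vec R_order."""
        dR3 = _unvec(self.dR_matrix(order), self.s, self.s)
        return dR3[: self.tau, : self.tau, :].reshape(self.tau * self.tau, self.p, order="F")

    def dP_matrix(self) -> np.ndarray:
        if self.dP is not None:
            return np.asarray(self.dP, dtype=float)
        if self.alpha != 1:
            raise ValueError(
                "perturbation map incomplete: dP (or dM) must be supplied when alpha > 1"
            )
        return dP_from_dU(self.dU, self.tau)


@dataclass
class SensitivityResult:
    """Derivative matrices of LRO moments and statistics w.r.t. theta.

    ``d_rho[k]`` is the ``tau x p`` sensitivity of the k-th raw moment;
    statistic blocks are filled in by :func:`statistic_sensitivity`.
    Rows where a statistic is undefined (sd = 0 or mean = 0) are NaN.
    """

    pmap: PerturbationMap
    d_rho: dict[int, np.ndarray]
    d_variance: np.ndarray | None = None
    d_sd: np.ndarray | None = None
    d_cv: np.ndarray | None = None
    d_crow: np.ndarray | None = None


def moment_sensitivity(
    chain: MarkovChain,
    rewards: RewardMoments,
    pmap: PerturbationMap,
    m: int = 2,
    moments: MomentVectors | None = None,
) -> SensitivityResult:
    """Sensitivities ``d rho~_k / d theta'`` for k = 1..m, built bottom-up.

    Order 1 uses ``N'(V_1 + X_1)``; order 2 adds ``2 W_{1,1}``; order 3
    adds ``3 W_{1,2} + 3 W_{2,1}``; the general order follows the binomial
    recursion.  Each order is one linear solve against ``(I - U)'``.
    """
    if pmap.tau != chain.tau or pmap.s != chain.s:
        raise ValueError("shape error: perturbation map does not match the chain")
    if m > rewards.order:
        raise ValueError(f"shape error: order {m} requested, rewards supply {rewards.order}")
    tau, s, p = chain.tau, chain.s, pmap.p
    U, P = chain.U, chain.P
    if moments is None:
        moments = lro_moment_vectors(chain, rewards, m)
    dP3 = _unvec(pmap.dP_matrix(), s, s)
    dU3 = _unvec(pmap.dU, tau, tau)
    A = (np.eye(tau) - U).T
    d_rho: dict[int, np.ndarray] = {}
    for order in range(1, m + 1):
        Rk = rewards.R(order)
        dR3 = _unvec(pmap.dR_matrix(order), s, s)
        # V_order: d[Z (P∘R)' 1] = column sums of d(P∘R), transient rows
        dPR = Rk[:, :, None] * dP3 + P[:, :, None] * dR3
        V = dPR.sum(axis=0)[:tau, :]
        # X_order: d[N'] contribution, dU' rho~_order
        X = np.einsum("ijp,i->jp", dU3, moments.raw(order))
        rhs = V + X
        for k in range(1, order):
            j = order - k
            Rt = rewards.Rtilde(j)
            dRt3 = _unvec(pmap.dRtilde_matrix(j), tau, tau)
            dURt = Rt[:, :, None] * dU3 + U[:, :, None] * dRt3
            W = np.einsum("ijp,i->jp", dURt, moments.raw(k))
            W = W + (U * Rt).T @ d_rho[k]
            rhs = rhs + comb(order, k, exact=True) * W
        d_rho[order] = np.linalg.solve(A, rhs)
    return SensitivityResult(pmap=pmap, d_rho=d_rho)


def statistic_sensitivity(
    result: SensitivityResult, moments: MomentVectors
) -> SensitivityResult:
    """Add derivative matrices of variance, SD, CV, and Crow's I.

    Requires moment sensitivities of orders 1 and 2.  Where sd = 0 the SD,
    CV, and Crow derivatives are undefined and reported as NaN rows; where
    the mean is 0 the CV and Crow derivatives are NaN.
    """
    if 1 not in result.d_rho or 2 not in result.d_rho:
        raise ValueError("statistic sensitivity requires moment orders 1 and 2")
    m1 = moments.raw(1)
    var = np.maximum(moments.raw(2) - m1 * m1, 0.0)
    sd = np.sqrt(var)
    d1, d2 = result.d_rho[1], result.d_rho[2]
    d_var = d2 - 2.0 * m1[:, None] * d1
    with np.errstate(divide="ignore", invalid="ignore"):
        d_sd = np.where(sd[:, None] > 0, 0.5 * d_var / sd[:, None], np.nan)
        d_cv = np.where(
            (m1[:, None] > 0),
            d_sd / m1[:, None] - (sd / (m1 * m1))[:, None] * d1,
            np.nan,
        )
        cv = np.where(m1 > 0, sd / m1, np.nan)
    d_crow = 2.0 * cv[:, None] * d_cv
    result.d_variance = d_var
    result.d_sd = d_sd
    result.d_cv = d_cv
    result.d_crow = d_crow
    return result


def elasticity(
    value: np.ndarray, dvalue: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Proportional sensitivity ``(theta_j / xi_i) * d xi_i / d theta_j``.

    Rows where the statistic is not strictly positive are NaN (elasticity
    undefined); columns with ``theta_j = 0`` are 0 (the limiting value).
    """
    value = np.atleast_1d(np.asarray(value, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    dvalue = np.asarray(dvalue, dtype=float)
    if np.any(theta < 0):
        raise ValueError("elasticity requires theta >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        e = dvalue * theta[None, :] / value[:, None]
    e[value <= 0, :] = np.nan
    e[:, theta == 0] = 0.0
    return e


# ---------------------------------------------------------------------------
# special perturbation maps


def _fertility_column_basis(
    tau: int, alpha: int, require_parental_survival: bool = False
) -> np.ndarray:
    """Dense ``(Z' ⊗ 1_s)``: d vec R / d f_j puts ones in column j of R.

    With the parental-survival flag the absorbing rows are masked out,
    matching the zeroed rows of the reward matrices themselves.
    """
    s = tau + alpha
    base = np.zeros((s * s, tau))
    for j in range(tau):
        rows = np.arange(s) + j * s
        if require_parental_survival:
            rows = rows[: tau]
        base[rows, j] = 1.0
    return base


def age_classified_pmap(
    schedule: AgeClassifiedSchedule,
    wrt: str = "mu",
    alpha: int = 1,
    m: int = 3,
    require_parental_survival: bool = False,
) -> PerturbationMap:
    """Perturbation map for an age-classified (Bernoulli-fertility) model.

    ``wrt='mu'``: perturbs age-specific mortality hazards; each hazard
    touches exactly the survival entries fed by that age, with
    ``dU_(i,j)/dmu_j = -exp(-mu_j)`` on the structural pattern ``Y``.
    Rewards do not depend on mortality, so all ``dR_k = 0``.

    ``wrt='f'``: perturbs age-specific fertility probabilities; under the
    Bernoulli model all moment matrices equal ``R_1``, so the derivatives
    of every order coincide: ``d vec R_k / d f' = (Z' ⊗ 1_s)``.
    """
    omega = schedule.omega
    s = omega + alpha
    if wrt == "mu":
        Y = schedule.Y
        p_surv = schedule.p
        dU = np.zeros((omega * omega, omega))
        for x in range(omega):
            col = -(Y[:, x] * p_surv[x])
            dU[x * omega : (x + 1) * omega, x] = col
        return PerturbationMap(
            theta=schedule.mu.copy(), dU=dU, dR={}, tau=omega, alpha=alpha,
            labels=[f"mu_{x+1}" for x in range(omega)],
        )
    if wrt == "f":
        base = _fertility_column_basis(omega, alpha, require_parental_survival)
        dU = np.zeros((omega * omega, omega))
        dR = {k: base.copy() for k in range(1, m + 1)}
        return PerturbationMap(
            theta=schedule.f.copy(), dU=dU, dR=dR, tau=omega, alpha=alpha,
            labels=[f"f_{x+1}" for x in range(omega)],
        )
    raise ValueError(f"unknown parameter set {wrt!r}; choose 'mu' or 'f'")


def stage_classified_pmap(
    decomp: StageDecomposition, wrt: str = "mu", alpha: int = 1
) -> PerturbationMap:
    """Perturbation map for stage survival or mortality via ``U = G Sigma``.

    ``wrt='sigma'``: ``d U_(i,j) / d sigma_j = G_(i,j)`` (each survival
    probability scales its own column of the conditional growth matrix).
    ``wrt='mu'``: chain rule through ``sigma = exp(-mu)`` multiplies each
    column by ``-sigma_j``.  Rewards are unaffected.
    """
    tau = decomp.tau
    G, sigma = decomp.G, decomp.sigma
    dU = np.zeros((tau * tau, tau))
    for j in range(tau):
        dU[j * tau : (j + 1) * tau, j] = G[:, j]
    if wrt == "sigma":
        theta = sigma.copy()
        labels = [f"sigma_{j+1}" for j in range(tau)]
    elif wrt == "mu":
        dU = dU * (-sigma)[None, :]
        theta = decomp.mu.copy()
        labels = [f"mu_{j+1}" for j in range(tau)]
    else:
        raise ValueError(f"unknown parameter set {wrt!r}; choose 'sigma' or 'mu'")
    return PerturbationMap(theta=theta, dU=dU, dR={}, tau=tau, alpha=alpha, labels=labels)


def compensated_growth_direction(G: np.ndarray, strict: bool = False) -> np.ndarray:
    """``d vec G / d vec Theta'`` under proportional column compensation.

    Perturbing entry ``g_(l,i)`` by ``d theta`` changes every other entry
    of column ``i`` by ``-g_(k,i) / (1 - g_(l,i)) d theta``, preserving the
    column sum to first order while keeping the proportional structure of
    the rest of the column:

        dG/dTheta = I - sum_i E_ii ⊗ [ D(g_i) (E - I) D(1 - g_i)^{-1} ].

    A perturbed entry equal to 1 leaves nothing in its column to
    compensate with; such directions are degenerate.  With
    ``strict=True`` they raise; otherwise the compensation block is zero
    there (the perturbation is applied uncompensated) — the rest of the
    column is identically zero, so no proportional reallocation exists.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    tau = G.shape[0]
    dG = np.eye(tau * tau)
    for i in range(tau):
        g = G[:, i]
        denom = 1.0 - g
        degenerate = denom <= 1e-12
        if np.any(degenerate) and strict:
            raise ValueError(
                f"degenerate compensation: column {i + 1} of G has an entry equal to 1"
            )
        B = np.zeros((tau, tau))
        ok = ~degenerate
        B[:, ok] = g[:, None] / denom[None, ok]
        np.fill_diagonal(B, 0.0)
        blk = slice(i * tau, (i + 1) * tau)
        dG[blk, blk] -= B
    return dG


def compensated_growth_pmap(
    decomp: StageDecomposition, alpha: int = 1, strict: bool = False
) -> PerturbationMap:
    """Perturbation map for the growth matrix ``G`` with compensation.

    theta is ``vec G`` (all tau^2 entries, column-stacked); each direction
    perturbs one entry and proportionally compensates the rest of its
    column, so ``G`` stays column-stochastic to first order.  The map into
    ``U`` is ``(Sigma ⊗ I) dG/dTheta``.
    """
    tau = decomp.tau
    dG = compensated_growth_direction(decomp.G, strict=strict)
    scale = np.repeat(decomp.sigma, tau)  # (Sigma ⊗ I) is diagonal on vec U
    dU = scale[:, None] * dG
    labels = [f"g_{i+1}{j+1}" for j in range(tau) for i in range(tau)]
    return PerturbationMap(
        theta=decomp.G.flatten(order="F"),
        dU=dU,
        dR={},
        tau=tau,
        alpha=alpha,
        labels=labels,
    )


def fertility_pmap(
    fert: FertilitySchedule, mode: str = "linked", alpha: int = 1
) -> PerturbationMap:
    """Perturbation maps for fertility means and variances (``dU = 0``).

    ``mode='mean_fixed_variance'``: theta = f1 with the per-stage variance
    held fixed, so ``d f2 / d f1' = 2 D(f1)`` and

        dR1 = (Z' ⊗ 1_s),   dR2 = 2 (Z' ⊗ 1_s) D(f1).

    ``mode='variance_fixed_mean'``: theta = v with the mean held fixed, so
    ``dR1 = 0`` and ``dR2 = (Z' ⊗ 1_s)``.  Not available for Bernoulli
    rewards, whose mean pins the variance.

    ``mode='linked'``: theta = f1 with higher moments sliding along the
    parametric family.  Poisson gives

        dR2 = [I + 2 D(vec R1)] (Z' ⊗ 1_s)
        dR3 = [I + 6 D(vec R1) + 3 D(vec R1∘R1)] (Z' ⊗ 1_s),

    while Bernoulli gives equal derivatives at every order.
    """
    tau = fert.tau
    s = tau + alpha
    base = _fertility_column_basis(tau, alpha, fert.require_parental_survival)
    zeros_dU = np.zeros((tau * tau, tau))
    if mode == "mean_fixed_variance":
        # column j of dR2 is 2 f1_j times column j of the basis
        dR = {1: base, 2: base * (2.0 * fert.f1)[None, :]}
        return PerturbationMap(
            theta=fert.f1.copy(), dU=zeros_dU, dR=dR,
            tau=tau, alpha=alpha, labels=[f"f1_{j+1}" for j in range(tau)],
        )
    if mode == "variance_fixed_mean":
        if fert.model == "bernoulli":
            raise ValueError("moments not independent under Bernoulli")
        return PerturbationMap(
            theta=fert.variance.copy(),
            dU=zeros_dU,
            dR={2: base},
            tau=tau,
            alpha=alpha,
            labels=[f"v_{j+1}" for j in range(tau)],
        )
    if mode == "linked":
        if fert.model == "bernoulli":
            dR = {1: base, 2: base.copy(), 3: base.copy()}
        elif fert.model == "poisson":
            R1 = rewards_from_fertility_vector(fert.f1, s, fert.require_parental_survival)
            vR1 = R1.flatten(order="F")
            dR = {
                1: base,
                2: base + 2.0 * vR1[:, None] * base,
                3: base + 6.0 * vR1[:, None] * base + 3.0 * (vR1 * vR1)[:, None] * base,
            }
        else:
            raise ValueError("linked mode requires a bernoulli or poisson fertility model")
        return PerturbationMap(
            theta=fert.f1.copy(), dU=zeros_dU, dR=dR, tau=tau, alpha=alpha,
            labels=[f"f_{j+1}" for j in range(tau)],
        )
    raise ValueError(
        f"unknown mode {mode!r}; choose 'mean_fixed_variance', "
        "'variance_fixed_mean', or 'linked'"
    )
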