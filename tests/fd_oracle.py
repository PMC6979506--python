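"""Central finite-difference oracle for the sensitivity machinery.

Each builder maps a parameter vector to the full forward pipeline
(rebuild U and/or the reward moments, solve the moment recursion, derive
the statistics) so the analytic Kronecker/vec machinery is validated end
to end, including the nonlinear compensated perturbation of the growth
matrix.  The oracle never touches the analytic derivative code.
"""

from __future__ import annotations

import numpy as np

from lro.lifecycle import (
    AgeClassifiedSchedule,
    LifeCycleModel,
    build_age_classified,
    build_markov_chain,
    decompose_stage_model,
)
from lro.moments import lro_moment_vectors, lro_statistics
from lro.rewards import FertilitySchedule
from lro.sensitivity import (
    age_classified_pmap,
    compensated_growth_pmap,
    fertility_pmap,
    moment_sensitivity,
    stage_classified_pmap,
    statistic_sensitivity,
)

STAT_KEYS = ("rho1", "rho2", "var", "sd", "cv", "crow")


def forward_stats(model: LifeCycleModel, fert: FertilitySchedule) -> dict[str, np.ndarray]:
    chain = build_markov_chain(model)
    mv = lro_moment_vectors(chain, fert.reward_moments(model.alpha, m=2))
    st = lro_statistics(mv)
    return {
        "rho1": mv.raw(1),
        "rho2": mv.raw(2),
        "var": st.variance,
        "sd": st.sd,
        "cv": st.cv,
        "crow": st.crow_i,
    }


def analytic_stats(model: LifeCycleModel, fert: FertilitySchedule, pmap) -> dict[str, np.ndarray]:
    chain = build_markov_chain(model)
    rew = fert.reward_moments(model.alpha, m=2)
    mv = lro_moment_vectors(chain, rew)
    res = statistic_sensitivity(moment_sensitivity(chain, rew, pmap, m=2, moments=mv), mv)
    return {
        "rho1": res.d_rho[1],
        "rho2": res.d_rho[2],
        "var": res.d_variance,
        "sd": res.d_sd,
        "cv": res.d_cv,
        "crow": res.d_crow,
    }


def central_fd(build, theta0: np.ndarray) -> dict[str, np.ndarray]:
    """Central differences of the forward pipeline, step 1e-6 * max(1, |theta|)."""
    out = None
    for j in range(theta0.size):
        h = 1e-6 * max(1.0, abs(theta0[j]))
        tp, tm = theta0.copy(), theta0.copy()
        tp[j] += h
        tm[j] -= h
        sp, sm = build(tp), build(tm)
        if out is None:
            out = {k: np.zeros((v.size, theta0.size)) for k, v in sp.items()}
        for k in out:
            out[k][:, j] = (sp[k] - sm[k]) / (2.0 * h)
    return out


def compensated_G_path(G0: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Apply the proportional column-compensated perturbation path to G.

    For each perturbed entry (i, j), the rest of column j is scaled by
    1 - eps/(1 - g_ij) so the column sum stays at 1 exactly.
    """
    tau = G0.shape[0]
    G = G0.copy()
    dth = theta - G0.flatten(order="F")
    for idx in np.flatnonzero(np.abs(dth) > 0):
        i, j = idx % tau, idx // tau
        eps = dth[idx]
        if G0[i, j] >= 1.0 - 1e-12:
            # degenerate column: nothing left to compensate with
            col = G[:, j].copy()
        else:
            col = G[:, j] * (1.0 - eps / (1.0 - G0[i, j]))
        col[i] = G0[i, j] + eps
        G[:, j] = col
    return G


def pmap_cases(model: LifeCycleModel):
    """Yield (name, pmap, fd_builder, theta0) for every perturbation map.

    Fertility-moment modes that a reward family cannot support (variance
    independent of the mean under Bernoulli) are skipped for that family.
    """
    fert = model.fertility
    dec = decompose_stage_model(model.U)
    G, sigma = dec.G, dec.sigma

    def build_mu(th):
        return forward_stats(LifeCycleModel(U=G * np.exp(-th)[None, :]), fert)

    yield "stage_mu", stage_classified_pmap(dec, wrt="mu"), build_mu, dec.mu.copy()

    def build_sigma(th):
        return forward_stats(LifeCycleModel(U=G * th[None, :]), fert)

    yield "stage_sigma", stage_classified_pmap(dec, wrt="sigma"), build_sigma, dec.sigma.copy()

    def build_G(th):
        return forward_stats(LifeCycleModel(U=compensated_G_path(G, th) * sigma[None, :]), fert)

    yield "compensated_G", compensated_growth_pmap(dec), build_G, G.flatten(order="F")

    v0 = fert.variance

    def build_fmean(th):
        fe = FertilitySchedule(th, model="empirical", f2=v0 + th * th)
        return forward_stats(model, fe)

    yield (
        "fert_mean_fixed_variance",
        fertility_pmap(fert, mode="mean_fixed_variance"),
        build_fmean,
        fert.f1.copy(),
    )

    if fert.model != "bernoulli":

        def build_fvar(th):
            fe = FertilitySchedule(fert.f1, model="empirical", f2=th + fert.f1**2)
            return forward_stats(model, fe)

        yield (
            "fert_variance_fixed_mean",
            fertility_pmap(fert, mode="variance_fixed_mean"),
            build_fvar,
            v0.copy(),
        )

    if fert.model in ("poisson", "bernoulli"):

        def build_flink(th):
            return forward_stats(model, FertilitySchedule(th, model=fert.model))

        yield "fert_linked", fertility_pmap(fert, mode="linked"), build_flink, fert.f1.copy()


def age_pmap_cases(model: LifeCycleModel):
    """Age-classified perturbation maps (mu, f) for a subdiagonal model."""
    omega = model.tau
    mu = np.full(omega, 0.5)
    if omega > 1:
        mu[:-1] = -np.log(np.diag(model.U, -1))
    sched = AgeClassifiedSchedule(mu=mu, f=model.fertility.f1)
    fert = model.fertility

    def build_amu(th):
        m2 = build_age_classified(AgeClassifiedSchedule(mu=th, f=sched.f))
        return forward_stats(m2, fert)

    yield "age_mu", age_classified_pmap(sched, wrt="mu"), build_amu, mu.copy()

    def build_af(th):
        return forward_stats(model, FertilitySchedule(th, model="bernoulli"))

    yield "age_f", age_classified_pmap(sched, wrt="f"), build_af, sched.f.copy()


def max_relative_error(analytic: dict, fd: dict, floor: float = 1e-8) -> float:
    """max_ij |analytic - fd| / max(|fd|, floor/rtol) over all statistic blocks."""
    worst = 0.0
    for k in analytic:
        denom = np.maximum(np.abs(fd[k]), floor / 1e-5)
        worst = max(worst, float(np.max(np.abs(analytic[k] - fd[k]) / denom)))
    return worst
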