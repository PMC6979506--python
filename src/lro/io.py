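"""File formats, the bundled hemlock fixture, and a synthetic generator.

Matrix files follow the COMPADRE/COMADRE export convention: plain CSV,
one matrix row per line, no header (``matU.csv`` / ``matF.csv``), with an
optional JSON sidecar carrying stage labels and the number of absorbing
states.  Life tables are CSVs with header columns ``age, mu, fx``.

The bundled fixture is the six-size-class Canadian hemlock (*Tsuga
canadensis*) projection matrix from a low-disturbance plot in Shenandoah
National Park: stasis and growth on the diagonal and subdiagonal of U,
recruitment fertilities 0.30, 0.77, 1.96, 6.03 for size classes 3-6.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lifecycle import (
    AgeClassifiedSchedule,
    LifeCycleModel,
    build_age_classified,
    build_markov_chain,
    decompose_stage_model,
    life_expectancy,
)
from .moments import lro_moment_vectors, lro_statistics, partition_variance
from .rewards import FertilitySchedule

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_projection_matrices",
    "read_life_table",
    "load_tsuga",
    "generate_synthetic_model",
    "AnalysisConfig",
    "run_protocol",
]

logger = logging.getLogger("lro")


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a headerless CSV matrix (one row per line)."""
    arr = pd.read_csv(path, header=None, float_precision="round_trip").to_numpy(dtype=float)
    return np.atleast_2d(arr)


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write a matrix as headerless CSV at full float precision."""
    pd.DataFrame(np.atleast_2d(matrix)).to_csv(
        path, header=False, index=False, float_format="%.17g"
    )


def fertility_from_F(F: np.ndarray) -> np.ndarray:
    """Stage fertility vector as the column sums of the fertility matrix.

    Column sums (rather than the first row alone) support models where
    offspring enter through more than one stage.
    """
    return np.atleast_2d(np.asarray(F, dtype=float)).sum(axis=0)


def read_projection_matrices(
    matU_path: str | Path,
    matF_path: str | Path | None = None,
    sidecar_path: str | Path | None = None,
    reward_model: str = "poisson",
    require_parental_survival: bool = False,
) -> LifeCycleModel:
    """Build a life-cycle model from COMPADRE-style matU/matF CSV files."""
    U = read_matrix(matU_path)
    if U.shape[0] != U.shape[1]:
        raise ValueError(f"invalid transition matrix: matU is not square {U.shape}")
    labels = None
    alpha = 1
    if sidecar_path is not None:
        meta = json.loads(Path(sidecar_path).read_text())
        labels = meta.get("stage_labels")
        alpha = int(meta.get("alpha", 1))
    fert = None
    if matF_path is not None:
        F = read_matrix(matF_path)
        if F.shape != U.shape:
            raise ValueError("shape error: matU and matF dimensions differ")
        fert = FertilitySchedule(
            fertility_from_F(F),
            model=reward_model,
            require_parental_survival=require_parental_survival,
        )
    return LifeCycleModel(U=U, fertility=fert, alpha=alpha, stage_labels=labels)


def read_life_table(path: str | Path, open_final_class: bool = False) -> AgeClassifiedSchedule:
    """Read a life-table CSV with header columns ``age, mu, fx``."""
    df = pd.read_csv(path)
    missing = {"age", "mu", "fx"} - set(df.columns)
    if missing:
        raise ValueError(f"life table missing columns: {sorted(missing)}")
    df = df.sort_values("age")
    return AgeClassifiedSchedule(
        mu=df["mu"].to_numpy(dtype=float),
        f=df["fx"].to_numpy(dtype=float),
        open_final_class=open_final_class,
    )


def load_tsuga(reward_model: str = "poisson") -> LifeCycleModel:
    """The bundled *Tsuga canadensis* six-size-class model."""
    data = resources.files("lro") / "data"
    with resources.as_file(data / "tsuga_matU.csv") as pU, resources.as_file(
        data / "tsuga_matF.csv"
    ) as pF:
        return read_projection_matrices(pU, pF, reward_model=reward_model)


def generate_synthetic_model(
    tau: int,
    seed: int,
    profile: str = "stage_like",
    fertility_model: str = "poisson",
) -> LifeCycleModel:
    """Draw a random valid life cycle for testing and validation.

    ``stage_like`` draws a column-stochastic conditional growth matrix
    (Dirichlet columns shrunk toward uniform, so no entry approaches 1)
    and stage survivals in (0.2, 0.99); the resulting U has spectral
    radius below 1 by construction.  ``age_like`` draws positive age
    hazards and a unimodal fertility window over the ages, with Bernoulli
    rewards.  Fertility means are strictly positive in every stage so that
    CV and Crow's index are defined from every starting stage.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    rng = np.random.default_rng(seed)
    if profile == "stage_like":
        G = rng.dirichlet(np.full(tau, 1.5), size=tau).T
        G = 0.85 * G + 0.15 / tau  # keep every entry well inside (0, 1)
        sigma = rng.uniform(0.2, 0.99, tau)
        U = G * sigma[None, :]
        if fertility_model == "bernoulli":
            f1 = rng.uniform(0.05, 0.95, tau)
        else:
            f1 = rng.uniform(0.1, 2.0, tau)
        if fertility_model == "empirical":
            f1sq = f1 * f1
            f2 = f1sq + rng.uniform(0.1, 1.0, tau)  # positive variance
            fert = FertilitySchedule(f1, model="empirical", f2=f2)
        else:
            fert = FertilitySchedule(f1, model=fertility_model)
        return LifeCycleModel(U=U, fertility=fert)
    if profile == "age_like":
        mu = rng.uniform(0.02, 0.4, tau)
        ages = np.arange(tau)
        center = rng.uniform(0.3, 0.7) * max(tau - 1, 1)
        width = rng.uniform(0.2, 0.5) * max(tau, 1)
        f1 = 0.02 + rng.uniform(0.3, 0.9) * np.exp(-(((ages - center) / width) ** 2))
        f1 = np.clip(f1, 0.01, 0.95)
        schedule = AgeClassifiedSchedule(mu=mu, f=f1)
        return build_age_classified(schedule, model="bernoulli")
    raise ValueError(f"unknown profile {profile!r}; choose 'stage_like' or 'age_like'")


# ---------------------------------------------------------------------------
# analysis protocol


@dataclass
class AnalysisConfig:
    """Configuration for the end-to-end analysis pipeline."""

    matU: str | None = None
    matF: str | None = None
    life_table: str | None = None
    reward_model: str = "poisson"
    moment_order: int = 3
    require_parental_survival: bool = False
    start_stage: int = 1
    output_dir: str | None = None
    seed: int | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(**data)

    def load_model(self) -> LifeCycleModel:
        if self.matU is not None:
            return read_projection_matrices(
                self.matU,
                self.matF,
                reward_model=self.reward_model,
                require_parental_survival=self.require_parental_survival,
            )
        if self.life_table is not None:
            return build_age_classified(read_life_table(self.life_table), model=self.reward_model)
        raise ValueError("config must point at matU/matF or a life table")


def run_protocol(
    config_or_model: AnalysisConfig | LifeCycleModel, moment_order: int = 3
) -> pd.DataFrame:
    """Run the full LRO analysis pipeline and return a summary table.

    Steps: build the absorbing chain, construct reward moments, solve the
    moment recursion, derive the statistics, and partition the variance.
    One row per starting stage with mean, variance, percentage shares, SD,
    CV, Crow's index, and life expectancy.
    """
    if isinstance(config_or_model, AnalysisConfig):
        model = config_or_model.load_model()
        moment_order = config_or_model.moment_order
    else:
        model = config_or_model
    if model.fertility is None:
        raise ValueError("protocol step 2 failed: model has no fertility schedule")
    logger.info("step 1: transition matrix U (%d stages)", model.tau)
    chain = build_markov_chain(model)
    logger.info("step 2-4: reward moments under %s model", model.fertility.model)
    m = min(moment_order, 3)
    rewards = model.fertility.reward_moments(model.alpha, m=max(m, 2))
    logger.info("step 5: moments of LRO up to order %d", rewards.order)
    moments = lro_moment_vectors(chain, rewards)
    logger.info("step 6: statistics of LRO")
    stats = lro_statistics(moments, life_expectancy(chain))
    partition = partition_variance(model, chain=chain)
    out = stats.to_frame()
    out.insert(3, "between_pct", partition.between_pct)
    out.insert(4, "within_pct", partition.within_pct)
    return out
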