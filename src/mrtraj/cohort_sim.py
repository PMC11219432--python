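"""Synthetic cohort generator for the progression-MR simulation study.

Generates, from an instrument table: additive genotype dosages, a continuous
exposure partly explained by the instruments (instrument strength set through
R²), a single confounder explaining half of the exposure's residual variance,
and linear longitudinal trajectories

    y_ij = a0 + u0i + a1*X_i + a2*C_i + (a3 + u1i + a4*X_i + a5*C_i)*t_ij + e_ij

with bivariate-normal random intercepts/slopes (u0i, u1i) and i.i.d. Gaussian
level-1 residuals.  The defaults mirror an MDS-UPDRS-III-like motor outcome in
Parkinson's disease: population intercept ~24 points, slope ~2.25 points/year,
random-effects covariance [[88.9, -6.0], [-6.0, 4.6]], residual variance 51.9.

The exposure and confounder are standardised to unit *expected* SD, so the
causal effects a1 (on the intercept) and a4 (on the slope) are per-SD effects
and are the same estimands whether the instruments explain 2% or 10% of the
exposure variance.  The standardised per-allele instrument effects needed by
the MR stage are returned in a :class:`ScalingReport`.

All randomness flows from a single seed through named substreams, so any
component can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .instruments import InstrumentTable, genetic_variance, synthesize_instruments

__all__ = [
    "BalancedSchedule",
    "UnbalancedSchedule",
    "ScenarioConfig",
    "GenotypeMatrix",
    "LongitudinalData",
    "ScalingReport",
    "Cohort",
    "simulate_genotypes",
    "simulate_exposure_confounder",
    "simulate_visit_schedule",
    "simulate_trajectories",
    "simulate_cohort",
    "substream_rng",
]

# Named substreams hanging off the scenario seed.  Fixed indices keep every
# component reproducible in isolation.
_STREAMS = {
    "instruments": 0,
    "genotypes": 1,
    "confounder": 2,
    "exposure_noise": 3,
    "schedule": 4,
    "random_effects": 5,
    "residuals": 6,
}


def substream_rng(seed: int, name: str) -> np.random.Generator:
    """Generator for a named substream of the scenario seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],))
    )


@dataclass(frozen=True)
class BalancedSchedule:
    """Every individual observed at the same fixed visit times."""

    times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)


@dataclass(frozen=True)
class UnbalancedSchedule:
    """Random visit counts, baseline times, and inter-visit gaps.

    Defaults follow the sensitivity design: 1/2/3/4 visits with probabilities
    0.2/0.3/0.3/0.2, baseline time uniform on [0, 3.5] (recruitment within 3.5
    years of diagnosis), gaps uniform on [1.4, 1.6] (~18-month follow-up).
    """

    count_probs: tuple[float, ...] = (0.2, 0.3, 0.3, 0.2)
    baseline_range: tuple[float, float] = (0.0, 3.5)
    gap_range: tuple[float, float] = (1.4, 1.6)

    def __post_init__(self) -> None:
        if abs(sum(self.count_probs) - 1.0) > 1e-12:
            raise ValueError("visit-count probabilities must sum to 1")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterisation of one simulated cohort.

    Fixed effects (per-SD where they multiply X or C):
    ``alpha0`` intercept grand mean, ``alpha1`` exposure->intercept,
    ``alpha2`` confounder->intercept, ``alpha3`` slope grand mean,
    ``alpha4`` exposure->slope, ``alpha5`` confounder->slope.
    """

    alpha0: float = 24.0
    alpha1: float = 2.0
    alpha2: float = 1.0
    alpha3: float = 2.25
    alpha4: float = 0.45
    alpha5: float = 0.225
    re_cov: np.ndarray = field(
        default_factory=lambda: np.array([[88.9, -6.0], [-6.0, 4.6]])
    )
    resid_var: float = 51.9
    r2: float = 0.10
    n_individuals: int = 10_000
    schedule: BalancedSchedule | UnbalancedSchedule = field(
        default_factory=BalancedSchedule
    )
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        re_cov = np.asarray(self.re_cov, dtype=float)
        if re_cov.shape != (2, 2) or not np.allclose(re_cov, re_cov.T):
            raise ValueError("re_cov must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(re_cov) <= 0):
            raise ValueError("re_cov must be positive-definite")
        if self.resid_var <= 0:
            raise ValueError("resid_var must be > 0")
        if not (0.0 < self.r2 < 1.0):
            raise ValueError("r2 must lie in (0, 1)")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        object.__setattr__(self, "re_cov", re_cov)

    @property
    def truth(self) -> tuple[float, float]:
        """True (exposure->intercept, exposure->slope) causal effects."""
        return (self.alpha1, self.alpha4)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x SNPs additive dosage matrix with entries in {0, 1, 2}."""

    values: np.ndarray
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2 or values.shape[1] != len(self.snp_ids):
            raise ValueError("values must be n_individuals x n_snps")
        if not np.isin(values, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")
        object.__setattr__(self, "values", values)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.snp_ids))
        df.insert(0, "id", np.arange(self.values.shape[0]))
        return df


@dataclass(frozen=True)
class LongitudinalData:
    """Long-format outcome records plus per-individual covariates.

    ``records`` has columns ``id``, ``time``, ``y`` (one row per visit);
    ``covariates`` has one row per individual with columns ``id``, ``x``
    (exposure, SD units) and ``c`` (confounder, SD units).
    """

    records: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        rec = self.records
        for col in ("id", "time", "y"):
            if col not in rec.columns:
                raise ValueError(f"records missing column {col!r}")
        if (rec["time"] < 0).any():
            raise ValueError("times must be non-negative")
        # strictly increasing within individual
        d = rec.groupby("id", sort=False)["time"].diff()
        if (d.dropna() <= 0).any():
            raise ValueError("times must be strictly increasing within individual")

    @property
    def n_individuals(self) -> int:
        return self.records["id"].nunique()

    @property
    def n_records(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ScalingReport:
    """How the raw exposure was standardised.

    ``sd_expected`` is the expected SD of the raw exposure,
    sqrt(genetic_variance / r2); ``gamma_std`` are the per-allele instrument
    effects on the *standardised* exposure, γk / sd_expected — these are the
    SNP-exposure effects the MR stage must use for per-SD causal estimates.
    """

    sd_expected: float
    gamma_std: np.ndarray
    confounder_coef: float
    noise_var: float


@dataclass(frozen=True)
class Cohort:
    """One fully simulated cohort, ready for the per-SNP modelling stage."""

    config: ScenarioConfig
    instruments: InstrumentTable
    genotypes: GenotypeMatrix
    exposure: np.ndarray
    confounder: np.ndarray
    data: LongitudinalData
    scaling: ScalingReport


def simulate_genotypes(table: InstrumentTable, n: int, seed: int) -> GenotypeMatrix:
    """Draw additive dosages, entry (i, k) ~ Binomial(2, eaf_k), independently."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = substream_rng(seed, "genotypes")
    values = rng.binomial(2, table.eaf, size=(n, len(table))).astype(np.int8)
    return GenotypeMatrix(values=values, snp_ids=table.snp_id)


def simulate_exposure_confounder(
    table: InstrumentTable,
    G: GenotypeMatrix,
    r2: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, ScalingReport]:
    """Build the exposure and confounder at instrument strength ``r2``.

    The raw exposure is Σk γk·Gik plus residual variance
    v_resid = genetic_variance·(1−r2)/r2, half contributed by a standard-normal
    confounder (coefficient b = sqrt(v_resid/2)) and half by independent noise.
    The returned exposure is divided by its expected SD, sqrt(genetic_variance/r2),
    so it has unit expected SD; the confounder is already standard normal.
    """
    if not (0.0 < r2 < 1.0):
        raise ValueError("r2 must lie in (0, 1)")
    if G.n_snps != len(table):
        raise ValueError("genotype columns do not match instrument table")
    gv = genetic_variance(table)
    v_resid = gv * (1.0 - r2) / r2
    b = np.sqrt(0.5 * v_resid)
    noise_var = 0.5 * v_resid
    c_raw = substream_rng(seed, "confounder").standard_normal(G.n_individuals)
    noise = substream_rng(seed, "exposure_noise").standard_normal(G.n_individuals)
    x_raw = G.values @ table.gamma + b * c_raw + np.sqrt(noise_var) * noise
    sd_expected = np.sqrt(gv / r2)
    report = ScalingReport(
        sd_expected=float(sd_expected),
        gamma_std=table.gamma / sd_expected,
        confounder_coef=float(b),
        noise_var=float(noise_var),
    )
    return x_raw / sd_expected, c_raw, report


def simulate_visit_schedule(
    schedule: BalancedSchedule | UnbalancedSchedule,
    n_individuals: int,
    seed: int,
) -> list[np.ndarray]:
    """Per-individual visit-time arrays under a balanced or unbalanced design."""
    if isinstance(schedule, BalancedSchedule):
        times = np.asarray(schedule.times, dtype=float)
        return [times] * n_individuals
    rng = substream_rng(seed, "schedule")
    counts = rng.choice(
        np.arange(1, len(schedule.count_probs) + 1),
        size=n_individuals,
        p=schedule.count_probs,
    )
    baselines = rng.uniform(*schedule.baseline_range, size=n_individuals)
    out: list[np.ndarray] = []
    for i in range(n_individuals):
        gaps = rng.uniform(*schedule.gap_range, size=counts[i] - 1)
        out.append(baselines[i] + np.concatenate(([0.0], np.cumsum(gaps))))
    return out


def simulate_trajectories(
    x: np.ndarray,
    c: np.ndarray,
    schedule: Sequence[np.ndarray],
    config: ScenarioConfig,
    seed: int,
) -> LongitudinalData:
    """Simulate outcomes along each individual's visit schedule."""
    n = len(x)
    if not (len(c) == len(schedule) == n):
        raise ValueError("x, c and schedule must be aligned by individual")
    chol = np.linalg.cholesky(config.re_cov)
    u = substream_rng(seed, "random_effects").standard_normal((n, 2)) @ chol.T
    counts = np.fromiter((len(t) for t in schedule), dtype=int, count=n)
    t_all = np.concatenate(schedule) if n else np.empty(0)
    ids = np.repeat(np.arange(n), counts)
    eps = substream_rng(seed, "residuals").standard_normal(t_all.size) * np.sqrt(
        config.resid_var
    )
    intercept_i = config.alpha0 + u[:, 0] + config.alpha1 * x + config.alpha2 * c
    slope_i = config.alpha3 + u[:, 1] + config.alpha4 * x + config.alpha5 * c
    y = intercept_i[ids] + slope_i[ids] * t_all + eps
    records = pd.DataFrame({"id": ids, "time": t_all, "y": y})
    covariates = pd.DataFrame({"id": np.arange(n), "x": x, "c": c})
    return LongitudinalData(records=records, covariates=covariates)


def simulate_cohort(
    config: ScenarioConfig,
    instruments: InstrumentTable | None = None,
    seed: int | None = None,
) -> Cohort:
    """Run the full data-generating mechanism for one cohort.

    If no instrument table is supplied, a 97-SNP synthetic table is drawn from
    the ``instruments`` substream of the seed.  The seed defaults to
    ``config.seed``.
    """
    if seed is None:
        seed = config.seed
    if instruments is None:
        instruments = synthesize_instruments(
            seed=int(substream_rng(seed, "instruments").integers(2**31))
        )
    G = simulate_genotypes(instruments, config.n_individuals, seed)
    x, c, scaling = simulate_exposure_confounder(instruments, G, config.r2, seed)
    schedule = simulate_visit_schedule(config.schedule, config.n_individuals, seed)
    data = simulate_trajectories(x, c, schedule, config, seed)
    return Cohort(
        config=config,
        instruments=instruments,
        genotypes=G,
        exposure=x,
        confounder=c,
        data=data,
        scaling=scaling,
    )
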