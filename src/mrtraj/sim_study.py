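"""ADEMP simulation harness: scenarios, replicates, and performance tables.

Runs the full pipeline per replicate — simulate a cohort, fit one mixed model
per SNP, estimate the joint causal effect with both the naive (two separate
IVW meta-regressions) and multivariate (stacked GLS) approaches, build
confidence regions — and aggregates bias, empirical SD, mean model SE,
per-dimension coverage, joint coverages (rectangle, naive ellipse,
multivariate ellipse), ellipse areas and the mean SNP-effect correlation
across replicates.

Six scenarios vary the exposure effects and the sign/magnitude of the
random-effects covariance; a sensitivity design uses a smaller cohort with
unbalanced 1-4 visit follow-up.  The instrument table is drawn once per study
and held fixed across replicates: in a two-sample design the GWAS
SNP-exposure effects are constants of the design, not re-sampled per cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_sim import (
    BalancedSchedule,
    Cohort,
    ScenarioConfig,
    UnbalancedSchedule,
    simulate_cohort,
)
from .instruments import InstrumentTable, synthesize_instruments
from .mlm_fit import fit_all_snps
from .mr_estimators import MrEstimate, mvmr_fixed, naive_estimate
from .regions import (
    confidence_interval,
    ellipse_area,
    joint_ellipse,
    joint_rectangle,
    region_contains,
)

__all__ = [
    "SCENARIO_NAMES",
    "scenario_registry",
    "ReplicateRecord",
    "PerformanceTable",
    "run_replicate",
    "run_study",
    "report_tables",
    "monte_carlo_se",
]

logger = logging.getLogger(__name__)

SCENARIO_NAMES = tuple(f"scenario{i}" for i in range(1, 7)) + ("sensitivity",)

_BASE_RE_COV = np.array([[88.9, -6.0], [-6.0, 4.6]])

# Fixed-effect deviations from the scenario-1 baseline.  Scenario 3 removes
# the exposure *and* confounder effects on the slope; scenario 4 removes both
# effects on the intercept.
_SCENARIO_OVERRIDES: dict[str, dict] = {
    "scenario1": {},
    "scenario2": {"alpha4": 0.25, "alpha5": 0.125},
    "scenario3": {"alpha4": 0.0, "alpha5": 0.0},
    "scenario4": {"alpha1": 0.0, "alpha2": 0.0},
    "scenario5": {"re_cov": np.array([[88.9, 6.0], [6.0, 4.6]])},
    "scenario6": {"re_cov": np.array([[88.9, 12.0], [12.0, 4.6]])},
}


def scenario_registry(
    name: str,
    r2: float = 0.10,
    n_individuals: int | None = None,
    seed: int = 0,
) -> ScenarioConfig:
    """Return the configuration of a named scenario.

    Scenarios 1-6 default to 10,000 individuals with balanced visits at
    0..6; the sensitivity design uses 1,000 individuals and unbalanced 1-4
    visit follow-up with scenario-1 effects at R² = 10%.  ``n_individuals``
    may be overridden for reduced-scale runs.
    """
    if name not in SCENARIO_NAMES:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    if name == "sensitivity":
        return ScenarioConfig(
            r2=0.10 if r2 is None else r2,
            n_individuals=1_000 if n_individuals is None else n_individuals,
            schedule=UnbalancedSchedule(),
            seed=seed,
            name=name,
        )
    kw = dict(_SCENARIO_OVERRIDES[name])
    return ScenarioConfig(
        r2=r2,
        n_individuals=10_000 if n_individuals is None else n_individuals,
        schedule=BalancedSchedule(),
        seed=seed,
        name=name,
        **kw,
    )


@dataclass(frozen=True)
class ReplicateRecord:
    """Outcome of one simulation replicate."""

    scenario: str
    replicate_seed: int
    naive: MrEstimate
    multivariate: MrEstimate
    mean_correlation: float
    contains: dict[str, bool]
    area_naive_ellipse: float
    area_mv_ellipse: float
    n_excluded: int
    failed: bool = False
    error: str | None = None


#: Containment-flag keys recorded per replicate.
_FLAG_KEYS = (
    "naive_int_ci",
    "naive_slope_ci",
    "mv_int_ci",
    "mv_slope_ci",
    "rectangle",
    "naive_ellipse",
    "mv_ellipse",
)


def analyse_cohort(cohort: Cohort) -> tuple[MrEstimate, MrEstimate, float, int]:
    """Per-SNP mixed models then both MR estimators on one cohort.

    Returns (naive, multivariate, mean SNP-effect correlation, n excluded).
    The SNP-exposure effects used are the standardised per-allele effects,
    so estimates are per exposure-SD.
    """
    pairs = fit_all_snps(cohort.data, cohort.genotypes)
    gammas = cohort.scaling.gamma_std
    usable = [p for p in pairs if p.usable]
    mean_corr = float(np.mean([p.correlation for p in usable]))
    naive = naive_estimate(gammas, pairs)
    mv = mvmr_fixed(gammas, pairs)
    return naive, mv, mean_corr, len(pairs) - len(usable)


def run_replicate(
    config: ScenarioConfig,
    replicate_seed: int,
    instruments: InstrumentTable | None = None,
    level: float = 0.95,
) -> ReplicateRecord:
    """Run the full pipeline on one simulated cohort.

    Deterministic given (config, instruments, replicate_seed); containment
    flags are evaluated against the generating truth (alpha1, alpha4).
    """
    truth = np.array(config.truth)
    try:
        cohort = simulate_cohort(config, instruments=instruments, seed=replicate_seed)
        naive, mv, mean_corr, n_excl = analyse_cohort(cohort)
    except Exception as exc:  # identifiability failures are recorded, not fatal
        logger.warning("replicate seed %d failed: %s", replicate_seed, exc)
        nan_est = MrEstimate(
            a_int=np.nan, a_slope=np.nan, vcov=np.zeros((2, 2)),
            method="naive", n_snps_used=0,
        )
        return ReplicateRecord(
            scenario=config.name,
            replicate_seed=replicate_seed,
            naive=nan_est,
            multivariate=nan_est,
            mean_correlation=np.nan,
            contains={k: False for k in _FLAG_KEYS},
            area_naive_ellipse=np.nan,
            area_mv_ellipse=np.nan,
            n_excluded=0,
            failed=True,
            error=str(exc),
        )
    rect = joint_rectangle(naive, level=level)
    ell_naive = joint_ellipse(naive, level=level, zero_covariance=True)
    ell_mv = joint_ellipse(mv, level=level)
    contains = {
        "naive_int_ci": _ci_contains(naive.a_int, naive.se_int, truth[0], level),
        "naive_slope_ci": _ci_contains(naive.a_slope, naive.se_slope, truth[1], level),
        "mv_int_ci": _ci_contains(mv.a_int, mv.se_int, truth[0], level),
        "mv_slope_ci": _ci_contains(mv.a_slope, mv.se_slope, truth[1], level),
        "rectangle": region_contains(rect, truth),
        "naive_ellipse": region_contains(ell_naive, truth),
        "mv_ellipse": region_contains(ell_mv, truth),
    }
    return ReplicateRecord(
        scenario=config.name,
        replicate_seed=replicate_seed,
        naive=naive,
        multivariate=mv,
        mean_correlation=mean_corr,
        contains=contains,
        area_naive_ellipse=ellipse_area(ell_naive),
        area_mv_ellipse=ellipse_area(ell_mv),
        n_excluded=n_excl,
    )


def _ci_contains(est: float, se: float, truth: float, level: float) -> bool:
    lo, hi = confidence_interval(est, se, level)
    return lo <= truth <= hi


def monte_carlo_se(empirical_sd: float, n_reps: int) -> float:
    """Monte Carlo standard error of a replicate mean: SD / sqrt(n)."""
    return empirical_sd / np.sqrt(n_reps)


@dataclass(frozen=True)
class PerformanceTable:
    """Aggregated performance metrics for one scenario run.

    ``metrics`` has one row per method x dimension with columns
    estimate_mean, empirical_sd, mean_model_se, coverage, bias, bias_mcse,
    relative_bias (NaN when the truth is zero); ``joint`` holds the three
    joint coverages and mean ellipse areas.
    """

    scenario: str
    r2: float
    n_individuals: int
    n_reps: int
    n_failed: int
    truth: tuple[float, float]
    metrics: pd.DataFrame
    joint: dict[str, float]
    correlation_mean: float
    correlation_sd: float

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        meta = {
            "scenario": self.scenario,
            "r2": self.r2,
            "n_individuals": self.n_individuals,
            "n_reps": self.n_reps,
            "n_failed": self.n_failed,
            "truth_int": self.truth[0],
            "truth_slope": self.truth[1],
            "correlation_mean": self.correlation_mean,
            "correlation_sd": self.correlation_sd,
        }
        metrics = self.metrics.assign(**meta)
        joint = pd.DataFrame([{**meta, **self.joint}])
        return metrics, joint


def summarise(records: list[ReplicateRecord], config: ScenarioConfig) -> PerformanceTable:
    """Aggregate replicate records into the performance table."""
    ok = [r for r in records if not r.failed]
    n_failed = len(records) - len(ok)
    if n_failed:
        logger.warning("%d of %d replicates failed", n_failed, len(records))
    if len(ok) < 2:
        raise ValueError("need at least 2 successful replicates")
    n = len(ok)
    truth = config.truth
    rows = []
    for method in ("naive", "multivariate"):
        for dim, tval in zip(("intercept", "slope"), truth):
            est = np.array(
                [getattr(r, method).a_int if dim == "intercept" else getattr(r, method).a_slope for r in ok]
            )
            se = np.array(
                [getattr(r, method).se_int if dim == "intercept" else getattr(r, method).se_slope for r in ok]
            )
            flag_key = ("naive" if method == "naive" else "mv") + (
                "_int_ci" if dim == "intercept" else "_slope_ci"
            )
            cov = float(np.mean([r.contains[flag_key] for r in ok]))
            sd = float(np.std(est, ddof=1))
            bias = float(np.mean(est) - tval)
            rows.append(
                {
                    "method": method,
                    "dimension": dim,
                    "truth": tval,
                    "estimate_mean": float(np.mean(est)),
                    "empirical_sd": sd,
                    "mean_model_se": float(np.mean(se)),
                    "coverage": cov,
                    "coverage_mcse": float(np.sqrt(cov * (1 - cov) / n)),
                    "bias": bias,
                    "bias_mcse": monte_carlo_se(sd, n),
                    "relative_bias": bias / tval if tval != 0 else np.nan,
                }
            )
    corrs = np.array([r.mean_correlation for r in ok])
    joint = {
        "rectangle_coverage": float(np.mean([r.contains["rectangle"] for r in ok])),
        "naive_ellipse_coverage": float(
            np.mean([r.contains["naive_ellipse"] for r in ok])
        ),
        "mv_ellipse_coverage": float(np.mean([r.contains["mv_ellipse"] for r in ok])),
        "mean_area_naive_ellipse": float(np.mean([r.area_naive_ellipse for r in ok])),
        "mean_area_mv_ellipse": float(np.mean([r.area_mv_ellipse for r in ok])),
    }
    return PerformanceTable(
        scenario=config.name,
        r2=config.r2,
        n_individuals=config.n_individuals,
        n_reps=n,
        n_failed=n_failed,
        truth=truth,
        metrics=pd.DataFrame(rows),
        joint=joint,
        correlation_mean=float(np.mean(corrs)),
        correlation_sd=float(np.std(corrs, ddof=1)),
    )


@dataclass
class StudyResult:
    config: ScenarioConfig
    instruments: InstrumentTable
    records: list[ReplicateRecord]
    table: PerformanceTable


def run_study(
    config: ScenarioConfig,
    n_reps: int,
    base_seed: int,
    instruments: InstrumentTable | None = None,
    progress: bool = False,
) -> StudyResult:
    """Run ``n_reps`` replicates of a scenario and aggregate them.

    Replicate seeds are base_seed + replicate index.  The instrument table is
    synthesised once from the base seed (unless supplied) and held fixed
    across replicates.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if instruments is None:
        instruments = synthesize_instruments(seed=base_seed)
    records = []
    for i in range(n_reps):
        records.append(run_replicate(config, base_seed + i, instruments=instruments))
        if progress and (i + 1) % 10 == 0:
            logger.info("%s: replicate %d/%d done", config.name, i + 1, n_reps)
    return StudyResult(
        config=config,
        instruments=instruments,
        records=records,
        table=summarise(records, config),
    )


def replicates_frame(records: list[ReplicateRecord]) -> pd.DataFrame:
    """Flatten replicate records to a machine-readable table."""
    rows = []
    for r in records:
        row = {
            "scenario": r.scenario,
            "replicate_seed": r.replicate_seed,
            "failed": r.failed,
            "naive_a_int": r.naive.a_int,
            "naive_a_slope": r.naive.a_slope,
            "naive_se_int": r.naive.se_int,
            "naive_se_slope": r.naive.se_slope,
            "mv_a_int": r.multivariate.a_int,
            "mv_a_slope": r.multivariate.a_slope,
            "mv_se_int": r.multivariate.se_int,
            "mv_se_slope": r.multivariate.se_slope,
            "mv_cov": float(r.multivariate.vcov[0, 1]),
            "mean_correlation": r.mean_correlation,
            "area_naive_ellipse": r.area_naive_ellipse,
            "area_mv_ellipse": r.area_mv_ellipse,
            "n_excluded": r.n_excluded,
        }
        row.update({f"contains_{k}": v for k, v in r.contains.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def report_tables(
    tables: list[PerformanceTable], out_dir: str | Path | None = None
) -> dict[str, pd.DataFrame]:
    """Combine performance tables into metric / joint-coverage / area reports.

    Returns the three frames; if ``out_dir`` is given, also writes
    ``metrics_<scenario>_<r2>.csv`` per table plus ``joint_coverage.csv`` and
    ``areas.csv``.
    """
    if not tables:
        raise ValueError("need at least one performance table")
    metric_frames, joint_frames = zip(*(t.to_frames() for t in tables))
    joint = pd.concat(joint_frames, ignore_index=True)
    areas = joint[
        ["scenario", "r2", "n_reps", "mean_area_naive_ellipse", "mean_area_mv_ellipse"]
    ].copy()
    coverage = joint.drop(columns=["mean_area_naive_ellipse", "mean_area_mv_ellipse"])
    out = {"joint_coverage": coverage, "areas": areas}
    for t, mf in zip(tables, metric_frames):
        out[f"metrics_{t.scenario}_{t.r2:g}"] = mf
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
    return out
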