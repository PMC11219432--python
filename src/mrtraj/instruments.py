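"""GWAS instrument tables: the SNP-exposure "first sample" of a two-sample MR design.

An instrument table holds, for each SNP used as an instrumental variable, its
effect-allele frequency and its per-effect-allele association with the exposure
(``gamma``, in exposure units per allele).  Tables can be read from TSV files,
or synthesised for simulation work: the Locke et al. BMI GWAS that motivates
the default 97-instrument design is not redistributable here, so
:func:`synthesize_instruments` draws a seeded stand-in with the same structure
(97 independent SNPs, right-skewed per-allele effects, documented total
genetic variance).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "InstrumentTable",
    "InstrumentValidationError",
    "MissingColumnError",
    "DuplicateSnpIdError",
    "AlleleFrequencyError",
    "EmptyTableError",
    "load_instruments",
    "write_instruments",
    "synthesize_instruments",
    "genetic_variance",
    "DEFAULT_N_SNPS",
    "DEFAULT_GENETIC_VARIANCE",
]

#: Number of instruments in the default simulated design (97 GWAS hits).
DEFAULT_N_SNPS = 97

#: Total genetic variance of the exposure, Σ γk²·2·p·(1−p), that
#: :func:`synthesize_instruments` rescales its per-allele effects to hit.
#: Exposure units are arbitrary in simulation (the cohort simulator
#: standardises the exposure), so only the ratio to the residual variance,
#: set through R², matters.
DEFAULT_GENETIC_VARIANCE = 0.05


class InstrumentValidationError(ValueError):
    """Base class for instrument-table validation failures."""


class MissingColumnError(InstrumentValidationError):
    """A required column is absent from the input file."""


class DuplicateSnpIdError(InstrumentValidationError):
    """Two rows share a SNP identifier."""


class AlleleFrequencyError(InstrumentValidationError):
    """An effect-allele frequency lies outside the open interval (0, 1)."""


class EmptyTableError(InstrumentValidationError):
    """The table contains no instruments."""


REQUIRED_COLUMNS = ("snp_id", "eaf", "gamma")


@dataclass(frozen=True)
class InstrumentTable:
    """Validated table of genetic instruments.

    Parameters
    ----------
    snp_id:
        Unique, non-empty SNP identifiers, in file/definition order.
    eaf:
        Effect-allele frequencies, each strictly inside (0, 1).
    gamma:
        Per-effect-allele effect on the exposure (exposure units/allele).
    """

    snp_id: np.ndarray
    eaf: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        snp_id = np.asarray(self.snp_id, dtype=object)
        eaf = np.asarray(self.eaf, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float)
        if not (len(snp_id) == len(eaf) == len(gamma)):
            raise InstrumentValidationError("snp_id, eaf and gamma must have equal length")
        if any(not str(s) for s in snp_id):
            raise InstrumentValidationError("empty snp_id")
        if len(set(map(str, snp_id))) != len(snp_id):
            seen: set[str] = set()
            dupes = sorted({str(s) for s in snp_id if str(s) in seen or seen.add(str(s))})
            raise DuplicateSnpIdError(f"duplicated snp_id values: {dupes}")
        bad = np.flatnonzero(~((eaf > 0.0) & (eaf < 1.0)))
        if bad.size:
            raise AlleleFrequencyError(
                f"eaf must lie strictly in (0, 1); offending rows (0-based): {bad.tolist()}"
            )
        if not np.all(np.isfinite(gamma)):
            raise InstrumentValidationError("gamma values must be finite")
        object.__setattr__(self, "snp_id", snp_id)
        object.__setattr__(self, "eaf", eaf)
        object.__setattr__(self, "gamma", gamma)

    def __len__(self) -> int:
        return len(self.snp_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_id, "eaf": self.eaf, "gamma": self.gamma}
        )


def load_instruments(path: str | Path) -> InstrumentTable:
    """Read a tab-separated instrument table.

    The file must have a header with columns ``snp_id``, ``eaf`` and
    ``gamma``; extra columns are ignored and lines starting with ``#`` are
    treated as comments.  Row order is preserved.  Invalid rows cause the
    whole file to be rejected (never silently dropped).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"missing required column(s): {missing}")
    return InstrumentTable(
        snp_id=df["snp_id"].astype(str).to_numpy(dtype=object),
        eaf=df["eaf"].to_numpy(dtype=float),
        gamma=df["gamma"].to_numpy(dtype=float),
    )


def write_instruments(table: InstrumentTable, path: str | Path) -> None:
    """Write a table as the canonical TSV interchange format."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def synthesize_instruments(
    n_snps: int = DEFAULT_N_SNPS,
    seed: int = 0,
    target_variance: float = DEFAULT_GENETIC_VARIANCE,
) -> InstrumentTable:
    """Draw a seeded synthetic instrument table.

    Effect-allele frequencies are uniform on [0.05, 0.95].  Per-allele effect
    magnitudes are drawn from a right-skewed Gamma(shape=2) distribution —
    GWAS hit effect sizes are strongly right-skewed — given random signs, and
    rescaled deterministically so that the table's total genetic variance
    (:func:`genetic_variance`) equals ``target_variance`` exactly.

    Deterministic given ``seed``.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(101,)))
    eaf = rng.uniform(0.05, 0.95, size=n_snps)
    magnitude = rng.gamma(shape=2.0, scale=1.0, size=n_snps)
    sign = rng.choice([-1.0, 1.0], size=n_snps)
    raw = sign * magnitude
    raw_var = float(np.sum(raw**2 * 2.0 * eaf * (1.0 - eaf)))
    gamma = raw * np.sqrt(target_variance / raw_var)
    width = len(str(n_snps))
    snp_id = np.array([f"snp{i + 1:0{width}d}" for i in range(n_snps)], dtype=object)
    return InstrumentTable(snp_id=snp_id, eaf=eaf, gamma=gamma)


def genetic_variance(table: InstrumentTable) -> float:
    """Expected exposure variance explained by the instruments.

    For independent SNPs with additive dosages G ~ Binomial(2, p), the
    variance contributed by SNP k is γk²·Var(G) = γk²·2·p·(1−p); the total is
    the sum over SNPs.
    """
    if len(table) == 0:
        raise EmptyTableError("cannot compute genetic variance of an empty table")
    return float(np.sum(table.gamma**2 * 2.0 * table.eaf * (1.0 - table.eaf)))
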