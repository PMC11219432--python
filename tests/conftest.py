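import numpy as np
import pytest

from mrtraj.cohort_sim import simulate_cohort
from mrtraj.instruments import InstrumentTable, synthesize_instruments
from mrtraj.sim_study import scenario_registry


@pytest.fixture(scope="session")
def tiny_table() -> InstrumentTable:
    return InstrumentTable(
        snp_id=np.array(["rs1", "rs2", "rs3"], dtype=object),
        eaf=np.array([0.2, 0.5, 0.8]),
        gamma=np.array([0.3, -0.1, 0.2]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small scenario-1 cohort (150 individuals, 5 SNPs) for model tests."""
    cfg = scenario_registry("scenario1", r2=0.10, n_individuals=150, seed=3)
    inst = synthesize_instruments(n_snps=5, seed=3)
    return simulate_cohort(cfg, instruments=inst, seed=3)


@pytest.fixture(scope="session")
def unbalanced_cohort():
    """A small sensitivity-design cohort (unbalanced 1-4 visits)."""
    cfg = scenario_registry("sensitivity", n_individuals=200, seed=5)
    inst = synthesize_instruments(n_snps=4, seed=5)
    return simulate_cohort(cfg, instruments=inst, seed=5)
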