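import numpy as np
import pytest

from selectmr import (
    PhenotypeConfig,
    SnpPanel,
    SurvivalConfig,
    random_panel,
)
from selectmr.harmonize import HarmonizedInstrument


@pytest.fixture(scope="session")
def panel() -> SnpPanel:
    """Ten independent instruments for e1 with MAF ~ U(0.1, 0.5)."""
    return random_panel(n_snps=10, exposures=("e1",), seed=0)


@pytest.fixture(scope="session")
def trio_panel() -> SnpPanel:
    """Twelve instruments split 5/4/3 over e1/e2/e3."""
    return random_panel(
        n_snps=12, exposures=("e1", "e2", "e3"), seed=0, snps_per_exposure=(5, 4, 3)
    )


@pytest.fixture
def pheno() -> PhenotypeConfig:
    return PhenotypeConfig(beta_e1d=0.3)


@pytest.fixture
def null_surv() -> SurvivalConfig:
    return SurvivalConfig()


def random_instruments(rng: np.random.Generator, k: int = 8, true_beta: float = 0.3):
    """Random harmonized instrument sets for estimator-vs-oracle checks."""
    bx = rng.uniform(0.05, 0.5, k) * rng.choice([-1.0, 1.0], k)
    sx = rng.uniform(0.005, 0.02, k)
    sy = rng.uniform(0.01, 0.05, k)
    by = true_beta * bx + rng.normal(0.0, sy)
    return [
        HarmonizedInstrument(f"rs{j}", bx[j], sx[j], by[j], sy[j]) for j in range(k)
    ]
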