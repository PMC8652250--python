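"""Packaged miniature scenarios for tests, docs and smoke runs.

Each scenario is a fully deterministic bundle (configs, two selected
cohorts, exposure and outcome summary tables) small enough to regenerate
in well under a second.  Panel sizes follow the applied-example scale of
roughly a dozen instruments split across exposures.
"""

from __future__ import annotations

from .config import PhenotypeConfig, SurvivalConfig, config_digest, random_panel
from .cohort import select_survivors, simulate_cohort
from .errors import ConfigError
from .gwas import generate_two_samples

SCENARIOS = ("no-selection", "fig3-selection", "antagonist-trio")

_N = 5_000  # individuals per cohort in every fixture


def _configs(scenario: str, seed: int):
    if scenario == "no-selection":
        panel = random_panel(n_snps=10, exposures=("e1",), seed=seed)
        pheno = PhenotypeConfig(beta_e1d=0.3)
        surv = SurvivalConfig()
    elif scenario == "fig3-selection":
        panel = random_panel(n_snps=10, exposures=("e1",), seed=seed)
        pheno = PhenotypeConfig(beta_e1d=0.3)
        surv = SurvivalConfig(hr_gs=1.5, hr_ds=2.0)
    elif scenario == "antagonist-trio":
        # primary e1, antagonist e2 (opposite causal sign, coupled
        # residuals), validated positive control e3; every instrument
        # loads on the shared survival score
        panel = random_panel(
            n_snps=12, exposures=("e1", "e2", "e3"), seed=seed,
            snps_per_exposure=(5, 4, 3),
        )
        pheno = PhenotypeConfig(
            beta_e1d=0.3, beta_e2d=-0.3, beta_e3d=0.3, antagonist_rho=-0.5
        )
        surv = SurvivalConfig(hr_gs=2.0, hr_ds=2.0)
    else:
        raise ConfigError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    return panel, pheno, surv


def make_fixture(scenario: str, seed: int = 0) -> dict:
    """Build a named scenario bundle.

    Returns a dict with keys ``panel``, ``pheno``, ``surv``,
    ``cohort_exposure``, ``cohort_outcome`` (both post-selection),
    ``exposure_tables`` (label -> SummaryStatsTable), ``outcome_table``
    and ``digest``.  Identical (scenario, seed) give identical bundles.
    """
    panel, pheno, surv = _configs(scenario, seed)
    exposure_tables, outcome_table = generate_two_samples(
        panel, pheno, surv, _N, _N, seed
    )
    cohort_exp = select_survivors(simulate_cohort(panel, pheno, surv, _N, seed + 1))
    cohort_out = select_survivors(simulate_cohort(panel, pheno, surv, _N, seed + 2))
    return {
        "scenario": scenario,
        "panel": panel,
        "pheno": pheno,
        "surv": surv,
        "cohort_exposure": cohort_exp,
        "cohort_outcome": cohort_out,
        "exposure_tables": exposure_tables,
        "outcome_table": outcome_table,
        "digest": config_digest(panel, pheno, surv, {"scenario": scenario, "seed": seed}),
    }
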