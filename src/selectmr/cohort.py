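"""Individual-level population simulation with survival selection.

The generative model: independent SNPs under Hardy–Weinberg, a measured
confounder C and an unmeasured confounder U (both standard normal), a
competing-risk liability CR driven by U, three standardized exposures with
instrument-explained variance ``r2_ge``, an outcome D (continuous, or
binary realized before recruitment), and an exponential death-time model
whose log hazard is linear in the mean-centered instrument score, E1, C,
D and U.  Individuals whose death time exceeds the one-unit recruitment
horizon are the survivors available for GWAS recruitment — analysing only
them is what induces the selection (collider) bias this package studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import PhenotypeConfig, SnpPanel, SurvivalConfig, config_digest
from .errors import ConfigError, DegenerateSelectionError

TRAITS = ("c", "u", "cr", "e1", "e2", "e3", "d")


@dataclass
class Cohort:
    """Individual-level arrays for one simulated population."""

    genotypes: np.ndarray  # (n, m) allele counts in {0, 1, 2}
    c: np.ndarray
    u: np.ndarray
    cr: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray
    d: np.ndarray
    s: np.ndarray  # survival-to-recruitment indicator in {0, 1}
    panel: SnpPanel
    pheno: PhenotypeConfig
    surv: SurvivalConfig
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def trait(self, label: str) -> np.ndarray:
        if label not in TRAITS:
            raise KeyError(f"unknown trait {label!r}; expected one of {TRAITS}")
        return getattr(self, label)

    def to_frame(self) -> pd.DataFrame:
        cols = {"iid": np.arange(self.n)}
        for j, sid in enumerate(self.panel.snp_id):
            cols[f"g_{sid}"] = self.genotypes[:, j]
        for t in TRAITS:
            cols[t] = self.trait(t)
        cols["s"] = self.s
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _standardized_exposures(
    genotypes: np.ndarray,
    c: np.ndarray,
    panel: SnpPanel,
    pheno: PhenotypeConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Build e1, e2, e3 with unit variance and instrument R^2 = r2_ge.

    gamma is rescaled (preserving relative sizes and signs) so the genetic
    variance of each instrumented exposure is exactly ``r2_ge`` under
    Hardy–Weinberg; the residual variance absorbs the remainder after the
    confounder contribution, and the e1/e2 residuals are coupled at
    ``antagonist_rho``.
    """
    n = genotypes.shape[0]
    var_g = 2.0 * panel.maf * (1.0 - panel.maf)

    # residual draws, coupled for (e1, e2)
    z = {lab: rng.standard_normal(n) for lab in ("e1", "e2", "e3")}
    rho = pheno.antagonist_rho
    z["e2"] = rho * z["e1"] + np.sqrt(max(0.0, 1.0 - rho**2)) * z["e2"]

    out: dict[str, np.ndarray] = {}
    for lab in ("e1", "e2", "e3"):
        gamma = panel.gamma_for(lab)
        genetic_var = float(np.sum(gamma**2 * var_g))
        if genetic_var > 0:
            gamma = gamma * np.sqrt(pheno.r2_ge / genetic_var)
            resid_var = 1.0 - pheno.r2_ge - pheno.phi_c_e**2
        else:
            resid_var = 1.0 - pheno.phi_c_e**2
        if resid_var < 0:
            raise ConfigError(
                f"exposure {lab}: residual variance is negative "
                f"(r2_ge={pheno.r2_ge}, phi_c_e={pheno.phi_c_e})"
            )
        genetic = genotypes @ gamma if genetic_var > 0 else 0.0
        out[lab] = genetic + pheno.phi_c_e * c + np.sqrt(resid_var) * z[lab]
    return out


def _outcome(
    exposures: dict[str, np.ndarray],
    c: np.ndarray,
    u: np.ndarray,
    pheno: PhenotypeConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    lp = (
        pheno.beta_e1d * exposures["e1"]
        + pheno.beta_e2d * exposures["e2"]
        + pheno.beta_e3d * exposures["e3"]
        + pheno.phi_c_d * c
        + pheno.psi_u_d * u
    )
    if pheno.d_type == "continuous":
        return lp + rng.standard_normal(lp.shape[0])
    # binary: logistic link, intercept calibrated so the sample-average
    # event probability equals d_prevalence (disease onset precedes
    # recruitment, so D is realized before selection)
    target = pheno.d_prevalence

    def gap(alpha: float) -> float:
        return float(np.mean(expit(alpha + lp))) - target

    alpha = brentq(gap, -40.0, 40.0)
    return (rng.random(lp.shape[0]) < expit(alpha + lp)).astype(float)


def _survival_probability(
    genotypes: np.ndarray,
    e1: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    u: np.ndarray,
    surv: SurvivalConfig,
) -> np.ndarray:
    """P(death time > 1) under the exponential model, per individual.

    eta is log-linear with per-unit hazard ratios; covariates (including
    the total allele-count score) are sample-mean-centered so that p_sel
    remains the approximate marginal survivor fraction away from the null
    and exactly the marginal fraction at the null.
    """
    score = genotypes.sum(axis=1).astype(float)
    eta = np.zeros(genotypes.shape[0])
    for hr, x in (
        (surv.hr_gs, score),
        (surv.hr_e1s, e1),
        (surv.hr_cs, c),
        (surv.hr_ds, d),
        (surv.hr_us, u),
    ):
        if hr != 1.0:
            eta = eta + np.log(hr) * (x - x.mean())
    return np.exp(-surv.lambda0 * np.exp(eta))


def simulate_cohort(
    panel: SnpPanel,
    pheno: PhenotypeConfig,
    surv: SurvivalConfig,
    n: int,
    seed: int,
) -> Cohort:
    """Simulate ``n`` individuals and their survival-to-recruitment status.

    The survival indicator ``s`` is drawn here but no one is removed;
    :func:`select_survivors` applies the recruitment filter.  Identical
    (config, n, seed) give bitwise-identical cohorts.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    panel.validate()
    pheno.validate()
    surv.validate()
    rng = np.random.default_rng(seed)

    genotypes = rng.binomial(2, panel.maf, size=(n, panel.n_snps)).astype(np.int8)
    c = rng.standard_normal(n)
    u = rng.standard_normal(n)
    cr = pheno.psi_u_cr * u + np.sqrt(1.0 - pheno.psi_u_cr**2) * rng.standard_normal(n)
    exposures = _standardized_exposures(genotypes, c, panel, pheno, rng)
    d = _outcome(exposures, c, u, pheno, rng)
    p_surv = _survival_probability(genotypes, exposures["e1"], c, d, u, surv)
    s = (rng.random(n) < p_surv).astype(np.int8)

    meta = {
        "seed": int(seed),
        "n_original": int(n),
        "config_digest": config_digest(panel, pheno, surv),
        "selected": False,
    }
    return Cohort(
        genotypes=genotypes,
        c=c,
        u=u,
        cr=cr,
        e1=exposures["e1"],
        e2=exposures["e2"],
        e3=exposures["e3"],
        d=d,
        s=s,
        panel=panel,
        pheno=pheno,
        surv=surv,
        meta=meta,
    )


def select_survivors(cohort: Cohort) -> Cohort:
    """Restrict a cohort to individuals who survived to recruitment.

    Raises :class:`DegenerateSelectionError` when nobody survives.
    """
    mask = cohort.s == 1
    n_sel = int(mask.sum())
    if n_sel == 0:
        raise DegenerateSelectionError(
            "survival selection removed every individual; "
            "check hazard ratios and p_sel"
        )
    meta = dict(cohort.meta)
    meta.update(selected=True, n_selected=n_sel)
    return replace(
        cohort,
        genotypes=cohort.genotypes[mask],
        c=cohort.c[mask],
        u=cohort.u[mask],
        cr=cohort.cr[mask],
        e1=cohort.e1[mask],
        e2=cohort.e2[mask],
        e3=cohort.e3[mask],
        d=cohort.d[mask],
        s=cohort.s[mask],
        meta=meta,
    )
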