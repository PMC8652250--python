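"""Per-SNP GWAS summary statistics and the two-sample orchestration.

Associations are univariable (no covariate adjustment — the bias
mechanisms under study operate precisely through the unadjusted paths):
simple linear regression per SNP for continuous traits, and per-SNP
logistic regression via vectorized IRLS for binary traits.  Effects are
per effect allele; p-values use the Wald normal approximation, matching
how public GWAS summary statistics are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cohort import Cohort, select_survivors, simulate_cohort
from .config import PhenotypeConfig, SnpPanel, SurvivalConfig
from .errors import ConfigError

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["SNP", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]

_TINY_P = 5e-324  # smallest subnormal float; keeps pval in (0, 1]


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP–trait association in summary form."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int


@dataclass
class SummaryStatsTable:
    """A trait's per-SNP summary statistics plus a drop log."""

    trait: str
    trait_type: str  # "continuous" | "binary"
    data: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in SUMMARY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigError(f"summary table missing columns {missing}")
        if self.data["SNP"].duplicated().any():
            raise ConfigError("snp_id must be unique within a summary table")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def records(self) -> Iterator[AssociationRecord]:
        for row in self.data.itertuples(index=False):
            yield AssociationRecord(
                snp_id=row.SNP,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=int(row.n),
            )


def _linear_per_snp(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-SNP simple linear regression (slope, residual SE)."""
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    beta = sxy / sxx
    syy = float(yc @ yc)
    rss = np.maximum(syy - sxy**2 / sxx, 0.0)
    se = np.sqrt(rss / (n - 2) / sxx)
    return beta, se


def _logistic_per_snp(
    g: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP univariable logistic regression by IRLS, vectorized over SNPs.

    Each SNP gets its own 2-parameter (intercept, slope) fit; the 2x2
    Newton updates are solved in closed form across all SNPs at once.
    Returns (slope, se, ok) where ``ok`` is False for non-converged or
    separated fits (|slope| > 20 on the log-odds scale).
    """
    n, m = g.shape
    ybar = y.mean()
    a = np.full(m, np.log(ybar / (1.0 - ybar)))
    b = np.zeros(m)
    ok = np.ones(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        eta = a + g * b
        mu = expit(eta)
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        s0 = w.sum(axis=0)
        s1 = np.einsum("ij,ij->j", w, g)
        s2 = np.einsum("ij,ij->j", w, g * g)
        u0 = r.sum(axis=0)
        u1 = np.einsum("ij,ij->j", r, g)
        det = s0 * s2 - s1 * s1
        bad = det <= 0
        det = np.where(bad, 1.0, det)
        da = (s2 * u0 - s1 * u1) / det
        db = (s0 * u1 - s1 * u0) / det
        da = np.where(converged | bad, 0.0, da)
        db = np.where(converged | bad, 0.0, db)
        a += da
        b += db
        ok &= ~bad
        converged |= np.maximum(np.abs(da), np.abs(db)) < tol
        if converged.all() or not ok.any():
            break
    ok &= converged
    ok &= np.abs(b) < 20.0  # quasi-separation guard
    eta = a + g * b
    mu = expit(eta)
    w = mu * (1.0 - mu)
    s0 = w.sum(axis=0)
    s1 = np.einsum("ij,ij->j", w, g)
    s2 = np.einsum("ij,ij->j", w, g * g)
    det = np.where(s0 * s2 - s1 * s1 > 0, s0 * s2 - s1 * s1, np.nan)
    se = np.sqrt(s0 / det)
    return b, se, ok


def regress_trait_on_snps(cohort: Cohort, trait: str) -> SummaryStatsTable:
    """GWAS of one trait on every panel SNP in a cohort.

    Monomorphic SNPs are dropped with a logged warning; binary-trait fits
    that fail to converge (or show separation) are flagged and excluded.
    """
    y = np.asarray(cohort.trait(trait), dtype=float)
    n = cohort.n
    if n < 30:
        raise ConfigError(f"need >= 30 individuals for GWAS, got {n}")
    g = cohort.genotypes.astype(float)

    dropped: list[tuple[str, str]] = []
    poly = g.std(axis=0) > 0
    for sid in np.asarray(cohort.panel.snp_id)[~poly]:
        dropped.append((str(sid), "monomorphic"))
        log.warning("SNP %s monomorphic in sample; dropped", sid)

    is_binary = (
        cohort.pheno.d_type == "binary" if trait == "d" else set(np.unique(y)) <= {0.0, 1.0}
    )
    trait_type = "binary" if is_binary else "continuous"

    rows = []
    if poly.any() and y.std() > 0:
        gp = g[:, poly]
        ids = np.asarray(cohort.panel.snp_id)[poly]
        eas = np.asarray(cohort.panel.effect_allele)[poly]
        oas = np.asarray(cohort.panel.other_allele)[poly]
        eaf = gp.mean(axis=0) / 2.0
        if is_binary:
            beta, se, ok = _logistic_per_snp(gp, y)
            for sid in ids[~ok]:
                dropped.append((str(sid), "non-converged"))
                log.warning("SNP %s: logistic fit did not converge; excluded", sid)
        else:
            beta, se = _linear_per_snp(gp, y)
            ok = np.ones(len(ids), dtype=bool)
        z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
        pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), _TINY_P, 1.0)
        for j in np.flatnonzero(ok):
            rows.append(
                (ids[j], eas[j], oas[j], eaf[j], beta[j], se[j], pval[j], n)
            )
    elif y.std() == 0:
        for sid in np.asarray(cohort.panel.snp_id)[poly]:
            dropped.append((str(sid), "zero-variance-trait"))
        log.warning("trait %s has zero variance; no associations estimable", trait)

    data = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return SummaryStatsTable(trait=trait, trait_type=trait_type, data=data, dropped=dropped)


def generate_two_samples(
    panel: SnpPanel,
    pheno: PhenotypeConfig,
    surv: SurvivalConfig,
    n_exposure: int,
    n_outcome: int,
    seed: int,
) -> tuple[dict[str, SummaryStatsTable], SummaryStatsTable]:
    """Two-sample MR summary statistics from one configuration.

    Two independent cohorts are simulated from derived sub-seeds and each
    passed through survival selection; exposure GWASs come from the first
    cohort, the outcome GWAS from the second, so there is no sample
    overlap by construction.  Returns ``(exposure_tables, outcome_table)``
    with one exposure table per instrumented exposure label.
    """
    ss = np.random.SeedSequence(seed)
    seed_exp, seed_out = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    coh_exp = select_survivors(simulate_cohort(panel, pheno, surv, n_exposure, seed_exp))
    coh_out = select_survivors(simulate_cohort(panel, pheno, surv, n_outcome, seed_out))
    exposure_tables = {
        lab: regress_trait_on_snps(coh_exp, lab) for lab in panel.exposure_labels
    }
    outcome_table = regress_trait_on_snps(coh_out, "d")
    return exposure_tables, outcome_table
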