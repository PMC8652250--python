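"""Simulator tests: calibration, standardization, selection mechanics."""

import numpy as np
import pytest
from scipy import stats

from selectmr import (
    PhenotypeConfig,
    SnpPanel,
    SurvivalConfig,
    random_panel,
    select_survivors,
    simulate_cohort,
)
from selectmr.errors import ConfigError, DegenerateSelectionError


def test_panel_invariants_enforced():
    with pytest.raises(ConfigError):
        SnpPanel(["rs1"], ["A"], ["A"], [0.2], [[1.0]])  # same alleles
    with pytest.raises(ConfigError):
        SnpPanel(["rs1"], ["A"], ["G"], [0.7], [[1.0]])  # maf > 0.5
    with pytest.raises(ConfigError):
        SnpPanel(["rs1"], ["A"], ["G"], [0.2], [[0.0]])  # relevance violated


def test_nonpositive_n_rejected(panel, pheno, null_surv):
    with pytest.raises(ConfigError):
        simulate_cohort(panel, pheno, null_surv, 0, seed=1)


def test_incompatible_r2_names_exposure(panel, null_surv):
    # r2_ge + phi_c_e^2 > 1 leaves negative residual variance
    bad = PhenotypeConfig(r2_ge=0.6, phi_c_e=0.8)
    with pytest.raises(ConfigError, match="e1"):
        simulate_cohort(panel, bad, null_surv, 100, seed=1)


def test_null_hazard_survivor_fraction_is_binomial(panel, pheno):
    """With all hazard ratios 1 every survival probability is exactly p_sel,
    so the survivor count is Binomial(n, p_sel); check the exact 99% interval."""
    n, p_sel = 50_000, 0.7
    cohort = simulate_cohort(panel, pheno, SurvivalConfig(p_sel=p_sel), n, seed=11)
    lo, hi = stats.binom.ppf([0.005, 0.995], n, p_sel)
    assert lo <= cohort.s.sum() <= hi


def test_instrument_r2_matches_target(panel, null_surv):
    pheno = PhenotypeConfig(r2_ge=0.1)
    cohort = simulate_cohort(panel, pheno, null_surv, 100_000, seed=3)
    score = cohort.genotypes.astype(float) @ np.linalg.lstsq(
        cohort.genotypes.astype(float), cohort.e1, rcond=None
    )[0]
    r2 = np.corrcoef(score, cohort.e1)[0, 1] ** 2
    assert r2 == pytest.approx(0.1, abs=0.01)


def test_exposures_standardized(trio_panel, null_surv):
    pheno = PhenotypeConfig(beta_e2d=-0.3, beta_e3d=0.3, antagonist_rho=-0.5)
    cohort = simulate_cohort(trio_panel, pheno, null_surv, 100_000, seed=4)
    for lab in ("e1", "e2", "e3"):
        assert cohort.trait(lab).var() == pytest.approx(1.0, abs=0.05)
    # residual coupling is negative for the antagonist pair
    assert np.corrcoef(cohort.e1, cohort.e2)[0, 1] < 0


def test_binary_outcome_prevalence_calibrated(panel, null_surv):
    pheno = PhenotypeConfig(d_type="binary", d_prevalence=0.1)
    cohort = simulate_cohort(panel, pheno, null_surv, 50_000, seed=5)
    assert set(np.unique(cohort.d)) <= {0.0, 1.0}
    assert cohort.d.mean() == pytest.approx(0.1, abs=0.01)


def test_seeded_determinism(panel, pheno, null_surv):
    a = simulate_cohort(panel, pheno, null_surv, 2_000, seed=42)
    b = simulate_cohort(panel, pheno, null_surv, 2_000, seed=42)
    assert np.array_equal(a.genotypes, b.genotypes)
    for t in ("c", "u", "cr", "e1", "e2", "e3", "d", "s"):
        assert np.array_equal(a.trait(t) if t != "s" else a.s, b.trait(t) if t != "s" else b.s)


def test_selection_filters_to_survivors(panel, pheno, null_surv):
    cohort = simulate_cohort(panel, pheno, null_surv, 5_000, seed=6)
    sel = select_survivors(cohort)
    assert np.all(sel.s == 1)
    assert sel.n == cohort.s.sum()
    assert sel.meta["n_original"] == 5_000


def test_outcome_hazard_depletes_cases(panel):
    """hr_ds > 1 with binary D: survival among cases strictly below controls."""
    pheno = PhenotypeConfig(d_type="binary", d_prevalence=0.2)
    surv = SurvivalConfig(hr_ds=2.0)
    cohort = simulate_cohort(panel, pheno, surv, 50_000, seed=7)
    cases, ctrls = cohort.s[cohort.d == 1], cohort.s[cohort.d == 0]
    stat = stats.norm.isf(0.005)
    p1, p0 = cases.mean(), ctrls.mean()
    se = np.sqrt(p1 * (1 - p1) / len(cases) + p0 * (1 - p0) / len(ctrls))
    assert p1 < p0 - stat * se


def test_null_selection_preserves_allele_frequencies(panel, pheno):
    """Under null hazards selection is a simple random subsample, so the
    survivor allele count for each SNP is hypergeometric from the cohort pool."""
    cohort = simulate_cohort(panel, pheno, SurvivalConfig(), 50_000, seed=8)
    sel = select_survivors(cohort)
    n_draw = 2 * sel.n
    for j in range(panel.n_snps):
        total = 2 * cohort.n
        good = int(cohort.genotypes[:, j].sum())
        lo, hi = stats.hypergeom.ppf([0.0005, 0.9995], total, good, n_draw)
        assert lo <= sel.genotypes[:, j].sum() <= hi


def test_genetic_hazard_shifts_allele_counts(panel, pheno):
    cohort = simulate_cohort(panel, pheno, SurvivalConfig(hr_gs=1.5), 50_000, seed=9)
    sel = select_survivors(cohort)
    assert sel.genotypes.sum(axis=1).mean() < cohort.genotypes.sum(axis=1).mean()


@pytest.mark.parametrize("hr_name", ["hr_gs", "hr_e1s", "hr_cs", "hr_ds", "hr_us"])
def test_survivor_fraction_decreasing_in_each_hazard(panel, pheno, hr_name):
    """Convexity of exp(eta): raising any hazard ratio above 1 lowers the
    expected survivor fraction below p_sel, monotonically on a 3-point grid."""
    fracs = []
    for hr in (1.0, 1.5, 2.5):
        surv = SurvivalConfig(**{hr_name: hr})
        cohort = simulate_cohort(panel, pheno, surv, 50_000, seed=10)
        fracs.append(cohort.s.mean())
    assert fracs[0] > fracs[1] > fracs[2]


def test_null_selection_neutrality_of_snp_betas(pheno):
    """With all hazards null, per-SNP exposure betas before vs after selection
    agree within Monte Carlo error over 200 replicates."""
    from selectmr.gwas import regress_trait_on_snps

    small = random_panel(n_snps=4, exposures=("e1",), seed=1)
    diffs = []
    for rep in range(200):
        cohort = simulate_cohort(small, pheno, SurvivalConfig(), 3_000, seed=1000 + rep)
        sel = select_survivors(cohort)
        full = regress_trait_on_snps(cohort, "e1").data["beta"].to_numpy()
        surv = regress_trait_on_snps(sel, "e1").data["beta"].to_numpy()
        diffs.append(surv - full)
    diffs = np.asarray(diffs)
    mc_se = diffs.std(axis=0, ddof=1) / np.sqrt(diffs.shape[0])
    assert np.all(np.abs(diffs.mean(axis=0)) < 3 * mc_se)


def test_degenerate_selection_raises():
    panel = random_panel(n_snps=2, exposures=("e1",), seed=2)
    pheno = PhenotypeConfig()
    cohort = simulate_cohort(panel, pheno, SurvivalConfig(p_sel=1e-12), 50, seed=12)
    if cohort.s.sum() == 0:
        with pytest.raises(DegenerateSelectionError):
            select_survivors(cohort)
    else:  # pragma: no cover - vanishingly unlikely
        pytest.skip("some individual survived a 1e-12 survival probability")


def test_cohort_tsv_round_trip(tmp_path, panel, pheno, null_surv):
    cohort = simulate_cohort(panel, pheno, null_surv, 200, seed=13)
    path = tmp_path / "cohort.tsv"
    cohort.to_tsv(path)
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    assert list(df.columns[:1]) == ["iid"]
    assert [c for c in df.columns if c.startswith("g_")] == [
        f"g_{s}" for s in panel.snp_id
    ]
    np.testing.assert_allclose(df["e1"], cohort.e1)
    assert df["s"].isin([0, 1]).all()
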