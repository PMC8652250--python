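"""MR estimator tests: brute-force oracles, reductions, robustness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selectmr.errors import NotEstimableError
from selectmr.harmonize import HarmonizedInstrument
from selectmr.mr import MRModel, cochran_q, ivw, mr_egger, wald_ratio, weighted_median

from conftest import random_instruments


def _insts(bx, sx, by, sy):
    return [
        HarmonizedInstrument(f"rs{j}", bx[j], sx[j], by[j], sy[j])
        for j in range(len(bx))
    ]


# ---------------------------------------------------------------- Wald ratio

def test_wald_ratio_point_and_collapse():
    r = wald_ratio(HarmonizedInstrument("rs1", 0.4, 0.01, 0.2, 0.1))
    assert r.estimate == pytest.approx(0.5)
    r0 = wald_ratio(HarmonizedInstrument("rs1", 0.4, 0.05, 0.0, 0.1))
    assert r0.estimate == 0.0
    assert r0.se == pytest.approx(0.25)
    with pytest.raises(NotEstimableError):
        wald_ratio(HarmonizedInstrument("rs1", 0.0, 0.05, 0.1, 0.1))


def test_wald_se_against_simulation_oracle():
    """Delta-method SE within 5% of the empirical SD of the simulated ratio
    when the instrument is strong (|beta_exp/se_exp| > 10)."""
    rng = np.random.default_rng(0)
    bx, sx, by, sy = 0.4, 0.02, 0.12, 0.05
    draws = rng.normal(by, sy, 1_000_000) / rng.normal(bx, sx, 1_000_000)
    res = wald_ratio(HarmonizedInstrument("rs1", bx, sx, by, sy))
    assert res.se == pytest.approx(draws.std(), rel=0.05)


# ----------------------------------------------------------------------- IVW

def test_ivw_equal_weights_is_mean():
    insts = _insts([0.1, 0.1, 0.1], [0.01] * 3, [0.01, 0.02, 0.03], [0.05] * 3)
    res = ivw(insts, effects_model="fixed")
    assert res.estimate == pytest.approx(0.2)


def test_ivw_k1_reduces_to_wald_first_order():
    inst = HarmonizedInstrument("rs1", 0.3, 0.02, 0.09, 0.05)
    res = ivw([inst], effects_model="fixed")
    assert res.estimate == pytest.approx(0.09 / 0.3, abs=1e-14)
    assert res.se == pytest.approx(0.05 / 0.3, abs=1e-14)


def test_ivw_matches_wls_through_origin_oracle():
    """IVW == weighted least squares of beta_out on beta_exp through the
    origin with weights 1/se_out^2, solved by the normal equation directly."""
    rng = np.random.default_rng(1)
    for _ in range(100):
        insts = random_instruments(rng, k=int(rng.integers(2, 12)))
        bx = np.array([i.beta_exp for i in insts])
        by = np.array([i.beta_out for i in insts])
        w = 1.0 / np.array([i.se_out for i in insts]) ** 2
        oracle = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
        oracle_se = float(1.0 / np.sqrt(np.sum(w * bx * bx)))
        res = ivw(insts, effects_model="fixed")
        assert res.estimate == pytest.approx(oracle, abs=1e-10)
        assert res.se == pytest.approx(oracle_se, abs=1e-10)


def test_ivw_random_effects_inflates_only_when_heterogeneous():
    rng = np.random.default_rng(2)
    insts = random_instruments(rng, k=8)
    fixed, rand = ivw(insts, "fixed"), ivw(insts, "multiplicative_random")
    assert rand.estimate == fixed.estimate
    expected = fixed.se * max(1.0, np.sqrt(fixed.q / (fixed.k - 1)))
    assert rand.se == pytest.approx(expected, abs=1e-12)


# ----------------------------------------------------------------- Cochran Q

def test_cochran_q_hand_values():
    insts = _insts([1.0, 1.0], [0.01] * 2, [0.0, 1.0], [1.0, 1.0])  # w={1,1}, theta={0,1}
    q, p = cochran_q(insts, pooled=0.5)
    assert q == pytest.approx(0.5)
    same = _insts([0.2, 0.2, 0.2], [0.01] * 3, [0.06] * 3, [0.05] * 3)
    q, p = cochran_q(same, pooled=0.3)
    assert q == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    assert np.isnan(cochran_q(same[:1], 0.3)[0])


def test_cochran_q_null_mean_near_one():
    """Homogeneous effects: E[Q/(k-1)] ~ 1 over 500 summary-level replicates."""
    rng = np.random.default_rng(3)
    k, ratios = 10, []
    for _ in range(500):
        bx = rng.uniform(0.2, 0.5, k)
        sy = rng.uniform(0.02, 0.05, k)
        by = 0.3 * bx + rng.normal(0, sy)
        res = ivw(_insts(bx, np.full(k, 1e-6), by, sy), "fixed")
        ratios.append(res.q / (k - 1))
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


# ------------------------------------------------------------ weighted median

def test_weighted_median_equal_weights_is_median():
    insts = _insts([0.1, 0.1, 0.1], [0.001] * 3, [0.01, 0.02, 0.03], [0.05] * 3)
    assert weighted_median(insts).estimate == pytest.approx(0.2)


def test_weighted_median_matches_interpolation_oracle():
    """Point estimate equals a from-scratch cumulative-weight interpolation
    (explicit loop over the sorted ratios) to 1e-12."""
    rng = np.random.default_rng(4)
    for _ in range(100):
        insts = random_instruments(rng, k=int(rng.integers(3, 12)))
        theta = np.array([i.beta_out / i.beta_exp for i in insts])
        w = np.array([i.beta_exp**2 / i.se_out**2 for i in insts])
        order = np.argsort(theta)
        ts, ws = theta[order], w[order] / w.sum()
        cum, prev_p, prev_t, oracle = 0.0, None, None, ts[0]
        for t, wt in zip(ts, ws):
            p = cum + wt / 2.0
            if p >= 0.5:
                if prev_p is None:
                    oracle = t
                else:
                    oracle = prev_t + (t - prev_t) * (0.5 - prev_p) / (p - prev_p)
                break
            cum += wt
            prev_p, prev_t = p, t
        else:
            oracle = ts[-1]
        assert weighted_median(insts, n_boot=2).estimate == pytest.approx(oracle, abs=1e-12)


def test_weighted_median_bootstrap_seeded():
    rng = np.random.default_rng(5)
    insts = random_instruments(rng, k=6)
    a = weighted_median(insts, n_boot=500, seed=7)
    b = weighted_median(insts, n_boot=500, seed=7)
    assert a.se == b.se
    with pytest.raises(NotEstimableError):
        weighted_median(insts[:2])


def test_weighted_median_breakdown_beats_ivw():
    """Half the panel pleiotropic (5 of 11 instruments, directional
    pleiotropy): the median lands closer to the true effect than IVW in at
    least 80% of 200 summary-level replicates."""
    rng = np.random.default_rng(6)
    k, n_bad, true = 11, 5, 0.3
    wins = 0
    for _ in range(200):
        # equally informative instruments, so the valid 6 of 11 hold their
        # weight majority -- the regime the estimator's consistency covers
        bx = np.full(k, 0.3)
        sx = np.full(k, 0.01)
        sy = np.full(k, 0.03)
        pleio = np.zeros(k)
        pleio[:n_bad] = 0.3
        by = true * bx + pleio + rng.normal(0, sy)
        insts = _insts(bx, sx, by, sy)
        med = weighted_median(insts, n_boot=2).estimate
        ivw_est = ivw(insts).estimate
        wins += abs(med - true) < abs(ivw_est - true)
    assert wins / 200 >= 0.8


# -------------------------------------------------------------------- Egger

def test_egger_matches_wls_with_intercept_oracle():
    """Slope/intercept/SEs equal numpy lstsq on the weighted design with the
    spec's sqrt(max(1, Q/(k-2))) inflation, to 1e-10."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        insts = random_instruments(rng, k=int(rng.integers(3, 12)))
        bx = np.array([i.beta_exp for i in insts])
        by = np.array([i.beta_out for i in insts])
        sy = np.array([i.se_out for i in insts])
        flip = np.where(bx < 0, -1.0, 1.0)
        bxo, byo = bx * flip, by * flip
        X = np.column_stack([np.ones_like(bxo), bxo])
        W = np.diag(1.0 / sy**2)
        xtwx = X.T @ W @ X
        coef = np.linalg.solve(xtwx, X.T @ W @ byo)
        resid = byo - X @ coef
        k = len(insts)
        infl2 = max(1.0, float(resid @ W @ resid) / (k - 2))
        ses = np.sqrt(np.diag(np.linalg.inv(xtwx)) * infl2)
        res = mr_egger(insts)
        assert res.egger_intercept == pytest.approx(coef[0], abs=1e-10)
        assert res.estimate == pytest.approx(coef[1], abs=1e-10)
        assert res.egger_intercept_se == pytest.approx(ses[0], abs=1e-10)
        assert res.se == pytest.approx(ses[1], abs=1e-10)


def test_egger_through_origin_equals_ivw_identity():
    """Forcing the intercept to zero reduces the Egger regression to the
    fixed-effects IVW estimate (WLS through the origin identity)."""
    rng = np.random.default_rng(8)
    insts = random_instruments(rng, k=8)
    bx = np.abs(np.array([i.beta_exp for i in insts]))
    by = np.array([i.beta_out for i in insts]) * np.sign([i.beta_exp for i in insts])
    w = 1.0 / np.array([i.se_out for i in insts]) ** 2
    slope_origin = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
    assert slope_origin == pytest.approx(ivw(insts, "fixed").estimate, abs=1e-10)


def test_egger_null_intercept_coverage():
    """No pleiotropy: intercept within 3 SE of zero in >= 98% of 500 reps."""
    rng = np.random.default_rng(9)
    k, hits = 10, 0
    for _ in range(500):
        bx = rng.uniform(0.1, 0.5, k)
        sy = rng.uniform(0.02, 0.05, k)
        by = 0.3 * bx + rng.normal(0, sy)
        res = mr_egger(_insts(bx, np.full(k, 0.005), by, sy))
        hits += abs(res.egger_intercept) < 3 * res.egger_intercept_se
    assert hits / 500 >= 0.98


def test_egger_guards():
    with pytest.raises(NotEstimableError):
        mr_egger(_insts([0.1, 0.2], [0.01] * 2, [0.03, 0.06], [0.05] * 2))
    with pytest.raises(NotEstimableError):
        mr_egger(_insts([0.2, 0.2, 0.2], [0.01] * 3, [0.06, 0.05, 0.07], [0.05] * 3))


# ------------------------------------------------------------- shared checks

@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.1, 10.0))
def test_scale_equivariance(seed, c):
    """Rescaling the exposure associations by c divides every estimate by c."""
    rng = np.random.default_rng(seed)
    insts = random_instruments(rng, k=6)
    scaled = [
        HarmonizedInstrument(i.snp_id, c * i.beta_exp, c * i.se_exp, i.beta_out, i.se_out)
        for i in insts
    ]
    for fn in (lambda x: ivw(x).estimate,
               lambda x: weighted_median(x, n_boot=2).estimate,
               lambda x: mr_egger(x).estimate):
        assert fn(scaled) == pytest.approx(fn(insts) / c, rel=1e-9)


def test_model_results_summary_and_ci_order():
    rng = np.random.default_rng(10)
    model = MRModel(random_instruments(rng, k=8), exposure="e1", outcome="d")
    for res in model.fit_all(("ivw", "weighted_median", "mr_egger")):
        assert res.ci_low <= res.estimate <= res.ci_high
        assert str(res.k) in res.summary()
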