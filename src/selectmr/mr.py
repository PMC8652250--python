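"""Two-sample MR estimators: Wald ratio, IVW, weighted median, MR-Egger.

The estimation layer follows the Model/Results convention: build an
:class:`MRModel` from harmonized instruments (or directly from a pair of
summary tables via :meth:`MRModel.from_tables`), call :meth:`MRModel.fit`
per method, and read estimates, uncertainties and heterogeneity
diagnostics off the returned :class:`MRResults`.

Conventions:

* IVW uses first-order weights ``w_j = beta_exp_j^2 / se_out_j^2`` on the
  Wald ratios ``theta_j = beta_out_j / beta_exp_j`` (equivalently, WLS of
  beta_out on beta_exp through the origin with weights 1/se_out^2).  The
  default "multiplicative_random" effects model inflates the fixed-effect
  SE by sqrt(max(1, Q/(k-1))).
* The Wald-ratio SE is the second-order delta-method expression.
* The weighted median interpolates the ordered ratios at cumulative
  normalized weight 0.5 on the midpoint grid (p_j - w_j/2), with a seeded
  parametric bootstrap for its SE.
* MR-Egger orients instruments to beta_exp >= 0, regresses beta_out on
  beta_exp with intercept and weights 1/se_out^2, inflates SEs by
  sqrt(max(1, Q_egger/(k-2))), and uses t(k-2) reference distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import NoInstrumentsError, NotEstimableError
from .gwas import SummaryStatsTable
from .harmonize import HarmonizedInstrument, InstrumentSet, harmonize, instrument_arrays, screen_instruments

__all__ = [
    "MRModel",
    "MRResults",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "weighted_median",
    "mr_egger",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MRResults:
    """Point estimate, uncertainty and diagnostics for one MR method."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    k: int
    q: float = np.nan
    q_pval: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_pval: float = np.nan

    @property
    def significant(self) -> bool:
        return bool(self.pval < 0.05)

    def summary(self) -> str:
        lines = [
            f"{'Method':<28}{self.method}",
            f"{'Instruments (k)':<28}{self.k}",
            f"{'Estimate':<28}{self.estimate:.6g}",
            f"{'Std. error':<28}{self.se:.6g}",
            f"{'95% CI':<28}[{self.ci_low:.6g}, {self.ci_high:.6g}]",
            f"{'P-value':<28}{self.pval:.3g}",
        ]
        if np.isfinite(self.q):
            lines.append(f"{'Cochran Q (df, p)':<28}{self.q:.4g} ({self.k - 1}, {self.q_pval:.3g})")
        if np.isfinite(self.egger_intercept):
            lines.append(
                f"{'Egger intercept (se, p)':<28}"
                f"{self.egger_intercept:.4g} ({self.egger_intercept_se:.4g}, "
                f"{self.egger_intercept_pval:.3g})"
            )
        width = max(len(s) for s in lines)
        rule = "=" * width
        return "\n".join([rule, "MR results".center(width), rule, *lines, rule])

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "k": self.k,
            "q": self.q,
            "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_pval": self.egger_intercept_pval,
        }


def _result(method, est, se, k, dist="norm", df=None, **extra) -> MRResults:
    if dist == "t":
        crit = stats.t.ppf(0.975, df)
        pval = 2.0 * stats.t.sf(abs(est / se), df) if se > 0 else np.nan
    else:
        crit = _Z95
        pval = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
    return MRResults(
        method=method,
        estimate=float(est),
        se=float(se),
        ci_low=float(est - crit * se),
        ci_high=float(est + crit * se),
        pval=float(pval),
        k=int(k),
        **extra,
    )


def wald_ratio(inst: HarmonizedInstrument) -> MRResults:
    """Single-instrument causal estimate beta_out / beta_exp.

    SE uses the second-order delta method:
    sqrt(se_out^2/beta_exp^2 + beta_out^2 * se_exp^2 / beta_exp^4).
    """
    if inst.beta_exp == 0:
        raise NotEstimableError(f"SNP {inst.snp_id}: beta_exp = 0, Wald ratio undefined")
    est = inst.beta_out / inst.beta_exp
    se = np.sqrt(
        inst.se_out**2 / inst.beta_exp**2
        + inst.beta_out**2 * inst.se_exp**2 / inst.beta_exp**4
    )
    return _result("wald_ratio", est, se, k=1)


def _weights_ratios(insts) -> tuple[np.ndarray, np.ndarray]:
    bx, _, by, sy = instrument_arrays(insts)
    if np.any(bx == 0):
        raise NotEstimableError("an instrument has beta_exp = 0")
    return bx**2 / sy**2, by / bx


def ivw(insts: Sequence[HarmonizedInstrument], effects_model: str = "multiplicative_random") -> MRResults:
    """Inverse-variance weighted average of the Wald ratios.

    ``effects_model`` is "fixed" or "multiplicative_random" (default);
    the latter scales the fixed-effect SE by sqrt(max(1, Q/(k-1))).
    With a single instrument this reduces exactly to the Wald ratio with
    its first-order SE.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    k = len(insts)
    if k == 0:
        raise NoInstrumentsError("IVW requires at least one instrument")
    w, theta = _weights_ratios(insts)
    est = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (theta - est) ** 2)) if k >= 2 else np.nan
    q_pval = float(stats.chi2.sf(q, k - 1)) if k >= 2 else np.nan
    if effects_model == "multiplicative_random" and k >= 2:
        se *= float(np.sqrt(max(1.0, q / (k - 1))))
    return _result(f"ivw_{effects_model}", est, se, k=k, q=q, q_pval=q_pval)


def cochran_q(insts: Sequence[HarmonizedInstrument], pooled: float) -> tuple[float, float]:
    """Heterogeneity statistic Q = sum w_j (theta_j - pooled)^2 and its p.

    Returns (nan, nan) when fewer than two instruments are available.
    """
    k = len(insts)
    if k < 2:
        return (np.nan, np.nan)
    w, theta = _weights_ratios(insts)
    q = float(np.sum(w * (theta - pooled) ** 2))
    return q, float(stats.chi2.sf(q, k - 1))


def _median_interp(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    theta_s, w_s = theta[order], w[order]
    wn = w_s / w_s.sum()
    p = np.cumsum(wn) - 0.5 * wn  # midpoint cumulative-weight grid
    return float(np.interp(0.5, p, theta_s))


def weighted_median(
    insts: Sequence[HarmonizedInstrument], n_boot: int = 1000, seed: int = 0
) -> MRResults:
    """Weighted median of the Wald ratios (valid-majority-of-weight robust).

    The SE comes from a seeded parametric bootstrap: exposure and outcome
    betas are redrawn from normals centered at the observed values with
    their reported SEs, and the median recomputed per draw.
    """
    k = len(insts)
    if k < 3:
        raise NotEstimableError(f"weighted median needs k >= 3 instruments, got {k}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    bx, sx, by, sy = instrument_arrays(insts)
    w = bx**2 / sy**2
    est = _median_interp(by / bx, w)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
    theta_b = by_b / bx_b
    w_b = bx_b**2 / sy**2
    order = np.argsort(theta_b, axis=1)
    theta_s = np.take_along_axis(theta_b, order, axis=1)
    w_s = np.take_along_axis(w_b, order, axis=1)
    wn = w_s / w_s.sum(axis=1, keepdims=True)
    p = np.cumsum(wn, axis=1) - 0.5 * wn
    boots = np.array(
        [np.interp(0.5, p[i], theta_s[i]) for i in range(n_boot)]
    )
    se = float(boots.std(ddof=1))
    return _result("weighted_median", est, se, k=k)


def mr_egger(insts: Sequence[HarmonizedInstrument]) -> MRResults:
    """MR-Egger regression: slope = causal estimate, intercept = pleiotropy.

    Instruments are oriented so beta_exp >= 0 (both betas sign-flipped
    together when negative — the InSIDE orientation, which fixes the
    intercept's sign convention); the weighted regression of beta_out on
    beta_exp with weights 1/se_out^2 then gives the slope and intercept,
    with SEs inflated by sqrt(max(1, Q_egger/(k-2))) and t(k-2) inference.
    """
    k = len(insts)
    if k < 3:
        raise NotEstimableError(f"MR-Egger needs k >= 3 instruments, got {k}")
    bx, sx, by, sy = instrument_arrays(insts)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise NotEstimableError("MR-Egger: no spread in beta_exp (collinear design)")
    w = 1.0 / sy**2
    # weighted normal equations for [intercept, slope]
    sw, swx = w.sum(), (w * bx).sum()
    swxx, swy, swxy = (w * bx * bx).sum(), (w * by).sum(), (w * bx * by).sum()
    det = sw * swxx - swx**2
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = by - intercept - slope * bx
    q_egger = float(np.sum(w * resid**2))
    infl = np.sqrt(max(1.0, q_egger / (k - 2)))
    se_slope = np.sqrt(sw / det) * infl
    se_int = np.sqrt(swxx / det) * infl
    int_pval = float(2.0 * stats.t.sf(abs(intercept / se_int), k - 2))
    return _result(
        "mr_egger",
        slope,
        se_slope,
        k=k,
        dist="t",
        df=k - 2,
        q=q_egger,
        q_pval=float(stats.chi2.sf(q_egger, k - 2)),
        egger_intercept=float(intercept),
        egger_intercept_se=float(se_int),
        egger_intercept_pval=int_pval,
    )


class MRModel:
    """Two-sample MR model over a set of harmonized instruments.

    Parameters
    ----------
    instruments
        Harmonized exposure/outcome effect pairs (e.g. from
        :func:`selectmr.harmonize.harmonize`).
    exposure, outcome
        Optional trait labels carried into reports.
    """

    METHODS = ("wald_ratio", "ivw", "weighted_median", "mr_egger")

    def __init__(
        self,
        instruments: Sequence[HarmonizedInstrument],
        exposure: str | None = None,
        outcome: str | None = None,
    ):
        if len(instruments) == 0:
            raise NoInstrumentsError("MRModel requires at least one instrument")
        self.instruments = list(instruments)
        self.exposure = exposure
        self.outcome = outcome

    @classmethod
    def from_tables(
        cls,
        exp_table: SummaryStatsTable,
        out_table: SummaryStatsTable,
        p_max: float = 5e-8,
        f_min: float = 10.0,
    ) -> "MRModel":
        """Screen the exposure table, harmonize against the outcome, build."""
        screened = screen_instruments(exp_table, p_max=p_max, f_min=f_min)
        insts = harmonize(screened, out_table)
        if len(insts) == 0:
            raise NoInstrumentsError(
                f"harmonization dropped every instrument: {insts.dropped}"
            )
        model = cls(insts, exposure=exp_table.trait, outcome=out_table.trait)
        model.drop_log = list(screened.dropped) + list(insts.dropped)
        return model

    @property
    def k(self) -> int:
        return len(self.instruments)

    def fit(
        self,
        method: str = "ivw",
        effects_model: str = "multiplicative_random",
        n_boot: int = 1000,
        seed: int = 0,
    ) -> MRResults:
        """Fit one estimator and return its :class:`MRResults`."""
        if method == "ivw":
            return ivw(self.instruments, effects_model=effects_model)
        if method == "wald_ratio":
            if self.k > 1:
                raise NotEstimableError("wald_ratio is a single-instrument method")
            return wald_ratio(self.instruments[0])
        if method == "weighted_median":
            return weighted_median(self.instruments, n_boot=n_boot, seed=seed)
        if method == "mr_egger":
            return mr_egger(self.instruments)
        raise ValueError(f"unknown method {method!r}; expected one of {self.METHODS}")

    def fit_all(
        self,
        methods: Sequence[str] = ("ivw", "weighted_median", "mr_egger"),
        **kw,
    ) -> list[MRResults]:
        """Fit several estimators; methods below their minimum k are skipped."""
        out = []
        for m in methods:
            try:
                out.append(self.fit(method=m, **kw))
            except NotEstimableError:
                continue
        return out
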