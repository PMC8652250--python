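"""Control-exposure audit: detect selection bias from MR result patterns.

The audit compares MR results for a primary exposure against declared
control exposures across one or more outcomes and applies a fixed rule
table:

* **R1 (antagonist control).** An antagonist should push the outcome the
  opposite way; both estimates significant with the SAME sign therefore
  points to shared selection bias rather than biology.
* **R2 (similar-activity control).** A control with similar biological
  activity should agree; both significant with OPPOSITE signs points to
  selection bias.
* **R3 (validated control, null).** A validated control has a
  well-established outcome association; a CI covering zero suggests
  systematic selection bias masking it.
* **R4 (validated control, reversed).** A significant association in the
  direction opposite to the established one also suggests systematic
  selection bias.
* **R5.** If no rule fires, the result pattern is labelled robust.

Verdicts are advisory labels with rationale strings — the audit detects
potential selection bias; it does not quantify or correct it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, IncompleteAuditError
from .mr import MRResults

ROLES = ("primary", "antagonist", "similar_activity", "validated_control")


def bonferroni_alpha(n_exposures: int, family_alpha: float = 0.05, digits: int = 3) -> float:
    """Per-test significance level for a family of exposures (rounded)."""
    if n_exposures < 1:
        raise ConfigError("n_exposures must be >= 1")
    return round(family_alpha / n_exposures, digits)


DEFAULT_ALPHA = bonferroni_alpha(3)  # three exposures: primary + two controls


@dataclass(frozen=True)
class ControlSpec:
    """Role declaration for one exposure in the audit."""

    exposure: str
    role: str
    expected_outcome_sign: int = 0  # +1 / -1; required for validated_control
    source_gwas: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.role == "validated_control" and self.expected_outcome_sign not in (-1, 1):
            raise ConfigError(
                f"validated_control {self.exposure!r} must declare "
                "expected_outcome_sign of +1 or -1"
            )


@dataclass
class RuleFiring:
    rule: str
    exposures: tuple[str, ...]
    outcome: str
    rationale: str


@dataclass
class AuditVerdict:
    """Outcome of one audit run."""

    alpha: float
    estimates: pd.DataFrame  # exposure, outcome, estimate, ci_low, ci_high, pval, significant
    firings: list[RuleFiring] = field(default_factory=list)
    quadrants: dict = field(default_factory=dict)  # (primary, control, outcome) -> str
    warnings: list[str] = field(default_factory=list)

    @property
    def selection_bias_suspected(self) -> bool:
        return any(f.rule in ("R1", "R2") for f in self.firings)

    @property
    def systematic_bias_suspected(self) -> bool:
        return any(f.rule in ("R3", "R4") for f in self.firings)

    @property
    def robust(self) -> bool:
        return not (self.selection_bias_suspected or self.systematic_bias_suspected)

    def report(self) -> str:
        lines = [f"control-exposure audit (alpha = {self.alpha:g})", ""]
        for f in self.firings:
            lines.append(f"{f.rule}\t{'/'.join(f.exposures)}\t{f.outcome}\t{f.rationale}")
        if not self.firings:
            lines.append("R5\t-\t-\tno rule fired; result pattern robust to the declared controls")
        lines.append("")
        lines.append(
            "flags: selection_bias_suspected="
            f"{self.selection_bias_suspected} "
            f"systematic_bias_suspected={self.systematic_bias_suspected} "
            f"robust={self.robust}"
        )
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def _sig(row, alpha: float) -> bool:
    return bool(row["pval"] < alpha)


def audit(
    results: dict[tuple[str, str], MRResults],
    specs: list[ControlSpec],
    alpha: float = DEFAULT_ALPHA,
) -> AuditVerdict:
    """Apply the control-exposure rule table to a set of MR results.

    ``results`` maps (exposure, outcome) to fitted :class:`MRResults`.
    Every declared exposure must have a result for every outcome present;
    a missing pair raises :class:`IncompleteAuditError`.  The verdict is a
    pure function of (estimates, CIs, p-values, specs, alpha): input
    ordering never matters.
    """
    if not 0 < alpha < 0.5:
        raise ConfigError("alpha must lie in (0, 0.5)")
    primaries = [s for s in specs if s.role == "primary"]
    if len(primaries) != 1:
        raise ConfigError(f"exactly one primary exposure required, got {len(primaries)}")
    primary = primaries[0]
    controls = sorted(
        (s for s in specs if s.role != "primary"), key=lambda s: s.exposure
    )
    declared = {s.exposure for s in specs}
    outcomes = sorted({out for (_, out) in results})
    if not outcomes:
        raise IncompleteAuditError("no MR results supplied")
    for exp in sorted(declared):
        for out in outcomes:
            if (exp, out) not in results:
                raise IncompleteAuditError(f"missing MR result for ({exp}, {out})")

    rows = []
    for (exp, out), res in sorted(results.items()):
        if exp not in declared:
            continue
        rows.append(
            {
                "exposure": exp,
                "outcome": out,
                "estimate": res.estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "pval": res.pval,
                "significant": res.pval < alpha,
            }
        )
    est = pd.DataFrame(rows)
    by_pair = {(r["exposure"], r["outcome"]): r for r in rows}

    firings: list[RuleFiring] = []
    quadrants: dict = {}
    for ctrl in controls:
        for out in outcomes:
            p = by_pair[(primary.exposure, out)]
            c = by_pair[(ctrl.exposure, out)]
            sp, sc = np.sign(p["estimate"]), np.sign(c["estimate"])
            same_sign = sp == sc and sp != 0
            both_sig = p["significant"] and c["significant"]
            if ctrl.role == "antagonist":
                quadrants[(primary.exposure, ctrl.exposure, out)] = (
                    "discordant" if same_sign else "concordant"
                )
                if both_sig and same_sign:
                    firings.append(
                        RuleFiring(
                            "R1",
                            (primary.exposure, ctrl.exposure),
                            out,
                            "antagonist control shows a significant effect in the SAME "
                            "direction as the primary exposure; consistent effects of an "
                            "antagonist pair point to shared selection bias",
                        )
                    )
            elif ctrl.role == "similar_activity":
                quadrants[(primary.exposure, ctrl.exposure, out)] = (
                    "concordant" if same_sign else "discordant"
                )
                if both_sig and not same_sign:
                    firings.append(
                        RuleFiring(
                            "R2",
                            (primary.exposure, ctrl.exposure),
                            out,
                            "similar-activity control shows a significant effect OPPOSITE "
                            "to the primary exposure; inconsistent effects of a "
                            "similar-activity pair point to selection bias",
                        )
                    )
            elif ctrl.role == "validated_control":
                expected = ctrl.expected_outcome_sign
                quadrants[(primary.exposure, ctrl.exposure, out)] = (
                    "concordant" if sc == expected and c["significant"] else "discordant"
                )
                if c["ci_low"] <= 0.0 <= c["ci_high"]:
                    firings.append(
                        RuleFiring(
                            "R3",
                            (ctrl.exposure,),
                            out,
                            "validated control's CI includes zero despite its "
                            "well-established outcome association; suggests systematic "
                            "selection bias",
                        )
                    )
                elif c["significant"] and sc == -expected:
                    firings.append(
                        RuleFiring(
                            "R4",
                            (ctrl.exposure,),
                            out,
                            "validated control is significant in the direction OPPOSITE "
                            "to its established association; suggests systematic "
                            "selection bias",
                        )
                    )

    warnings = []
    ctrl_sources = {c.source_gwas for c in controls}
    if (
        primary.source_gwas is not None
        and controls
        and ctrl_sources == {primary.source_gwas}
    ):
        warnings.append(
            "primary and all controls come from the same source GWAS "
            f"({primary.source_gwas}); systematic selection bias distorting all of "
            "them alike is undetectable by the antagonist/similar-activity rules alone"
        )

    return AuditVerdict(
        alpha=alpha,
        estimates=est,
        firings=firings,
        quadrants=quadrants,
        warnings=warnings,
    )


def _shaded_quadrants(role: str, expected_sign: int = 0) -> list[tuple[int, int]]:
    """Sign quadrants (x=primary, y=control) indicating selection bias."""
    if role == "antagonist":
        return [(1, 1), (-1, -1)]
    if role == "similar_activity":
        return [(1, -1), (-1, 1)]
    if role == "validated_control":
        # control axis opposite to its established direction
        return [(1, -expected_sign), (-1, -expected_sign)]
    return []


def concordance_scatter(
    results: dict[tuple[str, str], MRResults],
    specs: list[ControlSpec],
    path=None,
):
    """Primary-vs-control estimate scatter with bias quadrants shaded.

    One panel per (primary, control) pair; each shared outcome is one
    point with 95% CI bars on both axes.  The shaded region marks the
    sign quadrants whose occupancy would fire the pair's audit rule.
    Returns (figure, pairing table).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    primaries = [s for s in specs if s.role == "primary"]
    if len(primaries) != 1:
        raise ConfigError("exactly one primary exposure required")
    primary = primaries[0]
    controls = sorted((s for s in specs if s.role != "primary"), key=lambda s: s.exposure)
    outcomes = sorted({out for (_, out) in results})

    rows = []
    for ctrl in controls:
        for out in outcomes:
            if (primary.exposure, out) in results and (ctrl.exposure, out) in results:
                p, c = results[(primary.exposure, out)], results[(ctrl.exposure, out)]
                rows.append(
                    {
                        "primary": primary.exposure,
                        "control": ctrl.exposure,
                        "role": ctrl.role,
                        "outcome": out,
                        "x": p.estimate,
                        "x_lo": p.ci_low,
                        "x_hi": p.ci_high,
                        "y": c.estimate,
                        "y_lo": c.ci_low,
                        "y_hi": c.ci_high,
                    }
                )
    pairs = pd.DataFrame(rows)
    if pairs.empty:
        raise ConfigError("need >= 2 exposures with results on >= 1 shared outcome")

    panels = pairs.groupby(["primary", "control"], sort=True)
    n_panels = panels.ngroups
    fig, axes = plt.subplots(1, n_panels, figsize=(4.2 * n_panels, 4.2), squeeze=False)
    for ax, ((pname, cname), sub) in zip(axes[0], panels):
        role = sub["role"].iloc[0]
        expected = next(
            (s.expected_outcome_sign for s in controls if s.exposure == cname), 0
        )
        lim = 1.1 * max(
            float(np.abs(sub[["x_lo", "x_hi", "y_lo", "y_hi"]]).max().max()), 1e-6
        )
        for qx, qy in _shaded_quadrants(role, expected):
            ax.fill_between(
                [0, qx * lim], 0, qy * lim, color="0.8", alpha=0.6, linewidth=0
            )
        x, y = sub["x"].to_numpy(), sub["y"].to_numpy()
        ax.errorbar(
            x,
            y,
            xerr=[x - sub["x_lo"].to_numpy(), sub["x_hi"].to_numpy() - x],
            yerr=[y - sub["y_lo"].to_numpy(), sub["y_hi"].to_numpy() - y],
            fmt="o",
            capsize=2,
        )
        for _, r in sub.iterrows():
            ax.annotate(
                r["outcome"],
                (float(r["x"]), float(r["y"])),
                fontsize=8,
                xytext=(3, 3),
                textcoords="offset points",
            )
        ax.axhline(0, color="k", lw=0.7)
        ax.axvline(0, color="k", lw=0.7)
        ax.set_xlim(-lim, lim)
        ax.set_ylim(-lim, lim)
        ax.set_xlabel(f"{pname} effect on outcome")
        ax.set_ylabel(f"{cname} effect on outcome")
        ax.set_title(f"{pname} vs {cname} ({role})\nshaded: selection-bias pattern")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig, pairs
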