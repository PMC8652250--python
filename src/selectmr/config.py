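"""Simulation configuration: instrument panel, phenotype model, survival model.

The data-generating process is parameterized by three objects:

* :class:`SnpPanel` — the genetic instruments: alleles, effect-allele
  frequencies, and the per-allele additive effects (``gamma``) of each SNP
  on each exposure it instruments.
* :class:`PhenotypeConfig` — the phenotype model: causal effects of the
  exposures on the outcome, confounder effects, the competing-risk
  liability, and the instrument-explained variance ``r2_ge``.
* :class:`SurvivalConfig` — per-unit hazard ratios on survival to
  recruitment, and the target survivor fraction ``p_sel`` under all-null
  hazards.

All three serialize to/from JSON and flat ``key=value`` text, and carry a
stable content digest used by run manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np

from .errors import ConfigError

EXPOSURE_LABELS = ("e1", "e2", "e3")

# non-palindromic allele pairs cycled through by random_panel
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))
_PALINDROMIC = ({"A", "T"}, {"C", "G"})


def is_palindromic(a1: str, a2: str) -> bool:
    """True when the allele pair is strand-ambiguous (A/T or C/G)."""
    return {a1.upper(), a2.upper()} in _PALINDROMIC


@dataclass
class SnpPanel:
    """Instrument definitions for up to three exposures.

    Parameters
    ----------
    snp_id, effect_allele, other_allele
        Per-SNP identifiers and single-nucleotide allele codes.
    maf
        Effect-allele frequency, each in (0, 0.5].
    gamma
        ``(m, k)`` matrix of per-allele additive effects of SNP ``j`` on
        exposure ``k`` (exposure-SD units per allele, before the
        ``r2_ge`` rescaling applied at simulation time).
    exposure_labels
        Names of the instrumented exposures, drawn from ``("e1","e2","e3")``.
    """

    snp_id: list[str]
    effect_allele: list[str]
    other_allele: list[str]
    maf: np.ndarray
    gamma: np.ndarray
    exposure_labels: tuple[str, ...] = ("e1",)

    def __post_init__(self) -> None:
        self.maf = np.asarray(self.maf, dtype=float)
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        if self.gamma.shape[0] != self.n_snps and self.gamma.shape[1] == self.n_snps:
            self.gamma = self.gamma.T
        self.exposure_labels = tuple(self.exposure_labels)
        self.validate()

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def validate(self) -> None:
        m = self.n_snps
        if m == 0:
            raise ConfigError("SnpPanel must contain at least one SNP")
        if len(set(self.snp_id)) != m:
            raise ConfigError("snp_id values must be unique")
        for name in ("effect_allele", "other_allele"):
            if len(getattr(self, name)) != m:
                raise ConfigError(f"{name} length does not match snp_id")
        for sid, ea, oa in zip(self.snp_id, self.effect_allele, self.other_allele):
            if ea == oa:
                raise ConfigError(f"SNP {sid}: effect_allele equals other_allele")
        if self.maf.shape != (m,):
            raise ConfigError("maf length does not match snp_id")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ConfigError("maf must lie in (0, 0.5]")
        if self.gamma.shape != (m, len(self.exposure_labels)):
            raise ConfigError(
                f"gamma must have shape (n_snps, n_exposures) = "
                f"({m}, {len(self.exposure_labels)}), got {self.gamma.shape}"
            )
        if np.any(np.all(self.gamma == 0, axis=1)):
            bad = [s for s, row in zip(self.snp_id, self.gamma) if not row.any()]
            raise ConfigError(f"SNPs with no nonzero gamma (relevance violated): {bad}")
        unknown = set(self.exposure_labels) - set(EXPOSURE_LABELS)
        if unknown:
            raise ConfigError(f"unknown exposure labels {sorted(unknown)}")

    def gamma_for(self, label: str) -> np.ndarray:
        """Per-allele effects on one exposure (zeros if not instrumented)."""
        if label in self.exposure_labels:
            return self.gamma[:, self.exposure_labels.index(label)]
        return np.zeros(self.n_snps)

    def to_dict(self) -> dict:
        return {
            "snp_id": list(self.snp_id),
            "effect_allele": list(self.effect_allele),
            "other_allele": list(self.other_allele),
            "maf": self.maf.tolist(),
            "gamma": self.gamma.tolist(),
            "exposure_labels": list(self.exposure_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SnpPanel":
        return cls(
            snp_id=list(d["snp_id"]),
            effect_allele=list(d["effect_allele"]),
            other_allele=list(d["other_allele"]),
            maf=np.asarray(d["maf"], dtype=float),
            gamma=np.asarray(d["gamma"], dtype=float),
            exposure_labels=tuple(d.get("exposure_labels", ("e1",))),
        )


def random_panel(
    n_snps: int = 10,
    exposures: Sequence[str] = ("e1",),
    seed: int = 0,
    maf_range: tuple[float, float] = (0.1, 0.5),
    snps_per_exposure: Sequence[int] | None = None,
) -> SnpPanel:
    """Draw a panel of independent instruments with MAF ~ Uniform(maf_range).

    SNPs are partitioned into disjoint blocks, one block per exposure
    (evenly when ``snps_per_exposure`` is not given), so each exposure has
    its own instruments — the structure of a multi-exposure MR design with
    instruments from separate discovery GWASs.  Raw gamma is 1 within a
    block; the simulator rescales it to hit ``r2_ge``.
    """
    exposures = tuple(exposures)
    if snps_per_exposure is None:
        base, extra = divmod(n_snps, len(exposures))
        snps_per_exposure = [base + (i < extra) for i in range(len(exposures))]
    if sum(snps_per_exposure) != n_snps:
        raise ConfigError("snps_per_exposure must sum to n_snps")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, size=n_snps)
    gamma = np.zeros((n_snps, len(exposures)))
    start = 0
    for k, cnt in enumerate(snps_per_exposure):
        gamma[start : start + cnt, k] = 1.0
        start += cnt
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(n_snps)]
    return SnpPanel(
        snp_id=[f"rs{j + 1}" for j in range(n_snps)],
        effect_allele=[p[0] for p in pairs],
        other_allele=[p[1] for p in pairs],
        maf=maf,
        gamma=gamma,
        exposure_labels=exposures,
    )


@dataclass
class PhenotypeConfig:
    """Phenotype model parameters.

    ``beta_e*d`` are causal effects of each exposure on the outcome D, per
    exposure SD (log-odds per SD when ``d_type == "binary"``).  ``phi_c_e``
    and ``phi_c_d`` are the effects of the measured confounder C on every
    exposure and on D; ``psi_u_cr`` and ``psi_u_d`` those of the unmeasured
    shared confounder U on the competing-risk liability CR and on D.
    ``r2_ge`` is the variance fraction of each instrumented exposure
    explained by its instruments.  Exposures are standardized to unit
    marginal variance; ``antagonist_rho`` couples the non-genetic residuals
    of e1 and e2 (negative for a biochemical antagonist).
    """

    beta_e1d: float = 0.3
    beta_e2d: float = 0.0
    beta_e3d: float = 0.0
    phi_c_e: float = 0.3
    phi_c_d: float = 0.3
    psi_u_cr: float = 0.5
    psi_u_d: float = 0.3
    r2_ge: float = 0.1
    d_type: str = "continuous"
    d_prevalence: float = 0.1
    antagonist_rho: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.r2_ge < 1:
            raise ConfigError("r2_ge must lie in (0, 1)")
        if self.d_type not in ("binary", "continuous"):
            raise ConfigError("d_type must be 'binary' or 'continuous'")
        if self.d_type == "binary" and not 0 < self.d_prevalence < 1:
            raise ConfigError("d_prevalence must lie in (0, 1) for binary D")
        if not -1 <= self.antagonist_rho <= 1:
            raise ConfigError("antagonist_rho must lie in [-1, 1]")
        if abs(self.psi_u_cr) > 1:
            raise ConfigError("psi_u_cr must lie in [-1, 1] (CR has unit variance)")

    def beta_for(self, label: str) -> float:
        return {"e1": self.beta_e1d, "e2": self.beta_e2d, "e3": self.beta_e3d}[label]

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "PhenotypeConfig":
        return cls(**d)


@dataclass
class SurvivalConfig:
    """Survival-to-recruitment model parameters.

    Death times are exponential with rate ``lambda0 * exp(eta)`` where
    ``eta`` is log-linear in the (mean-centered) instrument score, E1, C,
    D and U with per-unit hazard ratios ``hr_gs``, ``hr_e1s``, ``hr_cs``,
    ``hr_ds``, ``hr_us``.  The recruitment horizon is one time unit and
    ``lambda0 = -ln(p_sel)``, so under all-null hazards the expected
    survivor fraction is exactly ``p_sel``.
    """

    hr_gs: float = 1.0
    hr_e1s: float = 1.0
    hr_cs: float = 1.0
    hr_ds: float = 1.0
    hr_us: float = 1.0
    p_sel: float = 0.7

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("hr_gs", "hr_e1s", "hr_cs", "hr_ds", "hr_us"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0 < self.p_sel < 1:
            raise ConfigError("p_sel must lie in (0, 1)")

    @property
    def lambda0(self) -> float:
        return -float(np.log(self.p_sel))

    @property
    def is_null(self) -> bool:
        """True when no variable affects survival (pure random thinning)."""
        return all(
            getattr(self, n) == 1.0
            for n in ("hr_gs", "hr_e1s", "hr_cs", "hr_ds", "hr_us")
        )

    def replace(self, **kw) -> "SurvivalConfig":
        d = self.to_dict()
        d.update(kw)
        return SurvivalConfig(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalConfig":
        return cls(**d)


def config_digest(*configs) -> str:
    """Stable sha256 hex digest of a set of config objects."""
    payload = [c.to_dict() if hasattr(c, "to_dict") else c for c in configs]
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


_SECTIONS = {"panel": SnpPanel, "pheno": PhenotypeConfig, "surv": SurvivalConfig}


def load_config(path: str) -> dict:
    """Read a simulation config (JSON or flat key=value) into objects.

    JSON documents hold sections ``panel`` / ``pheno`` / ``surv`` (each
    optional) mirroring the dataclasses field-for-field.  The key=value
    dialect uses dotted keys (``surv.hr_gs = 1.5``); list-valued panel
    fields take comma-separated values.  Missing sections fall back to
    defaults (panel: :func:`random_panel` driven by ``panel.n_snps`` /
    ``panel.seed`` if only those are given).
    """
    with open(path) as fh:
        text = fh.read()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        raw = _parse_keyvalue(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config document must be a mapping")
    out: dict = {}
    panel_raw = raw.get("panel", {})
    if set(panel_raw) and set(panel_raw) <= {"n_snps", "seed", "exposures", "snps_per_exposure"}:
        if "exposures" in panel_raw and isinstance(panel_raw["exposures"], str):
            panel_raw["exposures"] = tuple(panel_raw["exposures"].split(","))
        out["panel"] = random_panel(**{k: v for k, v in panel_raw.items()})
    elif panel_raw:
        out["panel"] = SnpPanel.from_dict(panel_raw)
    else:
        out["panel"] = random_panel()
    out["pheno"] = PhenotypeConfig.from_dict(raw.get("pheno", {}))
    out["surv"] = SurvivalConfig.from_dict(raw.get("surv", {}))
    return out


def _coerce(value: str):
    value = value.strip()
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    if "," in value:
        return [_coerce(v) for v in value.split(",")]
    return value


def _parse_keyvalue(text: str) -> dict:
    raw: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected key=value, got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if "." not in key:
            raise ConfigError(f"line {lineno}: key must be section.field, got {key!r}")
        section, fld = key.split(".", 1)
        if section not in _SECTIONS:
            raise ConfigError(f"line {lineno}: unknown section {section!r}")
        raw.setdefault(section, {})[fld] = _coerce(value)
    return raw
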