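"""Instrument screening and exposure/outcome harmonization.

Screening applies the standard instrument-selection rules: genome-wide
significance (p < 5e-8) on the exposure and instrument strength
F = (beta/se)^2 >= 10.  Harmonization aligns effect alleles between the
exposure and outcome summary tables, flipping outcome signs (and allele
frequencies) for swap-coded records and resolving palindromic (A/T, C/G)
variants by allele frequency, dropping the frequency-ambiguous ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import is_palindromic
from .errors import EmptyIntersectionError, NoInstrumentsError
from .gwas import AssociationRecord, SummaryStatsTable

log = logging.getLogger(__name__)

PALINDROMIC_EAF_WINDOW = (0.42, 0.58)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP's aligned exposure/outcome effect pair."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    aligned: bool = True


class InstrumentSet(list):
    """A list of :class:`HarmonizedInstrument` with a drop log."""

    def __init__(self, items=(), dropped=None):
        super().__init__(items)
        self.dropped: list[tuple[str, str]] = list(dropped or [])


def f_statistic(rec: AssociationRecord | float, se: float | None = None) -> float:
    """Instrument-strength F statistic, (beta / se)^2.

    Accepts an :class:`AssociationRecord` or a (beta, se) pair.
    """
    if se is None:
        beta, se = rec.beta, rec.se
    else:
        beta = float(rec)
    if se <= 0:
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


def screen_instruments(
    table: SummaryStatsTable, p_max: float = 5e-8, f_min: float = 10.0
) -> SummaryStatsTable:
    """Retain genome-wide-significant, non-weak instruments.

    Keeps records with exposure p < ``p_max`` and F >= ``f_min``; raises
    :class:`NoInstrumentsError` when nothing survives.
    """
    df = table.data
    f = (df["beta"] / df["se"]) ** 2
    keep = (df["pval"] < p_max) & (f >= f_min)
    dropped = list(table.dropped)
    for _, row in df[~keep].iterrows():
        fval = (row["beta"] / row["se"]) ** 2
        reason = "p>=p_max" if row["pval"] >= p_max else "weak-instrument"
        if row["pval"] >= p_max and fval < f_min:
            reason = "p>=p_max+weak-instrument"
        dropped.append((str(row["SNP"]), reason))
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("screen_instruments(%s): dropped %d of %d records", table.trait, n_drop, len(df))
    if not keep.any():
        raise NoInstrumentsError(
            f"no instruments for {table.trait} pass p<{p_max} and F>={f_min}"
        )
    return SummaryStatsTable(
        trait=table.trait,
        trait_type=table.trait_type,
        data=df[keep].reset_index(drop=True),
        dropped=dropped,
    )


def harmonize(
    exp_table: SummaryStatsTable, out_table: SummaryStatsTable
) -> InstrumentSet:
    """Pair exposure and outcome records SNP-by-SNP with allele alignment.

    Rules, applied to the snp_id intersection:

    * identical allele coding -> pass through;
    * swapped coding (exposure effect allele equals outcome other allele
      and vice versa) -> flip the outcome beta's sign, replace its eaf by
      1 - eaf;
    * palindromic SNPs (A/T or C/G) are dropped when either sample's eaf
      lies in [0.42, 0.58], otherwise aligned so both effect-allele
      frequencies fall on the same side of 0.5;
    * any other allele combination -> dropped as a coding mismatch.

    Raises :class:`EmptyIntersectionError` when the tables share no SNPs.
    """
    if len(exp_table) == 0 or len(out_table) == 0:
        raise EmptyIntersectionError("exposure or outcome table is empty")
    out_by_id = {r.snp_id: r for r in out_table.records}
    shared = [r for r in exp_table.records if r.snp_id in out_by_id]
    if not shared:
        raise EmptyIntersectionError(
            f"no overlapping SNPs between {exp_table.trait} and {out_table.trait}"
        )

    insts: list[HarmonizedInstrument] = []
    dropped: list[tuple[str, str]] = []
    lo, hi = PALINDROMIC_EAF_WINDOW
    for e in shared:
        o = out_by_id[e.snp_id]
        ea_e, oa_e = e.effect_allele.upper(), e.other_allele.upper()
        ea_o, oa_o = o.effect_allele.upper(), o.other_allele.upper()
        same = (ea_e, oa_e) == (ea_o, oa_o)
        swap = (ea_e, oa_e) == (oa_o, ea_o)
        if not (same or swap):
            dropped.append((e.snp_id, "allele-mismatch"))
            continue
        if is_palindromic(ea_e, oa_e):
            if lo <= e.eaf <= hi or lo <= o.eaf <= hi:
                dropped.append((e.snp_id, "palindromic-ambiguous"))
                continue
            # letters cannot distinguish strands; frequency decides
            flip = (e.eaf - 0.5) * (o.eaf - 0.5) < 0
        else:
            flip = swap
        beta_out = -o.beta if flip else o.beta
        insts.append(
            HarmonizedInstrument(
                snp_id=e.snp_id,
                beta_exp=e.beta,
                se_exp=e.se,
                beta_out=beta_out,
                se_out=o.se,
            )
        )
    for sid, reason in dropped:
        log.info("harmonize: dropped %s (%s)", sid, reason)
    return InstrumentSet(insts, dropped=dropped)


def instrument_arrays(insts) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(beta_exp, se_exp, beta_out, se_out) arrays from an instrument set."""
    bx = np.array([i.beta_exp for i in insts], dtype=float)
    sx = np.array([i.se_exp for i in insts], dtype=float)
    by = np.array([i.beta_out for i in insts], dtype=float)
    sy = np.array([i.se_out for i in insts], dtype=float)
    return bx, sx, by, sy
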