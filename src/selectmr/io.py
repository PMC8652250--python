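"""Summary-statistics file dialect, run manifests, result tables.

The canonical summary-statistics dialect is an 8-column tab-separated
table with header ``SNP effect_allele other_allele eaf beta se pval n``.
Columns are name-keyed (order free); extra columns are ignored and
logged.  The same dialect ingests externally supplied GWAS summary files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError
from .gwas import SUMMARY_COLUMNS, SummaryStatsTable

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "exposure",
    "outcome",
    "method",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "pval",
    "k",
    "q",
    "q_pval",
    "egger_intercept",
    "egger_intercept_se",
    "egger_intercept_pval",
]


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    table.data[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(
    path, trait: str | None = None, trait_type: str = "continuous"
) -> SummaryStatsTable:
    """Read a summary-statistics table, validating each row.

    Rows violating the record invariants (se <= 0, eaf outside (0,1),
    pval outside (0,1], non-finite beta) are rejected individually with
    their line numbers collected in ``table.dropped``; a missing
    mandatory column raises :class:`SchemaError` naming it.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    extra = [c for c in df.columns if c not in SUMMARY_COLUMNS]
    if extra:
        log.info("%s: ignoring extra columns %s", path, extra)
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")

    bad = (
        ~np.isfinite(df["beta"])
        | ~(df["se"] > 0)
        | ~((df["eaf"] > 0) & (df["eaf"] < 1))
        | ~((df["pval"] > 0) & (df["pval"] <= 1))
        | ~(df["n"] > 0)
    )
    dropped = []
    for idx in df.index[bad]:
        lineno = int(idx) + 2  # header is line 1
        dropped.append((str(df.loc[idx, "SNP"]), f"invalid-record (line {lineno})"))
        log.warning("%s line %d: record rejected", path, lineno)
    name = trait if trait is not None else _stem(path)
    return SummaryStatsTable(
        trait=name,
        trait_type=trait_type,
        data=df.loc[~bad, SUMMARY_COLUMNS].reset_index(drop=True),
        dropped=dropped,
    )


def write_results(results: list[tuple[str, str, "MRResults"]], path) -> None:
    """Write (exposure, outcome, MRResults) rows as a tab-separated table."""
    rows = []
    for exposure, outcome, res in results:
        d = res.to_dict()
        d.update(exposure=exposure, outcome=outcome)
        rows.append(d)
    pd.DataFrame(rows)[RESULT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("exposure", "outcome", "estimate", "pval") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return df


def _stem(path) -> str:
    name = str(path).rsplit("/", 1)[-1]
    return name.rsplit(".", 1)[0]


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    subcommand: str
    seed: int | None = None
    config_digest: str | None = None
    version: str = __version__
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def add_input(self, label: str, path) -> None:
        self.inputs[label] = {"path": str(path), "sha256": file_digest(path)}

    def add_output(self, label: str, path) -> None:
        self.outputs[label] = {"path": str(path), "sha256": file_digest(path)}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
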