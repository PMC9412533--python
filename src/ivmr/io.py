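"""Reading and writing GWAS summary statistics and instrument specifications.

File dialect
------------
UTF-8 tab-separated values with a header row; missing values are written
``NA``.  Canonical summary-statistic columns are::

    variant_id  effect_allele  other_allele  eaf  beta  se  pvalue  n

``variant_id``, ``effect_allele``, ``other_allele``, ``beta`` and ``se`` are
mandatory; ``eaf``, ``pvalue`` and ``n`` may be absent or ``NA``.  Consortium
exports that use different headers are adapted with a rename map (file column
name -> canonical name) passed as ``dialect``.

Betas are stored on the scale the source declares — SD units of the exposure
for exposure GWAS, log-odds for binary outcomes.  No rescaling is ever applied
silently; per-SD scaling of exposure effects is assumed done upstream.

Instrument specifications are TSV files with columns ``exposure_name`` and
``variant_id``, one row per instrument variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .exceptions import FormatError

__all__ = [
    "VariantAssociation",
    "InstrumentSpec",
    "ValidationReport",
    "SummaryStats",
    "read_summary_stats",
    "read_instrument_spec",
    "write_summary_stats",
    "write_results_table",
    "read_results_table",
]

VALID_ALLELES = frozenset("ACGT")

#: canonical column order for summary-statistic tables
SUMMARY_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)
MANDATORY_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se")

#: canonical column order for result tables (one row per source plus a
#: combined row per estimate)
RESULT_COLUMNS = (
    "exposure",
    "outcome",
    "source",
    "n_snps",
    "OR",
    "CI_low",
    "CI_high",
    "p",
    "q_BH",
    "method",
)


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is per effect-allele copy, in SD units of a continuous trait or
    log-odds for a binary one.  ``eaf``, ``pvalue`` and ``n`` may be ``None``.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    n: float | None = None

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele are identical")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError("standard error must be positive and finite")
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            raise ValueError("eaf must lie strictly inside (0, 1)")
        if self.pvalue is not None and not 0.0 < self.pvalue <= 1.0:
            raise ValueError("pvalue must lie in (0, 1]")
        if self.n is not None and not self.n > 0:
            raise ValueError("sample size must be positive")

    @property
    def is_palindromic(self) -> bool:
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass(frozen=True)
class InstrumentSpec:
    """Named set of instrument variants for one exposure (per-SD scale)."""

    exposure_name: str
    variant_ids: tuple[str, ...]
    scale_note: str = "per SD"

    def __post_init__(self) -> None:
        if len(self.variant_ids) == 0:
            raise ValueError(f"instrument for {self.exposure_name!r} lists no variants")
        seen: set[str] = set()
        for vid in self.variant_ids:
            if vid in seen:
                raise ValueError(
                    f"duplicate variant {vid!r} in instrument for {self.exposure_name!r}"
                )
            seen.add(vid)

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclass
class ValidationReport:
    """Row-level outcome of reading a summary-statistic file.

    Row numbers count data rows from 1 (the header is row 0).  The invariant
    ``n_accepted + n_rejected == n_total`` always holds.
    """

    n_total: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class SummaryStats:
    """A validated collection of :class:`VariantAssociation` records.

    ``table`` holds one accepted row per record with canonical columns;
    ``report`` records what was rejected and why.
    """

    table: pd.DataFrame
    report: ValidationReport = field(default_factory=ValidationReport)

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records())

    @property
    def variant_ids(self) -> set[str]:
        return set(self.table["variant_id"])

    def get(self, variant_id: str) -> VariantAssociation | None:
        rows = self.table[self.table["variant_id"] == variant_id]
        if rows.empty:
            return None
        return _row_to_record(rows.iloc[0])

    def for_variants(self, variant_ids: Iterable[str]) -> "SummaryStats":
        ids = set(variant_ids)
        return SummaryStats(
            self.table[self.table["variant_id"].isin(ids)].reset_index(drop=True)
        )

    def records(self) -> list[VariantAssociation]:
        return [_row_to_record(row) for _, row in self.table.iterrows()]

    @classmethod
    def from_records(cls, records: Iterable[VariantAssociation]) -> "SummaryStats":
        records = list(records)
        for rec in records:
            rec.validate()
        table = pd.DataFrame(
            [
                {
                    "variant_id": r.variant_id,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "eaf": np.nan if r.eaf is None else r.eaf,
                    "beta": r.beta,
                    "se": r.se,
                    "pvalue": np.nan if r.pvalue is None else r.pvalue,
                    "n": np.nan if r.n is None else r.n,
                }
                for r in records
            ],
            columns=list(SUMMARY_COLUMNS),
        )
        report = ValidationReport(n_total=len(records), n_accepted=len(records))
        return cls(table, report)


def _row_to_record(row: pd.Series) -> VariantAssociation:
    def opt(name: str) -> float | None:
        val = row[name]
        return None if pd.isna(val) else float(val)

    return VariantAssociation(
        variant_id=str(row["variant_id"]),
        effect_allele=str(row["effect_allele"]),
        other_allele=str(row["other_allele"]),
        beta=float(row["beta"]),
        se=float(row["se"]),
        eaf=opt("eaf"),
        pvalue=opt("pvalue"),
        n=opt("n"),
    )


def _validate_row(row: pd.Series) -> str | None:
    """Return a rejection reason for one parsed row, or None if acceptable."""
    if pd.isna(row["variant_id"]) or str(row["variant_id"]).strip() == "":
        return "missing variant_id"
    for col in ("effect_allele", "other_allele"):
        if row[col] not in VALID_ALLELES:
            return f"invalid {col} {row[col]!r}"
    if row["effect_allele"] == row["other_allele"]:
        return "effect and other allele identical"
    if pd.isna(row["beta"]):
        return "non-numeric beta"
    if pd.isna(row["se"]) or not row["se"] > 0:
        return "se must be > 0"
    if not pd.isna(row["eaf"]) and not 0.0 < row["eaf"] < 1.0:
        return "eaf outside (0, 1)"
    if not pd.isna(row["pvalue"]) and not 0.0 < row["pvalue"] <= 1.0:
        return "pvalue outside (0, 1]"
    if not pd.isna(row["n"]) and not row["n"] > 0:
        return "non-positive sample size"
    return None


def read_summary_stats(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> SummaryStats:
    """Read a tab-separated summary-statistic file.

    Parameters
    ----------
    path
        TSV file with a header row.
    dialect
        Optional rename map from the file's column names to the canonical
        names, for consortium exports with non-canonical headers.

    Rows violating the record invariants are rejected, not fatal; the
    rejection reasons (with 1-based data-row numbers) are collected in the
    returned :class:`SummaryStats.report`.  A reported p-value that disagrees
    with ``2*Phi(-|beta/se|)`` by more than a factor of two is recorded as a
    warning, not a rejection.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"])
    if dialect:
        df = df.rename(columns=dict(dialect))
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    for col in ("eaf", "pvalue", "n"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(SUMMARY_COLUMNS)].copy()

    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype("string").str.strip().str.upper()
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    report = ValidationReport(n_total=len(df))
    keep = np.ones(len(df), dtype=bool)
    for i, (_, row) in enumerate(df.iterrows()):
        reason = _validate_row(row)
        if reason is not None:
            keep[i] = False
            report.rejected.append((i + 1, reason))
            continue
        if not pd.isna(row["pvalue"]):
            p_implied = 2.0 * _stats.norm.sf(abs(row["beta"] / row["se"]))
            if p_implied > 0 and not (0.5 <= row["pvalue"] / p_implied <= 2.0):
                report.warnings.append(
                    (
                        i + 1,
                        f"pvalue {row['pvalue']:.3g} inconsistent with "
                        f"beta/se (implies {p_implied:.3g})",
                    )
                )
    accepted = df[keep].reset_index(drop=True)
    accepted["variant_id"] = accepted["variant_id"].astype(str)
    accepted["effect_allele"] = accepted["effect_allele"].astype(str)
    accepted["other_allele"] = accepted["other_allele"].astype(str)
    report.n_accepted = len(accepted)
    return SummaryStats(accepted, report)


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    """Write a summary-statistic table in the canonical TSV dialect."""
    stats.table.to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.10g"
    )


def read_instrument_spec(path: str | Path) -> dict[str, InstrumentSpec]:
    """Read instrument specifications (columns exposure_name, variant_id).

    Returns a mapping from exposure name to :class:`InstrumentSpec`,
    preserving file order.  A variant listed twice for the same exposure is a
    :class:`FormatError` naming the rsID.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("exposure_name", "variant_id"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    specs: dict[str, InstrumentSpec] = {}
    for name, group in df.groupby("exposure_name", sort=False):
        ids = [str(v).strip() for v in group["variant_id"]]
        dupes = {v for v in ids if ids.count(v) > 1}
        if dupes:
            raise FormatError(
                f"duplicate variant {sorted(dupes)[0]!r} in instrument for {name!r}"
            )
        specs[str(name)] = InstrumentSpec(str(name), tuple(ids))
    return specs


def _fmt(value: float | None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.6g}"


def write_results_table(results: Iterable, path: str | Path) -> None:
    """Serialize :class:`~ivmr.meta.MetaEstimate` objects as a results TSV.

    One row per per-source estimate plus a ``combined`` row, in the fixed
    column order ``exposure outcome source n_snps OR CI_low CI_high p q_BH
    method``.  Floats carry six significant digits so the table round-trips
    through :func:`read_results_table`.
    """
    lines = ["\t".join(RESULT_COLUMNS)]
    for meta in results:
        for label, est in meta.per_source:
            lo, hi = est.or_conf_int()
            lines.append(
                "\t".join(
                    [
                        meta.exposure,
                        meta.outcome,
                        label,
                        str(est.n_snps),
                        _fmt(est.odds_ratio),
                        _fmt(lo),
                        _fmt(hi),
                        _fmt(est.pvalue),
                        "NA",
                        est.method,
                    ]
                )
            )
        lo, hi = meta.or_conf_int()
        lines.append(
            "\t".join(
                [
                    meta.exposure,
                    meta.outcome,
                    "combined",
                    str(meta.n_snps),
                    _fmt(meta.odds_ratio),
                    _fmt(lo),
                    _fmt(hi),
                    _fmt(meta.pvalue),
                    _fmt(meta.q_bh),
                    meta.method,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results_table`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing result columns {missing} in {path}")
    return df[list(RESULT_COLUMNS)]
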