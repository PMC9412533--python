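"""Allele harmonization of exposure and outcome summary statistics.

Before a two-sample MR analysis, every instrument variant's outcome
association must be expressed for the *same* effect allele as its exposure
association.  Three situations arise:

* the outcome record already uses the exposure's effect allele — keep it;
* the outcome record uses the opposite allele (labels swapped) — negate the
  outcome beta and complement its frequency;
* the records were read off opposite strands — reconcile by complementing
  the outcome alleles (A<->T, C<->G) first, then apply the two rules above.

Palindromic variants (allele pair A/T or C/G) are their own strand
complement, so allele labels cannot reveal strand.  They are aligned by
effect-allele frequency instead, and dropped as ambiguous when the frequency
is too close to 0.5 to be informative (default window [0.42, 0.58]) or
missing on either side.  Variants whose allele sets cannot be reconciled at
all are dropped as non-concordant.

Every drop is logged with a reason code so the analysis is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .exceptions import EmptyInstrumentError
from .io import InstrumentSpec, SummaryStats, VariantAssociation

__all__ = [
    "ExclusionReason",
    "HarmonizedInstrument",
    "classify_palindromic",
    "align_alleles",
    "harmonize",
    "write_harmonization_log",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ExclusionReason:
    """Enumerated reason codes recorded in the harmonization log."""

    NON_CONCORDANT = "non_concordant"
    PALINDROMIC_AMBIGUOUS = "palindromic_ambiguous"
    MISSING_IN_OUTCOME = "missing_in_outcome"
    SENSITIVITY = "sensitivity_exclusion"


#: columns of :attr:`HarmonizedInstrument.records`
RECORD_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf_exposure",
    "beta_exposure",
    "se_exposure",
    "eaf_outcome",
    "beta_outcome",
    "se_outcome",
)


@dataclass
class HarmonizedInstrument:
    """Per-variant paired exposure/outcome effects after allele alignment.

    ``records`` is ordered by variant_id and oriented to the exposure's
    effect allele: ``beta_exposure`` in SD units, ``beta_outcome`` in
    log-odds.  ``exclusions`` lists (variant_id, reason) pairs; a variant
    never appears in both.
    """

    exposure_name: str
    outcome_name: str
    records: pd.DataFrame
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.records["variant_id"])


def classify_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    pair = {effect_allele, other_allele}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _swap(rec: VariantAssociation) -> VariantAssociation:
    """Re-express a record for the opposite effect allele."""
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def _relabel(rec: VariantAssociation, effect: str, other: str) -> VariantAssociation:
    """Rewrite allele labels (strand change) without touching effects."""
    return replace(rec, effect_allele=effect, other_allele=other)


def align_alleles(
    exposure_rec: VariantAssociation,
    outcome_rec: VariantAssociation,
    *,
    ambiguity_window: tuple[float, float] = (0.42, 0.58),
    try_strand_flip: bool = True,
) -> tuple[VariantAssociation | None, str | None]:
    """Align one outcome record to the exposure record's effect allele.

    Returns ``(aligned_outcome, None)`` on success or ``(None, reason)`` when
    the variant must be excluded.  Palindromic pairs are aligned by frequency
    concordance when both frequencies fall outside ``ambiguity_window``.
    """
    if exposure_rec.variant_id != outcome_rec.variant_id:
        raise ValueError(
            f"variant mismatch: {exposure_rec.variant_id} vs {outcome_rec.variant_id}"
        )
    exp_pair = (exposure_rec.effect_allele, exposure_rec.other_allele)
    out_pair = (outcome_rec.effect_allele, outcome_rec.other_allele)
    lo, hi = ambiguity_window

    if classify_palindromic(*exp_pair):
        if set(out_pair) != set(exp_pair):
            return None, ExclusionReason.NON_CONCORDANT
        if exposure_rec.eaf is None or outcome_rec.eaf is None:
            return None, ExclusionReason.PALINDROMIC_AMBIGUOUS
        if lo <= exposure_rec.eaf <= hi or lo <= outcome_rec.eaf <= hi:
            return None, ExclusionReason.PALINDROMIC_AMBIGUOUS
        # Labels first, then frequency concordance decides strand.
        cand = outcome_rec if out_pair == exp_pair else _swap(outcome_rec)
        if (cand.eaf < 0.5) != (exposure_rec.eaf < 0.5):
            cand = _swap(cand)
        return _relabel(cand, *exp_pair), None

    if out_pair == exp_pair:
        return outcome_rec, None
    if out_pair == (exp_pair[1], exp_pair[0]):
        return _swap(outcome_rec), None
    if try_strand_flip:
        flipped = (COMPLEMENT[out_pair[0]], COMPLEMENT[out_pair[1]])
        if flipped == exp_pair:
            return _relabel(outcome_rec, *exp_pair), None
        if flipped == (exp_pair[1], exp_pair[0]):
            return _relabel(_swap(outcome_rec), *exp_pair), None
    return None, ExclusionReason.NON_CONCORDANT


def harmonize(
    instrument: InstrumentSpec,
    exposure_stats: SummaryStats | pd.DataFrame,
    outcome_stats: SummaryStats | pd.DataFrame,
    *,
    outcome_name: str = "outcome",
    ambiguity_window: tuple[float, float] = (0.42, 0.58),
    try_strand_flip: bool = True,
) -> HarmonizedInstrument:
    """Pair and align exposure/outcome records for every instrument variant.

    The exposure table must contain every instrument variant (a missing one
    is a usage error); a variant absent from the outcome table is excluded
    with reason ``missing_in_outcome``.  Raises
    :class:`~ivmr.exceptions.EmptyInstrumentError` when nothing survives.
    """
    exposure_stats = _as_stats(exposure_stats)
    outcome_stats = _as_stats(outcome_stats)

    rows: list[dict] = []
    exclusions: list[tuple[str, str]] = []
    for vid in sorted(instrument.variant_ids):
        exp_rec = exposure_stats.get(vid)
        if exp_rec is None:
            raise LookupError(
                f"instrument variant {vid!r} absent from exposure statistics "
                f"for {instrument.exposure_name!r}"
            )
        out_rec = outcome_stats.get(vid)
        if out_rec is None:
            exclusions.append((vid, ExclusionReason.MISSING_IN_OUTCOME))
            continue
        aligned, reason = align_alleles(
            exp_rec,
            out_rec,
            ambiguity_window=ambiguity_window,
            try_strand_flip=try_strand_flip,
        )
        if aligned is None:
            exclusions.append((vid, reason))
            continue
        rows.append(
            {
                "variant_id": vid,
                "effect_allele": exp_rec.effect_allele,
                "other_allele": exp_rec.other_allele,
                "eaf_exposure": exp_rec.eaf,
                "beta_exposure": exp_rec.beta,
                "se_exposure": exp_rec.se,
                "eaf_outcome": aligned.eaf,
                "beta_outcome": aligned.beta,
                "se_outcome": aligned.se,
            }
        )
    if not rows:
        raise EmptyInstrumentError(
            f"no variants survive harmonization for "
            f"{instrument.exposure_name!r} / {outcome_name!r}"
        )
    records = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    return HarmonizedInstrument(
        instrument.exposure_name, outcome_name, records, exclusions
    )


def write_harmonization_log(
    harmonized: HarmonizedInstrument, path: str | Path
) -> None:
    """Write the exclusion log as TSV (variant_id, reason)."""
    df = pd.DataFrame(harmonized.exclusions, columns=["variant_id", "reason"])
    df.to_csv(path, sep="\t", index=False)


def _as_stats(stats: SummaryStats | pd.DataFrame) -> SummaryStats:
    if isinstance(stats, SummaryStats):
        return stats
    return SummaryStats(stats)
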