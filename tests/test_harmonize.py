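import itertools

import numpy as np
import pandas as pd
import pytest

from ivmr import (
    EmptyInstrumentError,
    InstrumentSpec,
    SummaryStats,
    VariantAssociation,
    align_alleles,
    classify_palindromic,
    harmonize,
)
from ivmr.harmonize import COMPLEMENT, ExclusionReason

from conftest import make_variant


@pytest.mark.parametrize(
    "ea,oa,expected",
    [
        ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
        ("A", "G", False), ("A", "C", False), ("T", "G", False), ("C", "T", False),
    ],
)
def test_palindromic_classification(ea, oa, expected):
    assert classify_palindromic(ea, oa) is expected


class TestAlignAlleles:
    def test_direct_match_unchanged(self):
        exp = make_variant("rs1", "T", "C", beta=0.1)
        out = make_variant("rs1", "T", "C", beta=0.05)
        aligned, reason = align_alleles(exp, out)
        assert reason is None and aligned.beta == 0.05

    def test_swapped_alleles_negate_outcome_beta(self):
        exp = make_variant("rs1", "T", "C", beta=0.1)
        out = make_variant("rs1", "C", "T", beta=0.05, eaf=0.3)
        aligned, reason = align_alleles(exp, out)
        assert reason is None
        assert aligned.beta == -0.05
        assert aligned.eaf == pytest.approx(0.7)
        assert (aligned.effect_allele, aligned.other_allele) == ("T", "C")

    def test_maximally_ambiguous_palindrome_excluded(self):
        exp = make_variant("rs1", "A", "T", eaf=0.50)
        out = make_variant("rs1", "A", "T", eaf=0.50)
        aligned, reason = align_alleles(exp, out)
        assert aligned is None
        assert reason == ExclusionReason.PALINDROMIC_AMBIGUOUS

    def test_palindrome_missing_eaf_excluded(self):
        exp = make_variant("rs1", "C", "G", eaf=0.2)
        out = make_variant("rs1", "C", "G", eaf=None)
        _, reason = align_alleles(exp, out)
        assert reason == ExclusionReason.PALINDROMIC_AMBIGUOUS

    def test_palindrome_frequency_concordance_flips_strand(self):
        # exposure effect allele has frequency 0.2; the outcome's nominally
        # matching label sits at 0.8, so the outcome was read off the other
        # strand and its beta applies to the exposure's other allele
        exp = make_variant("rs1", "A", "T", beta=0.1, eaf=0.2)
        out = make_variant("rs1", "A", "T", beta=0.05, eaf=0.8)
        aligned, reason = align_alleles(exp, out)
        assert reason is None
        assert aligned.beta == -0.05 and aligned.eaf == pytest.approx(0.2)

    def test_palindrome_concordant_frequencies_kept_as_is(self):
        exp = make_variant("rs1", "A", "T", beta=0.1, eaf=0.2)
        out = make_variant("rs1", "A", "T", beta=0.05, eaf=0.25)
        aligned, reason = align_alleles(exp, out)
        assert reason is None and aligned.beta == 0.05

    def test_strand_flip_reconciles_complement_pair(self):
        exp = make_variant("rs1", "A", "G", beta=0.1)
        out = make_variant("rs1", "T", "C", beta=0.05)  # other strand
        aligned, reason = align_alleles(exp, out)
        assert reason is None and aligned.beta == 0.05
        assert (aligned.effect_allele, aligned.other_allele) == ("A", "G")

    def test_strand_flip_plus_swap(self):
        exp = make_variant("rs1", "A", "G", beta=0.1)
        out = make_variant("rs1", "C", "T", beta=0.05, eaf=0.6)
        aligned, reason = align_alleles(exp, out)
        assert reason is None and aligned.beta == -0.05

    def test_strand_flip_disabled_declares_non_concordant(self):
        exp = make_variant("rs1", "A", "G")
        out = make_variant("rs1", "T", "C")
        _, reason = align_alleles(exp, out, try_strand_flip=False)
        assert reason == ExclusionReason.NON_CONCORDANT

    def test_variant_mismatch_is_usage_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            align_alleles(make_variant("rs1"), make_variant("rs2"))

    def test_reconcilable_configurations_match_brute_force(self):
        """Enumerate every ordered outcome allele pair against exposure A/G.

        Independent oracle: a pair reconciles iff its allele set equals the
        exposure's, directly or after complementing both alleles; e.g. T/G
        is absent because the strand flip of A/G is T/C.
        """
        exp = make_variant("rs1", "A", "G", beta=0.1, eaf=0.3)
        for ea, oa in itertools.permutations("ACGT", 2):
            out = make_variant("rs1", ea, oa, beta=0.05, eaf=0.4)
            aligned, reason = align_alleles(exp, out)
            direct = {ea, oa} == {"A", "G"}
            flipped = {COMPLEMENT[ea], COMPLEMENT[oa]} == {"A", "G"}
            if direct or flipped:
                assert reason is None
                expected_sign = 1 if (ea == "A" or COMPLEMENT[ea] == "A") else -1
                assert aligned.beta == expected_sign * 0.05
            else:
                assert reason == ExclusionReason.NON_CONCORDANT

    def test_a_g_versus_t_g_not_reconcilable(self):
        _, reason = align_alleles(
            make_variant("rs1", "A", "G"), make_variant("rs1", "T", "G")
        )
        assert reason == ExclusionReason.NON_CONCORDANT


class TestHarmonize:
    def test_all_concordant_four_records(self, concordant_pair):
        spec, exposure, outcome = concordant_pair
        h = harmonize(spec, exposure, outcome, outcome_name="VTE")
        assert h.n_snps == 4 and h.exclusions == []
        assert list(h.records["variant_id"]) == sorted(spec.variant_ids)

    def test_ambiguous_palindrome_dropped(self, concordant_pair):
        spec, exposure, outcome = concordant_pair
        exp = exposure.table.copy()
        out = outcome.table.copy()
        for df in (exp, out):
            df.loc[df["variant_id"] == "rs2", ["effect_allele", "other_allele"]] = ["A", "T"]
            df.loc[df["variant_id"] == "rs2", "eaf"] = 0.5
        h = harmonize(spec, SummaryStats(exp), SummaryStats(out))
        assert h.n_snps == 3
        assert h.exclusions == [("rs2", ExclusionReason.PALINDROMIC_AMBIGUOUS)]

    def test_variant_absent_from_outcome(self, concordant_pair):
        spec, exposure, outcome = concordant_pair
        out = outcome.table[outcome.table["variant_id"] != "rs3"]
        h = harmonize(spec, exposure, SummaryStats(out))
        assert ("rs3", ExclusionReason.MISSING_IN_OUTCOME) in h.exclusions
        assert h.n_snps == 3

    def test_variant_absent_from_exposure_is_error(self, concordant_pair):
        spec, exposure, outcome = concordant_pair
        exp = exposure.table[exposure.table["variant_id"] != "rs1"]
        with pytest.raises(LookupError, match="rs1"):
            harmonize(spec, SummaryStats(exp), outcome)

    def test_nothing_survives_names_the_pair(self, concordant_pair):
        spec, exposure, _ = concordant_pair
        empty = SummaryStats(exposure.table.iloc[0:0])
        with pytest.raises(EmptyInstrumentError, match="FA"):
            harmonize(spec, exposure, empty, outcome_name="VTE")

    def test_idempotent_on_aligned_data(self, concordant_pair):
        spec, exposure, outcome = concordant_pair
        h1 = harmonize(spec, exposure, outcome)
        # rebuild an outcome table from the harmonized records and re-run
        out2 = SummaryStats(
            h1.records.rename(
                columns={
                    "eaf_outcome": "eaf",
                    "beta_outcome": "beta",
                    "se_outcome": "se",
                }
            )[["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se"]]
            .assign(pvalue=np.nan, n=np.nan)
        )
        h2 = harmonize(spec, exposure, out2)
        pd.testing.assert_frame_equal(h1.records, h2.records)

    def test_flipping_every_exposure_allele_cancels_in_ratios(self, concordant_pair):
        """Recoding each exposure record onto its other allele negates both
        harmonized betas, so all ratio estimates are unchanged."""
        spec, exposure, outcome = concordant_pair
        flipped = exposure.table.copy()
        flipped[["effect_allele", "other_allele"]] = flipped[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1.0 - flipped["eaf"]
        h1 = harmonize(spec, exposure, outcome)
        h2 = harmonize(spec, SummaryStats(flipped), outcome)
        np.testing.assert_allclose(
            h1.records["beta_outcome"] / h1.records["beta_exposure"],
            h2.records["beta_outcome"] / h2.records["beta_exposure"],
        )
        np.testing.assert_allclose(
            h2.records["beta_exposure"], -h1.records["beta_exposure"]
        )
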