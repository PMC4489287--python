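"""Accessibility and conservation verdicts for seed-match sites."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from paccmit.fixtures import make_ensemble
from paccmit.sequence_model import SeedMatchSite
from paccmit.site_filters import (
    AccessibilityMode,
    AccessibilityPolicy,
    OrthologAlignment,
    StructureEnsemble,
    is_accessible,
    is_conserved,
    map_reference_window,
    read_alignment_fasta,
    read_ensemble_file,
    unpaired_window_fraction,
)


def ensemble_from(structures):
    return StructureEnsemble("TX", tuple(structures))


class TestStructureEnsemble:
    def test_unbalanced_brackets_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            ensemble_from(["(..."])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ensemble_from(["....", "....."])

    def test_bad_characters_rejected(self):
        with pytest.raises(ValueError):
            ensemble_from(["..x."])


class TestUnpairedWindowFraction:
    def test_fraction_counts_fully_unpaired_structures(self):
        # window 3..6 unpaired in exactly 1 of 5 structures
        ens = ensemble_from(
            ["........", "..(())..", "..(())..", "..(())..", "..(()).."]
        )
        assert unpaired_window_fraction(ens, 3, 4) == pytest.approx(0.2)

    def test_always_paired_window_is_zero(self):
        ens = ensemble_from(["..()....", "..()...."])
        assert unpaired_window_fraction(ens, 3, 2) == 0.0

    def test_all_dots_structure_is_one(self):
        ens = ensemble_from(["........"])
        assert unpaired_window_fraction(ens, 1, 8) == 1.0

    def test_out_of_bounds_window_rejected(self):
        ens = ensemble_from(["...."])
        with pytest.raises(ValueError):
            unpaired_window_fraction(ens, 3, 4)

    def test_invariant_under_structure_permutation(self):
        structs = ["........", "(......)", "..(())..", "........", "(()).().",]
        f1 = unpaired_window_fraction(ensemble_from(structs), 2, 3)
        f2 = unpaired_window_fraction(ensemble_from(structs[::-1]), 2, 3)
        assert f1 == f2


class TestIsAccessible:
    def test_loose_accepts_any_window(self):
        # only the window starting at transcript position 4 is ever unpaired
        ens = make_ensemble("TX", 40, 5, {4: 0.2})
        site = SeedMatchSite("TX", 4, 7)
        assert is_accessible(site, ens, AccessibilityPolicy(mode="loose")) is True

    def test_strict_requires_three_prime_window(self):
        # strict window of a site at 4 starts at position 7; make it too rare
        ens = make_ensemble("TX", 40, 10, {7: 0.1})
        site = SeedMatchSite("TX", 4, 7)
        assert is_accessible(site, ens, AccessibilityPolicy(mode="strict")) is False
        # but 0.2 passes
        ens2 = make_ensemble("TX", 40, 10, {7: 0.2})
        assert is_accessible(site, ens2, AccessibilityPolicy(mode="strict")) is True

    def test_threshold_is_inclusive_at_20_percent(self):
        ens = make_ensemble("TX", 40, 5, {7: 0.2})  # exactly 1/5
        site = SeedMatchSite("TX", 4, 7)
        policy = AccessibilityPolicy(mode="strict", min_fraction=0.20)
        assert is_accessible(site, ens, policy) is True

    def test_off_mode_has_no_verdict(self):
        ens = make_ensemble("TX", 40, 5, {})
        with pytest.raises(ValueError):
            is_accessible(SeedMatchSite("TX", 4, 7), ens, AccessibilityPolicy(mode="off"))

    @given(st.integers(min_value=0, max_value=10), st.integers(min_value=1, max_value=34))
    def test_strict_implies_loose(self, tenths, start):
        ens = make_ensemble("TX", 40, 10, {min(start + 3, 33): tenths / 10})
        site = SeedMatchSite("TX", start, 7)
        strict = is_accessible(site, ens, AccessibilityPolicy(mode="strict"))
        loose = is_accessible(site, ens, AccessibilityPolicy(mode="loose"))
        assert not strict or loose

    def test_raising_min_fraction_never_adds_sites(self):
        ens = make_ensemble("TX", 60, 10, {13: 0.4})
        site = SeedMatchSite("TX", 10, 7)
        verdicts = [
            is_accessible(site, ens, AccessibilityPolicy(mode="loose", min_fraction=f))
            for f in (0.1, 0.3, 0.5, 0.9)
        ]
        assert verdicts == sorted(verdicts, reverse=True)


REF_ALN = OrthologAlignment(
    "TX",
    (
        ("TX", "A-CGTACGT"),
        ("mouse", "AACGTACGT"),
        ("rat", "AACGAACGT"),
    ),
)


class TestMapReferenceWindow:
    def test_window_skips_gaps(self):
        aln = OrthologAlignment("TX", (("TX", "A-CG"),))
        assert map_reference_window(aln, 2, 2) == [3, 4]

    def test_gapless_reference_identity(self):
        aln = OrthologAlignment("TX", (("TX", "ACGT"),))
        assert map_reference_window(aln, 2, 3) == [2, 3, 4]

    def test_window_beyond_reference_rejected(self):
        aln = OrthologAlignment("TX", (("TX", "A-CG"),))
        with pytest.raises(ValueError):
            map_reference_window(aln, 3, 2)


class TestIsConserved:
    def test_identical_rows_conserved(self):
        site = SeedMatchSite("TX", 2, 3)  # CGT in the reference
        assert is_conserved(site, REF_ALN, 2) is False  # rat differs at ungapped pos 4
        assert is_conserved(site, REF_ALN, 1) is True

    def test_gap_in_other_row_breaks_conservation(self):
        aln = OrthologAlignment(
            "TX", (("TX", "ACGT"), ("mouse", "AC-T"), ("rat", "ACGT"))
        )
        site = SeedMatchSite("TX", 2, 2)
        assert is_conserved(site, aln, 2) is False
        assert is_conserved(site, aln, 1) is True

    def test_zero_required_species_always_true(self):
        site = SeedMatchSite("TX", 1, 3)
        assert is_conserved(site, REF_ALN, 0) is True

    def test_requirement_above_available_rows_rejected(self):
        with pytest.raises(ValueError):
            is_conserved(SeedMatchSite("TX", 1, 3), REF_ALN, 5)

    def test_raising_min_other_species_monotone(self):
        site = SeedMatchSite("TX", 1, 2)
        verdicts = [is_conserved(site, REF_ALN, k) for k in (0, 1, 2)]
        assert verdicts == sorted(verdicts, reverse=True)


class TestFileFormats:
    def test_ensemble_file_round_trip(self, tmp_path):
        path = tmp_path / "ens.txt"
        path.write_text(">TX1\n....\n(..)\n>TX2\n.....\n")
        ens = read_ensemble_file(path)
        assert set(ens) == {"TX1", "TX2"}
        assert ens["TX1"].structures == ("....", "(..)")

    def test_alignment_fasta_reference_first(self, tmp_path):
        path = tmp_path / "aln.fa"
        path.write_text(">TX ref\nA-CG\n>mouse\nAACG\n")
        aln = read_alignment_fasta(path)
        assert aln.transcript_id == "TX"
        assert aln.reference_ungapped() == "ACG"
        assert aln.n_other_species == 1
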