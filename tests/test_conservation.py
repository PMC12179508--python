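"""Profile conservation scoring: raw scores, grade binning, variant lookup."""

import numpy as np
import pytest

from indelstruct.conservation import (
    AMINO_ACIDS,
    BLOSUM62,
    AlignmentFormatError,
    AlphabetError,
    ConservationCategory,
    MultipleAlignment,
    grade_conservation,
    profile_from_msa,
    raw_conservation,
    read_alignment,
    variant_grades,
)
from indelstruct.variants import parse_hgvs_p

AA_IDX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def expected_column_score(column: str) -> float:
    """Independent brute-force double sum over residue frequencies."""
    residues = [c for c in column if c not in "-."]
    n = len(residues)
    total = 0.0
    for a in residues:
        for b in residues:
            total += BLOSUM62[AA_IDX[a], AA_IDX[b]]
    return total / (n * n)


def msa_from_columns(columns: list[str]) -> MultipleAlignment:
    n_rows = len(columns[0])
    rows = ["".join(col[i] for col in columns) for i in range(n_rows)]
    return MultipleAlignment(
        records=tuple((f"s{i}", row) for i, row in enumerate(rows)),
        reference_id="s0",
    )


class TestReadAlignment:
    def test_fasta(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nACDE\n>y\nACD-\n")
        msa = read_alignment(p, "fasta")
        assert msa.column_count == 4
        assert msa.reference_id == "x"

    def test_clustal_eleven_rows(self, tmp_path):
        seqs = [f"seq{i:02d}" for i in range(11)]
        body = "\n".join(f"{s}      ACDEFG" for s in seqs)
        p = tmp_path / "a.aln"
        p.write_text("CLUSTAL W multiple sequence alignment\n\n" + body + "\n")
        msa = read_alignment(p, "clustal")
        assert len(msa.records) == 11

    def test_ragged_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">x\nACDE\n>y\nACD\n")
        with pytest.raises(AlignmentFormatError):
            read_alignment(p, "fasta")

    def test_alphabet_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">x\nACDE\n>y\nAC1E\n")
        with pytest.raises(AlphabetError, match="1"):
            read_alignment(p, "fasta")


class TestRawConservation:
    def test_pure_tryptophan_column_scores_its_self_substitution(self):
        msa = msa_from_columns(["WWWW"])
        assert raw_conservation(msa)[0] == pytest.approx(11.0)

    @pytest.mark.parametrize("aa", list(AMINO_ACIDS))
    def test_pure_column_is_maximal_over_mixtures_containing_it(self, aa):
        pure = raw_conservation(msa_from_columns([aa * 6]))[0]
        for other in AMINO_ACIDS:
            if other == aa:
                continue
            mixed = raw_conservation(msa_from_columns([aa * 5 + other]))[0]
            assert mixed <= pure + 1e-12

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(7)
        cols = [
            "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=8))
            for _ in range(40)
        ]
        got = raw_conservation(msa_from_columns(cols))
        for j, col in enumerate(cols):
            assert got[j] == pytest.approx(expected_column_score(col))

    def test_substituted_column_scores_below_pure(self):
        pure = raw_conservation(msa_from_columns(["LLLL"]))[0]
        subst = raw_conservation(msa_from_columns(["LLLV"]))[0]
        assert subst < pure

    def test_gap_majority_column_unscorable(self):
        msa = msa_from_columns(["W---", "WWWW"])
        raw = raw_conservation(msa)
        assert np.isnan(raw[0]) and not np.isnan(raw[1])

    def test_row_order_and_duplication_invariance(self):
        rng = np.random.default_rng(3)
        cols = ["".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=6)) for _ in range(20)]
        msa = msa_from_columns(cols)
        shuffled = MultipleAlignment(
            records=tuple(reversed(msa.records)), reference_id="s0"
        )
        doubled = MultipleAlignment(
            records=msa.records + tuple((f"d{i}", s) for i, (_, s) in enumerate(msa.records)),
            reference_id="s0",
        )
        np.testing.assert_allclose(raw_conservation(msa), raw_conservation(shuffled))
        np.testing.assert_allclose(raw_conservation(msa), raw_conservation(doubled))


class TestGradeConservation:
    def test_nine_distinct_scores_give_permutation_of_grades(self):
        raw = np.array([5.0, 2.0, 9.0, 1.0, 7.0, 3.0, 8.0, 4.0, 6.0])
        grades = grade_conservation(raw)
        assert sorted(grades) == list(range(1, 10))
        assert grades[np.argmax(raw)] == 1
        assert grades[np.argmin(raw)] == 9

    def test_all_tied_scores_share_grade_one(self):
        assert grade_conservation(np.full(30, 4.0)) == [1] * 30

    def test_three_equal_tiers_of_ninety_columns(self):
        # 30 high, 30 mid, 30 low raw scores: tiers share grades, order kept
        raw = np.array([9.0] * 30 + [5.0] * 30 + [1.0] * 30)
        grades = grade_conservation(raw)
        assert set(grades[:30]) == {1}
        assert set(grades[30:60]) == {4}
        assert set(grades[60:]) == {7}

    def test_unscorable_columns_get_no_grade(self):
        grades = grade_conservation(np.array([4.0, np.nan, 2.0]))
        assert grades[1] is None
        assert grades[0] == 1


class TestVariantGrades:
    def test_fixture_style_lookup(self, bundle):
        from indelstruct.conservation import ConservationProfile

        profile = ConservationProfile.from_grades(
            {538: 1, 539: 1, 540: 2, 541: 1, 542: 1, 543: 1, 544: 6}
        )
        v = parse_hgvs_p("p.(Leu538_Leu544del)")
        g = variant_grades(v, profile)
        assert g.grades == (1, 1, 2, 1, 1, 1, 6)
        assert g.min_grade == 1
        assert g.category is ConservationCategory.highly_conserved

    def test_highly_variable_variant(self):
        from indelstruct.conservation import ConservationProfile

        profile = ConservationProfile.from_grades({824: 9, 825: 9})
        g = variant_grades(parse_hgvs_p("p.(Glu824_Glu825del)"), profile)
        assert g.grades == (9, 9)
        assert g.category is ConservationCategory.highly_variable

    def test_insertion_has_no_grades(self):
        from indelstruct.conservation import ConservationProfile

        profile = ConservationProfile.from_grades({165: 1, 166: 1})
        g = variant_grades(parse_hgvs_p("p.(Leu165_Leu166insTyrLeu)"), profile)
        assert g.grades == () and g.min_grade is None and g.coverage == "none"

    def test_partial_coverage_warns(self):
        from indelstruct.conservation import ConservationProfile

        profile = ConservationProfile.from_grades({824: 9})
        with pytest.warns(UserWarning, match="partial"):
            g = variant_grades(parse_hgvs_p("p.(Glu824_Glu825del)"), profile)
        assert g.coverage == "partial" and g.grades == (9,)


def test_profile_from_msa_projects_onto_ungapped_reference():
    msa = MultipleAlignment(
        records=(("ref", "AC-DE"), ("o1", "ACWDE"), ("o2", "ACWD-")),
        reference_id="ref",
    )
    profile = profile_from_msa(msa)
    # reference has 4 ungapped positions; the gapped column 3 is skipped
    assert profile.reference_positions == (1, 2, 3, 4)


def test_tier_recovery_on_synthetic_alignments():
    """Low-substitution columns land in grades 1-3 and high-substitution
    columns in grades 7-9 for >=95% of columns over 200 seeded replicates."""
    from indelstruct.synthetic import MsaSpec, make_msa

    ok_low = tot_low = ok_high = tot_high = 0
    for seed in range(200):
        msa, tiers = make_msa(MsaSpec(seed=seed))
        grades = grade_conservation(raw_conservation(msa))
        for t, g in zip(tiers, grades):
            if g is None:
                continue
            if t == 0:
                tot_low += 1
                ok_low += g <= 3
            elif t == 2:
                tot_high += 1
                ok_high += g >= 7
    assert ok_low / tot_low >= 0.95
    assert ok_high / tot_high >= 0.95
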