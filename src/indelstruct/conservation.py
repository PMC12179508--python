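"""Per-position conservation grading from an orthologue alignment.

The score of an alignment column is the expected pairwise BLOSUM62
substitution score under the column's residue frequencies,

    score(c) = sum_{a,b} f_a(c) * f_b(c) * B62(a, b),

computed over non-gap symbols only.  Higher scores mean stronger
conservation; a pure column of residue ``r`` attains the maximum
``B62(r, r)`` achievable by any mixture containing ``r``.

Scores are converted to the familiar nine-grade scale (1 = highly
conserved ... 9 = highly variable) by ranking the scorable columns and
splitting the ranks into nine equal-occupancy bins; tied scores share
the better (lower) grade.  Columns that are mostly gap (fraction > 0.5)
or hold fewer than two residues are unscorable and carry no grade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import substitution_matrices

from .variants import IndelVariant, grading_residues

__all__ = [
    "AMINO_ACIDS",
    "GAP_CHARS",
    "MultipleAlignment",
    "ConservationCategory",
    "ConservationProfile",
    "VariantGrades",
    "AlignmentFormatError",
    "AlphabetError",
    "read_alignment",
    "raw_conservation",
    "grade_conservation",
    "profile_from_msa",
    "variant_grades",
    "grade_category",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = "-."
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

_B62 = substitution_matrices.load("BLOSUM62")
#: BLOSUM62 restricted to the 20 standard residues, AMINO_ACIDS order.
BLOSUM62 = np.array(
    [[_B62[a, b] for b in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=float
)


class AlignmentFormatError(ValueError):
    pass


class AlphabetError(ValueError):
    pass


class ConservationCategory(str, Enum):
    highly_conserved = "highly_conserved"        # grades 1-3
    moderately_conserved = "moderately_conserved"  # grades 4-6
    highly_variable = "highly_variable"          # grades 7-9


def grade_category(grade: int) -> ConservationCategory:
    if not 1 <= grade <= 9:
        raise ValueError(f"grade must be in [1, 9], got {grade}")
    if grade <= 3:
        return ConservationCategory.highly_conserved
    if grade <= 6:
        return ConservationCategory.moderately_conserved
    return ConservationCategory.highly_variable


@dataclass(frozen=True)
class MultipleAlignment:
    """A validated gapped alignment with a designated reference row."""

    records: tuple[tuple[str, str], ...]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentFormatError("alignment needs at least 2 records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged alignment rows: lengths {sorted(lengths)}")
        ids = [rid for rid, _ in self.records]
        if self.reference_id not in ids:
            raise AlignmentFormatError(f"reference row {self.reference_id!r} not present")
        allowed = set(AMINO_ACIDS) | set(GAP_CHARS)
        bad = sorted({c for _, seq in self.records for c in seq.upper()} - allowed)
        if bad:
            raise AlphabetError(f"unknown alignment characters: {bad}")

    @property
    def column_count(self) -> int:
        return len(self.records[0][1])

    @property
    def reference_sequence(self) -> str:
        """Ungapped reference sequence."""
        gapped = dict(self.records)[self.reference_id]
        return "".join(c for c in gapped.upper() if c not in GAP_CHARS)

    def column(self, j: int) -> list[str]:
        return [seq[j].upper() for _, seq in self.records]


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    reference_id: str | None = None,
) -> MultipleAlignment:
    """Read a FASTA or Clustal alignment; reference defaults to row 1."""
    if format not in ("fasta", "clustal"):
        raise ValueError(f"format must be 'fasta' or 'clustal', got {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path}: {exc}") from exc
    records = tuple((rec.id, str(rec.seq)) for rec in aln)
    if not records:
        raise AlignmentFormatError(f"empty alignment: {path}")
    ref = reference_id if reference_id is not None else records[0][0]
    return MultipleAlignment(records=records, reference_id=ref)


def raw_conservation(msa: MultipleAlignment) -> np.ndarray:
    """Per-column expected pairwise BLOSUM62 score; NaN marks unscorable.

    A column is unscorable when its gap fraction exceeds 0.5 or fewer
    than two non-gap symbols remain.
    """
    n_rows = len(msa.records)
    out = np.full(msa.column_count, np.nan)
    for j in range(msa.column_count):
        col = msa.column(j)
        residues = [c for c in col if c not in GAP_CHARS]
        if len(residues) < 2 or (n_rows - len(residues)) / n_rows > 0.5:
            continue
        freqs = np.zeros(len(AMINO_ACIDS))
        for c in residues:
            freqs[_AA_INDEX[c]] += 1
        freqs /= freqs.sum()
        out[j] = freqs @ BLOSUM62 @ freqs
    return out


def grade_conservation(raw_scores: np.ndarray) -> list[int | None]:
    """Map raw scores to grades 1..9 by equal-occupancy rank binning.

    Columns are ranked by raw score, most conserved first; rank r of n
    scorable columns receives grade ``floor(9 r / n) + 1``.  Tied
    scores take the minimal (best) rank of their group, so ties share
    the better grade.  Unscorable (NaN) columns get ``None``.
    """
    raw_scores = np.asarray(raw_scores, dtype=float)
    scorable = ~np.isnan(raw_scores)
    n = int(scorable.sum())
    if n == 0:
        raise ValueError("no scorable columns to grade")
    scores = raw_scores[scorable]
    # min-rank in descending score order: count of strictly greater scores
    order = np.argsort(-scores, kind="stable")
    min_rank = np.empty(n, dtype=int)
    rank_of_sorted = np.arange(n)
    sorted_scores = scores[order]
    # positions where the score changes start a new tie group
    group_start = np.zeros(n, dtype=int)
    for k in range(1, n):
        group_start[k] = group_start[k - 1] if sorted_scores[k] == sorted_scores[k - 1] else k
    min_rank[order] = group_start[rank_of_sorted]
    grades_scorable = (min_rank * 9) // n + 1
    out: list[int | None] = [None] * len(raw_scores)
    for idx, g in zip(np.nonzero(scorable)[0], grades_scorable):
        out[idx] = int(g)
    return out


@dataclass(frozen=True)
class ConservationProfile:
    """Grades keyed by ungapped 1-based reference position."""

    reference_positions: tuple[int, ...]
    raw_score: tuple[float, ...]
    grade: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = self.reference_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("reference positions must be strictly increasing")
        if any(not 1 <= g <= 9 for g in self.grade):
            raise ValueError("grades must lie in [1, 9]")

    def category(self, position: int) -> ConservationCategory:
        return grade_category(self.grade_at(position))

    def grade_at(self, position: int) -> int:
        try:
            idx = self.reference_positions.index(position)
        except ValueError:
            raise KeyError(f"no grade for reference position {position}") from None
        return self.grade[idx]

    def has_position(self, position: int) -> bool:
        return position in self.reference_positions

    @classmethod
    def from_grades(cls, grades_by_position: dict[int, int]) -> "ConservationProfile":
        """Build a profile from externally supplied per-position grades."""
        items = sorted(grades_by_position.items())
        return cls(
            reference_positions=tuple(p for p, _ in items),
            raw_score=tuple(float("nan") for _ in items),
            grade=tuple(g for _, g in items),
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\traw\tgrade\tcategory\n")
            for p, r, g in zip(self.reference_positions, self.raw_score, self.grade):
                fh.write(f"{p}\t{r:.6g}\t{g}\t{grade_category(g).value}\n")


def profile_from_msa(msa: MultipleAlignment) -> ConservationProfile:
    """Grade all scorable columns, then project onto reference positions."""
    raw = raw_conservation(msa)
    grades = grade_conservation(raw)
    gapped = dict(msa.records)[msa.reference_id].upper()
    positions, raws, out_grades = [], [], []
    ref_pos = 0
    for j, c in enumerate(gapped):
        if c in GAP_CHARS:
            continue
        ref_pos += 1
        if grades[j] is None:
            continue
        positions.append(ref_pos)
        raws.append(float(raw[j]))
        out_grades.append(grades[j])
    return ConservationProfile(
        reference_positions=tuple(positions),
        raw_score=tuple(raws),
        grade=tuple(out_grades),
    )


@dataclass(frozen=True)
class VariantGrades:
    """Grades of a variant's removed residues, in residue order.

    ``coverage`` is "full", "partial" (some eligible residues missing
    from the profile) or "none" (no eligible residue covered, or the
    variant removes no residues).
    """

    grades: tuple[int, ...]
    min_grade: int | None
    category: ConservationCategory | None
    coverage: str

    @classmethod
    def from_list(cls, grades: list[int] | tuple[int, ...], coverage: str = "full") -> "VariantGrades":
        grades = tuple(grades)
        if not grades:
            return cls(grades=(), min_grade=None, category=None, coverage="none")
        mg = min(grades)
        return cls(grades=grades, min_grade=mg, category=grade_category(mg), coverage=coverage)


def variant_grades(v: IndelVariant, profile: ConservationProfile) -> VariantGrades:
    """Look up grades for a variant's grading-eligible residues.

    The variant-level category is driven by the minimum (best) grade:
    a variant is "highly conserved" when it removes at least one
    highly conserved residue.
    """
    eligible = grading_residues(v)
    if not eligible:
        return VariantGrades(grades=(), min_grade=None, category=None, coverage="none")
    covered = [p for p in eligible if profile.has_position(p)]
    if not covered:
        return VariantGrades(grades=(), min_grade=None, category=None, coverage="none")
    if len(covered) < len(eligible):
        warnings.warn(
            f"variant {v.hgvs_p}: {len(eligible) - len(covered)} residue(s) "
            "lack conservation grades (partial coverage)",
            stacklevel=2,
        )
    grades = tuple(profile.grade_at(p) for p in covered)
    coverage = "full" if len(covered) == len(eligible) else "partial"
    return VariantGrades.from_list(grades, coverage=coverage)
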