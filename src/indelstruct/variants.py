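"""Protein-level HGVS parsing for small in-frame indels.

Only non-truncating, in-frame events are supported: deletions,
insertions, duplications and deletion-insertions (delins) expressed in
protein (p.) notation.  Protein notation is authoritative; the cDNA
description, when present, is used only as a frame/length consistency
check (:func:`validate_against_cdna`).

Coordinates are 1-based closed intervals, following HGVS convention.
Range notations such as ``p.(Leu538_Leu544del)`` state only the
flanking residue identities; interior residues that the notation cannot
name are stored as ``X`` so that ``len(ref_residues)`` always equals
the span length.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from enum import Enum

from Bio.Data.IUPACData import protein_letters_3to1

__all__ = [
    "VariantKind",
    "Cohort",
    "IndelVariant",
    "HgvsParseError",
    "UnsupportedVariantError",
    "parse_hgvs_p",
    "format_hgvs_p",
    "affected_residues",
    "grading_residues",
    "membership_interval",
    "validate_against_cdna",
]

AA3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}
AA1TO3 = {v: k for k, v in protein_letters_3to1.items()}
AA1TO3["X"] = "Xaa"


class VariantKind(str, Enum):
    deletion = "deletion"
    insertion = "insertion"
    duplication = "duplication"
    delins = "delins"


class Cohort(str, Enum):
    A = "A"
    B = "B"
    unlabeled = "unlabeled"


class HgvsParseError(ValueError):
    """Malformed HGVS syntax; the message names the offending token."""


class UnsupportedVariantError(ValueError):
    """Well-formed HGVS outside the supported in-frame indel classes."""


@dataclass(frozen=True)
class IndelVariant:
    """One protein-level in-frame indel.

    ``ref_residues`` holds the removed residues (``X`` for interior
    positions a range notation cannot name); ``alt_residues`` holds the
    added residues, and for a duplication the duplicated segment.
    """

    hgvs_p: str
    kind: VariantKind
    start_res: int
    end_res: int
    ref_residues: str
    alt_residues: str
    hgvs_c: str | None = None
    cohort: Cohort = Cohort.unlabeled

    def __post_init__(self) -> None:
        if self.start_res < 1:
            raise ValueError(f"residue index must be >= 1, got {self.start_res}")
        if self.kind is VariantKind.insertion:
            if self.end_res != self.start_res + 1:
                raise ValueError("insertion flanks must be adjacent residues")
            if self.ref_residues:
                raise ValueError("pure insertion removes no residues")
            if not self.alt_residues:
                raise ValueError("insertion must add at least one residue")
        else:
            if self.end_res < self.start_res:
                raise ValueError("end_res must be >= start_res")
            span = self.end_res - self.start_res + 1
            if self.kind in (VariantKind.deletion, VariantKind.delins):
                if len(self.ref_residues) != span:
                    raise ValueError("ref_residues length must equal the residue span")
            if self.kind is VariantKind.duplication and len(self.alt_residues) != span:
                raise ValueError("duplication alt_residues must equal the duplicated segment")

    @property
    def net_residue_change(self) -> int:
        """Added minus removed residues (duplication adds its span)."""
        if self.kind is VariantKind.duplication:
            return self.end_res - self.start_res + 1
        return len(self.alt_residues) - len(self.ref_residues)

    def with_cohort(self, cohort: Cohort) -> "IndelVariant":
        return replace(self, cohort=cohort)


_AA3 = "|".join(sorted(AA3TO1, key=len, reverse=True))
_POS = rf"(?P<a1>{_AA3})(?P<p1>\d+)"
_POS2 = rf"(?:_(?P<a2>{_AA3})(?P<p2>\d+))?"
_HGVS_P_RE = re.compile(
    rf"^p\.\(?{_POS}{_POS2}"
    rf"(?P<op>delins|del|dup|ins)"
    rf"(?P<payload>(?:{_AA3})*)\)?$",
    re.IGNORECASE,
)
_UNSUPPORTED_RE = re.compile(r"(Ter|\*|fs|ext)", re.IGNORECASE)


def _aa3_to_1(token: str) -> str:
    try:
        return AA3TO1[token.upper()]
    except KeyError:
        raise HgvsParseError(f"unknown amino-acid code {token!r}") from None


def _split_aa3(payload: str) -> str:
    out = []
    i = 0
    while i < len(payload):
        tok = payload[i : i + 3]
        out.append(_aa3_to_1(tok))
        i += 3
    return "".join(out)


def parse_hgvs_p(text: str, cohort: Cohort = Cohort.unlabeled) -> IndelVariant:
    """Parse a protein-level HGVS in-frame indel description.

    Accepts del, ins, dup and delins with three-letter codes, with or
    without the parenthesized "predicted" form.  Frameshift, stop and
    extension notations raise :class:`UnsupportedVariantError`.
    """
    raw = text.strip()
    compact = re.sub(r"\s+", "", raw)
    if not compact.startswith("p."):
        raise HgvsParseError(f"not a protein-level description: {raw!r}")
    if _UNSUPPORTED_RE.search(compact):
        raise UnsupportedVariantError(
            f"unsupported (truncating/extension) notation in {raw!r}"
        )
    m = _HGVS_P_RE.match(compact)
    if m is None:
        raise HgvsParseError(f"malformed protein HGVS: {raw!r}")

    aa1 = _aa3_to_1(m.group("a1"))
    start = int(m.group("p1"))
    if m.group("a2") is not None:
        aa2 = _aa3_to_1(m.group("a2"))
        end = int(m.group("p2"))
    else:
        aa2, end = aa1, start
    op = m.group("op").lower()
    payload = _split_aa3(m.group("payload")) if m.group("payload") else ""
    span = end - start + 1

    if op == "ins":
        if m.group("a2") is None or end != start + 1:
            raise HgvsParseError(
                f"insertion flanks must be adjacent residues in {raw!r}"
            )
        if not payload:
            raise HgvsParseError(f"insertion without inserted residues: {raw!r}")
        kind, ref, alt = VariantKind.insertion, "", payload
    elif op == "dup":
        if payload:
            raise HgvsParseError(f"unexpected residues after dup in {raw!r}")
        kind, ref = VariantKind.duplication, ""
        alt = aa1 if span == 1 else aa1 + "X" * (span - 2) + aa2
    elif op == "del":
        if payload:
            raise HgvsParseError(f"unexpected residues after del in {raw!r}")
        kind, alt = VariantKind.deletion, ""
        ref = aa1 if span == 1 else aa1 + "X" * (span - 2) + aa2
    else:  # delins
        if not payload:
            raise HgvsParseError(f"delins without inserted residues: {raw!r}")
        kind, alt = VariantKind.delins, payload
        ref = aa1 if span == 1 else aa1 + "X" * (span - 2) + aa2
    if end < start:
        raise HgvsParseError(f"interval end before start in {raw!r}")

    return IndelVariant(
        hgvs_p=raw,
        kind=kind,
        start_res=start,
        end_res=end,
        ref_residues=ref,
        alt_residues=alt,
        cohort=cohort,
    )


def format_hgvs_p(v: IndelVariant, predicted: bool = True) -> str:
    """Format a variant back to protein HGVS (canonical, no whitespace)."""
    if v.kind is VariantKind.insertion:
        # flank identities are not stored for insertions parsed elsewhere;
        # re-derive from the original string when possible
        m = _HGVS_P_RE.match(re.sub(r"\s+", "", v.hgvs_p))
        if m is None:
            raise ValueError("cannot format insertion without flank identities")
        pos = f"{m.group('a1').capitalize()}{v.start_res}_{m.group('a2').capitalize()}{v.end_res}"
        body = pos + "ins" + "".join(AA1TO3[a] for a in v.alt_residues)
    else:
        seg = v.ref_residues if v.kind is not VariantKind.duplication else v.alt_residues
        pos = f"{AA1TO3[seg[0]]}{v.start_res}"
        if v.end_res != v.start_res:
            pos += f"_{AA1TO3[seg[-1]]}{v.end_res}"
        if v.kind is VariantKind.deletion:
            body = pos + "del"
        elif v.kind is VariantKind.duplication:
            body = pos + "dup"
        else:
            body = pos + "delins" + "".join(AA1TO3[a] for a in v.alt_residues)
    return f"p.({body})" if predicted else f"p.{body}"


def affected_residues(v: IndelVariant) -> list[int]:
    """Residue indices touched by the event.

    Deletions/delins: the removed residues; duplications: the duplicated
    template residues; pure insertions: empty (no residue removed).  Use
    :func:`grading_residues` for conservation-eligible positions and
    :func:`membership_interval` for region membership.
    """
    if v.kind is VariantKind.insertion:
        return []
    return list(range(v.start_res, v.end_res + 1))


def grading_residues(v: IndelVariant) -> list[int]:
    """Residues eligible for conservation grading: removed residues only.

    Duplications and insertions remove nothing, hence carry no grades.
    """
    if v.kind in (VariantKind.deletion, VariantKind.delins):
        return list(range(v.start_res, v.end_res + 1))
    return []


def membership_interval(v: IndelVariant) -> tuple[int, int]:
    """1-based closed interval used for region/low-complexity membership.

    For a pure insertion this is the two flanking residues: an insertion
    disrupts the region containing its flanks.
    """
    return (v.start_res, v.end_res)


_CDNA_RE = re.compile(
    r"^c\.(?P<s>\d+)(?:[_-](?P<e>\d+))?"
    r"(?P<op>delins|del|dup|ins)?"
    r"(?P<del>[ACGT]*)"
    r"(?:ins(?P<ins>[ACGT]+))?$",
    re.IGNORECASE,
)


def validate_against_cdna(v: IndelVariant, hgvs_c: str) -> bool:
    """Check frame/length consistency between p. and c. descriptions.

    True iff the net nucleotide change is a multiple of 3 and its
    residue equivalent matches the protein-level net residue change.
    An unparseable cDNA string produces a warning and is treated as
    not-contradicting (the check is skipped, not failed).
    """
    compact = re.sub(r"\s+", "", hgvs_c)
    m = _CDNA_RE.match(compact)
    if m is None or m.group("op") is None:
        warnings.warn(
            f"cDNA description {hgvs_c!r} not parseable; consistency check skipped",
            stacklevel=2,
        )
        return True
    s = int(m.group("s"))
    e = int(m.group("e")) if m.group("e") else s
    span = e - s + 1
    op = m.group("op").lower()
    if op == "del":
        deleted, inserted = span, len(m.group("ins") or "")
    elif op == "delins":
        deleted, inserted = span, len(m.group("ins") or m.group("del") or "")
    elif op == "dup":
        deleted, inserted = 0, span
    else:  # ins
        deleted, inserted = 0, len(m.group("del") or m.group("ins") or "")
    net_nt = inserted - deleted
    if net_nt % 3 != 0:
        return False
    return abs(net_nt) // 3 == abs(v.net_residue_change)
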