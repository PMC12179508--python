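"""The packaged CACNA1F / Ca_v_1.4-alpha-1 study fixture bundle.

Twenty in-frame indel variants with cohort labels and per-residue
conservation grades, the modeled-region intervals of the homology
model, the qualitative structural-feature rows for the cohort-A
variants, and the reconstructed poly-glutamate low-complexity
interval.  Grades and feature levels are recorded published data, not
recomputation; the files written by :func:`write_fixture_bundle` carry
that provenance in their headers.

Cohort A holds the disease-correlated (CSNB2) variants, cohort B the
putatively benign ones.
"""

from __future__ import annotations

from pathlib import Path

from .conservation import VariantGrades
from .regions import LowComplexityAnnotation, ModeledRegionMap
from .structure import (
    DisruptionLevel,
    IonicChange,
    SsSummary,
    StructuralFeatures,
)
from dataclasses import replace

from .variants import Cohort, IndelVariant, parse_hgvs_p

__all__ = [
    "PROTEIN_LENGTH",
    "MODELED_INTERVALS",
    "LCR_INTERVAL",
    "TABLE1",
    "TABLE2",
    "load_variants",
    "load_variant_grades",
    "load_region_map",
    "load_lcr_annotation",
    "load_features",
    "write_fixture_bundle",
]

#: Length of the Ca_v_1.4-alpha-1 protein (UniProt O60840).
PROTEIN_LENGTH = 1977

#: Residue spans shared by the homology model and its template
#: (1-based closed); about two-thirds of the protein.
MODELED_INTERVALS: tuple[tuple[int, int], ...] = ((67, 414), (516, 766), (858, 1580))

#: Reconstructed poly-glutamate low-complexity interval.  The study
#: names a glutamate-rich region with 16 consecutive glutamates but
#: prints no coordinates; this 16-residue window covers the affected
#: residues 820-825 of every low-complexity-flagged variant and is
#: used for membership tests only.
LCR_INTERVAL: tuple[int, int] = (814, 829)

# (hgvs_c, hgvs_p, cohort, modeled, grades or None, in_lcr, source)
TABLE1: tuple[tuple[str, str, str, bool, tuple[int, ...] | None, bool, str], ...] = (
    ("c.466_469delAGCGinsGTAGGGGTGCTCCACCCCGTAGGGGAGCTCCACC",
     "p.(Ser156_Ala157delinsValGlyValLeuHisProValGlyValLeuHisPro)",
     "A", True, (3, 2), False, "literature"),
    ("c.495_496insTACCTA", "p.(Leu165_Leu166insTyrLeu)",
     "A", True, None, False, "literature"),
    ("c.952_954delTTC", "p.(Phe318del)",
     "A", True, (3,), False, "literature"),
    ("c.1004_1009delTGCTCT", "p.(Val335_Tyr337delinsAsp)",
     "A", True, (1, 1, 1), False, "literature"),
    ("c.1612_1632delCTCGTCTTCCTCAACACGTTG", "p.(Leu538_Leu544del)",
     "A", True, (1, 1, 2, 1, 1, 1, 6), False, "MGDL"),
    ("c.2829_2830delGGinsCT", "p.(Leu943_Asp944delinsPheTyr)",
     "A", True, (1, 1), False, "literature"),
    ("c.3009_3011delCAT", "p.(Ile1003del)",
     "A", True, (1,), False, "literature"),
    ("c.3658_3669delGTCCATGGCATA", "p.(Tyr1220_Asp1223del)",
     "A", True, (8, 7, 3, 3), False, "literature"),
    ("c.3691_3702delAGTGAAGAGGCC", "p.(Gly1231_Thr1234del)",
     "A", True, (7, 3, 1, 5), False, "literature"),
    ("c.4093_4095delAAC", "p.(Asn1365del)",
     "A", True, (1,), False, "MGDL"),
    ("c.1466_1468delAGG", "p.(Glu489del)",
     "B", False, (8,), False, "gnomAD"),
    ("c.5195_5197delAAG", "p.(Glu1732del)",
     "B", False, (8,), False, "gnomAD"),
    ("c.5866_5868delGAG", "p.(Glu1956del)",
     "B", False, (8,), False, "gnomAD"),
    ("c.2442_2444delGGA", "p.(Glu825del)",
     "B", False, (3,), True, "MGDL"),
    ("c.2457_2474dupAGAGGAAGAAGAGGAAGA", "p.(Glu820_Glu825dup)",
     "B", False, None, True, "gnomAD"),
    ("c.2466_2474delAGAGGAAGA", "p.(Glu823_Glu825del)",
     "B", False, (6, 9, 9), True, "gnomAD"),
    ("c.2445_2450delAGAAGA", "p.(Glu824_Glu825del)",
     "B", False, (9, 9), True, "gnomAD"),
    ("c.2466_2474dupAGAGGAAGA", "p.(Glu823_Glu825dup)",
     "B", False, None, True, "gnomAD"),
    ("c.2439_2444dupGGAGGA", "p.(Glu824_Glu825dup)",
     "B", False, None, True, "gnomAD"),
    ("c.2442_2444dupGGA", "p.(Glu825dup)",
     "B", False, None, True, "gnomAD, MGDL"),
)

# (hgvs_p, acmg_class, secondary structure, hydrophobic, hbond, ionic)
TABLE2: tuple[tuple[str, str, str, str, str, str], ...] = (
    ("p.(Ser156_Ala157delinsValGlyValLeuHisProValGlyValLeuHisPro)",
     "LP", "alpha_helix", "possibly", "unlikely", "none"),
    ("p.(Leu165_Leu166insTyrLeu)",
     "VUS", "alpha_helix", "likely", "unlikely", "none"),
    ("p.(Phe318del)",
     "VUS", "alpha_helix", "possibly", "likely", "none"),
    ("p.(Val335_Tyr337delinsAsp)",
     "VUS", "alpha_helix", "likely", "unlikely", "possibly_created"),
    ("p.(Leu538_Leu544del)",
     "VUS", "alpha_helix", "likely", "likely", "none"),
    ("p.(Leu943_Asp944delinsPheTyr)",
     "VUS", "alpha_helix", "possibly", "unlikely", "possibly_lost"),
    ("p.(Ile1003del)",
     "VUS", "alpha_helix", "likely", "unlikely", "none"),
    ("p.(Tyr1220_Asp1223del)",
     "VUS", "alpha_helix", "possibly", "likely", "possibly_lost"),
    ("p.(Gly1231_Thr1234del)",
     "VUS", "alpha_helix", "likely", "likely", "none"),
    ("p.(Asn1365del)",
     "VUS", "loop", "unlikely", "likely", "none"),
)


def load_variants() -> list[IndelVariant]:
    """The 20 fixture variants, parsed, with cohort labels and cDNA."""
    out = []
    for hgvs_c, hgvs_p, cohort, *_ in TABLE1:
        v = parse_hgvs_p(hgvs_p, cohort=Cohort(cohort))
        out.append(replace(v, hgvs_c=hgvs_c))
    return out


def load_variant_grades() -> dict[str, VariantGrades]:
    """Published per-residue grades keyed by protein HGVS."""
    out = {}
    for _, hgvs_p, _, _, grades, _, _ in TABLE1:
        out[hgvs_p] = (
            VariantGrades.from_list(grades)
            if grades is not None
            else VariantGrades(grades=(), min_grade=None, category=None, coverage="none")
        )
    return out


def load_region_map() -> ModeledRegionMap:
    return ModeledRegionMap(intervals=MODELED_INTERVALS, protein_length=PROTEIN_LENGTH)


def load_lcr_annotation() -> LowComplexityAnnotation:
    s, e = LCR_INTERVAL
    return LowComplexityAnnotation(
        lcr_intervals=(LCR_INTERVAL,),
        homopolymer_runs=(("E", s, e, e - s + 1),),
    )


def load_features() -> dict[str, StructuralFeatures]:
    """Recorded qualitative structural features keyed by protein HGVS."""
    out = {}
    for hgvs_p, _, ss, hydro, hbond, ionic in TABLE2:
        out[hgvs_p] = StructuralFeatures(
            ss_summary=SsSummary(ss),
            residue_ss=(),
            hbonds_lost=(),
            hbond_level=DisruptionLevel(hbond),
            hydrophobic_level=DisruptionLevel(hydro),
            ionic=IonicChange(ionic),
        )
    return out


def load_acmg_classes() -> dict[str, str]:
    """Diagnostic (ACMG) class labels, carried as metadata only."""
    return {hgvs_p: acmg for hgvs_p, acmg, *_ in TABLE2}


def write_fixture_bundle(outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain TSV files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = outdir / "variants.tsv"
    with open(p, "w") as fh:
        fh.write("# CACNA1F in-frame indel variants; grades are recorded published data\n")
        fh.write("hgvs_c\thgvs_p\tcohort\tmodeled\tgrades\tin_lcr\tlabel_source\n")
        for hgvs_c, hgvs_p, cohort, modeled, grades, in_lcr, source in TABLE1:
            g = ",".join(map(str, grades)) if grades is not None else "-"
            fh.write(
                f"{hgvs_c}\t{hgvs_p}\t{cohort}\t{'yes' if modeled else 'no'}\t"
                f"{g}\t{'yes' if in_lcr else 'no'}\t{source}\n"
            )
    paths["variants"] = p

    p = outdir / "modeled_intervals.tsv"
    load_region_map().to_tsv(p)
    paths["modeled_intervals"] = p

    p = outdir / "table2_features.tsv"
    with open(p, "w") as fh:
        fh.write("# recorded qualitative structural features of the cohort-A variants\n")
        fh.write("hgvs_p\tacmg_class\tsecondary_structure\thydrophobic\thbond\tionic\n")
        for row in TABLE2:
            fh.write("\t".join(row) + "\n")
    paths["features"] = p

    p = outdir / "lcr.tsv"
    with open(p, "w") as fh:
        fh.write("# reconstructed poly-Glu low-complexity interval (membership only)\n")
        fh.write("start\tend\n")
        fh.write(f"{LCR_INTERVAL[0]}\t{LCR_INTERVAL[1]}\n")
    paths["lcr"] = p
    return paths
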