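"""Generators for every input class the pipeline consumes.

Toy structures (ideal alpha helix, extended chain, random side-chain
clouds), multiple sequence alignments with controlled per-column
substitution rates, homopolymer-bearing sequences, and labeled variant
cohorts that emulate the disease-correlated (A, modeled + conserved)
versus putatively benign (B, unmodeled / low-complexity) contrast.

All generators are pure functions of their spec, seed included: the
same spec yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conservation import AMINO_ACIDS, MultipleAlignment
from .regions import LowComplexityAnnotation, ModeledRegionMap, homopolymer_runs
from .structure import AA1TO3_PDB, Residue, StructureModel
from .variants import Cohort, IndelVariant, VariantKind

__all__ = [
    "MsaSpec",
    "CohortSpec",
    "make_ideal_helix",
    "make_extended_chain",
    "make_msa",
    "make_cohort",
    "make_random_contact_structure",
    "make_lcr_test_sequence",
    "SyntheticStudy",
    "make_study",
]

# Ideal backbone internal coordinates (Engh-Huber-style bond lengths/angles).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O = 120.8
_HELIX_PHI, _HELIX_PSI = -57.8, -47.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: place atom d bonded to c with given internal coordinates."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Tetrahedral CB for an L-amino acid from backbone N, CA, C."""
    u_n = (n - ca) / np.linalg.norm(n - ca)
    u_c = (c - ca) / np.linalg.norm(c - ca)
    bis = -(u_n + u_c)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u_c, u_n)
    perp /= np.linalg.norm(perp)
    theta = math.radians(54.75)
    direction = math.cos(theta) * bis + math.sin(theta) * perp
    return ca + 1.521 * direction / np.linalg.norm(direction)


def _build_chain(
    n_residues: int,
    phi: float,
    psi: float,
    sequence: str | None,
    start_number: int,
    chain_id: str,
    with_cb: bool,
) -> StructureModel:
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    if any(a not in AA1TO3_PDB for a in sequence):
        raise ValueError("sequence must use the 20 standard one-letter codes")
    coords: list[dict[str, np.ndarray]] = []
    # seed first residue in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_residues):
        prev = coords[-1]
        n = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca = _place(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, 180.0)  # omega
        c = _place(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
        coords.append({"N": n, "CA": ca, "C": c})
    # carbonyl O: torsion N-CA-C-O = psi + 180 (anti to the next N)
    for i, at in enumerate(coords):
        at["O"] = _place(at["N"], at["CA"], at["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
    residues = []
    for i, at in enumerate(coords):
        aa = sequence[i]
        atoms = dict(at)
        if with_cb and aa != "G":
            atoms["CB"] = _place_cb(at["N"], at["CA"], at["C"])
        elements = {name: name[:1] for name in atoms}
        residues.append(
            Residue(number=start_number + i, aa=aa, atoms=atoms, elements=elements)
        )
    return StructureModel(chain_id=chain_id, residues=residues)


def make_ideal_helix(
    n_residues: int,
    sequence: str | None = None,
    start_number: int = 1,
    chain_id: str = "A",
    with_cb: bool = True,
) -> StructureModel:
    """Ideal alpha-helical backbone (phi -57.8, psi -47.0).

    The construction yields the canonical helix geometry — a rise of
    about 1.5 A and about 100 degrees of rotation per residue — with
    O(i)...N(i+4) distances in the hydrogen-bonding range [2.7, 3.2] A.
    """
    if n_residues < 4:
        raise ValueError(f"helix needs >= 4 residues, got {n_residues}")
    return _build_chain(
        n_residues, _HELIX_PHI, _HELIX_PSI, sequence, start_number, chain_id, with_cb
    )


def make_extended_chain(
    n_residues: int,
    sequence: str | None = None,
    start_number: int = 1,
    chain_id: str = "A",
    with_cb: bool = True,
) -> StructureModel:
    """Fully extended chain (phi = psi = 180): no i->i+4 contacts."""
    if n_residues < 2:
        raise ValueError(f"chain needs >= 2 residues, got {n_residues}")
    return _build_chain(
        n_residues, 180.0, 180.0, sequence, start_number, chain_id, with_cb
    )


@dataclass(frozen=True)
class MsaSpec:
    """Alignment blueprint: column tiers with fixed substitution rates.

    Each non-reference row copies the reference and substitutes each
    column's residue, with that column's tier rate, by a uniformly
    chosen *different* residue — keeping the truth model independent of
    the BLOSUM62 scoring it is used to exercise.
    """

    n_seqs: int = 11
    length: int = 120
    column_tiers: tuple[tuple[float, float], ...] = (
        (0.25, 0.02),  # conserved sites: nearly invariant
        (0.50, 0.45),  # moderately variable (the bulk of positions)
        (0.25, 0.95),  # highly variable
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seqs < 2:
            raise ValueError("n_seqs must be >= 2")
        fractions = [f for f, _ in self.column_tiers]
        rates = [r for _, r in self.column_tiers]
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("tier fractions must sum to 1")
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        if rates != sorted(rates):
            raise ValueError("tier rates must be ascending")


def _tier_assignment(spec: MsaSpec, rng: np.random.Generator) -> np.ndarray:
    """Random tier index per column, respecting the tier fractions."""
    counts = [int(round(f * spec.length)) for f, _ in spec.column_tiers]
    while sum(counts) < spec.length:
        counts[-1] += 1
    while sum(counts) > spec.length:
        counts[int(np.argmax(counts))] -= 1
    tiers = np.repeat(np.arange(len(counts)), counts)
    rng.shuffle(tiers)
    return tiers


def make_msa(spec: MsaSpec) -> tuple[MultipleAlignment, np.ndarray]:
    """Generate an alignment plus its per-column tier truth labels."""
    rng = np.random.default_rng(spec.seed)
    aas = np.array(list(AMINO_ACIDS))
    tiers = _tier_assignment(spec, rng)
    rates = np.array([r for _, r in spec.column_tiers])[tiers]
    ref = rng.integers(0, len(aas), size=spec.length)
    rows = [("target", "".join(aas[ref]))]
    for k in range(1, spec.n_seqs):
        seq = ref.copy()
        hit = rng.random(spec.length) < rates
        for j in np.nonzero(hit)[0]:
            # uniform over the 19 alternatives
            alt = rng.integers(0, len(aas) - 1)
            if alt >= seq[j]:
                alt += 1
            seq[j] = alt
        rows.append((f"ortholog_{k}", "".join(aas[seq])))
    msa = MultipleAlignment(records=tuple(rows), reference_id="target")
    return msa, tiers


def make_lcr_test_sequence(
    length: int = 100,
    run_residue: str = "E",
    run_length: int = 16,
    run_start: int | None = None,
    seed: int = 0,
) -> tuple[str, tuple[int, int]]:
    """Uniform-random sequence with an embedded homopolymer run.

    Returns the sequence and the 1-based closed interval of the run.
    """
    rng = np.random.default_rng(seed)
    aas = [a for a in AMINO_ACIDS if a != run_residue]
    background = [aas[i] for i in rng.integers(0, len(aas), size=length - run_length)]
    if run_start is None:
        run_start = (length - run_length) // 2 + 1
    i0 = run_start - 1
    seq = background[:i0] + [run_residue] * run_length + background[i0:]
    return "".join(seq), (run_start, run_start + run_length - 1)


def make_random_contact_structure(
    n_residues: int = 30, box: float = 25.0, seed: int = 0
) -> StructureModel:
    """Random cloud of residues with charged/polar/hydrophobic side chains.

    A test bed for the contact detectors: residues are drawn from a mix
    of types, each with backbone atoms plus the side-chain atoms the
    detectors look at, scattered uniformly in a cube of edge ``box`` A.
    """
    rng = np.random.default_rng(seed)
    menu = {
        "R": ("CB", "CG", "CD", "NE", "NH1", "NH2"),
        "K": ("CB", "CG", "CD", "CE", "NZ"),
        "H": ("CB", "CG", "ND1", "NE2"),
        "D": ("CB", "CG", "OD1", "OD2"),
        "E": ("CB", "CG", "CD", "OE1", "OE2"),
        "L": ("CB", "CG", "CD1", "CD2"),
        "F": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
        "N": ("CB", "CG", "OD1", "ND2"),
        "Q": ("CB", "CG", "CD", "OE1", "NE2"),
        "S": ("CB", "OG"),
        "V": ("CB", "CG1", "CG2"),
        "A": ("CB",),
    }
    aas = list(menu)
    residues = []
    for i in range(n_residues):
        aa = aas[rng.integers(0, len(aas))]
        center = rng.uniform(0, box, size=3)
        atoms = {
            "N": center + rng.normal(0, 0.5, 3),
            "CA": center,
            "C": center + rng.normal(0, 0.5, 3),
            "O": center + rng.normal(0, 0.8, 3),
        }
        for name in menu[aa]:
            atoms[name] = center + rng.normal(0, 1.8, 3)
        elements = {name: name[:1] for name in atoms}
        residues.append(Residue(number=i + 1, aa=aa, atoms=atoms, elements=elements))
    return StructureModel(chain_id="A", residues=residues)


@dataclass(frozen=True)
class CohortSpec:
    """Blueprint for a labeled synthetic variant cohort.

    Cohort A: 1-7-residue deletions inside the modeled intervals, each
    guaranteed to touch at least one conserved-tier column (emulating
    "every disease-correlated indel hits a highly conserved residue").
    Cohort B: 1-6-residue deletions or duplications inside unmodeled or
    low-complexity territory.
    """

    n_variants_A: int = 10
    n_variants_B: int = 10
    protein_length: int = 240
    modeled_intervals: tuple[tuple[int, int], ...] = ((11, 90), (121, 200))
    lcr_interval: tuple[int, int] = (101, 116)
    seed: int = 0


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete synthetic study: inputs plus ground truth."""

    sequence: str
    region_map: ModeledRegionMap
    lcr: LowComplexityAnnotation
    msa: MultipleAlignment
    column_tiers: np.ndarray
    variants: tuple[IndelVariant, ...]
    truth: tuple[str, ...]  # intended class per variant: "A" or "B"
    structures: tuple[StructureModel, ...]  # one helix per modeled interval


def _conserved_positions(tiers: np.ndarray, modeled: ModeledRegionMap) -> list[int]:
    """Conserved-tier columns strictly inside a modeled interval.

    Edge columns are excluded: generated deletions are kept off the
    interval edges, so an edge anchor could not be honoured.
    """
    return [
        p
        for s, e in modeled.intervals
        for p in range(s + 1, e)
        if tiers[p - 1] == 0
    ]


def make_cohort(spec: CohortSpec) -> SyntheticStudy:
    """Generate a full synthetic study matching the spec's contrast.

    The MSA's conserved tier is laid over the modeled intervals (where
    cohort-A deletions fall) and the variable tier over unmodeled and
    low-complexity territory, so conservation and structure tell the
    same story, as in the real protein.
    """
    rng = np.random.default_rng(spec.seed)
    region_map = ModeledRegionMap(
        intervals=spec.modeled_intervals, protein_length=spec.protein_length
    )
    lcr_s, lcr_e = spec.lcr_interval
    if any(region_map.contains(p) for p in range(lcr_s, lcr_e + 1)):
        raise ValueError("lcr_interval must lie in unmodeled territory")

    # tier layout: modeled -> conserved/moderate mix, unmodeled -> variable.
    # The conserved tier is held just under one third of all columns
    # (30%) so that it sits strictly inside the top (1-3) band of the
    # equal-occupancy grade scale: at exactly one third, conserved
    # columns straddle the grade-3/4 rank boundary and their intended
    # labels flip on sampling noise.
    tiers = np.full(spec.protein_length, 2, dtype=int)
    modeled_positions = [p for s, e in spec.modeled_intervals for p in range(s, e + 1)]
    p_conserved = (0.30 * spec.protein_length) / len(modeled_positions)
    for p in modeled_positions:
        tiers[p - 1] = 0 if rng.random() < p_conserved else 1

    msa_spec = MsaSpec(
        n_seqs=11,
        length=spec.protein_length,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    rates = {0: 0.02, 1: 0.45, 2: 0.95}
    aas = np.array(list(AMINO_ACIDS))
    msa_rng = np.random.default_rng(msa_spec.seed)
    ref = msa_rng.integers(0, len(aas), size=spec.protein_length)
    # embed the poly-Glu cassette in the reference sequence
    e_idx = AMINO_ACIDS.index("E")
    ref[lcr_s - 1 : lcr_e] = e_idx
    rows = [("target", "".join(aas[ref]))]
    for k in range(1, msa_spec.n_seqs):
        seq = ref.copy()
        for j in range(spec.protein_length):
            if msa_rng.random() < rates[int(tiers[j])]:
                alt = msa_rng.integers(0, len(aas) - 1)
                if alt >= seq[j]:
                    alt += 1
                seq[j] = alt
        rows.append((f"ortholog_{k}", "".join(aas[seq])))
    msa = MultipleAlignment(records=tuple(rows), reference_id="target")
    sequence = msa.reference_sequence

    lcr = LowComplexityAnnotation(
        lcr_intervals=((lcr_s, lcr_e),),
        homopolymer_runs=homopolymer_runs(sequence, min_len=4),
    )

    variants: list[IndelVariant] = []
    truth: list[str] = []
    conserved = _conserved_positions(tiers, region_map)
    from .variants import AA1TO3  # local import to avoid cycle at module load

    def deletion_at(start: int, end: int, cohort: Cohort) -> IndelVariant:
        ref_res = sequence[start - 1 : end]
        first3, last3 = AA1TO3[ref_res[0]], AA1TO3[ref_res[-1]]
        name = (
            f"p.({first3}{start}del)"
            if start == end
            else f"p.({first3}{start}_{last3}{end}del)"
        )
        return IndelVariant(
            hgvs_p=name, kind=VariantKind.deletion, start_res=start, end_res=end,
            ref_residues=ref_res, alt_residues="", cohort=cohort,
        )

    for _ in range(spec.n_variants_A):
        anchor = conserved[int(rng.integers(0, len(conserved)))]
        length = int(rng.integers(1, 8))
        s_itv, e_itv = next(
            (s, e) for s, e in spec.modeled_intervals if s <= anchor <= e
        )
        # interval of `length` residues containing the conserved anchor,
        # clipped to the modeled interval and kept off its edges so the
        # deletion sits inside the helix
        lo = max(s_itv + 1, anchor - length + 1)
        hi = min(e_itv - length, anchor)
        if hi >= lo:
            start = int(rng.integers(lo, hi + 1))
            end = start + length - 1
        else:  # interval too cramped: fall back to a 1-residue deletion
            start = end = max(s_itv + 1, min(anchor, e_itv - 1))
        variants.append(deletion_at(start, end, Cohort.A))
        truth.append("A")

    unmodeled_pool = [
        p
        for p in range(1, spec.protein_length + 1)
        if not region_map.contains(p)
    ]
    for _ in range(spec.n_variants_B):
        length = int(rng.integers(1, 7))
        while True:
            start = unmodeled_pool[int(rng.integers(0, len(unmodeled_pool)))]
            end = start + length - 1
            if end <= spec.protein_length and not any(
                region_map.contains(p) for p in range(start, end + 1)
            ):
                break
        if rng.random() < 0.4:
            seg = sequence[start - 1 : end]
            first3, last3 = AA1TO3[seg[0]], AA1TO3[seg[-1]]
            name = (
                f"p.({first3}{start}dup)"
                if start == end
                else f"p.({first3}{start}_{last3}{end}dup)"
            )
            v = IndelVariant(
                hgvs_p=name, kind=VariantKind.duplication, start_res=start,
                end_res=end, ref_residues="", alt_residues=seg, cohort=Cohort.B,
            )
        else:
            v = deletion_at(start, end, Cohort.B)
        variants.append(v)
        truth.append("B")

    structures = tuple(
        make_ideal_helix(
            e - s + 1, sequence=sequence[s - 1 : e], start_number=s, with_cb=True
        )
        for s, e in spec.modeled_intervals
    )
    return SyntheticStudy(
        sequence=sequence,
        region_map=region_map,
        lcr=lcr,
        msa=msa,
        column_tiers=tiers,
        variants=tuple(variants),
        truth=tuple(truth),
        structures=structures,
    )


# Backwards-friendly alias: a study is a cohort plus its inputs.
make_study = make_cohort


def evaluate_study(study: SyntheticStudy, config=None) -> list[tuple[str, str]]:
    """Run the full pipeline on a synthetic study.

    Conservation is recomputed from the study's MSA, structural
    features from its helix models — nothing is read off the truth
    labels.  Returns (intended class, call) per variant.
    """
    from .assess import AssessmentConfig, assess_variant
    from .conservation import profile_from_msa, variant_grades
    from .regions import Membership, region_membership
    from .structure import variant_structural_features

    config = config or AssessmentConfig()
    profile = profile_from_msa(study.msa)
    out = []
    for v, intended in zip(study.variants, study.truth):
        grades = variant_grades(v, profile)
        membership, _ = region_membership(v, study.region_map)
        feats = None
        if membership is not Membership.unmodeled:
            for model in study.structures:
                numbers = set(model.residue_numbers)
                if set(range(v.start_res, v.end_res + 1)) <= numbers:
                    feats = variant_structural_features(
                        model, v,
                        hbond_likely_at=config.hbond_likely_at,
                        hydrophobic_likely_at=config.hydrophobic_likely_at,
                    )
                    break
        a = assess_variant(v, study.region_map, grades, study.lcr, feats, config)
        out.append((intended, a.call))
    return out
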