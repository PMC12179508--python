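# Methods

This note records the models, parameter choices and numerical
decisions behind `indelstruct`, and what the synthetic experiments do
and do not demonstrate.

## Scope and inputs

The pipeline interprets protein-level HGVS in-frame indels (del, ins,
dup, delins).  Protein notation is authoritative; cDNA descriptions
are used only to cross-check frame and length (a cDNA→protein
projection would require the transcript sequence and is deliberately
not implemented, keeping the package free of database downloads).
Frameshift, nonsense and extension notations are rejected as
out-of-class.  Coordinates are 1-based closed intervals throughout,
following HGVS convention.  Range notations name only their flanking
residues; interior residues are stored as `X` placeholders so that the
removed-segment length is always explicit.

Three residue sets per variant are distinguished deliberately:

* *membership interval* — `start..end` for every kind, including the
  two flanking residues of a pure insertion (an insertion disrupts the
  region containing its flanks);
* *affected residues* — removed residues, or the duplicated template
  residues for a duplication;
* *grading-eligible residues* — removed residues only (deletions and
  delins).  Insertions and duplications remove nothing and therefore
  carry no conservation grades; in the packaged cohort this reproduces
  the published accounting of 25 graded residues over 9 disease-cohort
  variants and 9 over 6 benign-cohort variants.

For a delins, grades attach to the replaced residues only; how the
*inserted* residues should enter conservation analysis is undefined in
the source data, and we take the conservative position that they
cannot be graded against a reference alignment they do not appear in.

## Conservation model

The raw column score is the expected pairwise BLOSUM62 score under the
column's residue frequencies, `score(c) = Σ f_a f_b B62(a,b)`.  This
uses exactly two ingredients — column frequencies and BLOSUM62 — and
has convenient properties: it is invariant to row order and to
duplicating the alignment, and a pure column of residue *r* attains
the maximum over any mixture containing *r* (both are property-tested).
Gaps are excluded from frequencies; columns with gap fraction > 0.5 or
fewer than two residues are unscorable and carry no grade, which
prevents terminal-extension artifacts.

Grades are equal-occupancy over ranks: rank *r* of *n* scorable
columns (most conserved first, ties taking the minimal rank of their
group) maps to grade `⌊9r/n⌋ + 1`.  Equal-occupancy was chosen over
equal-width binning because it is deterministic, independent of
alignment length and score scale, and matches the familiar nine-grade
convention of conservation servers; ties share the better grade so
that an all-identical alignment is all grade 1.

A known property of the raw score is identity confounding: a perfect
leucine column scores 4 while a perfect tryptophan column scores 11,
so a lightly substituted column of a high-self-score residue can
outrank a perfect column of a common residue.  This matters wherever
grade bands are interpreted as substitution-rate classes (see the
synthetic-data section).

## Modeled regions and low complexity

Modeled intervals come either from a 2-row target–template alignment
(target positions facing non-gap template symbols, merged into maximal
intervals — property-tested as a round trip against interval sets the
alignment was synthesized from) or from an explicit interval file.
The packaged study ships the printed intervals (67–414, 516–766,
858–1580 of 1977 residues) as the canonical fixture because the
underlying modeling alignment is not redistributable.

Low-complexity detection is a Wootton–Federhen-style two-threshold
scan: Shannon entropy (bits, 20-letter alphabet) over 12-residue
windows; windows ≤ 2.2 bits seed a region, which extends across
neighbouring windows ≤ 2.5 bits; overlapping regions merge.  These are
the classic SEG-like defaults; with them a 16-residue poly-Glu run
embedded in random sequence is always flagged while uniform-random
200-mers are unflagged in ≥95% of seeds.  Boundary resolution is one
window: a flagged interval may overhang the true run by up to ~12
residues, because any window touching enough of the run qualifies.
The packaged poly-Glu interval is a reconstruction — the study names
the region but prints no coordinates — chosen as a 16-residue window
(814–829) covering the affected residues 820–825 of every
low-complexity-flagged cohort-B variant; it is used for membership
tests only, never for coordinate assertions.  Disorder prediction is
out of scope; unmodeled status plus low complexity stand in for it.

## Structural features

The published analysis identified hydrogen bonds with an external
validation tool and judged hydrophobic/ionic disruption by visual
inspection.  This package replaces both with explicit geometric
criteria so the procedure is reproducible:

* backbone H-bonds: Kabsch–Sander electrostatic energy with the
  standard −0.5 kcal/mol cutoff; amide hydrogens reconstructed 1.0 Å
  from N opposite the preceding carbonyl (prolines donate nothing;
  pairs closer than 0.5 Å or with O···N > 5.2 Å are skipped as
  degenerate/unreachable);
* side-chain polar contacts: N/O pairs ≤ 3.5 Å with at least one
  side-chain atom (backbone–backbone pairs belong to the H-bond
  detector);
* salt bridges: Arg NH1/NH2/NE, Lys NZ, His ND1/NE2 versus Asp
  OD1/OD2, Glu OE1/OE2 at ≤ 4.0 Å;
* hydrophobic contacts: side-chain carbon pairs ≤ 4.5 Å between
  residues of {A,V,L,I,M,F,W,Y,P} at sequence separation ≥ 2.

Side-chain hydrogens are never placed; all side-chain criteria are
heavy-atom.  Detectors use a KD-tree and are tested for exact equality
against O(n²) all-pairs scans on seeded random structures.

Secondary structure is two-state: a residue is H when it lies in a run
of ≥ 4 residues covered by i→i+4 backbone bonds, else L.  Strand
assignment is omitted because the feature tables only distinguish
α-helix from loop; 3₁₀/π helices fold into L.  Labels are invariant
under rigid-body motion (tested with random rotations/translations).

Per-variant disruption levels count interactions touching the
variant's residues: hydrogen bonding is *likely* at ≥ 2 lost bonds,
*possibly* at 1; hydrophobic packing is *likely* at ≥ 4 lost contacts,
*possibly* at 1–3.  A salt bridge touching the interval marks the
ionic column *possibly lost*; a delins introducing a charged residue
with a counter-charge within 4.0 Å of the replaced position's CB site
is flagged *possibly created* — flagged, never asserted, since no
side-chain is actually built.  These count thresholds are config keys;
the defaults reproduce the recorded qualitative levels on generated
toy analogues (a mid-helix deletion loses multiple backbone bonds, a
loop deletion with one polar contact is *possibly*).

The packaged per-variant feature table is recorded published data, not
recomputation: the real homology model is an optional external input,
and when supplied the same functions recompute features from it.

## Combination rule

The evidence-combination rule is the least constrained part of the
source procedure ("all features were combined") and is therefore kept
minimal, explicit, and config-overridable:

1. unmodeled → features are never computed (supplying them is a
   consistency error); call `benign_leaning` iff low-complexity
   overlap or min grade ≥ 7, else `uncertain`;
2. modeled → call `destabilizing` iff (min grade ≤ 3 or no grades
   exist) and at least one feature level is disruptive, else
   `uncertain`.

The grades-absent clause in rule 2 is a deliberate extension: a
modeled pure insertion removes no residues, so it can never present a
min grade, yet a disrupted helix is still disruptive evidence — the
packaged cohort's one insertion is exactly this case.  On the packaged
cohort the rule yields a clean 10/0 split (all disease-cohort variants
destabilizing, no benign-cohort variant).  `benign_leaning`
deliberately avoids the word "benign": the benign cohort is only
putatively benign.

## Cohort statistic

U counts pairs (a < b) plus half-ties, so large U means cohort A holds
the lower (more conserved) grades.  The p-value uses the normal
approximation with tie-corrected variance
`(n_A n_B / 12)·[(N+1) − Σ(t³−t)/(N(N−1))]` and no continuity
correction; for n_A + n_B ≤ 10 the exact permutation null is
enumerated instead (the implementation is property-tested against an
independent brute-force oracle on all small inputs).  The one-sided
alternative (A more conserved) is the default: on the packaged grades
it gives p = 2.72 × 10⁻⁵ (3 × 10⁻⁵ at one significant figure) where
the two-sided tail gives ~5.4 × 10⁻⁵; both are always reported.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their spec (seed included).

* **Ideal helix / extended chain** — backbones built from ideal
  internal coordinates (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O
  1.231 Å; φ/ψ = −57.8/−47.0° for the helix, 180/180° for the chain),
  yielding the canonical ~1.5 Å rise and ~100°/residue twist with
  O(i)···N(i+4) = 3.05 Å, comfortably inside the 2.7–3.2 Å
  hydrogen-bonding range.  CB atoms are placed tetrahedrally; no other
  side-chain atoms exist, so hydrophobic contacts on these models are
  sparse by construction.
* **Alignments** — each non-reference row copies the reference and
  substitutes per-column with that column's tier rate, uniformly over
  the 19 alternatives.  Uniform (not BLOSUM-biased) substitution keeps
  the truth model independent of the scoring matrix being tested.
  Default tiers: 25% of columns nearly invariant (rate 0.02), 50%
  moderately variable (0.45), 25% highly variable (0.95), 11 rows.
  The extreme tiers are held to a quarter each — strictly inside the
  top and bottom thirds of the rank scale — because at exactly one
  third the tier boundary coincides with the grade-3/4 (and 6/7) rank
  boundary and identity confounding (above) flips labels there; with
  this margin, low-rate columns land in grades 1–3 and high-rate
  columns in grades 7–9 for ≥95% of columns across seeds.
* **Cohorts** — a full study in miniature: modeled intervals covering
  two-thirds of a 240-residue protein, a 16-residue poly-Glu cassette
  in unmodeled territory, an alignment whose conserved tier (30% of
  columns) lies inside the modeled intervals, helix models spanning
  them, class-A variants as 1–7-residue deletions anchored on a
  conserved column strictly inside a modeled interval, class-B
  variants as 1–6-residue deletions/duplications in unmodeled or
  low-complexity territory.

Full-pipeline recovery on 50 such cohorts calls ~99% of class-A
variants destabilizing and 0% of class-B (the truth labels are never
visible to the pipeline).  The residual class-A misses are honest:
anchor columns that graded 4–6 through rank-boundary noise, and rare
single-residue deletions next to a proline whose only backbone bond
does not exist.  What these experiments show is internal consistency —
the pipeline recovers planted signal under its own assumptions.  They
do not show clinical accuracy: real alignments have gaps, indels and
phylogenetic structure rather than i.i.d. substitutions; real
structures are not ideal helices; and real benign variants are not
guaranteed to avoid modeled regions.  The packaged 20-variant study is
a single gene with a distinctive architecture (the benign cohort
clusters in a glutamate-rich disordered region), so the clean 10/0
split should be read as a property of that study, not an expected
error rate.

## Numerical and degenerate-input conventions

* Grades of tied raw scores share the better grade; an all-tied
  alignment is all grade 1.
* Unscorable columns propagate as absent grades; a variant with no
  covered eligible residue carries a no-coverage marker, and partial
  coverage warns.
* Unparseable cDNA strings downgrade the consistency check to a
  warning (skipped, not failed).
* Alternate locations in PDB input keep the highest-occupancy atom;
  residues missing backbone atoms are kept but recorded as warnings,
  and secondary-structure assignment refuses CA-only models.
* Floating-point output is fixed at 6 significant digits, p-values in
  scientific notation; reports are byte-identical across reruns with
  identical inputs.
* Problem sizes in the test suite and acceptance script (50 synthetic
  cohorts of 20 variants on 240-residue proteins, 200-replicate
  alignment recovery, 50-seed detector cross-checks) were chosen so
  the full battery runs in well under a minute while keeping binomial
  noise on the 95% recovery margins small.
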