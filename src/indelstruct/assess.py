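"""Evidence combination and cohort statistics.

Per-variant call
----------------
Evidence is combined by a fixed, auditable rule set (thresholds live in
:class:`AssessmentConfig` so diagnostics teams can re-weight them):

* unmodeled variant — no structural features are computed; the call is
  ``benign_leaning`` when the variant sits in a low-complexity region
  or removes only highly variable residues (min grade >= 7), else
  ``uncertain``.
* modeled variant — the call is ``destabilizing`` when the variant
  removes at least one highly conserved residue (min grade <= 3) and
  at least one structural feature is disrupted (hydrogen bonding,
  hydrophobic packing, or an ionic interaction).  A modeled variant
  that carries no conservation grades (a pure insertion or a
  duplication) is called on the structural evidence alone.  Everything
  else is ``uncertain``.

Every rule that fires is appended to the assessment's evidence trail.
The label ``benign_leaning`` is deliberate: the benign cohort of such
studies is only *putatively* benign.

Cohort statistic
----------------
The Mann–Whitney U statistic counts pairs (a, b) with a < b plus half
the ties, so large U means group A holds the lower (more conserved)
grades.  The p-value uses the normal approximation with tie-corrected
variance

    Var(U) = (nA nB / 12) * [(N + 1) - sum(t^3 - t) / (N (N - 1))],

except that for small samples (nA + nB <= 10) the exact permutation
null is enumerated instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .conservation import VariantGrades
from .regions import (
    LowComplexityAnnotation,
    Membership,
    ModeledRegionMap,
    in_low_complexity,
    region_membership,
)
from .structure import DisruptionLevel, IonicChange, SsSummary, StructuralFeatures
from .variants import Cohort, IndelVariant

__all__ = [
    "Call",
    "AssessmentConfig",
    "VariantAssessment",
    "CohortStats",
    "assess_variant",
    "mann_whitney_u",
    "cohort_report",
]

EXACT_ENUMERATION_MAX_N = 10


class Call:
    destabilizing = "destabilizing"
    benign_leaning = "benign_leaning"
    uncertain = "uncertain"


@dataclass(frozen=True)
class AssessmentConfig:
    """Every threshold of the combination rule, with defaults."""

    conserved_max_grade: int = 3      # min grade <= this counts as highly conserved
    variable_min_grade: int = 7       # min grade >= this counts as highly variable
    hbond_likely_at: int = 2
    hydrophobic_likely_at: int = 4
    alternative: str = "a_lower"      # sidedness of the cohort U test

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssessmentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class VariantAssessment:
    variant: IndelVariant
    membership: Membership
    modeled_fraction: float
    grades: VariantGrades
    low_complexity: bool
    features: StructuralFeatures | None
    call: str
    evidence: tuple[tuple[str, str], ...]


class ConsistencyError(ValueError):
    """Contradictory inputs (e.g. features for an unmodeled variant)."""


def assess_variant(
    v: IndelVariant,
    region_map: ModeledRegionMap,
    grades: VariantGrades,
    lcr: LowComplexityAnnotation,
    features: StructuralFeatures | None = None,
    config: AssessmentConfig = AssessmentConfig(),
) -> VariantAssessment:
    """Combine region, conservation, low-complexity and structural
    evidence into a single call.  See the module docstring for the rule
    order."""
    membership, fraction = region_membership(v, region_map)
    low_complexity = in_low_complexity(v, lcr)
    evidence: list[tuple[str, str]] = [
        ("region", f"{membership.value} (fraction {fraction:.2f})"),
    ]
    if grades.min_grade is not None:
        evidence.append(
            ("conservation", f"grades {list(grades.grades)}, min {grades.min_grade}")
        )
    else:
        evidence.append(("conservation", "no grading-eligible residues covered"))
    if low_complexity:
        evidence.append(("low_complexity", "interval overlaps a low-complexity region"))

    if membership is Membership.unmodeled:
        if features is not None:
            raise ConsistencyError(
                f"{v.hgvs_p}: structural features supplied for an unmodeled variant"
            )
        if low_complexity or (
            grades.min_grade is not None
            and grades.min_grade >= config.variable_min_grade
        ):
            call = Call.benign_leaning
            evidence.append(
                ("call", "unmodeled and (low-complexity or highly variable)")
            )
        else:
            call = Call.uncertain
            evidence.append(("call", "unmodeled; no benign-leaning signal"))
    else:
        if features is None:
            call = Call.uncertain
            evidence.append(("call", "modeled but structural features unavailable"))
        else:
            disrupted = features.any_disruption
            if disrupted:
                evidence.append(
                    (
                        "structure",
                        f"hbond={features.hbond_level.value}, "
                        f"hydrophobic={features.hydrophobic_level.value}, "
                        f"ionic={features.ionic.value}",
                    )
                )
            conserved = (
                grades.min_grade is not None
                and grades.min_grade <= config.conserved_max_grade
            )
            if disrupted and (conserved or grades.min_grade is None):
                call = Call.destabilizing
                why = (
                    "highly conserved residue removed and structure disrupted"
                    if conserved
                    else "no removed residues to grade; structure disrupted"
                )
                evidence.append(("call", why))
            else:
                call = Call.uncertain
                evidence.append(("call", "modeled; evidence insufficient"))

    return VariantAssessment(
        variant=v,
        membership=membership,
        modeled_fraction=fraction,
        grades=grades,
        low_complexity=low_complexity,
        features=features,
        call=call,
        evidence=tuple(evidence),
    )


@dataclass(frozen=True)
class CohortStats:
    n_A: int
    n_B: int
    U: float
    z: float
    p_one_sided: float
    p_two_sided: float
    tie_corrected_variance: float
    method: str  # "exact" or "normal"

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"n_A\t{self.n_A}\n")
            fh.write(f"n_B\t{self.n_B}\n")
            fh.write(f"U\t{self.U:.6g}\n")
            fh.write(f"z\t{self.z:.6g}\n")
            fh.write(f"p_one_sided\t{self.p_one_sided:.6e}\n")
            fh.write(f"p_two_sided\t{self.p_two_sided:.6e}\n")
            fh.write(f"tie_corrected_variance\t{self.tie_corrected_variance:.6g}\n")
            fh.write(f"method\t{self.method}\n")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    less = (a[:, None] < b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    return float(less + 0.5 * ties)


def mann_whitney_u(
    a: list[float], b: list[float], alternative: str = "a_lower"
) -> CohortStats:
    """Tie-corrected Mann–Whitney U test of group A versus group B.

    ``alternative="a_lower"`` tests whether A's values are
    stochastically lower than B's (one-sided); ``"two_sided"`` reports
    the symmetric tail.  Both p-values are always populated.  The exact
    permutation null is enumerated whenever nA + nB <= 10.
    """
    if alternative not in ("a_lower", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    n_a, n_b = len(av), len(bv)
    n = n_a + n_b
    u = _u_statistic(av, bv)
    mu = n_a * n_b / 2.0

    pooled = np.concatenate([av, bv])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    if n <= EXACT_ENUMERATION_MAX_N:
        us = []
        idx = range(n)
        for comb in combinations(idx, n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(comb)] = True
            us.append(_u_statistic(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        eps = 1e-9
        p_one = float((us >= u - eps).mean())
        p_two = float((np.abs(us - mu) >= abs(u - mu) - eps).mean())
        method = "exact"
    else:
        method = "normal"

    if var <= 0:
        z = 0.0
        p_one_norm = p_two_norm = 1.0
    else:
        z = (u - mu) / math.sqrt(var)
        p_one_norm = float(norm.sf(z))
        p_two_norm = min(1.0, 2.0 * float(norm.sf(abs(z))))
    if method == "normal":
        p_one, p_two = p_one_norm, p_two_norm

    return CohortStats(
        n_A=n_a,
        n_B=n_b,
        U=u,
        z=z,
        p_one_sided=p_one,
        p_two_sided=p_two,
        tie_corrected_variance=var,
        method=method,
    )


_SS_LABEL = {SsSummary.alpha_helix: "α-Helix", SsSummary.loop: "Loop", SsSummary.mixed: "Mixed"}
_LEVEL_LABEL = {
    DisruptionLevel.likely: "Likely",
    DisruptionLevel.possibly: "Possibly",
    DisruptionLevel.unlikely: "Unlikely",
}
_IONIC_LABEL = {
    IonicChange.none: "None",
    IonicChange.possibly_lost: "Possibly (lost)",
    IonicChange.possibly_created: "Possibly (created)",
}


def cohort_report(
    assessments: list[VariantAssessment],
    stats: CohortStats | None = None,
) -> pd.DataFrame:
    """Per-variant report table mirroring the published layout.

    One row per variant with cohort, modeled status, grades, LCR flag,
    feature levels (display strings) and the combined call.  Footer
    statistics are attached in ``df.attrs["summary"]``.
    """
    if not assessments:
        raise ValueError("need at least one assessment")
    rows = []
    for a in assessments:
        f = a.features
        rows.append(
            {
                "hgvs_c": a.variant.hgvs_c or "",
                "hgvs_p": a.variant.hgvs_p,
                "cohort": a.variant.cohort.value,
                "modeled": a.membership.value,
                "grades": ",".join(map(str, a.grades.grades)) if a.grades.grades else "-",
                "min_grade": a.grades.min_grade if a.grades.min_grade is not None else "-",
                "category": a.grades.category.value if a.grades.category else "-",
                "low_complexity": "yes" if a.low_complexity else "no",
                "secondary_structure": _SS_LABEL[f.ss_summary] if f else "NA",
                "hydrophobic_disrupted": _LEVEL_LABEL[f.hydrophobic_level] if f else "NA",
                "hbond_disrupted": _LEVEL_LABEL[f.hbond_level] if f else "NA",
                "ionic_involved": _IONIC_LABEL[f.ionic] if f else "NA",
                "call": a.call,
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "n_variants": len(df),
        "n_fully_modeled": int((df["modeled"] == Membership.fully_modeled.value).sum()),
        "n_unmodeled": int((df["modeled"] == Membership.unmodeled.value).sum()),
        "n_low_complexity": int((df["low_complexity"] == "yes").sum()),
        "calls": df["call"].value_counts().to_dict(),
        "categories": df["category"].value_counts().to_dict(),
    }
    if stats is not None:
        summary["U"] = stats.U
        summary["p_one_sided"] = stats.p_one_sided
        summary["p_two_sided"] = stats.p_two_sided
    df.attrs["summary"] = summary
    return df


def write_report_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write the report with its summary footer as comment lines."""
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        summary = df.attrs.get("summary", {})
        for key, value in summary.items():
            if isinstance(value, float):
                fh.write(f"# {key}\t{value:.6e}\n")
            else:
                fh.write(f"# {key}\t{value}\n")


def cohort_grade_vectors(
    variants: list[IndelVariant],
    grades_by_variant: dict[str, VariantGrades],
) -> tuple[list[int], list[int]]:
    """Pool per-residue grades of graded variants by cohort (A, B)."""
    pooled = {Cohort.A: [], Cohort.B: []}
    for v in variants:
        g = grades_by_variant.get(v.hgvs_p)
        if g is None or not g.grades:
            continue
        if v.cohort in pooled:
            pooled[v.cohort].extend(g.grades)
    return pooled[Cohort.A], pooled[Cohort.B]
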