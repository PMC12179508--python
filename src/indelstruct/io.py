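"""Run configuration, variant-table I/O and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .assess import AssessmentConfig
from .conservation import VariantGrades
from .variants import Cohort, IndelVariant, parse_hgvs_p

__all__ = [
    "RunConfig",
    "ConfigError",
    "read_variant_tsv",
    "write_manifest",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    variants: str | None = None
    msa: str | None = None
    msa_format: str = "fasta"
    structure: str | None = None
    intervals: str | None = None
    out: str = "out"
    seed: int = 0
    log_level: str = "INFO"
    assessment: AssessmentConfig = field(default_factory=AssessmentConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping: {path}")
        known = set(cls.__dataclass_fields__)
        assess_keys = set(AssessmentConfig.__dataclass_fields__)
        top = {}
        nested = {}
        for key, value in data.items():
            if key in assess_keys:
                nested[key] = value
            elif key == "assessment" and isinstance(value, dict):
                bad = set(value) - assess_keys
                if bad:
                    raise ConfigError(f"unknown assessment keys: {sorted(bad)}")
                nested.update(value)
            elif key in known:
                top[key] = value
            else:
                raise ConfigError(f"unknown config key: {key!r}")
        try:
            top["assessment"] = AssessmentConfig(**nested)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        return cls(**top)


def read_variant_tsv(
    path: str | Path,
) -> tuple[list[IndelVariant], dict[str, VariantGrades]]:
    """Read a variant TSV (hgvs_c, hgvs_p, cohort, optional grades...).

    Tab-separated, UTF-8, ``#`` comment lines allowed.  A ``grades``
    column, when present, supplies externally computed per-residue
    grades ("-" for none); these are returned keyed by protein HGVS.
    """
    variants: list[IndelVariant] = []
    grades: dict[str, VariantGrades] = {}
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                if "hgvs_p" not in header:
                    raise ConfigError(f"{path}: missing required column 'hgvs_p'")
                continue
            row = dict(zip(header, cells))
            cohort = Cohort(row.get("cohort", "unlabeled") or "unlabeled")
            v = parse_hgvs_p(row["hgvs_p"], cohort=cohort)
            if row.get("hgvs_c"):
                v = replace(v, hgvs_c=row["hgvs_c"])
            variants.append(v)
            raw_grades = row.get("grades", "").strip()
            if raw_grades and raw_grades != "-":
                parsed = [int(tok) for tok in raw_grades.split(",")]
                grades[v.hgvs_p] = VariantGrades.from_list(parsed)
            elif raw_grades == "-":
                grades[v.hgvs_p] = VariantGrades(
                    grades=(), min_grade=None, category=None, coverage="none"
                )
    return variants, grades


def _hash_config(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(config: RunConfig, outdir: str | Path, **extra) -> Path:
    """Machine-readable record of one run: inputs, config hash, seed."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "indelstruct",
        "version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "config_hash": _hash_config(config),
        "seed": config.seed,
        **extra,
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
        fh.write("\n")
    return path
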