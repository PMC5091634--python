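"""Cohort file readers/writers, VCF variant input and report documents.

Cohort schema (CSV, UTF-8, mandatory header; TSV via ``sep="\\t"``):
``case_id``, ``histotype`` (HGSOC|EC), ``variant`` (HGVS p./c. notation or
``NDM``) and one staining column per assay, ``pattern_m1`` .. ``pattern_m4``
(values OE/CA/WT/CY/unscored; blank allowed for assays not run).  Row-level
problems are aggregated and reported with line numbers in one exception rather
than failing on the first.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .classify import classify_cohort, classify_case
from .discordance import RevisionRecord
from .predict import PATTERNS, UNSCORED
from .reference import (
    HgvsParseError,
    ProteinVariant,
    VariantKind,
    parse_coding_hgvs,
    parse_protein_hgvs,
    parse_variant_field,
)

__all__ = [
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "read_revisions",
    "read_vcf_variants",
    "cohort_from_vcf",
    "build_report",
    "write_report",
]

logger = logging.getLogger("tp53ihc")

REQUIRED_COLUMNS = ("case_id", "histotype", "variant")
PATTERN_COLUMNS = tuple(f"pattern_m{i}" for i in range(1, 5))
HISTOTYPES = ("HGSOC", "EC")
VALID_PATTERNS = set(PATTERNS) | {UNSCORED}


class CohortValidationError(ValueError):
    """Aggregated row-level validation failures, with line numbers."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} cohort validation problem(s):\n  "
            + "\n  ".join(self.problems)
        )


def read_cohort(path, sep: str = ",", classify: bool = True) -> pd.DataFrame:
    """Read and validate a cohort table; optionally derive classification columns."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise CohortValidationError([f"{path}: file is empty or has no header"])
    problems: List[str] = []
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            problems.append(f"missing required column {col!r}")
    pattern_cols = [c for c in PATTERN_COLUMNS if c in df.columns]
    if not pattern_cols:
        problems.append("no staining column (pattern_m1..pattern_m4) present")
    if problems:
        raise CohortValidationError(problems)

    for i, row in df.iterrows():
        line = i + 2  # header occupies line 1
        if pd.isna(row["case_id"]) or not str(row["case_id"]).strip():
            problems.append(f"line {line}: empty case_id")
        if row["histotype"] not in HISTOTYPES:
            problems.append(
                f"line {line}: histotype {row['histotype']!r} not in {HISTOTYPES}"
            )
        for col in pattern_cols:
            val = row[col]
            if pd.notna(val) and val not in VALID_PATTERNS:
                problems.append(
                    f"line {line}: unknown staining pattern {val!r} in {col}"
                )
        try:
            parse_variant_field(row["variant"])
        except ValueError as exc:
            problems.append(f"line {line}: {exc}")
    dup = df["case_id"][df["case_id"].duplicated()]
    for cid in dup:
        problems.append(f"duplicate case_id {cid!r}")
    if problems:
        raise CohortValidationError(problems)
    return classify_cohort(df) if classify else df


def write_cohort(cohort: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a cohort table; derived classification columns are not persisted."""
    derived = [c for c in ("mutation_type", "indel_frame", "functional_class")
               if c in cohort.columns]
    cohort.drop(columns=derived).to_csv(path, sep=sep, index=False)


def read_revisions(path) -> List[RevisionRecord]:
    """Read revision records from CSV (case_id,field,old_value,new_value,evidence[,method_id])
    or from a JSON list of objects with the same keys."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
    else:
        raw = pd.read_csv(path, dtype=str).to_dict(orient="records")
    records = []
    for entry in raw:
        records.append(RevisionRecord(
            case_id=str(entry["case_id"]),
            field=str(entry["field"]),
            old_value=str(entry["old_value"]),
            new_value=str(entry["new_value"]),
            evidence=str(entry.get("evidence") or ""),
            method_id=int(entry.get("method_id") or 1),
        ))
    return records


def read_vcf_variants(
    path,
    protein_key: str = "HGVSP",
    coding_key: str = "HGVSC",
    case_key: str = "CASE",
    case_ids: Optional[Sequence[str]] = None,
) -> Dict[str, ProteinVariant]:
    """Extract one protein-level variant per case from an annotated VCF.

    Each record must carry the case identifier and an HGVS annotation in the
    documented INFO keys.  Records lacking any usable annotation are skipped
    with a logged warning count.  Cases with several records are collapsed to
    the most disruptive variant (the classifier's priority rule); case ids
    passed in ``case_ids`` but absent from the VCF come back as no-mutation.
    """
    import pysam

    per_case: Dict[str, List[ProteinVariant]] = {}
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            info = rec.info
            case = info.get(case_key)
            if isinstance(case, tuple):
                case = case[0]
            notation = info.get(protein_key) or info.get(coding_key)
            if isinstance(notation, tuple):
                notation = notation[0]
            if not case or not notation:
                skipped += 1
                continue
            try:
                variant = (
                    parse_coding_hgvs(notation)
                    if str(notation).lower().startswith("c.")
                    else parse_protein_hgvs(str(notation))
                )
            except ValueError:
                skipped += 1
                continue
            per_case.setdefault(str(case), []).append(variant)
    if skipped:
        logger.warning("skipped %d VCF record(s) without usable annotation", skipped)

    result = {
        case: classify_case(variants)[0] for case, variants in per_case.items()
    }
    for cid in case_ids or ():
        result.setdefault(str(cid), parse_variant_field(None))
    return result


def cohort_from_vcf(vcf_path, cohort: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Replace a cohort's variant column with per-case calls from an annotated VCF."""
    calls = read_vcf_variants(vcf_path, case_ids=list(cohort["case_id"]), **kwargs)
    out = cohort.copy()
    out["variant"] = [
        calls[cid].raw if calls[cid].kind is not VariantKind.NONE else "NDM"
        for cid in out["case_id"]
    ]
    return classify_cohort(out.drop(
        columns=[c for c in ("mutation_type", "indel_frame", "functional_class")
                 if c in out.columns]
    ))


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def build_report(
    results: Sequence,
    discordant: Optional[dict] = None,
    input_path=None,
    seed: Optional[int] = None,
) -> dict:
    """Assemble a self-contained report document from fitted results.

    Every proportion in the document is recomputable from the embedded
    confusion matrices.
    """
    from importlib.metadata import version

    try:
        pkg_version = version("tp53ihc")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    doc = {
        "software": {"name": "tp53ihc", "version": pkg_version},
        "results": [r.to_dict() for r in results],
    }
    if discordant is not None:
        doc["discordance"] = discordant
    if input_path is not None:
        doc["input"] = {"path": str(input_path), "sha256_16": _digest(input_path)}
    if seed is not None:
        doc["seed"] = seed
    return doc


def write_report(doc: dict, path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
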