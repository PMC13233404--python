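"""Annotation-table CSV dialect and run configuration.

The on-disk table has one row per (phenotype, replicate): columns
``hpo_id, hpo_name, replicate`` followed, in the canonical characteristic
order, by ``<char>_freq`` and ``<char>_justification`` pairs. Frequencies
are stored lower-case and read case-insensitively; quoting follows RFC 4180
(pandas' default writer/reader), so commas and quotes in justifications
round-trip. Row order on write is (hpo_id, replicate), making output files
byte-stable across runs.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import (
    CHARACTERISTICS,
    AnnotationSet,
    CharacteristicAnnotation,
    Frequency,
    PhenotypeAnnotation,
)

__all__ = [
    "ANNOTATION_COLUMNS",
    "AnnotationSchemaError",
    "read_annotations",
    "write_annotations",
    "annotations_to_frame",
    "frame_to_annotations",
    "RunConfig",
]

ANNOTATION_COLUMNS: tuple[str, ...] = tuple(
    ["hpo_id", "hpo_name", "replicate"]
    + [
        col
        for c in CHARACTERISTICS
        for col in (f"{c.value}_freq", f"{c.value}_justification")
    ]
)

_FREQ_WORDS = {f.word for f in Frequency}


class AnnotationSchemaError(ValueError):
    """Schema violations, carrying per-row diagnostics in ``problems``."""

    def __init__(self, message: str, problems: list[str] | None = None):
        self.problems = problems or []
        detail = "".join(f"\n  {p}" for p in self.problems[:20])
        super().__init__(message + detail)


def annotations_to_frame(aset: AnnotationSet) -> pd.DataFrame:
    rows = []
    for r in aset.records:
        row: dict = {"hpo_id": r.phenotype, "hpo_name": r.name, "replicate": r.replicate}
        for c in CHARACTERISTICS:
            a = r.annotations[c]
            row[f"{c.value}_freq"] = a.frequency.word
            row[f"{c.value}_justification"] = a.justification
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    return df.sort_values(["hpo_id", "replicate"], kind="stable").reset_index(drop=True)


def frame_to_annotations(df: pd.DataFrame, provenance: dict | None = None) -> AnnotationSet:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationSchemaError(f"missing columns: {', '.join(missing)}")
    problems: list[str] = []
    records: list[PhenotypeAnnotation] = []
    for idx, row in df.iterrows():
        lineno = int(idx) + 2  # header is line 1
        try:
            replicate = int(row["replicate"])
        except (TypeError, ValueError):
            problems.append(f"line {lineno}: bad replicate {row['replicate']!r}")
            continue
        pa = PhenotypeAnnotation(
            phenotype=str(row["hpo_id"]), name=str(row["hpo_name"]), replicate=replicate
        )
        ok = True
        for c in CHARACTERISTICS:
            word = str(row[f"{c.value}_freq"]).strip().lower()
            if word not in _FREQ_WORDS:
                problems.append(
                    f"line {lineno}: bad frequency {row[f'{c.value}_freq']!r}"
                    f" in column {c.value}_freq"
                )
                ok = False
                continue
            just = row[f"{c.value}_justification"]
            pa.annotations[c] = CharacteristicAnnotation(
                c, Frequency.from_word(word), "" if pd.isna(just) else str(just)
            )
        if ok:
            records.append(pa)
    if problems:
        raise AnnotationSchemaError("malformed annotation rows", problems)
    return AnnotationSet(records=records, provenance=provenance or {})


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read and validate an annotation CSV; malformed rows are reported with
    their line numbers."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    return frame_to_annotations(df, provenance={"source": str(path)})


def write_annotations(aset: AnnotationSet, path: str | Path) -> None:
    """Write the canonical CSV: fixed column order, rows sorted by
    (hpo_id, replicate), RFC 4180 quoting."""
    annotations_to_frame(aset).to_csv(path, index=False, lineterminator="\n")


@dataclass
class RunConfig:
    """Flat run configuration for the CLI, loadable from a TOML document."""

    ontology: str | None = None
    root_name: str = "Phenotypic abnormality"
    benchmark_spec: str | None = None
    annotator: str = "mock"  # mock | random
    batch_size: int = 2
    max_retries: int = 2
    seed: int = 0
    out_dir: str = "."
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.annotator not in ("mock", "random"):
            raise ValueError(f"unknown annotator: {self.annotator!r}")
        if not 1 <= self.batch_size <= 2:
            raise ValueError("batch_size must be 1 or 2")
        if self.max_retries < 0:
            raise ValueError("max_retries must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        doc = tomllib.loads(Path(path).read_text())
        known = {k: doc.pop(k) for k in list(doc) if k in cls.__dataclass_fields__}
        return cls(**known, extra=doc)
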