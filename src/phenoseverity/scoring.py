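"""Weighted severity scoring and tier-based severity classification.

Each characteristic's frequency code (never=0 .. always=3) is multiplied by
an integer severity weight (1-6). Summing the weighted values over all ten
characteristics and normalising by the theoretical maximum (sum of
weight x 3 = 99 under the default weights) gives the composite severity
score NSS on a 0-100 scale.

The categorical severity class comes from a separate tier-based decision
tree adapted from the Lazarin et al. carrier-screening severity survey:
characteristics are ranked into tiers 1 (most severe) to 4, and the counts
of tiered characteristics a phenotype often/always causes decide the class
Profound > Severe > Moderate > Mild, the most severe applicable class
winning. Congenital onset carries weight in the score but no tier, so it
never influences the class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .annotation import (
    CHARACTERISTICS,
    AnnotationSet,
    Characteristic,
    CharacteristicAnnotation,
    F_MAX,
    Frequency,
    PhenotypeAnnotation,
)

__all__ = [
    "SeverityWeights",
    "DEFAULT_WEIGHTS",
    "TierMap",
    "DEFAULT_TIERS",
    "SeverityClass",
    "SeverityScore",
    "weighted_value",
    "composite_score",
    "classify_severity",
    "score_all",
    "rank_phenotypes",
    "consensus_annotations",
]

C = Characteristic


@dataclass(frozen=True)
class SeverityWeights:
    """Integer severity weight per characteristic, 6 = most severe."""

    weights: Mapping[C, int] = field(
        default_factory=lambda: {
            C.DEATH: 6,
            C.INTELLECTUAL_DISABILITY: 5,
            C.IMPAIRED_MOBILITY: 4,
            C.BLINDNESS: 4,
            C.PHYSICAL_MALFORMATIONS: 3,
            C.SENSORY_IMPAIRMENTS: 3,
            C.IMMUNODEFICIENCY: 3,
            C.CANCER: 3,
            C.REDUCED_FERTILITY: 1,
            C.CONGENITAL_ONSET: 1,
        }
    )

    def __post_init__(self) -> None:
        missing = [c.value for c in CHARACTERISTICS if c not in self.weights]
        if missing:
            raise ValueError(f"weights missing characteristics: {missing}")
        bad = {c.value: w for c, w in self.weights.items() if not 1 <= int(w)}
        if bad:
            raise ValueError(f"weights must be positive integers: {bad}")

    def __getitem__(self, c: C) -> int:
        return int(self.weights[c])

    @property
    def max_raw_sum(self) -> int:
        """Theoretical maximum raw score: every characteristic at 'always'."""
        return sum(self[c] * F_MAX for c in CHARACTERISTICS)


DEFAULT_WEIGHTS = SeverityWeights()


@dataclass(frozen=True)
class TierMap:
    """Severity tier (1 = most severe) per characteristic; congenital onset
    deliberately has no tier and is excluded from classification."""

    tiers: Mapping[C, int] = field(
        default_factory=lambda: {
            C.DEATH: 1,
            C.INTELLECTUAL_DISABILITY: 1,
            C.IMPAIRED_MOBILITY: 2,
            C.PHYSICAL_MALFORMATIONS: 2,
            C.BLINDNESS: 3,
            C.SENSORY_IMPAIRMENTS: 3,
            C.IMMUNODEFICIENCY: 3,
            C.CANCER: 3,
            C.REDUCED_FERTILITY: 4,
        }
    )

    def __post_init__(self) -> None:
        if C.CONGENITAL_ONSET in self.tiers:
            raise ValueError("congenital_onset must not carry a tier")
        bad = {c.value: t for c, t in self.tiers.items() if t not in (1, 2, 3, 4)}
        if bad:
            raise ValueError(f"tiers must be in 1..4: {bad}")

    def tier_members(self, *tiers: int) -> set[C]:
        return {c for c, t in self.tiers.items() if t in tiers}


DEFAULT_TIERS = TierMap()


class SeverityClass(enum.IntEnum):
    """Categorical severity; larger is more severe (used for tie-breaking)."""

    MILD = 1
    MODERATE = 2
    SEVERE = 3
    PROFOUND = 4

    @property
    def label(self) -> str:
        return self.name.capitalize()


@dataclass(frozen=True)
class SeverityScore:
    weighted: Mapping[C, int]
    raw_sum: int
    raw_mean: float
    normalised: float  # NSS, 0-100


def weighted_value(
    c: Characteristic, f: Frequency, w: SeverityWeights = DEFAULT_WEIGHTS
) -> int:
    """Weight x frequency code, e.g. (intellectual_disability, always) -> 15."""
    return w[c] * int(f)


def composite_score(
    pa: PhenotypeAnnotation, w: SeverityWeights = DEFAULT_WEIGHTS
) -> SeverityScore:
    """Weighted per-characteristic values and the normalised composite NSS."""
    missing = [c.value for c in CHARACTERISTICS if c not in pa.annotations]
    if missing:
        raise ValueError(f"{pa.phenotype}: missing characteristics {missing}")
    weighted = {c: weighted_value(c, pa.annotations[c].frequency, w) for c in CHARACTERISTICS}
    raw_sum = sum(weighted.values())
    return SeverityScore(
        weighted=weighted,
        raw_sum=raw_sum,
        raw_mean=raw_sum / len(CHARACTERISTICS),
        normalised=100.0 * raw_sum / w.max_raw_sum,
    )


def classify_severity(
    pa: PhenotypeAnnotation, tiers: TierMap = DEFAULT_TIERS
) -> SeverityClass:
    """Tier-based decision tree; the most severe applicable class wins.

    With H = characteristics the phenotype often/always causes:
    Profound if |H ∩ Tier1| >= 2; Severe if |H ∩ Tier1| == 1 or
    |H ∩ (Tier2 ∪ Tier3)| >= 3; Moderate if |H ∩ Tier2| >= 1; else Mild.
    """
    high = {
        c
        for c, a in pa.annotations.items()
        if a.frequency in (Frequency.OFTEN, Frequency.ALWAYS)
    }
    n_tier1 = len(high & tiers.tier_members(1))
    if n_tier1 >= 2:
        return SeverityClass.PROFOUND
    if n_tier1 == 1 or len(high & tiers.tier_members(2, 3)) >= 3:
        return SeverityClass.SEVERE
    if high & tiers.tier_members(2):
        return SeverityClass.MODERATE
    return SeverityClass.MILD


def score_all(
    aset: AnnotationSet,
    w: SeverityWeights = DEFAULT_WEIGHTS,
    tiers: TierMap = DEFAULT_TIERS,
) -> pd.DataFrame:
    """Score and classify every record (replicates independently).

    Columns: hpo_id, hpo_name, replicate, per-characteristic ``<char>_freq``
    and ``<char>_weighted``, raw_sum, nss, severity_class.
    """
    rows = []
    for r in aset.records:
        score = composite_score(r, w)
        row: dict = {"hpo_id": r.phenotype, "hpo_name": r.name, "replicate": r.replicate}
        for c in CHARACTERISTICS:
            row[f"{c.value}_freq"] = r.annotations[c].frequency.word
        for c in CHARACTERISTICS:
            row[f"{c.value}_weighted"] = score.weighted[c]
        row["raw_sum"] = score.raw_sum
        row["nss"] = score.normalised
        row["severity_class"] = classify_severity(r, tiers).label
        rows.append(row)
    columns = (
        ["hpo_id", "hpo_name", "replicate"]
        + [f"{c.value}_freq" for c in CHARACTERISTICS]
        + [f"{c.value}_weighted" for c in CHARACTERISTICS]
        + ["raw_sum", "nss", "severity_class"]
    )
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values(["hpo_id", "replicate"], kind="stable").reset_index(drop=True)


def rank_phenotypes(scored: pd.DataFrame, descending: bool = True) -> pd.DataFrame:
    """Stable sort by NSS, ties broken by term id (lexicographic, ascending)."""
    df = scored.sort_values(
        ["nss", "hpo_id"], ascending=[not descending, True], kind="stable"
    )
    return df.reset_index(drop=True)


def consensus_annotations(aset: AnnotationSet) -> AnnotationSet:
    """Collapse replicates to one record per phenotype by modal frequency.

    Ties go to the more severe (higher) frequency. Off by default in every
    pipeline stage; provided for sensitivity analyses.
    """
    out = AnnotationSet(provenance={**aset.provenance, "consensus": True})
    for phen, reps in aset.by_phenotype().items():
        pa = PhenotypeAnnotation(phenotype=phen, name=reps[0].name, replicate=1)
        for c in CHARACTERISTICS:
            freqs = [r.annotations[c].frequency for r in reps]
            counts = {f: freqs.count(f) for f in set(freqs)}
            best = max(counts, key=lambda f: (counts[f], int(f)))
            pa.annotations[c] = CharacteristicAnnotation(
                c, best, reps[0].annotations[c].justification
            )
        out.records.append(pa)
    return out
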