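"""Annotation-quality evaluation: consistency, recall, indirect-causation
auditing, and the association statistics used to characterise them.

Consistency is measured over phenotypes annotated more than once. The
lenient metric collapses the vocabulary into {always, often} vs
{never, rarely} and calls replicates consistent when they all fall in one
group; the stringent metric requires exact agreement. Under a
uniform-random annotator with two replicates the chance levels are 1/2
(lenient) and 1/4 (stringent).

Recall (true positive rate) checks that ontology-derived truth-set members
are annotated often/always for their characteristic. The indirect-causation
audit scans justifications for phrases such as "indirectly" or "does not
directly", and can reassign flagged annotations to "never", which can only
lower severity scores and classes.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import (
    CHARACTERISTICS,
    AnnotationSet,
    Characteristic,
    CharacteristicAnnotation,
    Frequency,
    PhenotypeAnnotation,
)
from .scoring import SeverityClass

__all__ = [
    "ConsistencyReport",
    "RecallReport",
    "IndirectFlag",
    "DEFAULT_INDIRECT_PATTERNS",
    "consistency_rates",
    "chance_consistency",
    "true_positive_rate",
    "flag_indirect",
    "reassign_indirect",
    "metric_correlations",
    "congenital_by_branch",
    "depth_consistency_association",
    "class_score_concordance",
]

_LENIENT_GROUP = {
    Frequency.NEVER: 0,
    Frequency.RARELY: 0,
    Frequency.OFTEN: 1,
    Frequency.ALWAYS: 1,
}


@dataclass(frozen=True)
class ConsistencyReport:
    """Per-characteristic replicate-agreement rates over duplicated phenotypes."""

    n_duplicated: dict[Characteristic, int]
    lenient_rate: dict[Characteristic, float]
    stringent_rate: dict[Characteristic, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "characteristic": [c.value for c in CHARACTERISTICS],
                "n_duplicated": [self.n_duplicated[c] for c in CHARACTERISTICS],
                "lenient_rate": [self.lenient_rate[c] for c in CHARACTERISTICS],
                "stringent_rate": [self.stringent_rate[c] for c in CHARACTERISTICS],
            }
        )


@dataclass(frozen=True)
class RecallReport:
    """Per-characteristic truth-set recall; recall is NaN when no truth-set
    member was annotated (undefined, never coerced to 0)."""

    n_truth: dict[Characteristic, int]
    n_hit: dict[Characteristic, int]
    recall: dict[Characteristic, float]

    def to_frame(self) -> pd.DataFrame:
        chars = sorted(self.n_truth, key=lambda c: CHARACTERISTICS.index(c))
        return pd.DataFrame(
            {
                "characteristic": [c.value for c in chars],
                "n_truth": [self.n_truth[c] for c in chars],
                "n_hit": [self.n_hit[c] for c in chars],
                "recall": [self.recall[c] for c in chars],
            }
        )


@dataclass(frozen=True)
class IndirectFlag:
    phenotype: str
    replicate: int
    characteristic: Characteristic
    matched_pattern: str


def _replicate_groups(aset: AnnotationSet) -> dict[str, list[PhenotypeAnnotation]]:
    return {p: reps for p, reps in aset.by_phenotype().items() if len(reps) >= 2}


def consistency_rates(aset: AnnotationSet) -> ConsistencyReport:
    """Lenient and stringent replicate-consistency rates per characteristic.

    With more than two replicates, consistency requires *all* replicates to
    agree (within the lenient grouping, or exactly). Stringent consistency
    implies lenient consistency, so stringent_rate <= lenient_rate.
    """
    groups = _replicate_groups(aset)
    if not groups:
        raise ValueError("no phenotype has >= 2 replicates")
    n_dup, lenient, stringent = {}, {}, {}
    for c in CHARACTERISTICS:
        n = len(groups)
        n_len = n_str = 0
        for reps in groups.values():
            freqs = [r.annotations[c].frequency for r in reps]
            if len({_LENIENT_GROUP[f] for f in freqs}) == 1:
                n_len += 1
            if len(set(freqs)) == 1:
                n_str += 1
        n_dup[c] = n
        lenient[c] = n_len / n
        stringent[c] = n_str / n
    return ConsistencyReport(n_dup, lenient, stringent)


def chance_consistency(k: int, metric: str) -> float:
    """Probability that k uniform draws over the 4 frequencies are consistent.

    Lenient: both groups have probability 1/2, so 2 * (1/2)**k.
    Stringent: 4 * (1/4)**k. For k=2 these are 1/2 and 1/4.
    """
    if k < 2:
        raise ValueError("need at least 2 replicates")
    if metric == "lenient":
        return 2.0 * 0.5**k
    if metric == "stringent":
        return 4.0 * 0.25**k
    raise ValueError(f"unknown metric: {metric!r}")


def true_positive_rate(
    aset: AnnotationSet,
    truth: Mapping[Characteristic, set[str]],
    use_consensus: bool = False,
) -> RecallReport:
    """Recall of truth-set members: hit iff annotated often/always.

    The denominator counts truth-set members actually present in the set
    (first replicate by default, consensus if requested); absent members are
    excluded rather than counted as misses.
    """
    if not aset.records:
        raise ValueError("empty annotation set")
    if use_consensus:
        from .scoring import consensus_annotations

        records = consensus_annotations(aset).records
    else:
        records = aset.first_replicates()
    by_id = {r.phenotype: r for r in records}
    n_truth, n_hit, recall = {}, {}, {}
    for c, members in truth.items():
        present = [by_id[t] for t in members if t in by_id]
        hits = sum(
            1
            for r in present
            if r.annotations[c].frequency in (Frequency.OFTEN, Frequency.ALWAYS)
        )
        n_truth[c] = len(present)
        n_hit[c] = hits
        recall[c] = hits / len(present) if present else math.nan
    return RecallReport(n_truth, n_hit, recall)


DEFAULT_INDIRECT_PATTERNS = ("indirectly", "does not directly")


def flag_indirect(
    aset: AnnotationSet, patterns: Sequence[str] = DEFAULT_INDIRECT_PATTERNS
) -> list[IndirectFlag]:
    """Case-insensitive substring scan of justifications for indirect-causation
    phrases; one flag per (record, characteristic, pattern) hit."""
    flags = []
    lowered = [(p, p.casefold()) for p in patterns]
    for r in aset.records:
        for c in CHARACTERISTICS:
            just = r.annotations[c].justification.casefold()
            for original, p in lowered:
                if p and p in just:
                    flags.append(IndirectFlag(r.phenotype, r.replicate, c, original))
    return flags


def reassign_indirect(aset: AnnotationSet, flags: Iterable[IndirectFlag]) -> AnnotationSet:
    """Return a copy with every flagged annotation reassigned to "never".

    Frequencies can only move down, so no record's severity score or class
    can increase.
    """
    by_key = {(r.phenotype, r.replicate): r for r in aset.records}
    out = copy.deepcopy(aset)
    out.provenance = {**aset.provenance, "indirect_reassigned": True}
    out_by_key = {(r.phenotype, r.replicate): r for r in out.records}
    for f in flags:
        key = (f.phenotype, f.replicate)
        if key not in by_key:
            raise KeyError(f"flag references unknown record {key}")
        rec = out_by_key[key]
        old = rec.annotations[f.characteristic]
        rec.annotations[f.characteristic] = CharacteristicAnnotation(
            f.characteristic, Frequency.NEVER, old.justification
        )
    return out


def metric_correlations(scored: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the ten frequency codes plus NSS.

    Constant columns give NaN off-diagonal entries (undefined, not 0); the
    diagonal is fixed at 1.
    """
    if len(scored) < 3:
        raise ValueError("need at least 3 records for correlations")
    word_to_code = {f.word: int(f) for f in Frequency}
    data = {
        c.value: scored[f"{c.value}_freq"].map(word_to_code).astype(float)
        for c in CHARACTERISTICS
    }
    data["nss"] = scored["nss"].astype(float)
    frame = pd.DataFrame(data)
    corr = frame.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def congenital_by_branch(aset: AnnotationSet, ont) -> pd.DataFrame:
    """Per-branch proportions of congenital-onset frequencies.

    Each branch row gives the fraction of its member phenotypes (first
    replicate) annotated never/rarely/often/always congenital; rows sum to 1
    and are ordered by descending always-proportion. Phenotypes under
    several branches count once in each.
    """
    records = aset.first_replicates()
    rows = []
    for branch in ont.branch_roots:
        members = [
            r
            for r in records
            if r.phenotype in ont and branch in ont.branch_of(r.phenotype)
        ]
        if not members:
            continue
        counts = {f: 0 for f in Frequency}
        for r in members:
            counts[r.annotations[Characteristic.CONGENITAL_ONSET].frequency] += 1
        n = len(members)
        rows.append(
            {
                "branch_id": branch,
                "branch_name": ont.terms[branch].name,
                "n": n,
                **{f.word: counts[f] / n for f in Frequency},
            }
        )
    df = pd.DataFrame(
        rows, columns=["branch_id", "branch_name", "n", "never", "rarely", "often", "always"]
    )
    return df.sort_values(
        ["always", "branch_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def depth_consistency_association(aset: AnnotationSet, ont) -> dict:
    """Association between ontology depth and replicate consistency.

    Spearman's rho correlates each duplicated phenotype's depth with its
    fraction of stringently consistent characteristics; the chi-square test
    and Cramér's V use the depth-level x (all-consistent vs not) table.
    """
    groups = _replicate_groups(aset)
    if not groups:
        raise ValueError("no phenotype has >= 2 replicates")
    depths, fractions, all_consistent = [], [], []
    for phen, reps in groups.items():
        if phen not in ont:
            continue
        n_cons = sum(
            1
            for c in CHARACTERISTICS
            if len({r.annotations[c].frequency for r in reps}) == 1
        )
        depths.append(ont.depth(phen))
        fractions.append(n_cons / len(CHARACTERISTICS))
        all_consistent.append(n_cons == len(CHARACTERISTICS))
    if len(set(depths)) < 2:
        raise ValueError("degenerate input: a single depth level")

    rho, rho_p = stats.spearmanr(depths, fractions)
    table = pd.crosstab(pd.Series(depths, name="depth"), pd.Series(all_consistent))
    # chi-square needs both outcome columns; a one-column table is degenerate
    if table.shape[1] < 2:
        chi2, chi2_p, cramers_v = math.nan, math.nan, math.nan
    else:
        chi2, chi2_p, _, _ = stats.chi2_contingency(table.values, correction=False)
        n = table.values.sum()
        k = min(table.shape) - 1
        cramers_v = math.sqrt(chi2 / (n * k)) if k else math.nan
    return {
        "n": len(depths),
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "chi_square": float(chi2),
        "chi_square_p": float(chi2_p),
        "cramers_v": float(cramers_v),
    }


def class_score_concordance(scored: pd.DataFrame) -> dict:
    """Partial omega-squared of NSS across severity classes, with F-test p.

    omega^2_p = (SSb - dfb * MSw) / (SSt + MSw), the standard between-groups
    ANOVA effect size; values near 1 mean class membership explains nearly
    all NSS variance.
    """
    groups = [
        g["nss"].to_numpy(dtype=float)
        for _, g in scored.groupby("severity_class", sort=False)
    ]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 populated severity classes")
    values = np.concatenate(groups)
    grand = values.mean()
    n = len(values)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_total = ss_between + ss_within
    df_between = len(groups) - 1
    df_within = n - len(groups)
    if df_within <= 0:
        raise ValueError("not enough records for within-group variance")
    ms_within = ss_within / df_within
    omega = (ss_between - df_between * ms_within) / (ss_total + ms_within)
    if ms_within == 0:
        p_value = 0.0 if ss_between > 0 else 1.0
    else:
        f_stat = (ss_between / df_between) / ms_within
        p_value = float(stats.f.sf(f_stat, df_between, df_within))
    return {"omega_squared_partial": float(omega), "p_value": p_value, "n": n}


def class_order_check(scored: pd.DataFrame) -> bool:
    """True iff mean NSS strictly increases over Mild < Moderate < Severe <
    Profound among the populated classes."""
    means = scored.groupby("severity_class")["nss"].mean()
    ordered = [
        means[cls.label] for cls in sorted(SeverityClass) if cls.label in means.index
    ]
    return all(a < b for a, b in zip(ordered, ordered[1:]))
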