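"""Synthetic fixtures: seeded toy ontologies and simulated annotation sets.

The generator emulates the statistical shape of an LLM-annotated phenotype
ontology: a rooted is_a DAG with named branches (several of which carry the
standard truth-set query names, so benchmark truth sets are non-empty), and
per-characteristic four-level categorical frequency marginals with an
optional shared latent-severity variable inducing cross-characteristic
correlation. A configurable subset of phenotypes is annotated in replicate,
truth-set members are answered often/always with probability 1 - eps
(planted truth), and indirect-causation phrases are injected into
justifications at a configurable rate.

Default marginals are stylised from the published annotation resource:
most characteristics are dominated by "never" (a majority of phenotypes
never cause blindness, cancer, immunodeficiency, reduced fertility,
sensory impairments or intellectual disability; under 1% always cause
death), while congenital onset is the exception with only ~22% "never".
About 4.5% of phenotypes are duplicated (793 of 17,502 in the study) and
~2.6% of justifications describe indirect causation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .annotation import (
    CHARACTERISTICS,
    AnnotationSet,
    Characteristic,
    CharacteristicAnnotation,
    Frequency,
    PhenotypeAnnotation,
)
from .ontology import (
    BenchmarkSpec,
    PhenotypeOntology,
    PhenotypeTerm,
    build_truth_sets,
    default_benchmark,
)

__all__ = ["FixtureSpec", "make_toy_ontology", "simulate_annotations", "write_obo", "write_obographs"]

C = Characteristic

# (never, rarely, often, always) per characteristic
DEFAULT_MARGINALS: dict[Characteristic, tuple[float, float, float, float]] = {
    C.INTELLECTUAL_DISABILITY: (0.55, 0.25, 0.16, 0.04),
    C.DEATH: (0.45, 0.35, 0.19, 0.01),
    C.IMPAIRED_MOBILITY: (0.35, 0.35, 0.27, 0.03),
    C.PHYSICAL_MALFORMATIONS: (0.45, 0.30, 0.20, 0.05),
    C.BLINDNESS: (0.60, 0.25, 0.12, 0.03),
    C.SENSORY_IMPAIRMENTS: (0.60, 0.25, 0.12, 0.03),
    C.IMMUNODEFICIENCY: (0.60, 0.25, 0.12, 0.03),
    C.CANCER: (0.60, 0.25, 0.12, 0.03),
    C.REDUCED_FERTILITY: (0.60, 0.25, 0.12, 0.03),
    C.CONGENITAL_ONSET: (0.22, 0.25, 0.25, 0.28),
}

UNIFORM_MARGINALS: dict[Characteristic, tuple[float, float, float, float]] = {
    c: (0.25, 0.25, 0.25, 0.25) for c in CHARACTERISTICS
}

# Branch-root names; the first eight match the default benchmark queries so
# every characteristic with a truth set gets a non-empty one.
_BRANCH_NAMES = (
    "Intellectual disability",
    "Gait disturbance",
    "Malformation of the body",
    "Blindness",
    "Abnormality of vision",
    "Immunodeficiency",
    "Cancer",
    "Decreased fertility",
    "Abnormal cellular phenotype",
    "Neoplasm",
    "Constitutional symptom",
    "Abnormality of prenatal development or birth",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic ontology + annotation generator."""

    n_branches: int = 8
    terms_per_branch: int = 40
    max_depth: int = 5
    seed: int = 0
    marginals: Mapping[Characteristic, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    duplicated_fraction: float = 0.045
    replicates: int = 2
    indirect_rate: float = 0.026
    plant_truth: bool = False
    noise_eps: float = 0.0  # truth members miss (never/rarely) with this prob
    latent_r: float = 0.0  # shared latent-severity correlation, 0 = independent
    id_prefix: str = "HP"

    def __post_init__(self) -> None:
        for c, probs in self.marginals.items():
            if len(probs) != 4 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"marginal for {c.value} is not a distribution: {probs}")
        if not 0.0 <= self.noise_eps <= 1.0:
            raise ValueError("noise_eps must be in [0, 1]")
        if not 0.0 <= self.indirect_rate <= 1.0:
            raise ValueError("indirect_rate must be in [0, 1]")
        if not 0.0 <= self.latent_r < 1.0:
            raise ValueError("latent_r must be in [0, 1)")
        if self.max_depth < 1 and self.terms_per_branch > 0:
            raise ValueError("max_depth must be >= 1 to attach terms to branches")
        if not 1 <= self.n_branches <= len(_BRANCH_NAMES):
            raise ValueError(f"n_branches must be in 1..{len(_BRANCH_NAMES)}")


def _tid(prefix: str, n: int) -> str:
    return f"{prefix}:{n:07d}"


def make_toy_ontology(spec: FixtureSpec) -> PhenotypeOntology:
    """Build a seeded random DAG: root -> branch roots -> term subtrees.

    Each branch root takes one of the canonical branch names; its
    ``terms_per_branch`` descendants are named "<branch> phenotype k" and
    attach to a random existing node in the branch (depth capped at
    ``max_depth``), with a 15% chance of a second within-branch parent to
    create diamond structure.
    """
    rng = np.random.default_rng(spec.seed)
    prefix = spec.id_prefix
    counter = 1
    root_id = _tid(prefix, counter)
    terms: dict[str, PhenotypeTerm] = {
        root_id: PhenotypeTerm(id=root_id, name="Phenotypic abnormality")
    }
    depth_of = {root_id: 0}
    for b in range(spec.n_branches):
        counter += 1
        branch_id = _tid(prefix, counter)
        branch_name = _BRANCH_NAMES[b]
        terms[branch_id] = PhenotypeTerm(
            id=branch_id, name=branch_name, parents=frozenset({root_id})
        )
        depth_of[branch_id] = 1
        branch_nodes = [branch_id]
        for k in range(1, spec.terms_per_branch + 1):
            counter += 1
            tid = _tid(prefix, counter)
            candidates = [n for n in branch_nodes if depth_of[n] < spec.max_depth]
            parent = candidates[rng.integers(len(candidates))]
            parents = {parent}
            if len(branch_nodes) > 1 and rng.random() < 0.15:
                second = branch_nodes[rng.integers(len(branch_nodes))]
                if second != tid:
                    parents.add(second)
            terms[tid] = PhenotypeTerm(
                id=tid, name=f"{branch_name} phenotype {k}", parents=frozenset(parents)
            )
            depth_of[tid] = min(depth_of[p] for p in parents) + 1
            branch_nodes.append(tid)
    return PhenotypeOntology(terms, root_id)


def _category_draws(
    rng: np.random.Generator,
    n: int,
    marginal: tuple[float, float, float, float],
    latent_z: np.ndarray | None,
    latent_r: float,
) -> np.ndarray:
    """Draw n frequency codes from a marginal, optionally via a Gaussian
    copula with shared latent severity (preserves the marginal exactly)."""
    if latent_z is None or latent_r == 0.0:
        return rng.choice(4, size=n, p=np.asarray(marginal))
    from scipy.stats import norm

    eps = rng.standard_normal(n)
    x = np.sqrt(latent_r) * latent_z + np.sqrt(1.0 - latent_r) * eps
    u = norm.cdf(x)
    thresholds = np.cumsum(np.asarray(marginal))[:-1]
    return np.searchsorted(thresholds, u, side="right")


def simulate_annotations(
    ont: PhenotypeOntology,
    spec: FixtureSpec,
    truth_sets: Mapping[Characteristic, set[str]] | None = None,
    benchmark: BenchmarkSpec | None = None,
) -> AnnotationSet:
    """Simulate an annotation set over every non-root term of ``ont``.

    Frequencies are drawn per characteristic from ``spec.marginals`` (with
    optional latent-severity correlation). When ``spec.plant_truth`` is on,
    truth-set members (from ``truth_sets`` or the default benchmark) are
    instead answered often/always with probability 1 - ``spec.noise_eps``
    and never/rarely otherwise. A random ``spec.duplicated_fraction`` of
    phenotypes receives ``spec.replicates`` independent replicates, and
    justifications carry an indirect-causation phrase with probability
    ``spec.indirect_rate``. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed + 1)
    term_ids = sorted(ont.descendants(ont.root))
    n = len(term_ids)
    if n == 0:
        return AnnotationSet(provenance={"annotator": "simulated", "seed": spec.seed})

    if spec.plant_truth and truth_sets is None:
        truth_sets = build_truth_sets(ont, benchmark or default_benchmark())
    truth_sets = truth_sets or {}

    n_dup = int(round(spec.duplicated_fraction * n))
    dup_idx = set(rng.choice(n, size=n_dup, replace=False).tolist()) if n_dup else set()
    rep_counts = [spec.replicates if i in dup_idx else 1 for i in range(n)]

    truth_mask = {
        c: np.fromiter((t in truth_sets.get(c, ()) for t in term_ids), bool, n)
        for c in CHARACTERISTICS
        if c in truth_sets
    }

    indirect_phrases = ("does not directly", "indirectly")
    aset = AnnotationSet(
        provenance={"annotator": "simulated", "seed": spec.seed, "spec": repr(spec)}
    )
    max_reps = max(rep_counts)
    for rep in range(1, max_reps + 1):
        active = np.array([rc >= rep for rc in rep_counts])
        latent_z = rng.standard_normal(n) if spec.latent_r > 0 else None
        codes: dict[Characteristic, np.ndarray] = {}
        for c in CHARACTERISTICS:
            draws = _category_draws(rng, n, tuple(spec.marginals[c]), latent_z, spec.latent_r)
            if spec.plant_truth and c in truth_mask:
                mask = truth_mask[c]
                m = int(mask.sum())
                if m:
                    hit = rng.random(m) >= spec.noise_eps
                    high = rng.choice([2, 3], size=m)
                    low = rng.choice([0, 1], size=m)
                    draws[mask] = np.where(hit, high, low)
            codes[c] = draws
        inject = {
            c: rng.random(n) < spec.indirect_rate for c in CHARACTERISTICS
        }
        pick_phrase = {c: rng.integers(2, size=n) for c in CHARACTERISTICS}
        for i, tid in enumerate(term_ids):
            if not active[i]:
                continue
            name = ont.terms[tid].name
            pa = PhenotypeAnnotation(phenotype=tid, name=name, replicate=rep)
            for c in CHARACTERISTICS:
                freq = Frequency(int(codes[c][i]))
                just = f"{name} {freq.word} causes {c.label}."
                if inject[c][i]:
                    phrase = indirect_phrases[int(pick_phrase[c][i])]
                    just = f"{name} {phrase} cause {c.label}; the effect is mediated."
                pa.annotations[c] = CharacteristicAnnotation(c, freq, just)
            aset.records.append(pa)
    return aset


# -- fixture serialisation ----------------------------------------------


def write_obo(ont: PhenotypeOntology, path: str | Path) -> None:
    """Write the ontology as a minimal OBO 1.2 document (is_a edges only)."""
    lines = ["format-version: 1.2", "ontology: toy", ""]
    for term in ont.iter_terms(include_obsolete=True):
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        lines.append(f"name: {term.name}")
        for p in sorted(term.parents):
            lines.append(f"is_a: {p} ! {ont.terms[p].name if p in ont.terms else p}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_obographs(ont: PhenotypeOntology, path: str | Path) -> None:
    """Write the ontology as an obographs-JSON document (is_a edges only)."""
    import json

    nodes = []
    edges = []
    for term in ont.iter_terms(include_obsolete=True):
        node: dict = {"id": term.id, "lbl": term.name}
        if term.obsolete:
            node["meta"] = {"deprecated": True}
        nodes.append(node)
        for p in sorted(term.parents):
            edges.append({"sub": term.id, "pred": "is_a", "obj": p})
    doc = {"graphs": [{"nodes": nodes, "edges": edges}]}
    Path(path).write_text(json.dumps(doc, indent=1))


def uniform_spec(n_phenotypes: int, seed: int = 0, replicates: int = 2) -> FixtureSpec:
    """A spec for replicate-consistency null experiments: uniform marginals,
    every phenotype duplicated. ``n_phenotypes`` is rounded up to fill the
    branch structure."""
    per_branch = max(1, -(-n_phenotypes // 8))
    return FixtureSpec(
        n_branches=8,
        terms_per_branch=per_branch,
        seed=seed,
        marginals=dict(UNIFORM_MARGINALS),
        duplicated_fraction=1.0,
        replicates=replicates,
        indirect_rate=0.0,
    )
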