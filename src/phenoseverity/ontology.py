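"""Phenotype-ontology loading and DAG queries.

Wraps an is_a DAG of phenotype terms (the Human Phenotype Ontology, or a
toy ontology with the same shape) and exposes the traversal primitives the
severity pipeline needs: descendant closure, branch membership, depth, and
name queries used to assemble per-characteristic truth sets.

The ontology is rooted at a configurable term (for the HPO this is
"Phenotypic abnormality"); *branches* are the direct children of that root,
and every other term belongs to one or more branches through its ancestors.
Terms outside the root's subtree are dropped on load; obsolete terms are
retained and flagged but excluded from traversal and truth sets, since they
cannot be annotated.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .annotation import Characteristic

__all__ = [
    "OntologyError",
    "PhenotypeTerm",
    "PhenotypeOntology",
    "BenchmarkQuery",
    "BenchmarkSpec",
    "default_benchmark",
    "load_ontology",
    "build_truth_sets",
]

TERM_ID_RE = re.compile(r"^[A-Za-z]+:\d+$")


class OntologyError(ValueError):
    """Raised for unparseable files, cycles, or unresolvable terms."""


def normalize_term_id(value: str) -> str:
    """Upper-case the prefix of a CURIE-style term id (``hp:0000118`` -> ``HP:0000118``)."""
    value = value.strip()
    if ":" not in value:
        raise OntologyError(f"not a term id: {value!r}")
    prefix, local = value.split(":", 1)
    return f"{prefix.upper()}:{local}"


@dataclass(frozen=True)
class PhenotypeTerm:
    """One ontology term: id, name, optional definition, parents, obsolete flag."""

    id: str
    name: str
    parents: frozenset[str] = frozenset()
    definition: str | None = None
    obsolete: bool = False


class PhenotypeOntology:
    """An acyclic is_a ontology restricted to the subtree under ``root``.

    Parameters
    ----------
    terms
        Mapping of term id to :class:`PhenotypeTerm`. Parent references must
        stay within the mapping.
    root
        Id of the root term; its direct (non-obsolete) children are the
        branch roots.
    """

    def __init__(self, terms: Mapping[str, PhenotypeTerm], root: str):
        if root not in terms:
            raise OntologyError(f"root {root!r} not among terms")
        # parent -> child DiGraph over non-obsolete terms only
        dag = nx.DiGraph()
        for t in terms.values():
            if t.obsolete:
                continue
            dag.add_node(t.id)
            for p in t.parents:
                if p not in terms:
                    raise OntologyError(f"{t.id} references unknown parent {p}")
                if not terms[p].obsolete:
                    dag.add_edge(p, t.id)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise OntologyError(f"cycle detected: {cycle}")

        keep = {root} | nx.descendants(dag, root)
        self.terms: dict[str, PhenotypeTerm] = {
            tid: t for tid, t in terms.items() if tid in keep or t.obsolete
        }
        self.root = root
        self._dag = dag.subgraph(keep).copy()
        self.branch_roots: tuple[str, ...] = tuple(sorted(self._dag.successors(root)))
        self._depths = nx.single_source_shortest_path_length(self._dag, root)

    # -- queries ---------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def _check(self, term_id: str) -> str:
        if term_id not in self._dag:
            raise OntologyError(f"unknown or obsolete term: {term_id}")
        return term_id

    def descendants(self, term_id: str, include_self: bool = False) -> set[str]:
        """Transitive closure under the child relation, obsolete terms excluded."""
        tid = self._check(term_id)
        out = nx.descendants(self._dag, tid)
        if include_self:
            out = out | {tid}
        return out

    def ancestors(self, term_id: str, include_self: bool = False) -> set[str]:
        tid = self._check(term_id)
        out = nx.ancestors(self._dag, tid)
        if include_self:
            out = out | {tid}
        return out

    def branch_of(self, term_id: str) -> set[str]:
        """Branch roots that are ancestors-or-self of ``term_id`` (can be several)."""
        return self.ancestors(term_id, include_self=True) & set(self.branch_roots)

    def depth(self, term_id: str) -> int:
        """Length of the shortest parent-path to the root; the root has depth 0."""
        return self._depths[self._check(term_id)]

    def find_terms(self, query: str, mode: str = "exact-name") -> set[str]:
        """Case-insensitive name search; ``mode`` is ``exact-name`` or ``substring``."""
        if not query:
            raise OntologyError("empty query")
        if mode not in ("exact-name", "substring"):
            raise OntologyError(f"unknown match mode: {mode!r}")
        q = query.casefold()
        hits = set()
        for tid in self._dag.nodes:
            name = self.terms[tid].name.casefold()
            if (mode == "exact-name" and name == q) or (mode == "substring" and q in name):
                hits.add(tid)
        return hits

    def iter_terms(self, include_obsolete: bool = False) -> Iterable[PhenotypeTerm]:
        for tid, t in sorted(self.terms.items()):
            if t.obsolete and not include_obsolete:
                continue
            yield t


# -- loading ------------------------------------------------------------


def _terms_from_obo(path: Path) -> dict[str, PhenotypeTerm]:
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=False)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise OntologyError(f"cannot parse OBO file {path}: {exc}") from exc
    terms: dict[str, PhenotypeTerm] = {}
    for node, data in graph.nodes(data=True):
        tid = normalize_term_id(node)
        terms[tid] = PhenotypeTerm(
            id=tid,
            name=data.get("name", tid),
            parents=frozenset(normalize_term_id(p) for p in data.get("is_a", [])),
            definition=data.get("def"),
            obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
        )
    return terms


def _terms_from_obographs(path: Path) -> dict[str, PhenotypeTerm]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise OntologyError(f"cannot parse obographs JSON {path}: {exc}") from exc
    graphs = doc.get("graphs")
    if not graphs:
        raise OntologyError(f"{path}: no 'graphs' entry")
    nodes = {}
    parents: dict[str, set[str]] = {}
    for g in graphs:
        for node in g.get("nodes", []):
            nid = _curie(node["id"])
            meta = node.get("meta", {}) or {}
            nodes[nid] = PhenotypeTerm(
                id=nid,
                name=node.get("lbl", nid),
                definition=(meta.get("definition") or {}).get("val"),
                obsolete=bool(meta.get("deprecated", False)),
            )
        for edge in g.get("edges", []):
            if edge.get("pred") not in ("is_a", "rdfs:subClassOf"):
                continue
            child, parent = _curie(edge["sub"]), _curie(edge["obj"])
            parents.setdefault(child, set()).add(parent)
    return {
        nid: PhenotypeTerm(
            id=t.id,
            name=t.name,
            parents=frozenset(parents.get(nid, ())),
            definition=t.definition,
            obsolete=t.obsolete,
        )
        for nid, t in nodes.items()
    }


def _curie(iri: str) -> str:
    """Map an OBO PURL (``.../HP_0000118``) or CURIE to ``HP:0000118``."""
    tail = iri.rsplit("/", 1)[-1]
    if "_" in tail and ":" not in tail:
        tail = tail.replace("_", ":", 1)
    return normalize_term_id(tail)


def load_ontology(path: str | Path, root_name: str) -> PhenotypeOntology:
    """Load an OBO or obographs-JSON file rooted at the term named ``root_name``.

    The format is sniffed from the file content (JSON object vs OBO stanzas).
    ``root_name`` must resolve to exactly one non-obsolete term; for the HPO
    the conventional root is ``"Phenotypic abnormality"``, whose direct
    children become the branch roots.
    """
    path = Path(path)
    head = path.read_text(errors="replace").lstrip()[:1]
    terms = _terms_from_obographs(path) if head == "{" else _terms_from_obo(path)
    if not terms:
        raise OntologyError(f"{path}: no terms parsed")

    target = root_name.casefold()
    roots = [t.id for t in terms.values() if not t.obsolete and t.name.casefold() == target]
    if not roots:
        raise OntologyError(f"root {root_name!r} not found")
    if len(roots) > 1:
        raise OntologyError(f"root {root_name!r} is ambiguous: {sorted(roots)}")
    return PhenotypeOntology(terms, roots[0])


# -- benchmark truth sets ------------------------------------------------


@dataclass(frozen=True)
class BenchmarkQuery:
    query: str
    mode: str = "exact-name"  # or "substring"


@dataclass
class BenchmarkSpec:
    """Per-characteristic ontology queries defining recall truth sets.

    Each characteristic maps to name queries whose matched terms, together
    with all their descendants, form the true-positive set; ``exclusions``
    are case-insensitive name substrings removed afterwards (used to drop
    colour/night blindness from the blindness set).
    """

    queries: dict[Characteristic, list[BenchmarkQuery]] = field(default_factory=dict)
    exclusions: dict[Characteristic, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "queries": {
                    c.value: [[q.query, q.mode] for q in qs] for c, qs in self.queries.items()
                },
                "exclusions": {c.value: list(xs) for c, xs in self.exclusions.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "BenchmarkSpec":
        doc = json.loads(text)
        return cls(
            queries={
                Characteristic(c): [BenchmarkQuery(q, m) for q, m in qs]
                for c, qs in doc.get("queries", {}).items()
            },
            exclusions={
                Characteristic(c): list(xs) for c, xs in doc.get("exclusions", {}).items()
            },
        )


def default_benchmark() -> BenchmarkSpec:
    """The standard truth-set queries for nine of the ten characteristics.

    Congenital onset has no ontology-derived truth set. Full term names are
    matched exactly; lower-case fragments are substring queries.
    """
    E, S = "exact-name", "substring"
    C = Characteristic
    q = {
        C.INTELLECTUAL_DISABILITY: [
            BenchmarkQuery("Intellectual disability", E),
            BenchmarkQuery("Mental deterioration", E),
        ],
        C.IMPAIRED_MOBILITY: [
            BenchmarkQuery("Gait disturbance", E),
            BenchmarkQuery("Diminished movement", E),
            BenchmarkQuery("mobility", S),
        ],
        C.PHYSICAL_MALFORMATIONS: [BenchmarkQuery("malformation", S)],
        C.BLINDNESS: [BenchmarkQuery("blindness", S)],
        C.SENSORY_IMPAIRMENTS: [
            BenchmarkQuery("Abnormality of vision", E),
            BenchmarkQuery("Abnormality of the sense of smell", E),
            BenchmarkQuery("Abnormality of taste sensation", E),
            BenchmarkQuery("Somatic sensory dysfunction", E),
            BenchmarkQuery("Hearing abnormality", E),
        ],
        C.IMMUNODEFICIENCY: [
            BenchmarkQuery("Immunodeficiency", E),
            BenchmarkQuery("Impaired antigen-specific response", E),
        ],
        C.CANCER: [
            BenchmarkQuery("Cancer", E),
            BenchmarkQuery("malignant", S),
            BenchmarkQuery("carcinoma", S),
        ],
        C.REDUCED_FERTILITY: [
            BenchmarkQuery("Decreased fertility", E),
            BenchmarkQuery("Hypogonadism", E),
        ],
    }
    return BenchmarkSpec(
        queries=q,
        exclusions={C.BLINDNESS: ["color", "colour", "night blindness"]},
    )


def build_truth_sets(
    ont: PhenotypeOntology, spec: BenchmarkSpec | None = None
) -> dict[Characteristic, set[str]]:
    """Union of descendants-or-self of every query match, minus exclusions."""
    spec = spec if spec is not None else default_benchmark()
    out: dict[Characteristic, set[str]] = {}
    for char, queries in spec.queries.items():
        members: set[str] = set()
        for bq in queries:
            for tid in ont.find_terms(bq.query, bq.mode):
                members |= ont.descendants(tid, include_self=True)
        for pattern in spec.exclusions.get(char, []):
            p = pattern.casefold()
            members = {t for t in members if p not in ont.terms[t].name.casefold()}
        out[char] = members
    return out
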