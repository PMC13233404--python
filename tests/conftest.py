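import pytest

from phenoseverity.annotation import (
    CHARACTERISTICS,
    AnnotationSet,
    Characteristic,
    CharacteristicAnnotation,
    Frequency,
    PhenotypeAnnotation,
)
from phenoseverity.ontology import PhenotypeOntology, PhenotypeTerm


def build_ontology(edges: dict[str, list[str]], names: dict[str, str] | None = None,
                   root: str = "HP:0000001", obsolete: set[str] = frozenset()) -> PhenotypeOntology:
    """Assemble an ontology from a child -> parents mapping."""
    names = names or {}
    ids = set(edges) | {p for ps in edges.values() for p in ps}
    terms = {
        tid: PhenotypeTerm(
            id=tid,
            name=names.get(tid, tid),
            parents=frozenset(edges.get(tid, [])),
            obsolete=tid in obsolete,
        )
        for tid in ids
    }
    return PhenotypeOntology(terms, root)


def make_record(phenotype: str = "HP:0000042", name: str = "Toy phenotype",
                replicate: int = 1, default: Frequency = Frequency.NEVER,
                justifications: dict[Characteristic, str] | None = None,
                **freqs: str) -> PhenotypeAnnotation:
    """A full 10-characteristic record; keyword args override by enum value,
    e.g. make_record(death='always')."""
    overrides = {Characteristic(k): Frequency.from_word(v) for k, v in freqs.items()}
    justifications = justifications or {}
    pa = PhenotypeAnnotation(phenotype=phenotype, name=name, replicate=replicate)
    for c in CHARACTERISTICS:
        f = overrides.get(c, default)
        pa.annotations[c] = CharacteristicAnnotation(
            c, f, justifications.get(c, f"{name} {f.word} causes {c.label}.")
        )
    return pa


def make_set(*records: PhenotypeAnnotation) -> AnnotationSet:
    return AnnotationSet(records=list(records), provenance={"annotator": "test"})


@pytest.fixture
def diamond_ontology() -> PhenotypeOntology:
    """root <- A <- {B, C} <- D plus a leaf E under B (diamond with a tail)."""
    return build_ontology(
        {
            "HP:0000002": ["HP:0000001"],          # A (branch root)
            "HP:0000003": ["HP:0000002"],          # B
            "HP:0000004": ["HP:0000002"],          # C
            "HP:0000005": ["HP:0000003", "HP:0000004"],  # D
            "HP:0000006": ["HP:0000003"],          # E
        },
        names={
            "HP:0000001": "Phenotypic abnormality",
            "HP:0000002": "Branch A",
            "HP:0000003": "Term B",
            "HP:0000004": "Term C",
            "HP:0000005": "Term D",
            "HP:0000006": "Term E",
        },
    )
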