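"""Clinical-characteristic annotation: vocabulary, prompts, parsing, drivers.

A phenotype is annotated with how frequently it *directly causes* each of
ten severity-related clinical characteristics, on the four-level vocabulary
never / rarely / often / always, each answer carrying a free-text
justification. Annotators are pluggable callables mapping a prompt string
to a response string; a deterministic mock and a stateful uniform-random
annotator are bundled so the whole pipeline runs offline.
"""

from __future__ import annotations

import enum
import hashlib
import json
import random
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "Characteristic",
    "Frequency",
    "F_MAX",
    "CharacteristicAnnotation",
    "PhenotypeAnnotation",
    "AnnotationSet",
    "AnnotationFailure",
    "PromptError",
    "ResponseParseError",
    "DEFAULT_PROMPT_TEMPLATE",
    "build_prompt",
    "render_response",
    "parse_response",
    "validate_annotation",
    "annotate",
    "mock_annotator",
    "random_annotator",
]


class Characteristic(enum.Enum):
    """The ten severity-related clinical characteristics, in canonical order."""

    INTELLECTUAL_DISABILITY = "intellectual_disability"
    DEATH = "death"
    IMPAIRED_MOBILITY = "impaired_mobility"
    PHYSICAL_MALFORMATIONS = "physical_malformations"
    BLINDNESS = "blindness"
    SENSORY_IMPAIRMENTS = "sensory_impairments"
    IMMUNODEFICIENCY = "immunodeficiency"
    CANCER = "cancer"
    REDUCED_FERTILITY = "reduced_fertility"
    CONGENITAL_ONSET = "congenital_onset"

    @property
    def label(self) -> str:
        return self.value.replace("_", " ")


CHARACTERISTICS: tuple[Characteristic, ...] = tuple(Characteristic)


class Frequency(enum.IntEnum):
    """Response vocabulary with its numeric encoding (never=0 .. always=3)."""

    NEVER = 0
    RARELY = 1
    OFTEN = 2
    ALWAYS = 3

    @property
    def word(self) -> str:
        return self.name.lower()

    @classmethod
    def from_word(cls, word: str) -> "Frequency":
        try:
            return cls[word.strip().upper()]
        except KeyError:
            raise ValueError(f"unrecognised frequency word: {word!r}") from None


F_MAX = int(Frequency.ALWAYS)  # 3


@dataclass(frozen=True)
class CharacteristicAnnotation:
    characteristic: Characteristic
    frequency: Frequency
    justification: str = ""


@dataclass
class PhenotypeAnnotation:
    """All ten characteristic annotations for one phenotype, one replicate."""

    phenotype: str
    name: str
    replicate: int = 1
    annotations: dict[Characteristic, CharacteristicAnnotation] = field(default_factory=dict)

    def frequency(self, c: Characteristic) -> Frequency:
        return self.annotations[c].frequency


@dataclass
class AnnotationFailure:
    phenotype: str
    name: str
    replicate: int
    error: str
    attempts: int


@dataclass
class AnnotationSet:
    """A collection of annotation records with provenance.

    (phenotype, replicate) pairs are unique; permanent annotator failures
    are kept alongside, never silently dropped.
    """

    records: list[PhenotypeAnnotation] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    failures: list[AnnotationFailure] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.phenotype, r.replicate) for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (phenotype, replicate) pairs: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def by_phenotype(self) -> dict[str, list[PhenotypeAnnotation]]:
        out: dict[str, list[PhenotypeAnnotation]] = {}
        for r in self.records:
            out.setdefault(r.phenotype, []).append(r)
        for lst in out.values():
            lst.sort(key=lambda r: r.replicate)
        return out

    def first_replicates(self) -> list[PhenotypeAnnotation]:
        return [reps[0] for reps in self.by_phenotype().values()]


# -- prompt construction -------------------------------------------------

PHENOTYPE_LIST_PLACEHOLDER = "{phenotype_list}"

DEFAULT_PROMPT_TEMPLATE = """\
You are annotating human phenotypes with the clinical characteristics they
directly cause. For each phenotype below, state how frequently it directly
causes each of the following clinical characteristics:
intellectual disability, death, impaired mobility, physical malformations,
blindness, sensory impairments, immunodeficiency, cancer, reduced fertility,
congenital onset.

Answer with exactly one of: never, rarely, often, always.
Provide a brief justification for every answer.
Do not consider indirect effects: only count characteristics the phenotype
itself directly causes.

Respond with one line per phenotype and characteristic in the format:
<id> | <phenotype name> | <characteristic>: <frequency> - <justification>

Phenotypes to annotate:
{phenotype_list}
"""


class PromptError(ValueError):
    pass


def build_prompt(
    phenotypes: Sequence[tuple[str, str]],
    template: str = DEFAULT_PROMPT_TEMPLATE,
) -> str:
    """Fill the template's phenotype-list slot with at most two (id, name) pairs.

    Keeping prompts to two phenotypes avoids long-input degradation and
    token-limit failures in LLM annotators; the limit is enforced, not
    advisory.
    """
    if not 1 <= len(phenotypes) <= 2:
        raise PromptError(f"a prompt takes 1 or 2 phenotypes, got {len(phenotypes)}")
    if PHENOTYPE_LIST_PLACEHOLDER not in template:
        raise PromptError(f"template lacks the {PHENOTYPE_LIST_PLACEHOLDER} placeholder")
    listing = "\n".join(f"- {tid} ({name})" for tid, name in phenotypes)
    return template.replace(PHENOTYPE_LIST_PLACEHOLDER, listing)


_PROMPT_ITEM_RE = re.compile(r"^- (\S+) \((.*)\)$", re.MULTILINE)


def phenotypes_in_prompt(prompt: str) -> list[tuple[str, str]]:
    """Recover the (id, name) pairs listed in a prompt built by :func:`build_prompt`."""
    return _PROMPT_ITEM_RE.findall(prompt)


# -- response grammar ----------------------------------------------------

_LINE_RE = re.compile(
    r"^(?P<id>\S+)\s*\|\s*(?P<name>[^|]*?)\s*\|\s*(?P<char>[a-z_ ]+?)\s*:\s*"
    r"(?P<freq>\S+)\s*(?:-\s*(?P<just>.*))?$"
)


class ResponseParseError(ValueError):
    """Raised when an annotator response violates the grammar or vocabulary."""


def render_response(records: Iterable[PhenotypeAnnotation], fmt: str = "lines") -> str:
    """Serialise records in the response grammar (inverse of :func:`parse_response`)."""
    if fmt == "json":
        doc = [
            {
                "id": r.phenotype,
                "name": r.name,
                "annotations": {
                    c.value: {
                        "frequency": a.frequency.word,
                        "justification": a.justification,
                    }
                    for c, a in r.annotations.items()
                },
            }
            for r in records
        ]
        return json.dumps(doc, indent=1)
    lines = []
    for r in records:
        for c in CHARACTERISTICS:
            a = r.annotations[c]
            just = a.justification.replace("\n", " ")
            lines.append(f"{r.phenotype} | {r.name} | {c.value}: {a.frequency.word} - {just}")
    return "\n".join(lines) + "\n"


def _parse_json_response(text: str, expected: Sequence[str]) -> list[PhenotypeAnnotation]:
    doc = json.loads(text)
    by_id: dict[str, PhenotypeAnnotation] = {}
    for block in doc:
        pa = PhenotypeAnnotation(phenotype=block["id"], name=block.get("name", block["id"]))
        for cname, entry in block.get("annotations", {}).items():
            c = Characteristic(cname)
            pa.annotations[c] = CharacteristicAnnotation(
                c, Frequency.from_word(entry["frequency"]), entry.get("justification", "")
            )
        by_id[pa.phenotype] = pa
    return _finish_parse(by_id, expected)


def parse_response(text: str, expected: Sequence[str]) -> list[PhenotypeAnnotation]:
    """Parse an annotator response into one record per expected phenotype id.

    Accepts the line grammar ``<id> | <name> | <characteristic>: <frequency>
    - <justification>`` or the strict-JSON alternative (detected by a
    leading ``[``). Every expected phenotype must be covered with all ten
    characteristics; unknown frequency words and characteristics are
    rejected with their position.
    """
    if not text.strip():
        raise ResponseParseError("empty response")
    if text.lstrip().startswith("["):
        try:
            return _parse_json_response(text, expected)
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise ResponseParseError(f"bad JSON response: {exc}") from exc

    by_id: dict[str, PhenotypeAnnotation] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = _LINE_RE.match(line)
        if not m:
            raise ResponseParseError(f"line {lineno}: does not match grammar: {line!r}")
        tid = m["id"]
        try:
            char = Characteristic(m["char"].strip().replace(" ", "_"))
        except ValueError:
            raise ResponseParseError(
                f"line {lineno}: unknown characteristic {m['char']!r}"
            ) from None
        try:
            freq = Frequency.from_word(m["freq"])
        except ValueError:
            raise ResponseParseError(
                f"line {lineno}: unrecognised frequency token {m['freq']!r}"
            ) from None
        pa = by_id.setdefault(tid, PhenotypeAnnotation(phenotype=tid, name=m["name"]))
        if char in pa.annotations:
            raise ResponseParseError(f"line {lineno}: duplicate characteristic {char.value}")
        pa.annotations[char] = CharacteristicAnnotation(char, freq, m["just"] or "")
    return _finish_parse(by_id, expected)


def _finish_parse(
    by_id: dict[str, PhenotypeAnnotation], expected: Sequence[str]
) -> list[PhenotypeAnnotation]:
    out = []
    for tid in expected:
        if tid not in by_id:
            raise ResponseParseError(f"missing phenotype block for {tid}")
        pa = by_id[tid]
        problems = validate_annotation(pa)
        if problems:
            raise ResponseParseError(f"{tid}: " + "; ".join(problems))
        out.append(pa)
    return out


def validate_annotation(pa: PhenotypeAnnotation) -> list[str]:
    """Return structural violations (empty list means the record is valid)."""
    problems = []
    missing = [c.value for c in CHARACTERISTICS if c not in pa.annotations]
    if missing:
        problems.append(f"missing characteristics: {', '.join(missing)}")
    for c, a in pa.annotations.items():
        if a.characteristic is not c:
            problems.append(f"mislabelled entry under {c.value}")
        if not isinstance(a.frequency, Frequency):
            problems.append(f"{c.value}: frequency outside vocabulary")
    if pa.replicate < 1:
        problems.append("replicate must be >= 1")
    return problems


# -- batch driver --------------------------------------------------------

Annotator = Callable[[str], str]


def annotate(
    ont,
    term_ids: Sequence[str],
    annotator: Annotator,
    batch_size: int = 2,
    replicates: int | Mapping[str, int] = 1,
    max_retries: int = 2,
    seed: int = 0,
    template: str = DEFAULT_PROMPT_TEMPLATE,
) -> AnnotationSet:
    """Drive batch annotation of ``term_ids`` through a pluggable annotator.

    Terms are batched two per prompt. Each (term, replicate) either yields a
    validated record or, after ``max_retries`` additional attempts, a logged
    :class:`AnnotationFailure`; no annotator exception escapes. The result
    is deterministic given a deterministic annotator.
    """
    if not 1 <= batch_size <= 2:
        raise PromptError("batch_size must be 1 or 2")
    reps: dict[str, int] = (
        {t: int(replicates) for t in term_ids}
        if isinstance(replicates, int)
        else {t: int(replicates.get(t, 1)) for t in term_ids}
    )
    for tid in term_ids:
        if tid not in ont.terms:
            raise KeyError(f"unknown term: {tid}")

    aset = AnnotationSet(
        provenance={
            "annotator": getattr(annotator, "label", repr(annotator)),
            "seed": seed,
            "batch_size": batch_size,
        }
    )
    max_rounds = max(reps.values(), default=0)
    for round_no in range(1, max_rounds + 1):
        todo = [t for t in term_ids if reps[t] >= round_no]
        for i in range(0, len(todo), batch_size):
            batch = todo[i : i + batch_size]
            pairs = [(t, ont.terms[t].name) for t in batch]
            prompt = build_prompt(pairs, template)
            parsed: list[PhenotypeAnnotation] | None = None
            last_error = ""
            for _attempt in range(1 + max_retries):
                try:
                    parsed = parse_response(annotator(prompt), expected=batch)
                    break
                except Exception as exc:  # annotator or parse failure — retry
                    last_error = f"{type(exc).__name__}: {exc}"
                    parsed = None
            if parsed is None:
                for tid, name in pairs:
                    aset.failures.append(
                        AnnotationFailure(tid, name, round_no, last_error, 1 + max_retries)
                    )
                continue
            for pa in parsed:
                pa.replicate = round_no
                aset.records.append(pa)
    return aset


# -- bundled annotators --------------------------------------------------


def _hashed_frequency(seed: int, term_id: str, char: Characteristic) -> Frequency:
    digest = hashlib.sha256(f"{seed}:{term_id}:{char.value}".encode()).digest()
    return Frequency(digest[0] % 4)


def mock_annotator(
    seed: int = 0,
    rules: Mapping[str, tuple[Characteristic, Frequency]] | None = None,
) -> Annotator:
    """A deterministic offline annotator emitting grammar-conformant responses.

    Frequencies are a pure hash of (seed, term id, characteristic), so the
    same prompt always yields byte-identical output. ``rules`` maps
    case-insensitive name keywords to (characteristic, frequency) overrides,
    e.g. ``{"lethal": (Characteristic.DEATH, Frequency.ALWAYS)}``.
    """
    rules = dict(rules or {})

    def _annotate(prompt: str) -> str:
        pairs = phenotypes_in_prompt(prompt)
        records = []
        for tid, name in pairs:
            pa = PhenotypeAnnotation(phenotype=tid, name=name)
            for c in CHARACTERISTICS:
                freq = _hashed_frequency(seed, tid, c)
                for keyword, (rc, rf) in rules.items():
                    if rc is c and keyword.casefold() in name.casefold():
                        freq = rf
                pa.annotations[c] = CharacteristicAnnotation(
                    c, freq, f"{name} {freq.word} causes {c.label}."
                )
            records.append(pa)
        return render_response(records)

    _annotate.label = f"mock(seed={seed})"  # type: ignore[attr-defined]
    return _annotate


def random_annotator(seed: int = 0) -> Annotator:
    """A stateful annotator drawing every frequency uniformly at random.

    Unlike the mock it is not a pure function of the prompt: repeated calls
    with the same prompt give fresh draws, which is what replicate-
    consistency null experiments need.
    """
    rng = random.Random(seed)

    def _annotate(prompt: str) -> str:
        records = []
        for tid, name in phenotypes_in_prompt(prompt):
            pa = PhenotypeAnnotation(phenotype=tid, name=name)
            for c in CHARACTERISTICS:
                freq = Frequency(rng.randrange(4))
                pa.annotations[c] = CharacteristicAnnotation(
                    c, freq, f"{name} {freq.word} causes {c.label}."
                )
            records.append(pa)
        return render_response(records)

    _annotate.label = f"uniform-random(seed={seed})"  # type: ignore[attr-defined]
    return _annotate
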