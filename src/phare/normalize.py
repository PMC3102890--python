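"""Normalization of raw text-mined relationships against the ontology.

The pipeline has four steps: normalize the subject composite entity,
normalize the object composite entity, normalize the relationship type, and
assemble the pieces — expanding inverse and symmetric roles into their
derived counterparts.  Equivalent relationships are merged with concatenated
provenance; anything that cannot be matched to the ontology is collected for
the curation/refinement loop instead of being silently dropped.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .ontology import (
    AmbiguityError,
    EntityType,
    KeyEntity,
    CompositionAxiom,
    Ontology,
    Role,
    encode_local,
    find_entity_type,
    find_role,
    resolve_key_entity,
)

Provenance = tuple[str, str]  # (pmid, sentence)


@dataclass(frozen=True)
class RawCompositeEntity:
    """Extractor-ordered token sequence: key entity first, head last."""

    tokens: tuple[str, ...]

    def __post_init__(self):
        if not self.tokens:
            raise ValueError("composite entity must have at least one token")
        if any((not t) or any(c.isspace() for c in t) for t in self.tokens):
            raise ValueError(f"tokens must be non-empty and whitespace-free: {self.tokens}")

    @classmethod
    def of(cls, *tokens: str) -> "RawCompositeEntity":
        return cls(tuple(tokens))


@dataclass(frozen=True)
class RawRelationship:
    raw_type: str
    subject: RawCompositeEntity
    object: RawCompositeEntity
    pmid: str
    sentence: str

    def __post_init__(self):
        if not (self.pmid.isdigit() and int(self.pmid) > 0):
            raise ValueError(f"pmid must be a positive integer string: {self.pmid!r}")
        if not self.sentence:
            raise ValueError("sentence must be non-empty")

    @property
    def provenance(self) -> Provenance:
        return (self.pmid, self.sentence)

    def surface_key(self) -> tuple:
        """String identity of the raw expression (type, subject, object)."""
        return (self.raw_type, self.subject.tokens, self.object.tokens)


@dataclass(frozen=True)
class NormalizedEntity:
    """Either a bare key entity, or an entity type wrapping (`modified`) an
    inner normalized entity; the chain bottoms out at a key entity (or, for
    key-less anchors, at a bare entity type)."""

    key_id: Optional[str] = None
    type_id: Optional[str] = None
    modified: Optional["NormalizedEntity"] = None

    def __post_init__(self):
        if (self.key_id is None) == (self.type_id is None):
            raise ValueError("exactly one of key_id / type_id must be set")
        if self.key_id is not None and self.modified is not None:
            raise ValueError("a key entity cannot itself be modified")

    @property
    def is_key(self) -> bool:
        return self.key_id is not None

    def innermost_key(self) -> Optional[str]:
        node = self
        while node.modified is not None:
            node = node.modified
        return node.key_id

    def chain(self) -> list["NormalizedEntity"]:
        out, node = [], self
        while node is not None:
            out.append(node)
            node = node.modified
        return out

    def individual_id(self, onto: Ontology) -> str:
        """Deterministic `=`-encoded individual identifier, innermost first
        (e.g. ``vkorc1=expression``)."""
        parts: list[str] = []
        for node in reversed(self.chain()):
            if node.is_key:
                parts.append(encode_local(onto.lexicon[node.key_id].preferred_name))
            else:
                parts.append(encode_local(onto.entity_types[node.type_id].preferred_label))
        return "=".join(parts)

    def surface_tokens(self, onto: Ontology) -> tuple[str, ...]:
        """Preferred-name token rendering in extractor order (key first)."""
        tokens: list[str] = []
        for node in reversed(self.chain()):
            if node.is_key:
                tokens.extend(onto.lexicon[node.key_id].preferred_name.lower().split())
            else:
                tokens.extend(
                    onto.entity_types[node.type_id].preferred_label.lower().split()
                )
        return tuple(tokens)


@dataclass(frozen=True)
class NormalizedRelationship:
    role_id: str
    subject: NormalizedEntity
    object: NormalizedEntity
    provenance: tuple[Provenance, ...]
    derived_by_inverse: bool = False

    def identity(self, onto: Ontology) -> tuple[str, str, str]:
        return (
            self.role_id,
            self.subject.individual_id(onto),
            self.object.individual_id(onto),
        )


def expression_key(rel: NormalizedRelationship, onto: Ontology) -> tuple[str, str, str]:
    """Canonical key folding a relationship and its inverse/symmetric twin
    into one *expression*; used to count distinct integrated facts."""
    role = onto.roles[rel.role_id]
    s = rel.subject.individual_id(onto)
    o = rel.object.individual_id(onto)
    if role.symmetric:
        lo, hi = sorted((s, o))
        return (role.id, lo, hi)
    if role.inverse is not None and role.inverse < role.id:
        return (role.inverse, o, s)
    return (role.id, s, o)


class NormalizationFailure(Exception):
    """A raw relationship (or one of its entities) could not be normalized."""

    def __init__(self, stage: str, token: str, detail: str = ""):
        super().__init__(f"normalization failed at {stage} on {token!r}" +
                         (f": {detail}" if detail else ""))
        self.stage = stage  # 'key' | 'modifier' | 'type'
        self.token = token
        self.detail = detail


@dataclass(frozen=True)
class FailureRecord:
    raw: RawRelationship
    stage: str
    token: str


@dataclass
class NormalizationOutcome:
    normalized: list[NormalizedRelationship] = field(default_factory=list)
    failed: list[FailureRecord] = field(default_factory=list)
    n_input: int = 0
    normalized_sources: list[RawRelationship] = field(default_factory=list)
    expression_counts: dict[tuple[str, str, str], int] = field(default_factory=dict)

    @property
    def n_expressions(self) -> int:
        return len(self.expression_counts)


# ---------------------------------------------------------------------------
# steps 1-2: composite entities


def normalize_entity(raw: RawCompositeEntity, onto: Ontology) -> NormalizedEntity:
    """Resolve the key entity (greedy, longest span first), then wrap each
    following word left-to-right as an entity type specializing what came
    before.  First-seen compositions append a restriction axiom to ``onto``.

    Raises :class:`NormalizationFailure` when any token cannot be matched.
    """
    tokens = raw.tokens
    consumed = 0
    current: Optional[NormalizedEntity] = None
    category: Optional[str] = None

    for length in range(len(tokens), 0, -1):
        span = " ".join(tokens[:length])
        try:
            key = resolve_key_entity(span, onto)
        except AmbiguityError as exc:
            raise NormalizationFailure("key", span, str(exc)) from exc
        if key is not None:
            current = NormalizedEntity(key_id=key.id)
            category = key.category
            consumed = length
            break

    if current is None:
        # fall back to an entity-type anchor for key-less composites
        try:
            anchor = find_entity_type(tokens[0], None, onto)
        except AmbiguityError as exc:
            raise NormalizationFailure("key", tokens[0], str(exc)) from exc
        if anchor is None:
            raise NormalizationFailure("key", tokens[0])
        current = NormalizedEntity(type_id=anchor.id)
        category = anchor.modifier_category
        consumed = 1

    for token in tokens[consumed:]:
        try:
            et = find_entity_type(token, category, onto)
        except AmbiguityError as exc:
            raise NormalizationFailure("modifier", token, str(exc)) from exc
        if et is None:
            raise NormalizationFailure("modifier", token)
        inner_id = (
            onto.lexicon[current.key_id].category if current.is_key else current.type_id
        )
        onto.add_axiom(CompositionAxiom(outer=et.id, inner=inner_id))
        current = NormalizedEntity(type_id=et.id, modified=current)

    return current


# ---------------------------------------------------------------------------
# step 3: relationship type


def normalize_type(raw_type: str, onto: Ontology) -> tuple[Role, str]:
    """Map a raw type string to its owning role.  Passive labels (with the
    ``$$`` separator) belong to the passive-direction role, so the
    orientation is always ``as-stated``; argument swapping is done by the
    assembly step through inverses."""
    role = find_role(raw_type, onto)
    if role is None:
        raise NormalizationFailure("type", raw_type)
    return role, "as-stated"


# ---------------------------------------------------------------------------
# step 4: assembly


def assemble(
    role: Role,
    subj: NormalizedEntity,
    obj: NormalizedEntity,
    provenance: Sequence[Provenance],
) -> list[NormalizedRelationship]:
    prov = tuple(provenance)
    out = [NormalizedRelationship(role.id, subj, obj, prov, derived_by_inverse=False)]
    if role.inverse is not None and role.inverse != role.id:
        out.append(
            NormalizedRelationship(role.inverse, obj, subj, prov, derived_by_inverse=True)
        )
    elif role.symmetric and subj != obj:
        out.append(
            NormalizedRelationship(role.id, obj, subj, prov, derived_by_inverse=True)
        )
    return out


# ---------------------------------------------------------------------------
# integration


def normalize_relationship(
    raw: RawRelationship, onto: Ontology
) -> list[NormalizedRelationship]:
    subj = normalize_entity(raw.subject, onto)
    obj = normalize_entity(raw.object, onto)
    role, _ = normalize_type(raw.raw_type, onto)
    return assemble(role, subj, obj, [raw.provenance])


def integrate(raws: Iterable[RawRelationship], onto: Ontology) -> NormalizationOutcome:
    """Run the four normalization steps over a batch, merging identical
    relationships (same role, subject, object) and concatenating provenance.
    Failures are collected as data, never raised."""
    outcome = NormalizationOutcome()
    merged: dict[tuple[str, str, str], dict] = {}

    for raw in raws:
        outcome.n_input += 1
        try:
            rels = normalize_relationship(raw, onto)
        except NormalizationFailure as failure:
            outcome.failed.append(FailureRecord(raw, failure.stage, failure.token))
            continue
        outcome.normalized_sources.append(raw)
        ekey = expression_key(rels[0], onto)
        outcome.expression_counts[ekey] = outcome.expression_counts.get(ekey, 0) + 1
        for rel in rels:
            ident = rel.identity(onto)
            slot = merged.get(ident)
            if slot is None:
                merged[ident] = {
                    "rel": rel,
                    "provenance": list(rel.provenance),
                    "derived": rel.derived_by_inverse,
                }
            else:
                for p in rel.provenance:
                    if p not in slot["provenance"]:
                        slot["provenance"].append(p)
                slot["derived"] = slot["derived"] and rel.derived_by_inverse

    for slot in merged.values():
        rel = slot["rel"]
        outcome.normalized.append(
            NormalizedRelationship(
                role_id=rel.role_id,
                subject=rel.subject,
                object=rel.object,
                provenance=tuple(slot["provenance"]),
                derived_by_inverse=slot["derived"],
            )
        )
    return outcome


# ---------------------------------------------------------------------------
# refinement report


@dataclass(frozen=True)
class RefinementCandidate:
    term: str
    kind: str  # 'role' for unmatched raw types, 'term' for unmatched tokens
    count: int
    example_sentence: str


def refinement_report(
    outcome: NormalizationOutcome, top_n: Optional[int] = None
) -> list[RefinementCandidate]:
    """Frequency-ranked unmatched raw types and modifier tokens with example
    sentences, for curator review.  Ties break lexicographically."""
    counts: Counter[tuple[str, str]] = Counter()
    examples: dict[tuple[str, str], str] = {}
    for rec in outcome.failed:
        kind = "role" if rec.stage == "type" else "term"
        key = (rec.token, kind)
        counts[key] += 1
        examples.setdefault(key, rec.raw.sentence)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    if top_n is not None:
        ranked = ranked[:top_n]
    return [
        RefinementCandidate(term=term, kind=kind, count=n, example_sentence=examples[(term, kind)])
        for (term, kind), n in ranked
    ]


# ---------------------------------------------------------------------------
# raw relationship I/O (JSON-lines and TSV dialects)


def read_raw_relationships(path, fmt: Optional[str] = None) -> list[RawRelationship]:
    fmt = fmt or ("tsv" if str(path).endswith((".tsv", ".txt")) else "jsonl")
    out: list[RawRelationship] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        if fmt == "jsonl":
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                out.append(
                    RawRelationship(
                        raw_type=rec["raw_type"],
                        subject=RawCompositeEntity(tuple(rec["subject_tokens"])),
                        object=RawCompositeEntity(tuple(rec["object_tokens"])),
                        pmid=str(rec["pmid"]),
                        sentence=rec["sentence"],
                    )
                )
        elif fmt == "tsv":
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or row[0].startswith("#"):
                    continue
                raw_type, subj, obj, pmid, sentence = row
                out.append(
                    RawRelationship(
                        raw_type=raw_type,
                        subject=RawCompositeEntity(tuple(subj.split())),
                        object=RawCompositeEntity(tuple(obj.split())),
                        pmid=pmid,
                        sentence=sentence,
                    )
                )
        else:
            raise ValueError(f"unknown raw-relationship format: {fmt!r}")
    return out


def write_raw_relationships(raws: Iterable[RawRelationship], path, fmt: Optional[str] = None) -> None:
    fmt = fmt or ("tsv" if str(path).endswith((".tsv", ".txt")) else "jsonl")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if fmt == "jsonl":
            for raw in raws:
                fh.write(
                    json.dumps(
                        {
                            "raw_type": raw.raw_type,
                            "subject_tokens": list(raw.subject.tokens),
                            "object_tokens": list(raw.object.tokens),
                            "pmid": raw.pmid,
                            "sentence": raw.sentence,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
        elif fmt == "tsv":
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for raw in raws:
                writer.writerow(
                    [
                        raw.raw_type,
                        " ".join(raw.subject.tokens),
                        " ".join(raw.object.tokens),
                        raw.pmid,
                        raw.sentence,
                    ]
                )
        else:
            raise ValueError(f"unknown raw-relationship format: {fmt!r}")
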