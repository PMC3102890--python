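"""Ontology model: entity-type and role hierarchies plus the key-entity lexicon.

Entity types form a subsumption DAG and may carry a *modifier restriction*
(the category of key entity that specializes them), which is what lets a
surface word like ``level`` resolve to gene expression in a gene context but
to drug dose in a drug context.  Roles carry alternative surface labels
(including passive-voice forms marked with the opaque ``$$`` separator),
an optional inverse and an optional symmetry flag.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional

from .rdfio import (
    DEFAULT_PREFIXES,
    Graph,
    IRI,
    Literal,
    OWL_NS,
    PHARE_NS,
    RDF_NS,
    RDFS_NS,
)

KEY_CATEGORIES = ("Gene", "Drug", "Phenotype")

_RDF_TYPE = IRI(RDF_NS + "type")
_RDFS_LABEL = IRI(RDFS_NS + "label")
_RDFS_SUBCLASS = IRI(RDFS_NS + "subClassOf")
_RDFS_SUBPROP = IRI(RDFS_NS + "subPropertyOf")
_RDFS_COMMENT = IRI(RDFS_NS + "comment")
_OWL_CLASS = IRI(OWL_NS + "Class")
_OWL_OBJPROP = IRI(OWL_NS + "ObjectProperty")
_OWL_SYMPROP = IRI(OWL_NS + "SymmetricProperty")
_OWL_INVERSE = IRI(OWL_NS + "inverseOf")
_OWL_RESTRICTION = IRI(OWL_NS + "Restriction")
_OWL_ONPROP = IRI(OWL_NS + "onProperty")
_OWL_SOMEVALUES = IRI(OWL_NS + "someValuesFrom")
_MODIFIED = IRI(PHARE_NS + "modified")


class OntologyError(Exception):
    """Base class for ontology-layer errors."""


class OntologyFormatError(OntologyError):
    """A file could not be parsed or uses an unexpected structure."""


class ValidationError(OntologyError):
    def __init__(self, violations: list[str]):
        super().__init__("ontology validation failed:\n" + "\n".join(violations))
        self.violations = violations


class AmbiguityError(OntologyError):
    """A surface string is owned by several candidates and context cannot pick one."""

    def __init__(self, span: str, candidates: list):
        ids = ", ".join(sorted(c.id for c in candidates))
        super().__init__(f"ambiguous span {span!r}: candidates {ids}")
        self.span = span
        self.candidates = candidates


def encode_local(name: str) -> str:
    """Spaces in compound nouns become ``=`` in local identifiers."""
    return name.strip().lower().replace(" ", "=")


@dataclass(frozen=True)
class EntityType:
    id: str
    preferred_label: str
    alt_labels: tuple[str, ...] = ()
    parents: frozenset[str] = frozenset()
    modifier_category: Optional[str] = None  # a key category, or None

    @property
    def labels(self) -> tuple[str, ...]:
        return (self.preferred_label,) + self.alt_labels


@dataclass(frozen=True)
class Role:
    id: str
    preferred_label: str
    alt_labels: tuple[str, ...] = ()
    parent: Optional[str] = None
    inverse: Optional[str] = None
    symmetric: bool = False

    @property
    def labels(self) -> tuple[str, ...]:
        return (self.preferred_label,) + self.alt_labels


@dataclass(frozen=True)
class KeyEntity:
    id: str
    preferred_name: str
    synonyms: tuple[str, ...]
    category: str
    external_ids: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.category not in KEY_CATEGORIES:
            raise ValueError(f"unknown key category: {self.category!r}")
        lowered = {s.lower() for s in self.synonyms}
        if self.preferred_name.lower() not in lowered:
            object.__setattr__(
                self, "synonyms", (self.preferred_name,) + tuple(self.synonyms)
            )

    @property
    def external_id_map(self) -> dict[str, str]:
        return dict(self.external_ids)


@dataclass(frozen=True)
class CompositionAxiom:
    """Restriction axiom: the composed class (outer ⊓ Ǝ modified.inner) ⊑ outer."""

    outer: str
    inner: str
    note: str = "added during normalization"

    @property
    def composed_id(self) -> str:
        return f"{self.outer}=modified={self.inner}"


@dataclass
class Ontology:
    entity_types: dict[str, EntityType] = field(default_factory=dict)
    roles: dict[str, Role] = field(default_factory=dict)
    lexicon: dict[str, KeyEntity] = field(default_factory=dict)
    axioms: list[CompositionAxiom] = field(default_factory=list)

    # -- construction ------------------------------------------------------

    def add_entity_type(self, et: EntityType) -> None:
        self.entity_types[et.id] = et

    def add_role(self, role: Role) -> None:
        self.roles[role.id] = role

    def add_key_entity(self, ke: KeyEntity) -> None:
        self.lexicon[ke.id] = ke

    def add_axiom(self, axiom: CompositionAxiom) -> bool:
        """Record a composition axiom unless it is already implied; returns
        True when the axiom was actually added."""
        outer = self.entity_types.get(axiom.outer)
        if outer is not None and outer.modifier_category == axiom.inner:
            return False  # the declared modifier restriction already covers it
        if any(a.outer == axiom.outer and a.inner == axiom.inner for a in self.axioms):
            return False
        self.axioms.append(axiom)
        return True

    # -- reasoning helpers -------------------------------------------------

    def subsumes(self, ancestor: str, descendant: str) -> bool:
        """Reflexive-transitive reachability through entity-type parents."""
        if ancestor == descendant:
            return True
        seen = set()
        stack = [descendant]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            et = self.entity_types.get(cur)
            if et is None:
                continue
            for p in et.parents:
                if p == ancestor:
                    return True
                stack.append(p)
        return False

    def supertypes(self, type_id: str) -> set[str]:
        """All ancestors of a type, including the type itself."""
        out = {type_id}
        stack = [type_id]
        while stack:
            et = self.entity_types.get(stack.pop())
            if et is None:
                continue
            for p in et.parents:
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out


# ---------------------------------------------------------------------------
# lookup services


def _plural_forms(word: str) -> list[str]:
    """The word itself, then light pluralization fallbacks (strip s / es)."""
    w = word.lower()
    forms = [w]
    if w.endswith("s") and len(w) > 1:
        forms.append(w[:-1])
    if w.endswith("es") and len(w) > 2:
        forms.append(w[:-2])
    return forms


def resolve_key_entity(token_span: str, onto: Ontology) -> Optional[KeyEntity]:
    """Case-insensitive synonym lookup of a (possibly multiword) span."""
    span = " ".join(token_span.lower().split())
    hits = [
        ke
        for ke in onto.lexicon.values()
        if any(span == s.lower() for s in ke.synonyms)
    ]
    if not hits:
        return None
    if len(hits) > 1:
        raise AmbiguityError(span, hits)
    return hits[0]


def find_entity_type(
    word: str, modifier_category: Optional[str], onto: Ontology
) -> Optional[EntityType]:
    """Match a surface word against entity-type labels; a shared label is
    disambiguated by the modifier restriction of the candidates."""
    for form in _plural_forms(word):
        candidates = [
            et
            for et in onto.entity_types.values()
            if any(form == lbl.lower() for lbl in et.labels)
        ]
        if not candidates:
            continue
        if len(candidates) == 1:
            return candidates[0]
        scoped = [et for et in candidates if et.modifier_category == modifier_category]
        if len(scoped) == 1:
            return scoped[0]
        raise AmbiguityError(word, candidates)
    return None


def find_role(raw_type: str, onto: Ontology) -> Optional[Role]:
    """Case-insensitive match of a raw relationship type (``$$`` kept opaque)
    against role labels, with the pluralization fallback."""
    for form in _plural_forms(raw_type):
        for role in onto.roles.values():
            if any(form == lbl.lower() for lbl in role.labels):
                return role
    return None


def subsumes(ancestor: EntityType, descendant: EntityType, onto: Ontology) -> bool:
    return onto.subsumes(ancestor.id, descendant.id)


# ---------------------------------------------------------------------------
# validation


def validate(onto: Ontology) -> list[str]:
    """Structural validation; an empty report means the ontology is valid."""
    report: list[str] = []

    # label injectivity for roles: each label string belongs to one role
    owner: dict[str, str] = {}
    for role in onto.roles.values():
        for lbl in role.labels:
            key = lbl.lower()
            if key in owner and owner[key] != role.id:
                report.append(
                    f"role label {lbl!r} belongs to both {owner[key]!r} and {role.id!r}"
                )
            owner.setdefault(key, role.id)

    # preferred labels unique across entity types; alt labels unique per scope
    pref_owner: dict[str, str] = {}
    scope_owner: dict[tuple[str, Optional[str]], str] = {}
    for et in onto.entity_types.values():
        key = et.preferred_label.lower()
        if key in pref_owner and pref_owner[key] != et.id:
            report.append(
                f"preferred label {et.preferred_label!r} used by both "
                f"{pref_owner[key]!r} and {et.id!r}"
            )
        pref_owner.setdefault(key, et.id)
        for lbl in et.labels:
            skey = (lbl.lower(), et.modifier_category)
            if skey in scope_owner and scope_owner[skey] != et.id:
                report.append(
                    f"entity label {lbl!r} (modifier scope "
                    f"{et.modifier_category}) belongs to both "
                    f"{scope_owner[skey]!r} and {et.id!r}"
                )
            scope_owner.setdefault(skey, et.id)

    # dangling references
    for et in onto.entity_types.values():
        for p in et.parents:
            if p not in onto.entity_types:
                report.append(f"entity type {et.id!r} has unknown parent {p!r}")
        if et.modifier_category is not None and et.modifier_category not in KEY_CATEGORIES:
            report.append(
                f"entity type {et.id!r} has non key-category modifier "
                f"restriction {et.modifier_category!r}"
            )
    for role in onto.roles.values():
        if role.parent is not None and role.parent not in onto.roles:
            report.append(f"role {role.id!r} has unknown parent {role.parent!r}")
        if role.inverse is not None and role.inverse not in onto.roles:
            report.append(f"role {role.id!r} has unknown inverse {role.inverse!r}")

    # subsumption acyclicity (entity types)
    report.extend(
        f"cyclic subsumption through entity type {tid!r}"
        for tid in _find_cycles({t.id: t.parents for t in onto.entity_types.values()})
    )
    # role hierarchy acyclicity
    report.extend(
        f"cyclic sub-role chain through role {rid!r}"
        for rid in _find_cycles(
            {
                r.id: (frozenset({r.parent}) if r.parent else frozenset())
                for r in onto.roles.values()
            }
        )
    )

    # inverse involution and symmetry conflicts
    for role in onto.roles.values():
        if role.inverse is not None:
            inv = onto.roles.get(role.inverse)
            if inv is not None and inv.inverse != role.id:
                report.append(
                    f"inverse not involutive: inverse({role.id}) = {role.inverse} "
                    f"but inverse({role.inverse}) = {inv.inverse}"
                )
            if role.symmetric and role.inverse != role.id:
                report.append(
                    f"role {role.id!r} is symmetric yet paired with distinct "
                    f"inverse {role.inverse!r}"
                )

    # lexicon sanity
    for ke in onto.lexicon.values():
        if not any(ke.preferred_name.lower() == s.lower() for s in ke.synonyms):
            report.append(f"key entity {ke.id!r} preferred name not in synonyms")

    # composition axioms reference known types
    for ax in onto.axioms:
        if ax.outer not in onto.entity_types:
            report.append(f"composition axiom references unknown outer type {ax.outer!r}")
        if ax.inner not in onto.entity_types and ax.inner not in KEY_CATEGORIES:
            report.append(f"composition axiom references unknown inner type {ax.inner!r}")

    return report


def _find_cycles(parents: dict[str, frozenset[str]]) -> list[str]:
    """Nodes participating in a parent-relation cycle (within the id set)."""
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {k: WHITE for k in parents}
    bad: list[str] = []

    def visit(node: str) -> bool:
        color[node] = GRAY
        for p in parents.get(node, ()):  # unknown parents reported elsewhere
            if p not in color:
                continue
            if color[p] == GRAY or (color[p] == WHITE and visit(p)):
                return True
        color[node] = BLACK
        return False

    for node in parents:
        if color[node] == WHITE and visit(node):
            bad.append(node)
    return bad


# ---------------------------------------------------------------------------
# Turtle serialization


def _iri(local: str) -> IRI:
    return IRI(PHARE_NS + local)


def _restriction_id(inner: str) -> str:
    return f"restr=modified={inner}"


def save_ontology(onto: Ontology, path, fmt: str = "turtle") -> None:
    violations = validate(onto)
    if violations:
        raise ValidationError(violations)
    ontology_to_graph(onto).save(path, fmt)


def ontology_to_graph(onto: Ontology) -> Graph:
    g = Graph()
    restrictions_emitted: set[str] = set()

    def emit_restriction(inner: str) -> IRI:
        rid = _restriction_id(inner)
        node = _iri(rid)
        if rid not in restrictions_emitted:
            g.add(node, _RDF_TYPE, _OWL_RESTRICTION)
            g.add(node, _OWL_ONPROP, _MODIFIED)
            g.add(node, _OWL_SOMEVALUES, _iri(inner))
            restrictions_emitted.add(rid)
        return node

    for et in onto.entity_types.values():
        node = _iri(et.id)
        g.add(node, _RDF_TYPE, _OWL_CLASS)
        for lbl in et.labels:
            g.add(node, _RDFS_LABEL, Literal(lbl))
        for parent in sorted(et.parents):
            g.add(node, _RDFS_SUBCLASS, _iri(parent))
        if et.modifier_category is not None:
            g.add(node, _RDFS_SUBCLASS, emit_restriction(et.modifier_category))

    for role in onto.roles.values():
        node = _iri(role.id)
        g.add(node, _RDF_TYPE, _OWL_OBJPROP)
        if role.symmetric:
            g.add(node, _RDF_TYPE, _OWL_SYMPROP)
        for lbl in role.labels:
            g.add(node, _RDFS_LABEL, Literal(lbl))
        if role.parent:
            g.add(node, _RDFS_SUBPROP, _iri(role.parent))
        if role.inverse:
            g.add(node, _OWL_INVERSE, _iri(role.inverse))

    for ke in onto.lexicon.values():
        node = _iri(ke.id)
        g.add(node, _RDF_TYPE, _iri(ke.category))
        for syn in ke.synonyms:
            g.add(node, _RDFS_LABEL, Literal(syn))
        for source, ident in ke.external_ids:
            g.add(node, _iri(f"xref_{source}"), Literal(ident))

    for ax in onto.axioms:
        node = _iri(ax.composed_id)
        g.add(node, _RDF_TYPE, _OWL_CLASS)
        g.add(node, _RDFS_SUBCLASS, _iri(ax.outer))
        g.add(node, _RDFS_SUBCLASS, emit_restriction(ax.inner))
        g.add(node, _RDFS_COMMENT, Literal(ax.note))

    return g


def load_ontology(path, fmt: str = "turtle") -> Ontology:
    graph = Graph.load(path, fmt)
    onto = graph_to_ontology(graph)
    violations = validate(onto)
    if violations:
        raise ValidationError(violations)
    return onto


def graph_to_ontology(graph: Graph) -> Ontology:
    onto = Ontology()
    ns = PHARE_NS

    def local(iri: IRI) -> str:
        if not iri.value.startswith(ns):
            raise OntologyFormatError(f"IRI outside ontology namespace: {iri.value}")
        return iri.value[len(ns):]

    # restriction nodes: restr=modified=<Inner>
    restriction_inner: dict[str, str] = {}
    for s, _, _ in graph.triples(p=_RDF_TYPE, o=_OWL_RESTRICTION):
        inners = graph.objects(s, _OWL_SOMEVALUES)
        if len(inners) != 1 or not isinstance(inners[0], IRI):
            raise OntologyFormatError(
                f"restriction {s.value} lacks a unique someValuesFrom filler"
            )
        restriction_inner[local(s)] = local(inners[0])

    class_nodes = [s for s, _, _ in graph.triples(p=_RDF_TYPE, o=_OWL_CLASS)]
    role_nodes = [s for s, _, _ in graph.triples(p=_RDF_TYPE, o=_OWL_OBJPROP)]
    symmetric = {local(s) for s, _, _ in graph.triples(p=_RDF_TYPE, o=_OWL_SYMPROP)}

    composed: list[tuple[str, str, str, str]] = []  # (id, outer, inner, note)
    for node in class_nodes:
        tid = local(node)
        labels = [o.value for _, _, o in graph.triples(s=node, p=_RDFS_LABEL)
                  if isinstance(o, Literal)]
        parents: set[str] = set()
        modifier: Optional[str] = None
        sub_restr: Optional[str] = None
        for _, _, o in graph.triples(s=node, p=_RDFS_SUBCLASS):
            target = local(o)
            if target in restriction_inner:
                sub_restr = restriction_inner[target]
            else:
                parents.add(target)
        if not labels and sub_restr is not None and len(parents) == 1:
            # an unlabeled composed class is a recorded composition axiom
            notes = [o.value for _, _, o in graph.triples(s=node, p=_RDFS_COMMENT)
                     if isinstance(o, Literal)]
            composed.append((tid, next(iter(parents)), sub_restr,
                             notes[0] if notes else "added during normalization"))
            continue
        if sub_restr is not None:
            modifier = sub_restr
        if not labels:
            labels = [tid]
        onto.add_entity_type(
            EntityType(
                id=tid,
                preferred_label=labels[0],
                alt_labels=tuple(labels[1:]),
                parents=frozenset(parents),
                modifier_category=modifier,
            )
        )

    for node in role_nodes:
        rid = local(node)
        labels = [o.value for _, _, o in graph.triples(s=node, p=_RDFS_LABEL)
                  if isinstance(o, Literal)]
        if not labels:
            labels = [rid]
        parents = [local(o) for _, _, o in graph.triples(s=node, p=_RDFS_SUBPROP)]
        inverses = [local(o) for _, _, o in graph.triples(s=node, p=_OWL_INVERSE)]
        onto.add_role(
            Role(
                id=rid,
                preferred_label=labels[0],
                alt_labels=tuple(labels[1:]),
                parent=parents[0] if parents else None,
                inverse=inverses[0] if inverses else None,
                symmetric=rid in symmetric,
            )
        )

    # key entities: individuals typed by a key-category class
    for category in KEY_CATEGORIES:
        for s, _, _ in graph.triples(p=_RDF_TYPE, o=_iri(category)):
            kid = local(s)
            labels = [o.value for _, _, o in graph.triples(s=s, p=_RDFS_LABEL)
                      if isinstance(o, Literal)]
            if not labels:
                labels = [kid.replace("=", " ")]
            xrefs = []
            for _, p, o in graph.triples(s=s):
                if not p.value.startswith(ns):
                    continue
                pl = local(p)
                if pl.startswith("xref_") and isinstance(o, Literal):
                    xrefs.append((pl[len("xref_"):], o.value))
            onto.add_key_entity(
                KeyEntity(
                    id=kid,
                    preferred_name=labels[0],
                    synonyms=tuple(labels),
                    category=category,
                    external_ids=tuple(sorted(xrefs)),
                )
            )

    for cid, outer, inner, note in composed:
        ax = CompositionAxiom(outer=outer, inner=inner, note=note)
        if ax.composed_id != cid:
            raise OntologyFormatError(
                f"composed class id {cid!r} does not match its axiom "
                f"({ax.composed_id!r})"
            )
        onto.axioms.append(ax)

    return onto


# ---------------------------------------------------------------------------
# lexicon TSV

LEXICON_COLUMNS = ["id", "preferred_name", "synonyms", "category", "entrez", "drugbank", "mesh"]


def load_lexicon(path) -> dict[str, KeyEntity]:
    """Read the key-entity lexicon TSV (synonyms pipe-delimited)."""
    out: dict[str, KeyEntity] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(LEXICON_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise OntologyFormatError(
                f"lexicon is missing columns: {', '.join(sorted(missing))}"
            )
        for row in reader:
            xrefs = []
            for source in ("entrez", "drugbank", "mesh"):
                if row.get(source):
                    xrefs.append((source, row[source]))
            syns = tuple(s for s in (row["synonyms"] or "").split("|") if s)
            out[row["id"]] = KeyEntity(
                id=row["id"],
                preferred_name=row["preferred_name"],
                synonyms=syns,
                category=row["category"],
                external_ids=tuple(xrefs),
            )
    return out


def save_lexicon(lexicon: dict[str, KeyEntity], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(LEXICON_COLUMNS)
        for ke in lexicon.values():
            ids = ke.external_id_map
            writer.writerow(
                [
                    ke.id,
                    ke.preferred_name,
                    "|".join(ke.synonyms),
                    ke.category,
                    ids.get("entrez", ""),
                    ids.get("drugbank", ""),
                    ids.get("mesh", ""),
                ]
            )
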