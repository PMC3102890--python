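"""Knowledge-base construction, inference materialization, querying and
network export.

Role instantiations become RDF triples between `=`-encoded individuals,
each carrying its sentence-level provenance as "[PMID, sentence]" comment
strings.  Materialization computes the closure under supertype typing,
inverse roles and symmetric roles, so queries see asserted and inferred
facts alike.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import networkx as nx

from .normalize import NormalizationOutcome, NormalizedEntity, Provenance
from .ontology import Ontology
from .rdfio import (
    Graph,
    IRI,
    Literal,
    OWL_NS,
    PHARE_NS,
    RDF_NS,
    RDFS_NS,
)

TYPE_PREDICATE = "rdf:type"
MODIFIED_PREDICATE = "modified"

_RDF_TYPE = IRI(RDF_NS + "type")
_RDFS_COMMENT = IRI(RDFS_NS + "comment")
_OWL_AXIOM = IRI(OWL_NS + "Axiom")
_OWL_SOURCE = IRI(OWL_NS + "annotatedSource")
_OWL_PROPERTY = IRI(OWL_NS + "annotatedProperty")
_OWL_TARGET = IRI(OWL_NS + "annotatedTarget")
_INFERRED = IRI(PHARE_NS + "inferred")

_PROV_RE = re.compile(r"^\[(\d+), (.*)\]$", re.DOTALL)


class ConsistencyError(Exception):
    """A triple references a role, type, or individual the KB does not know."""


@dataclass(frozen=True)
class Triple:
    subject: str
    predicate: str
    object: str
    inferred: bool = False
    provenance: tuple[Provenance, ...] = ()

    @property
    def spo(self) -> tuple[str, str, str]:
        return (self.subject, self.predicate, self.object)


@dataclass
class Individual:
    id: str
    types: set[str] = field(default_factory=set)
    external_ids: dict[str, str] = field(default_factory=dict)


class KnowledgeBase:
    def __init__(self) -> None:
        self._triples: dict[tuple[str, str, str], Triple] = {}
        self.individuals: dict[str, Individual] = {}

    # -- basic access ------------------------------------------------------

    @property
    def triples(self) -> list[Triple]:
        return list(self._triples.values())

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, spo: tuple[str, str, str]) -> bool:
        return spo in self._triples

    def get(self, spo: tuple[str, str, str]) -> Optional[Triple]:
        return self._triples.get(spo)

    def add(self, triple: Triple) -> None:
        """Insert or merge: same (s,p,o) merges provenance; an asserted
        triple overrides an inferred duplicate."""
        existing = self._triples.get(triple.spo)
        if existing is None:
            self._triples[triple.spo] = triple
        else:
            prov = list(existing.provenance)
            for p in triple.provenance:
                if p not in prov:
                    prov.append(p)
            self._triples[triple.spo] = replace(
                existing,
                inferred=existing.inferred and triple.inferred,
                provenance=tuple(prov),
            )

    def individual(self, ind_id: str) -> Individual:
        return self.individuals.setdefault(ind_id, Individual(ind_id))

    def role_triples(self, onto: Ontology) -> list[Triple]:
        return [t for t in self.triples if t.predicate in onto.roles]

    def copy(self) -> "KnowledgeBase":
        out = KnowledgeBase()
        out._triples = dict(self._triples)
        out.individuals = {
            k: Individual(v.id, set(v.types), dict(v.external_ids))
            for k, v in self.individuals.items()
        }
        return out


# ---------------------------------------------------------------------------
# construction


def _register_entity(kb: KnowledgeBase, entity: NormalizedEntity, onto: Ontology,
                     provenance: tuple[Provenance, ...]) -> str:
    """Register the full `modified` chain of an entity as individuals and
    return the outermost individual id."""
    chain = list(reversed(entity.chain()))  # innermost first
    prev_id: Optional[str] = None
    for node in chain:
        sub = NormalizedEntity(
            key_id=node.key_id, type_id=node.type_id, modified=node.modified
        )
        ind_id = sub.individual_id(onto)
        ind = kb.individual(ind_id)
        if node.is_key:
            ke = onto.lexicon[node.key_id]
            ind.types.add(ke.category)
            ind.external_ids.update(ke.external_id_map)
            kb.add(Triple(ind_id, TYPE_PREDICATE, ke.category, inferred=False))
        else:
            ind.types.add(node.type_id)
            kb.add(Triple(ind_id, TYPE_PREDICATE, node.type_id, inferred=False))
            kb.add(
                Triple(ind_id, MODIFIED_PREDICATE, prev_id, inferred=False,
                       provenance=provenance)
            )
        prev_id = ind_id
    return prev_id


def build_kb(outcome: NormalizationOutcome, onto: Ontology) -> KnowledgeBase:
    """One asserted role triple per normalized relationship; individuals are
    registered with their most specific types and lexicon external IDs."""
    kb = KnowledgeBase()
    for rel in outcome.normalized:
        if rel.role_id not in onto.roles:
            raise ConsistencyError(f"relationship uses unknown role {rel.role_id!r}")
        sid = _register_entity(kb, rel.subject, onto, rel.provenance)
        oid = _register_entity(kb, rel.object, onto, rel.provenance)
        kb.add(
            Triple(sid, rel.role_id, oid, inferred=False, provenance=rel.provenance)
        )
    return kb


# ---------------------------------------------------------------------------
# materialization


def materialize(kb: KnowledgeBase, onto: Ontology) -> KnowledgeBase:
    """Closure under (i) supertype typing, (ii) inverse roles, (iii) symmetric
    roles.  Monotone and idempotent; additions are flagged inferred and share
    the provenance of their source triple."""
    out = kb.copy()
    changed = True
    while changed:
        changed = False
        for t in list(out.triples):
            new: list[Triple] = []
            if t.predicate == TYPE_PREDICATE:
                for sup in onto.supertypes(t.object) - {t.object}:
                    new.append(Triple(t.subject, TYPE_PREDICATE, sup, inferred=True))
            else:
                role = onto.roles.get(t.predicate)
                if role is not None:
                    if role.inverse is not None and role.inverse != role.id:
                        new.append(
                            Triple(t.object, role.inverse, t.subject,
                                   inferred=True, provenance=t.provenance)
                        )
                    elif role.symmetric:
                        new.append(
                            Triple(t.object, role.id, t.subject,
                                   inferred=True, provenance=t.provenance)
                        )
            for nt in new:
                if nt.spo not in out:
                    out.add(nt)
                    changed = True
    for ind in out.individuals.values():
        closure = set()
        for tid in ind.types:
            closure |= onto.supertypes(tid)
        ind.types = closure
    return out


# ---------------------------------------------------------------------------
# query


def query(
    kb: KnowledgeBase,
    pattern: tuple[Optional[str], Optional[str], Optional[str]],
) -> list[Triple]:
    """Triple-pattern matching; ``None`` positions are wildcards.  Returns
    asserted and inferred triples alike."""
    s, p, o = pattern
    return [
        t
        for t in kb.triples
        if (s is None or t.subject == s)
        and (p is None or t.predicate == p)
        and (o is None or t.object == o)
    ]


# ---------------------------------------------------------------------------
# RDF import/export

# Axiom-node ids must not collide with `=`-encoded individual ids, so a
# different separator joins the (s, p, o) components.
_AXIOM_SEP = "--"


def _axiom_id(t: Triple) -> str:
    return _AXIOM_SEP.join(("axiom", t.subject, t.predicate.replace(":", "_"), t.object))


def kb_to_graph(kb: KnowledgeBase) -> Graph:
    g = Graph()

    def iri(local: str) -> IRI:
        return IRI(PHARE_NS + local)

    for ind in kb.individuals.values():
        for source, ident in sorted(ind.external_ids.items()):
            g.add(iri(ind.id), iri(f"xref_{source}"), Literal(ident))

    for t in kb.triples:
        pred = _RDF_TYPE if t.predicate == TYPE_PREDICATE else iri(t.predicate)
        g.add(iri(t.subject), pred, iri(t.object))
        if t.provenance or t.inferred:
            ax = iri(_axiom_id(t))
            g.add(ax, _RDF_TYPE, _OWL_AXIOM)
            g.add(ax, _OWL_SOURCE, iri(t.subject))
            g.add(ax, _OWL_PROPERTY, pred)
            g.add(ax, _OWL_TARGET, iri(t.object))
            g.add(ax, _INFERRED, Literal("true" if t.inferred else "false"))
            for pmid, sentence in t.provenance:
                g.add(ax, _RDFS_COMMENT, Literal(f"[{pmid}, {sentence}]"))
    return g


def export_rdf(kb: KnowledgeBase, path, fmt: str = "turtle") -> None:
    kb_to_graph(kb).save(path, fmt)


def graph_to_kb(graph: Graph) -> KnowledgeBase:
    kb = KnowledgeBase()
    ns = PHARE_NS

    def local(term) -> str:
        if isinstance(term, IRI):
            if term == _RDF_TYPE:
                return TYPE_PREDICATE
            if term.value.startswith(ns):
                return term.value[len(ns):]
        raise ConsistencyError(f"term outside the KB namespace: {term!r}")

    # collect axiom annotations first
    axiom_nodes = {s for s, _, _ in graph.triples(p=_RDF_TYPE, o=_OWL_AXIOM)}
    annotations: dict[tuple[str, str, str], tuple[bool, tuple[Provenance, ...]]] = {}
    for ax in axiom_nodes:
        src = graph.objects(ax, _OWL_SOURCE)
        prop = graph.objects(ax, _OWL_PROPERTY)
        tgt = graph.objects(ax, _OWL_TARGET)
        if not (len(src) == len(prop) == len(tgt) == 1):
            raise ConsistencyError(f"malformed axiom annotation node {ax.value}")
        spo = (local(src[0]), local(prop[0]), local(tgt[0]))
        flags = [o.value for o in graph.objects(ax, _INFERRED) if isinstance(o, Literal)]
        inferred = flags == ["true"]
        prov: list[Provenance] = []
        for o in graph.objects(ax, _RDFS_COMMENT):
            if isinstance(o, Literal):
                m = _PROV_RE.match(o.value)
                if m is None:
                    raise ConsistencyError(f"malformed provenance string: {o.value!r}")
                prov.append((m.group(1), m.group(2)))
        annotations[spo] = (inferred, tuple(prov))

    for s, p, o in graph:
        if s in axiom_nodes:
            continue
        sl = local(s)
        if isinstance(o, Literal):
            pl = local(p)
            if pl.startswith("xref_"):
                kb.individual(sl).external_ids[pl[len("xref_"):]] = o.value
            continue
        pl = local(p)
        ol = local(o)
        inferred, prov = annotations.get((sl, pl, ol), (False, ()))
        kb.add(Triple(sl, pl, ol, inferred=inferred, provenance=prov))
        if pl == TYPE_PREDICATE:
            kb.individual(sl).types.add(ol)
        else:
            kb.individual(sl)
            kb.individual(ol)
    return kb


def import_rdf(path, fmt: str = "turtle") -> KnowledgeBase:
    return graph_to_kb(Graph.load(path, fmt))


# ---------------------------------------------------------------------------
# network export


def subnetwork(
    kb: KnowledgeBase,
    focus: str,
    onto: Ontology,
    min_sentences: int = 5,
    top_labels: int = 2,
) -> nx.Graph:
    """Undirected display graph of individuals linked to ``focus`` by role
    triples mentioned in strictly more than ``min_sentences`` distinct
    sentences; edges carry the ``top_labels`` most frequent role names.
    Typing (and structural `modified`) triples are excluded."""
    if focus not in kb.individuals:
        raise KeyError(f"unknown focus individual: {focus!r}")

    pair_prov: dict[frozenset, set[Provenance]] = {}
    pair_roles: dict[frozenset, Counter] = {}
    for t in kb.role_triples(onto):
        if t.subject == t.object:
            continue
        pair = frozenset((t.subject, t.object))
        prov = set(t.provenance)
        pair_prov.setdefault(pair, set()).update(prov)
        counts = pair_roles.setdefault(pair, Counter())
        role = onto.roles[t.predicate]
        counts[role.preferred_label] += max(len(prov), 1)

    graph = nx.Graph()
    graph.add_node(focus)
    qualifying = {
        pair
        for pair, prov in pair_prov.items()
        if len(prov) > min_sentences
    }
    members = {focus}
    for pair in qualifying:
        if focus in pair:
            members.update(pair)
    for pair in qualifying:
        if not pair <= members:
            continue
        a, b = sorted(pair)
        ranked = sorted(pair_roles[pair].items(), key=lambda kv: (-kv[1], kv[0]))
        labels = [name for name, _ in ranked[:top_labels]]
        graph.add_edge(a, b, label=", ".join(labels), sentences=len(pair_prov[pair]))
    for node in graph.nodes:
        graph.nodes[node]["label"] = node
    return graph


def export_gml(graph: nx.Graph, path) -> None:
    nx.write_gml(graph, path)
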