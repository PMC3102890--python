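"""Automatic ontology induction from raw relationships and a synonym resource.

Terms observed in the corpus are merged into groups by synset co-membership
(connected components by default); each group becomes one flat role or
entity type whose members are the alternative labels and whose preferred
label is the lexicographically first member.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .normalize import RawRelationship
from .ontology import EntityType, Ontology, Role


@dataclass
class SynonymResource:
    """A list of synsets (non-empty sets of words); a word may appear in
    several synsets, as in real synonym inventories."""

    synsets: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self):
        cleaned = []
        for s in self.synsets:
            fs = frozenset(w.lower() for w in s)
            if not fs:
                raise ValueError("synsets must be non-empty")
            cleaned.append(fs)
        self.synsets = cleaned

    @classmethod
    def load(cls, path) -> "SynonymResource":
        """One whitespace-separated synset per line; '#' starts a comment."""
        synsets = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                synsets.append(frozenset(line.split()))
        return cls(synsets)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for s in self.synsets:
                fh.write(" ".join(sorted(s)) + "\n")


@dataclass
class FrequencyInventory:
    type_counts: Counter = field(default_factory=Counter)
    modifier_counts: Counter = field(default_factory=Counter)


def count_inventory(raws: Iterable[RawRelationship]) -> FrequencyInventory:
    """Exact multiset counts of raw relationship types and of the non-key
    tokens of composite entities (every token after the first)."""
    inv = FrequencyInventory()
    for raw in raws:
        inv.type_counts[raw.raw_type.lower()] += 1
        for entity in (raw.subject, raw.object):
            for token in entity.tokens[1:]:
                inv.modifier_counts[token.lower()] += 1
    return inv


def top_n(counts: Counter, n: int) -> list[str]:
    """Top-n terms by count; ties (including at the cut) break
    lexicographically."""
    if n < 0:
        raise ValueError("n must be >= 0")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [term for term, _ in ranked[:n]]


def group_terms(
    terms: Sequence[str],
    syn: SynonymResource,
    merge_overlapping: bool = True,
) -> list[tuple[str, ...]]:
    """Partition ``terms`` into synonym groups.

    With ``merge_overlapping`` (default) groups are the connected components
    of the term–synset co-membership graph, so overlapping synsets chain
    transitively.  Otherwise each synset forms its own group and a term
    appearing in several synsets stays with the first.
    """
    vocab = list(dict.fromkeys(t.lower() for t in terms))
    vocab_set = set(vocab)
    if merge_overlapping:
        g: nx.Graph = nx.Graph()
        g.add_nodes_from(vocab)
        for idx, synset in enumerate(syn.synsets):
            members = [w for w in synset if w in vocab_set]
            hub = ("synset", idx)
            for w in members:
                g.add_edge(hub, w)
        groups = []
        for comp in nx.connected_components(g):
            words = sorted(w for w in comp if isinstance(w, str))
            if words:
                groups.append(tuple(words))
    else:
        assigned: set[str] = set()
        groups = []
        for synset in syn.synsets:
            members = sorted(w for w in synset if w in vocab_set and w not in assigned)
            if members:
                groups.append(tuple(members))
                assigned.update(members)
        for w in vocab:
            if w not in assigned:
                groups.append((w,))
    return sorted(groups)


_ID_SANITIZE = re.compile(r"[^a-z0-9=_-]+")


def _term_id(term: str, taken: set[str]) -> str:
    base = _ID_SANITIZE.sub("_", term.lower().replace(" ", "=")) or "term"
    out, i = base, 2
    while out in taken:
        out = f"{base}_{i}"
        i += 1
    taken.add(out)
    return out


def induce_ontology(
    inventory: FrequencyInventory,
    syn: SynonymResource,
    mode: str = "all",
    n: int = 200,
    merge_overlapping: bool = True,
) -> Ontology:
    """Build a flat ontology (no hierarchy, no inverses) whose roles and
    entity types are the synonym groups of the observed vocabulary.

    ``mode='all'`` uses every observed term; ``mode='top'`` restricts to the
    ``n`` most frequent ones in each inventory.
    """
    if mode not in ("all", "top", "all-terms", "top-n"):
        raise ValueError(f"unknown induction mode: {mode!r}")
    restrict = mode in ("top", "top-n")
    role_terms = (
        top_n(inventory.type_counts, n) if restrict else sorted(inventory.type_counts)
    )
    entity_terms = (
        top_n(inventory.modifier_counts, n) if restrict else sorted(inventory.modifier_counts)
    )

    onto = Ontology()
    taken: set[str] = set()
    for group in group_terms(entity_terms, syn, merge_overlapping):
        onto.add_entity_type(
            EntityType(
                id=_term_id(group[0], taken),
                preferred_label=group[0],
                alt_labels=group[1:],
            )
        )
    taken = set()
    for group in group_terms(role_terms, syn, merge_overlapping):
        onto.add_role(
            Role(
                id=_term_id(group[0], taken),
                preferred_label=group[0],
                alt_labels=group[1:],
            )
        )
    return onto
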