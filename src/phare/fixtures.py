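"""Deterministic fixture ontology and a synthetic raw-relationship generator
with retained ground truth.

``figure_fixture`` builds a small but complete ontology (roles with
inverses and symmetry, entity types with modifier restrictions, a
gene/drug/phenotype lexicon) together with four raw relationships that
exercise synonym merging, modifier-scope disambiguation and inverse roles.
``generate`` renders sampled ground-truth facts as heterogeneous paraphrases
(synonyms, past tense, passive ``$$`` voice, inverse orientation) while
keeping the fact each raw record came from, so recovery can be checked
exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .normalize import (
    NormalizedEntity,
    RawCompositeEntity,
    RawRelationship,
)
from .ontology import (
    EntityType,
    KeyEntity,
    Ontology,
    Role,
    find_entity_type,
)

# ---------------------------------------------------------------------------
# figure fixture


def fixture_ontology() -> Ontology:
    onto = Ontology()

    # key categories and the small phenotype hierarchy
    onto.add_entity_type(EntityType("Gene", "gene"))
    onto.add_entity_type(EntityType("Drug", "drug"))
    onto.add_entity_type(EntityType("Phenotype", "phenotype"))
    onto.add_entity_type(
        EntityType("Disease", "disease", ("disorder", "illness"),
                   parents=frozenset({"Phenotype"}))
    )
    # 'level' is deliberately shared: gene scope -> expression, drug scope -> dose
    onto.add_entity_type(
        EntityType(
            "GeneExpression",
            "expression",
            ("level", "transcription"),
            parents=frozenset({"Phenotype"}),
            modifier_category="Gene",
        )
    )
    onto.add_entity_type(
        EntityType(
            "DrugDose",
            "dose",
            ("dosage", "requirement", "level", "amount"),
            modifier_category="Drug",
        )
    )
    onto.add_entity_type(
        EntityType(
            "Variant",
            "variant",
            ("polymorphism", "mutation", "allele"),
            modifier_category="Gene",
        )
    )
    onto.add_entity_type(
        EntityType("Variation", "variation", ("difference", "change"))
    )

    onto.add_role(
        Role(
            "influences",
            "influences",
            ("influence", "influenced", "affects", "affect", "affected",
             "modulates", "modulate"),
        )
    )
    onto.add_role(
        Role(
            "inhibits",
            "inhibits",
            ("inhibit", "inhibited", "represses", "repress", "repressed",
             "antagonizes", "antagonize", "suppresses", "suppress", "blocks",
             "block"),
            parent="influences",
            inverse="isInhibitedBy",
        )
    )
    onto.add_role(
        Role(
            "isInhibitedBy",
            "isInhibitedBy",
            ("is$$inhibited", "is$$repressed", "is$$antagonized",
             "is$$suppressed", "is$$blocked"),
            inverse="inhibits",
        )
    )
    onto.add_role(
        Role(
            "stimulates",
            "stimulates",
            ("stimulate", "stimulated", "activates", "activate", "induces",
             "induce", "induced"),
            parent="influences",
            inverse="isStimulatedBy",
        )
    )
    onto.add_role(
        Role(
            "isStimulatedBy",
            "isStimulatedBy",
            ("is$$stimulated", "is$$activated", "is$$induced"),
            inverse="stimulates",
        )
    )
    onto.add_role(
        Role(
            "isAssociatedWith",
            "isAssociatedWith",
            ("associated", "is$$associated", "associates", "associate",
             "correlates", "correlate", "is$$correlated", "linked",
             "is$$linked"),
            symmetric=True,
        )
    )

    onto.add_key_entity(
        KeyEntity(
            "warfarin",
            "warfarin",
            ("warfarin", "coumadin"),
            "Drug",
            (("drugbank", "DB00682"),),
        )
    )
    onto.add_key_entity(
        KeyEntity("vkorc1", "vkorc1", ("vkorc1",), "Gene", (("entrez", "79001"),))
    )
    onto.add_key_entity(
        KeyEntity("uchl1", "uchl1", ("uchl1", "uch-l1"), "Gene", (("entrez", "7345"),))
    )
    onto.add_key_entity(
        KeyEntity(
            "parkinson=disease",
            "parkinson disease",
            ("parkinson disease", "parkinson's disease"),
            "Phenotype",
            (("mesh", "D010300"),),
        )
    )
    return onto


def fixture_raw_relationships() -> list[RawRelationship]:
    """Four heterogeneous raw relationships that integrate to exactly two
    normalized expressions: two synonym-variant statements of the same fact,
    and an active/passive inverse pair."""
    return [
        RawRelationship(
            "affects",
            RawCompositeEntity.of("VKORC1"),
            RawCompositeEntity.of("warfarin", "dose"),
            "10000001",
            "VKORC1 affects warfarin dose.",
        ),
        RawRelationship(
            "influences",
            RawCompositeEntity.of("vkorc1"),
            RawCompositeEntity.of("coumadin", "requirements"),
            "10000002",
            "VKORC1 influences coumadin requirements.",
        ),
        RawRelationship(
            "is$$inhibited",
            RawCompositeEntity.of("vkorc1", "level"),
            RawCompositeEntity.of("warfarin"),
            "10000003",
            "The VKORC1 level is inhibited by warfarin.",
        ),
        RawRelationship(
            "represses",
            RawCompositeEntity.of("warfarin"),
            RawCompositeEntity.of("vkorc1", "expression"),
            "10000004",
            "Warfarin represses VKORC1 expression.",
        ),
    ]


def nested_entity_tokens() -> RawCompositeEntity:
    """The worked composite entity ``coumadin requirements differences``
    (from the text "differences in coumadin requirements")."""
    return RawCompositeEntity.of("coumadin", "requirements", "differences")


def provenance_example() -> RawRelationship:
    """A gene-disease association with real-looking sentence provenance."""
    return RawRelationship(
        "linked",
        RawCompositeEntity.of("uchl1"),
        RawCompositeEntity.of("parkinson", "disease"),
        "14522054",
        "Neuronal ubiquitin C-terminal hydrolase (UCH-L1) has been linked to "
        "Parkinson's disease (PD), the progression of certain nonneuronal "
        "tumors, and neuropathic pain",
    )


def figure_fixture() -> tuple[Ontology, list[RawRelationship]]:
    return fixture_ontology(), fixture_raw_relationships()


# ---------------------------------------------------------------------------
# ground-truth generator


@dataclass(frozen=True)
class GroundTruthFact:
    fact_id: str
    role_id: str
    subject: NormalizedEntity
    object: NormalizedEntity
    n_paraphrases: int


@dataclass(frozen=True)
class GeneratorConfig:
    n_facts: int = 100
    paraphrases_per_fact: int = 5
    p_passive: float = 0.3
    p_inverse_orientation: float = 0.3
    p_synonym_substitution: float = 0.7
    seed: int = 0

    def __post_init__(self):
        for name in ("p_passive", "p_inverse_orientation", "p_synonym_substitution"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_facts < 0 or self.paraphrases_per_fact < 0:
            raise ValueError("counts must be non-negative")


def _entity_specs(onto: Ontology) -> list[NormalizedEntity]:
    """Enumerate normalizable entity structures over the ontology: bare key
    entities, single-wrap composites whose type label resolves under the key
    category, and double wraps under unrestricted outer types."""
    specs: list[NormalizedEntity] = []
    singles: list[NormalizedEntity] = []
    for ke in onto.lexicon.values():
        base = NormalizedEntity(key_id=ke.id)
        specs.append(base)
        for et in onto.entity_types.values():
            if et.id in ("Gene", "Drug", "Phenotype", "Disease"):
                continue
            if et.modifier_category == ke.category:
                singles.append(NormalizedEntity(type_id=et.id, modified=base))
    specs.extend(singles)
    for inner in singles:
        for et in onto.entity_types.values():
            if et.modifier_category is None and et.id not in (
                "Gene", "Drug", "Phenotype", "Disease",
            ):
                specs.append(NormalizedEntity(type_id=et.id, modified=inner))
    return specs


def _entity_renders(
    entity: NormalizedEntity, onto: Ontology
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All (preferred, variant) token renderings of an entity such that the
    variant normalizes back to the same structure; each render is a token
    tuple, with the preferred rendering listed first."""
    chain = list(reversed(entity.chain()))  # innermost (key) first
    per_node: list[list[tuple[str, ...]]] = []
    for node in chain:
        options: list[tuple[str, ...]] = []
        if node.is_key:
            ke = onto.lexicon[node.key_id]
            for syn in ke.synonyms:
                options.append(tuple(syn.lower().split()))
        else:
            et = onto.entity_types[node.type_id]
            category = entity.innermost_key() and onto.lexicon[entity.innermost_key()].category
            for lbl in et.labels:
                if " " in lbl:
                    continue  # tokens must be whitespace-free
                for form in (lbl.lower(), lbl.lower() + "s"):
                    try:
                        resolved = find_entity_type(form, category, onto)
                    except Exception:
                        continue
                    if resolved is not None and resolved.id == et.id:
                        options.append((form,))
        per_node.append(options)

    renders: list[tuple[str, ...]] = [()]
    for options in per_node:
        renders = [r + opt for r in renders for opt in options]
    preferred = renders[0]
    return [(preferred, r) for r in renders]


def _role_directions(role: Role, onto: Ontology) -> list[tuple[str, bool, str]]:
    """(label, swap_arguments, kind) renderings of a fact held by ``role``.

    kind is 'direct', 'passive' or 'inverse'; passive labels are the ``$$``
    forms of the inverse role (or of the role itself when symmetric).
    """
    out: list[tuple[str, bool, str]] = []
    for lbl in role.labels:
        if "$$" in lbl:
            continue
        out.append((lbl, False, "direct"))
    if role.symmetric:
        for lbl in role.labels:
            kind = "passive" if "$$" in lbl else "inverse"
            out.append((lbl, True, kind))
    elif role.inverse is not None:
        inv = onto.roles[role.inverse]
        for lbl in inv.labels:
            kind = "passive" if "$$" in lbl else "inverse"
            out.append((lbl, True, kind))
    return out


def generate(
    config: GeneratorConfig, onto: Ontology
) -> tuple[list[RawRelationship], dict]:
    """Sample distinct ground-truth facts and render each as heterogeneous
    raw paraphrases.  Returns the raw records and a truth map linking every
    record back to its fact.

    When every transformation probability is zero all paraphrases of a fact
    are string-identical (the degenerate case); otherwise paraphrases of one
    fact are kept pairwise distinct by falling back to the first unused
    variant whenever a sampled rendering repeats.
    """
    rng = random.Random(config.seed)
    from .normalize import expression_key, NormalizedRelationship

    entity_specs = _entity_specs(onto)
    # canonical representative role per inverse pair, plus symmetric/plain roles
    roles = []
    for role in onto.roles.values():
        if role.inverse is not None and role.inverse < role.id:
            continue
        roles.append(role)

    seen_expr: set = set()
    facts: list[GroundTruthFact] = []
    attempts = 0
    while len(facts) < config.n_facts:
        attempts += 1
        if attempts > 100 * max(config.n_facts, 1) + 1000:
            raise RuntimeError(
                "fact space too small for the requested number of distinct facts"
            )
        role = rng.choice(roles)
        subj = rng.choice(entity_specs)
        obj = rng.choice(entity_specs)
        if subj == obj:
            continue
        probe = NormalizedRelationship(role.id, subj, obj, (("1", "probe"),))
        ekey = expression_key(probe, onto)
        if ekey in seen_expr:
            continue
        seen_expr.add(ekey)
        facts.append(
            GroundTruthFact(
                fact_id=f"fact{len(facts):04d}",
                role_id=role.id,
                subject=subj,
                object=obj,
                n_paraphrases=config.paraphrases_per_fact,
            )
        )

    raws: list[RawRelationship] = []
    raw_to_fact: list[str] = []
    any_variation = (
        config.p_passive > 0
        or config.p_inverse_orientation > 0
        or config.p_synonym_substitution > 0
    )
    pmid_counter = 20000000

    truth_facts: dict[str, dict] = {}
    for fact in facts:
        role = onto.roles[fact.role_id]
        directions = _role_directions(role, onto)
        subj_renders = _entity_renders(fact.subject, onto)
        obj_renders = _entity_renders(fact.object, onto)

        # full variant space, deterministically shuffled for the fallback walk
        space = [
            (d, sr, orr)
            for d in directions
            for sr in subj_renders
            for orr in obj_renders
        ]
        fallback = list(space)
        rng.shuffle(fallback)

        used: set[tuple] = set()
        for _ in range(fact.n_paraphrases):
            use_passive = config.p_passive > 0 and rng.random() < config.p_passive
            use_inverse = (
                config.p_inverse_orientation > 0
                and rng.random() < config.p_inverse_orientation
            )
            use_syn = (
                config.p_synonym_substitution > 0
                and rng.random() < config.p_synonym_substitution
            )
            wanted_kind = (
                "passive" if use_passive else ("inverse" if use_inverse else "direct")
            )
            candidates = [d for d in directions if d[2] == wanted_kind] or [
                d for d in directions if d[2] == "direct"
            ]
            direction = rng.choice(candidates) if use_syn else candidates[0]
            if use_syn:
                sr = rng.choice(subj_renders)
                orr = rng.choice(obj_renders)
            else:
                sr = subj_renders[0]
                orr = obj_renders[0]
            choice = (direction, sr, orr)
            surface = _surface(choice)
            if any_variation and surface in used:
                for alt in fallback:
                    if _surface(alt) not in used:
                        choice = alt
                        surface = _surface(choice)
                        break
            used.add(surface)

            (label, swap, _), (_, subj_tokens), (_, obj_tokens) = choice
            s_tokens, o_tokens = (obj_tokens, subj_tokens) if swap else (subj_tokens, obj_tokens)
            pmid_counter += 1
            sentence = (
                " ".join(s_tokens)
                + f" {label.replace('$$', ' ')} "
                + " ".join(o_tokens)
                + "."
            )
            raws.append(
                RawRelationship(
                    raw_type=label,
                    subject=RawCompositeEntity(s_tokens),
                    object=RawCompositeEntity(o_tokens),
                    pmid=str(pmid_counter),
                    sentence=sentence,
                )
            )
            raw_to_fact.append(fact.fact_id)

        probe = NormalizedRelationship(
            fact.role_id, fact.subject, fact.object, (("1", "probe"),)
        )
        truth_facts[fact.fact_id] = {
            "role": fact.role_id,
            "subject": fact.subject.individual_id(onto),
            "object": fact.object.individual_id(onto),
            "expression": list(expression_key(probe, onto)),
        }

    truth = {
        "facts": truth_facts,
        "raw_to_fact": {str(i): fid for i, fid in enumerate(raw_to_fact)},
    }
    return raws, truth


def _surface(choice) -> tuple:
    (label, swap, _), (_, subj_tokens), (_, obj_tokens) = choice
    s, o = (obj_tokens, subj_tokens) if swap else (subj_tokens, obj_tokens)
    return (label, s, o)
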