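"""Knowledge-base construction, materialization, querying and export."""

import random

import pytest

from phare import (
    KnowledgeBase,
    Triple,
    build_kb,
    export_gml,
    export_rdf,
    import_rdf,
    integrate,
    materialize,
    provenance_example,
    query,
    subnetwork,
)
from phare.kb import ConsistencyError, TYPE_PREDICATE
from phare.normalize import (
    NormalizedEntity,
    NormalizedRelationship,
    NormalizationOutcome,
)


@pytest.fixture()
def fig_kb(fig):
    onto, raws = fig
    raws = raws + [provenance_example()]
    outcome = integrate(raws, onto)
    return build_kb(outcome, onto), onto


# -- build_kb -----------------------------------------------------------------


def test_merged_fact_has_two_provenance_sentences(fig_kb):
    kb, onto = fig_kb
    t = kb.get(("vkorc1", "influences", "warfarin=dose"))
    assert t is not None and len(t.provenance) == 2


def test_empty_outcome_builds_empty_kb(onto):
    kb = build_kb(NormalizationOutcome(), onto)
    assert len(kb.role_triples(onto)) == 0


def test_association_provenance_string_content(fig_kb):
    kb, onto = fig_kb
    t = kb.get(("uchl1", "isAssociatedWith", "parkinson=disease"))
    assert t is not None
    pmid, sentence = t.provenance[0]
    assert pmid == "14522054"
    assert sentence.startswith("Neuronal ubiquitin C-terminal hydrolase")


def test_individuals_carry_types_and_external_ids(fig_kb):
    kb, onto = fig_kb
    assert "Gene" in kb.individuals["vkorc1"].types
    assert kb.individuals["warfarin"].external_ids["drugbank"] == "DB00682"
    assert "GeneExpression" in kb.individuals["vkorc1=expression"].types


def test_unknown_role_is_consistency_error(onto):
    outcome = NormalizationOutcome(
        normalized=[
            NormalizedRelationship(
                "bogus",
                NormalizedEntity(key_id="warfarin"),
                NormalizedEntity(key_id="vkorc1"),
                (("1", "s"),),
            )
        ]
    )
    with pytest.raises(ConsistencyError):
        build_kb(outcome, onto)


# -- materialization ----------------------------------------------------------


def test_classification_infers_supertype(fig_kb):
    kb, onto = fig_kb
    assert ("vkorc1=expression", TYPE_PREDICATE, "Phenotype") not in kb
    mat = materialize(kb, onto)
    t = mat.get(("vkorc1=expression", TYPE_PREDICATE, "Phenotype"))
    assert t is not None and t.inferred


def test_materialize_is_idempotent_fixpoint(fig_kb):
    kb, onto = fig_kb
    once = materialize(kb, onto)
    twice = materialize(once, onto)
    assert set(once.triples) == set(twice.triples)


def test_materialize_monotone(fig_kb):
    kb, onto = fig_kb
    mat = materialize(kb, onto)
    assert set(t.spo for t in kb.triples) <= set(t.spo for t in mat.triples)
    for t in kb.triples:
        assert not mat.get(t.spo).inferred or t.inferred


def test_inverse_count_on_random_kbs(onto):
    rng = random.Random(13)
    inds = [f"i{k}" for k in range(8)]
    invertible = [r for r in onto.roles.values() if r.inverse and r.inverse != r.id]
    for _ in range(10):
        kb = KnowledgeBase()
        pairs = set()
        n = rng.randrange(1, 15)
        while len(pairs) < n:
            role = rng.choice(invertible)
            s, o = rng.sample(inds, 2)
            if (role.inverse, o, s) in pairs or (role.id, s, o) in pairs:
                continue
            pairs.add((role.id, s, o))
        for s_role, s, o in pairs:
            kb.individual(s)
            kb.individual(o)
            kb.add(Triple(s, s_role, o, provenance=(("1", "x"),)))
        mat = materialize(kb, onto)
        role_triples = [t for t in mat.triples if t.predicate in onto.roles]
        # exactly one inferred inverse per asserted invertible triple
        assert len(role_triples) == 2 * n
        assert sum(t.inferred for t in role_triples) == n


def test_inverse_closure_property_random(onto):
    rng = random.Random(29)
    inds = [f"x{k}" for k in range(10)]
    role_ids = list(onto.roles)
    kb = KnowledgeBase()
    for _ in range(500):
        role = onto.roles[rng.choice(role_ids)]
        s, o = rng.sample(inds, 2)
        kb.individual(s)
        kb.individual(o)
        kb.add(Triple(s, role.id, o, provenance=(("1", "s"),)))
    mat = materialize(kb, onto)
    spos = {t.spo for t in mat.triples}
    for t in mat.triples:
        role = onto.roles.get(t.predicate)
        if role is None:
            continue
        if role.inverse and role.inverse != role.id:
            assert (t.object, role.inverse, t.subject) in spos
        if role.symmetric:
            assert (t.object, role.id, t.subject) in spos


# -- query --------------------------------------------------------------------


def test_query_uchl1_returns_association(fig_kb):
    kb, onto = fig_kb
    mat = materialize(kb, onto)
    results = query(mat, ("uchl1", None, None))
    assert any(
        t.predicate == "isAssociatedWith" and t.object == "parkinson=disease"
        for t in results
    )


def test_query_fully_unbound_returns_all(fig_kb):
    kb, _ = fig_kb
    assert len(query(kb, (None, None, None))) == len(kb.triples)


def test_query_exact_missing_pattern_empty(fig_kb):
    kb, _ = fig_kb
    assert query(kb, ("warfarin", "treats", "uchl1")) == []


def test_query_matches_brute_force_on_random_patterns(fig_kb):
    kb, onto = fig_kb
    mat = materialize(kb, onto)
    rng = random.Random(3)
    pool_s = [t.subject for t in mat.triples]
    pool_p = [t.predicate for t in mat.triples]
    pool_o = [t.object for t in mat.triples]
    for _ in range(100):
        s = rng.choice(pool_s) if rng.random() < 0.5 else None
        p = rng.choice(pool_p) if rng.random() < 0.5 else None
        o = rng.choice(pool_o) if rng.random() < 0.5 else None
        expected = [
            t for t in mat.triples
            if (s is None or t.subject == s)
            and (p is None or t.predicate == p)
            and (o is None or t.object == o)
        ]
        assert sorted(query(mat, (s, p, o)), key=lambda t: t.spo) == sorted(
            expected, key=lambda t: t.spo
        )


# -- RDF round-trip -----------------------------------------------------------


@pytest.mark.parametrize("fmt", ["turtle", "nt"])
def test_kb_round_trip(fig_kb, tmp_path, fmt):
    kb, onto = fig_kb
    mat = materialize(kb, onto)
    path = tmp_path / f"kb.{fmt}"
    export_rdf(mat, path, fmt)
    loaded = import_rdf(path, fmt)
    assert set(loaded.triples) == set(mat.triples)
    assert set(loaded.individuals) == set(mat.individuals)
    for k, ind in mat.individuals.items():
        assert loaded.individuals[k].external_ids == ind.external_ids


def test_round_trip_preserves_two_provenance_comments(fig_kb, tmp_path):
    kb, onto = fig_kb
    path = tmp_path / "kb.ttl"
    export_rdf(kb, path)
    text = path.read_text()
    assert '"[10000001, VKORC1 affects warfarin dose.]"' in text
    assert '"[10000002, VKORC1 influences coumadin requirements.]"' in text
    loaded = import_rdf(path)
    assert len(loaded.get(("vkorc1", "influences", "warfarin=dose")).provenance) == 2


def test_empty_kb_round_trip(tmp_path):
    path = tmp_path / "kb.ttl"
    export_rdf(KnowledgeBase(), path)
    assert len(import_rdf(path).triples) == 0


# -- subnetwork / GML ---------------------------------------------------------


def _kb_with_sentence_counts(onto):
    """focus-A linked by 6 sentences, focus-B by 2."""
    kb = KnowledgeBase()
    for name in ("focus", "a", "b"):
        kb.individual(name)
    prov_a = tuple((str(500 + i), f"sentence {i}") for i in range(6))
    prov_b = tuple((str(600 + i), f"other {i}") for i in range(2))
    kb.add(Triple("focus", "isAssociatedWith", "a", provenance=prov_a))
    kb.add(Triple("focus", "isAssociatedWith", "b", provenance=prov_b))
    return kb


def test_subnetwork_sentence_threshold(onto):
    kb = _kb_with_sentence_counts(onto)
    g = subnetwork(kb, "focus", onto, min_sentences=5)
    assert "a" in g.nodes and "b" not in g.nodes


def test_subnetwork_threshold_is_strictly_greater(onto):
    kb = _kb_with_sentence_counts(onto)
    g = subnetwork(kb, "focus", onto, min_sentences=6)
    assert "a" not in g.nodes  # exactly 6 sentences is not > 6


def test_subnetwork_min_zero_keeps_single_edge(onto):
    kb = KnowledgeBase()
    kb.individual("x")
    kb.individual("y")
    kb.add(Triple("x", "influences", "y", provenance=(("1", "s"),)))
    g = subnetwork(kb, "x", onto, min_sentences=0)
    assert g.has_edge("x", "y")


def test_subnetwork_excludes_typing_triples(fig_kb):
    kb, onto = fig_kb
    mat = materialize(kb, onto)
    g = subnetwork(mat, "uchl1", onto, min_sentences=0)
    assert "Gene" not in g.nodes and "Phenotype" not in g.nodes


def test_subnetwork_unknown_focus_errors(fig_kb):
    kb, onto = fig_kb
    with pytest.raises(KeyError):
        subnetwork(kb, "nobody", onto)


def test_edge_labels_top_two_by_frequency(onto):
    kb = KnowledgeBase()
    kb.individual("g")
    kb.individual("d")
    provs = {
        "influences": tuple((str(i), f"s{i}") for i in range(4)),
        "inhibits": tuple((str(10 + i), f"t{i}") for i in range(2)),
        "isAssociatedWith": ((str(20), "u0"),),
    }
    for role, prov in provs.items():
        kb.add(Triple("g", role, "d", provenance=prov))
    g = subnetwork(kb, "g", onto, min_sentences=0, top_labels=2)
    assert g.edges["g", "d"]["label"] == "influences, inhibits"


def test_gml_export_counts(tmp_path, onto):
    kb = _kb_with_sentence_counts(onto)
    g = subnetwork(kb, "focus", onto, min_sentences=0)
    path = tmp_path / "net.gml"
    export_gml(g, path)
    text = path.read_text()
    assert text.count("node [") == g.number_of_nodes()
    assert text.count("edge [") == g.number_of_edges()
    import networkx as nx

    back = nx.read_gml(path)
    assert set(back.nodes) == set(g.nodes)


def test_gml_empty_graph(tmp_path):
    import networkx as nx

    path = tmp_path / "empty.gml"
    export_gml(nx.Graph(), path)
    assert "graph" in path.read_text()


def test_subnetwork_labels_match_gml(fig_kb, tmp_path):
    kb, onto = fig_kb
    g = subnetwork(kb, "warfarin", onto, min_sentences=0, top_labels=2)
    path = tmp_path / "w.gml"
    export_gml(g, path)
    import networkx as nx

    back = nx.read_gml(path)
    for a, b, data in g.edges(data=True):
        assert back.edges[a, b]["label"] == data["label"]
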