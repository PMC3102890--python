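"""Normalization steps 1-4, integration, and the refinement report."""

import random

import pytest

from phare import (
    NormalizationFailure,
    RawCompositeEntity,
    RawRelationship,
    assemble,
    expression_key,
    integrate,
    nested_entity_tokens,
    normalize_entity,
    normalize_type,
    refinement_report,
)
from phare.normalize import (
    read_raw_relationships,
    write_raw_relationships,
)


# -- step 1/2: composite entities -------------------------------------------


def test_nested_composite_entity(onto):
    ent = normalize_entity(nested_entity_tokens(), onto)
    assert ent.type_id == "Variation"
    assert ent.modified.type_id == "DrugDose"
    assert ent.modified.modified.key_id == "warfarin"
    assert ent.modified.modified.modified is None
    # synonym replaced by the preferred name in the individual id
    assert ent.individual_id(onto) == "warfarin=dose=variation"


def test_atomic_key_entity_unchanged(onto):
    ent = normalize_entity(RawCompositeEntity.of("VKORC1"), onto)
    assert ent.is_key and ent.key_id == "vkorc1"


def test_level_scope_disambiguation(onto):
    gene = normalize_entity(RawCompositeEntity.of("vkorc1", "level"), onto)
    drug = normalize_entity(RawCompositeEntity.of("warfarin", "level"), onto)
    assert gene.type_id == "GeneExpression"
    assert drug.type_id == "DrugDose"


def test_multiword_key_matched_longest_first(onto):
    ent = normalize_entity(RawCompositeEntity.of("parkinson", "disease"), onto)
    assert ent.is_key and ent.key_id == "parkinson=disease"


def test_unknown_key_fails_at_key_stage(onto):
    with pytest.raises(NormalizationFailure) as exc:
        normalize_entity(RawCompositeEntity.of("mystery", "expression"), onto)
    assert exc.value.stage == "key" and exc.value.token == "mystery"


def test_unknown_modifier_fails_with_token(onto):
    with pytest.raises(NormalizationFailure) as exc:
        normalize_entity(RawCompositeEntity.of("warfarin", "gibberish"), onto)
    assert exc.value.stage == "modifier" and exc.value.token == "gibberish"


def test_first_seen_composition_appends_one_axiom(onto):
    assert onto.axioms == []
    normalize_entity(nested_entity_tokens(), onto)
    assert len(onto.axioms) == 1
    ax = onto.axioms[0]
    assert (ax.outer, ax.inner) == ("Variation", "DrugDose")
    # observed again: no second copy
    normalize_entity(nested_entity_tokens(), onto)
    assert len(onto.axioms) == 1


def test_declared_modifier_restriction_not_reasserted(onto):
    normalize_entity(RawCompositeEntity.of("warfarin", "dose"), onto)
    assert onto.axioms == []  # DrugDose already carries the Drug restriction


def test_composite_tokens_must_be_whitespace_free():
    with pytest.raises(ValueError):
        RawCompositeEntity.of("two words")
    with pytest.raises(ValueError):
        RawCompositeEntity(())


# -- step 3: relationship type ----------------------------------------------


def test_normalize_type_examples(onto):
    assert normalize_type("inhibits", onto)[0].id == "inhibits"
    assert normalize_type("antagonize", onto)[0].id == "inhibits"
    role, orientation = normalize_type("is$$inhibited", onto)
    assert role.id == "isInhibitedBy" and orientation == "as-stated"


def test_unmatched_type_feeds_refinement(onto):
    with pytest.raises(NormalizationFailure) as exc:
        normalize_type("potentiates", onto)
    assert exc.value.stage == "type"


# -- step 4: assembly --------------------------------------------------------


def _ents(onto):
    a = normalize_entity(RawCompositeEntity.of("vkorc1"), onto)
    b = normalize_entity(RawCompositeEntity.of("warfarin"), onto)
    return a, b


def test_assemble_inverse_pair(onto):
    a, b = _ents(onto)
    rels = assemble(onto.roles["isInhibitedBy"], a, b, [("1", "s")])
    assert len(rels) == 2
    base, derived = rels
    assert base.role_id == "isInhibitedBy" and not base.derived_by_inverse
    assert derived.role_id == "inhibits" and derived.derived_by_inverse
    assert (derived.subject, derived.object) == (b, a)


def test_assemble_symmetric_swap(onto):
    a, b = _ents(onto)
    rels = assemble(onto.roles["isAssociatedWith"], a, b, [("1", "s")])
    assert len(rels) == 2
    assert {r.role_id for r in rels} == {"isAssociatedWith"}
    assert (rels[1].subject, rels[1].object) == (b, a)


def test_assemble_plain_role_is_singleton(onto):
    a, b = _ents(onto)
    rels = assemble(onto.roles["influences"], a, b, [("1", "s")])
    assert len(rels) == 1 and not rels[0].derived_by_inverse


# -- integration --------------------------------------------------------------


def test_four_fixture_raws_give_two_expressions(fig):
    onto, raws = fig
    outcome = integrate(raws, onto)
    assert outcome.n_input == 4
    assert not outcome.failed
    assert outcome.n_expressions == 2


def test_merged_provenance_concatenated(fig):
    onto, raws = fig
    outcome = integrate(raws, onto)
    by_id = {r.identity(onto): r for r in outcome.normalized}
    merged = by_id[("influences", "vkorc1", "warfarin=dose")]
    assert {p[0] for p in merged.provenance} == {"10000001", "10000002"}


def test_inverse_twin_merges_with_asserted(fig):
    onto, raws = fig
    outcome = integrate(raws, onto)
    by_id = {r.identity(onto): r for r in outcome.normalized}
    inh = by_id[("inhibits", "warfarin", "vkorc1=expression")]
    inv = by_id[("isInhibitedBy", "vkorc1=expression", "warfarin")]
    # both carry both sentences and neither is purely derived
    assert {p[0] for p in inh.provenance} == {"10000003", "10000004"}
    assert {p[0] for p in inv.provenance} == {"10000003", "10000004"}
    assert not inh.derived_by_inverse and not inv.derived_by_inverse


def test_empty_input_empty_outcome(onto):
    outcome = integrate([], onto)
    assert outcome.n_input == 0 and not outcome.normalized and not outcome.failed


def test_conservation(fig):
    onto, raws = fig
    raws = raws + [
        RawRelationship("potentiates", RawCompositeEntity.of("warfarin"),
                        RawCompositeEntity.of("vkorc1"), "7", "w potentiates v."),
    ]
    outcome = integrate(raws, onto)
    assert len(outcome.normalized_sources) + len(outcome.failed) == outcome.n_input


def test_order_invariance(fig):
    onto, raws = fig
    rng = random.Random(5)
    baseline = integrate(raws, fig[0])
    base_ids = {r.identity(onto) for r in baseline.normalized}
    for _ in range(5):
        shuffled = list(raws)
        rng.shuffle(shuffled)
        out = integrate(shuffled, fig[0])
        assert {r.identity(onto) for r in out.normalized} == base_ids
        assert set(out.expression_counts) == set(baseline.expression_counts)


def test_inverse_closure_of_integration(fig):
    onto, raws = fig
    outcome = integrate(raws, onto)
    present = {r.identity(onto) for r in outcome.normalized}
    for role_id, s, o in present:
        inv = onto.roles[role_id].inverse
        if inv is not None:
            assert (inv, o, s) in present


def test_idempotence_on_surface_forms(fig):
    onto, raws = fig
    first = integrate(raws, onto)
    # re-render every normalized relationship with preferred surface forms
    rendered = []
    for i, rel in enumerate(r for r in first.normalized if not r.derived_by_inverse):
        rendered.append(
            RawRelationship(
                raw_type=onto.roles[rel.role_id].preferred_label,
                subject=RawCompositeEntity(rel.subject.surface_tokens(onto)),
                object=RawCompositeEntity(rel.object.surface_tokens(onto)),
                pmid=str(900000 + i),
                sentence=f"rendered {i}",
            )
        )
    second = integrate(rendered, onto)
    assert not second.failed
    assert set(second.expression_counts) == set(first.expression_counts)


def test_partial_failure_fails_whole_relationship(onto):
    raw = RawRelationship(
        "inhibits",
        RawCompositeEntity.of("warfarin"),
        RawCompositeEntity.of("vkorc1", "gibberish"),
        "42",
        "w inhibits v gibberish.",
    )
    outcome = integrate([raw], onto)
    assert not outcome.normalized
    assert outcome.failed[0].stage == "modifier"
    assert outcome.failed[0].token == "gibberish"


# -- refinement report --------------------------------------------------------


def _failing_raw(raw_type, i):
    return RawRelationship(
        raw_type,
        RawCompositeEntity.of("warfarin"),
        RawCompositeEntity.of("vkorc1"),
        str(100 + i),
        f"sentence {i}",
    )


def test_refinement_counts_and_ranks(onto):
    raws = [_failing_raw("potentiates", i) for i in range(3)]
    raws.append(_failing_raw("exacerbates", 9))
    outcome = integrate(raws, onto)
    report = refinement_report(outcome)
    assert report[0].term == "potentiates" and report[0].count == 3
    assert report[0].kind == "role"
    assert report[0].example_sentence == "sentence 0"


def test_refinement_empty_when_no_failures(fig):
    onto, raws = fig
    assert refinement_report(integrate(raws, onto)) == []


def test_refinement_ties_break_lexicographically(onto):
    raws = [_failing_raw("zeta", 1), _failing_raw("alpha", 2)]
    report = refinement_report(integrate(raws, onto))
    assert [c.term for c in report] == ["alpha", "zeta"]


# -- raw relationship I/O -----------------------------------------------------


@pytest.mark.parametrize("fmt", ["jsonl", "tsv"])
def test_raw_io_round_trip(fig_raws, tmp_path, fmt):
    path = tmp_path / f"raws.{fmt}"
    write_raw_relationships(fig_raws, path, fmt)
    assert read_raw_relationships(path, fmt) == fig_raws
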