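"""Annotation records: serialization canon, round trips, validation."""

import json
import re

import pytest

from litanno import fixtures, store
from litanno.model import (Annotation, EquationLocalizer, FigureLocalizer,
                           FunctionDesc, IdFactory, NumericalTraceDesc,
                           Parameter, PointValueDesc, PositionLocalizer,
                           Relationship, SerializationError, TableLocalizer,
                           TextLocalizer, TraceAxis, DependentAxis,
                           ValuesCompound, ValuesSimple, DeserializationError,
                           deserialize, new_id, serialize, validate)
from litanno.vocab import OntologyTerm


def simple(mags=(1.0,), unit="mV", stat="raw"):
    return ValuesSimple(tuple(mags), unit, stat)


def minimal_annotation(aid="a-1", **kw):
    defaults = dict(publication_id="PMID_1", localizer=FigureLocalizer("1"))
    defaults.update(kw)
    return Annotation(annotation_id=aid, **defaults)


# --- round trips and determinism ------------------------------------------

def test_roundtrip_identity_over_generated_corpus(corpus):
    for anns in corpus.publications.values():
        text = serialize(anns)
        assert deserialize(text) == sorted(anns, key=lambda a: a.annotation_id)


def test_serialize_deserialize_serialize_is_byte_stable(corpus):
    for anns in corpus.publications.values():
        text = serialize(anns)
        assert serialize(deserialize(text)) == text


def test_record_order_does_not_affect_bytes(corpus):
    anns = next(iter(corpus.publications.values()))
    assert serialize(anns) == serialize(list(reversed(anns)))


def test_serialized_form_is_pretty_printed_json_list(corpus):
    text = serialize(next(iter(corpus.publications.values())))
    assert text.endswith("\n") and "\r" not in text
    parsed = json.loads(text)
    assert isinstance(parsed, list)
    assert "    \"annotation_id\"" in text  # 4-space indent


def test_unknown_fields_survive_a_round_trip():
    ann = minimal_annotation(extra={"future_field": {"x": 1}})
    back = deserialize(serialize([ann]))[0]
    assert back.extra == {"future_field": {"x": 1}}


# --- deserialization errors ------------------------------------------------

def test_empty_list_gives_empty_corpus():
    assert deserialize("[]") == []


def test_missing_publication_id_names_record_and_field():
    obj = [{"annotation_id": "a", "format_version": "1.0",
            "localizer": {"kind": "figure", "number": "1"}}]
    with pytest.raises(DeserializationError, match=r"record 0: publication_id"):
        deserialize(json.dumps(obj))


def test_malformed_json_reports_line_number():
    with pytest.raises(DeserializationError, match=r"line \d+"):
        deserialize('[\n{"annotation_id": }\n]')


def test_all_five_localizer_variants_round_trip():
    locs = [TextLocalizer("snippet text", 10), FigureLocalizer("2"),
            EquationLocalizer("3"), TableLocalizer("1", row=2, column=3),
            PositionLocalizer(4, (10.0, 20.0, 30.0, 40.0))]
    anns = [minimal_annotation(f"a-{i}", localizer=loc)
            for i, loc in enumerate(locs)]
    back = deserialize(serialize(anns))
    assert [type(a.localizer) for a in back] == [type(l) for l in locs]
    assert [a.localizer for a in back] == locs


# --- serialization refusal -------------------------------------------------

def test_missing_localizer_refused_naming_the_rule():
    ann = minimal_annotation(localizer=None)
    with pytest.raises(SerializationError, match="localizer"):
        serialize([ann])


# --- identifiers -----------------------------------------------------------

def test_new_ids_are_distinct_rfc4122_strings():
    a, b = new_id(), new_id()
    assert a != b
    pattern = r"^[0-9a-f]{8}-[0-9a-f]{4}-4[0-9a-f]{3}-[0-9a-f]{4}-[0-9a-f]{12}$"
    assert re.match(pattern, a) and re.match(pattern, b)


def test_seeded_factory_reproduces_the_same_sequence():
    f1, f2 = IdFactory(42), IdFactory(42)
    run1 = [f1() for _ in range(10)]
    run2 = [f2() for _ in range(10)]
    assert run1 == run2
    assert len(set(run1)) == 10


# --- validation completeness ----------------------------------------------
# each structural invariant has one constructed violation and yields
# exactly one corresponding issue

def _param(desc, type_name="resting_membrane_potential", **kw):
    return Parameter("p-1", type_name, desc, **kw)


VIOLATIONS = [
    ("missing-localizer", minimal_annotation(localizer=None)),
    ("missing-format-version", minimal_annotation(format_version="")),
    ("missing-publication", minimal_annotation(publication_id="")),
    ("empty-snippet", minimal_annotation(localizer=TextLocalizer("", 0))),
    ("bad-offset", minimal_annotation(localizer=TextLocalizer("x", -1))),
    ("bad-number", minimal_annotation(localizer=FigureLocalizer(""))),
    ("bad-table-index", minimal_annotation(localizer=TableLocalizer("1", row=0))),
    ("bad-page", minimal_annotation(localizer=PositionLocalizer(0, (0, 0, 1, 1)))),
    ("bad-box", minimal_annotation(localizer=PositionLocalizer(1, (0, 0, 0, 1)))),
    ("empty-magnitudes",
     minimal_annotation(parameters=(_param(PointValueDesc(simple(()))),))),
    ("unknown-statistic",
     minimal_annotation(parameters=(_param(PointValueDesc(simple(stat="mode"))),))),
    ("bad-sample-size", minimal_annotation(parameters=(
        _param(PointValueDesc(simple((2.5,), "", "sample_size"))),))),
    ("compound-too-small", minimal_annotation(parameters=(
        _param(PointValueDesc(ValuesCompound((simple(),)))),))),
    ("duplicate-statistic-role", minimal_annotation(parameters=(
        _param(PointValueDesc(ValuesCompound((simple(stat="mean"),
                                              simple(stat="mean"))))),))),
    ("mixed-dimensions", minimal_annotation(parameters=(
        _param(PointValueDesc(ValuesCompound((simple(stat="mean"),
                                              simple(unit="Mohm", stat="sem"))))),))),
    ("duplicate-parameter-id", minimal_annotation(parameters=(
        _param(PointValueDesc(simple())),
        _param(PointValueDesc(simple())),))),
    ("trace-length-mismatch", minimal_annotation(parameters=(_param(
        NumericalTraceDesc(TraceAxis("age", "day", (1.0, 2.0)),
                           DependentAxis("d", "mm^-3", (simple(),)))),))),
    ("trace-too-short", minimal_annotation(parameters=(_param(
        NumericalTraceDesc(TraceAxis("age", "day", (1.0,)),
                           DependentAxis("d", "mm^-3", (simple(),)))),))),
    ("trace-not-monotone", minimal_annotation(parameters=(_param(
        NumericalTraceDesc(TraceAxis("age", "day", (1.0, 1.0)),
                           DependentAxis("d", "mm^-3", (simple(), simple())))),))),
    ("unbound-function-symbol", minimal_annotation(parameters=(_param(
        FunctionDesc("a+b", "f", ("a",), ())),))),
    ("bad-expression", minimal_annotation(parameters=(_param(
        FunctionDesc("import os", "f", (), ())),))),
    ("relationship-entities", minimal_annotation(parameters=(
        _param(PointValueDesc(simple()),
               relationship=Relationship("directed",
                                         OntologyTerm("t", "T"), None)),))),
    ("bad-relationship-kind", minimal_annotation(parameters=(
        _param(PointValueDesc(simple()), relationship=Relationship("sideways")),))),
]


@pytest.mark.parametrize("code,ann", VIOLATIONS, ids=[c for c, _ in VIOLATIONS])
def test_each_seeded_violation_yields_exactly_one_matching_issue(code, ann):
    issues = [i for i in validate(ann) if i.severity == "error"]
    assert [i.code for i in issues].count(code) == 1, issues


def test_missing_required_tag_cites_the_missing_root(vocab_tree):
    ann = minimal_annotation(parameters=(
        _param(PointValueDesc(simple()), type_name="neuron_density"),))
    issues = [i for i in validate(ann, vocab_tree) if i.severity == "error"]
    assert len(issues) == 1
    assert issues[0].code == "missing-required-tag"
    assert "sao1813327414" in issues[0].message


def test_pristine_generated_corpus_validates_cleanly(corpus, vocab_tree):
    for ann in corpus.annotations():
        assert [i for i in validate(ann, vocab_tree)
                if i.severity == "error"] == []
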