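"""Corpus queries: filtering, experiment-property joins, harmonization."""

import copy

import pytest

from litanno.measure import parse_quantity
from litanno.model import (NumericalTraceDesc, PointValueDesc, ValuesCompound,
                           ValuesSimple)
from litanno.query import (attach_experiment_properties, filter_parameters,
                           harmonize, rows_to_dataframe)


def full_scan(corpus, predicate):
    out = []
    for did, anns in corpus.publications.items():
        for ann in anns:
            for p in ann.parameters:
                if predicate(did, ann, p):
                    out.append((did, ann.annotation_id, p.parameter_id))
    return sorted(out)


def keys(rows):
    return [(r.document_id, r.annotation_id, r.parameter_id) for r in rows]


# --- filtering -------------------------------------------------------------

def test_no_criteria_returns_every_parameter(corpus, ledger):
    rows = filter_parameters(corpus)
    assert len(rows) == ledger.n_parameters
    assert keys(rows) == full_scan(corpus, lambda *_: True)


def test_type_filter_matches_generator_ledger(corpus, ledger):
    rows = filter_parameters(corpus, type_name="neuron_density")
    assert len(rows) == ledger.per_type_counts["neuron_density"]
    assert keys(rows) == full_scan(
        corpus, lambda d, a, p: p.type_name == "neuron_density")


def test_unknown_type_cites_the_vocabulary(corpus, vocab_tree):
    with pytest.raises(KeyError, match="vocabulary"):
        filter_parameters(corpus, type_name="no_such_type", vocab=vocab_tree)


def test_type_plus_absent_tag_gives_empty_list(corpus):
    rows = filter_parameters(corpus, type_name="neuron_density",
                             tag_ids=["no_such_term"])
    assert rows == []


def test_document_filter(corpus, ledger):
    did = ledger.document_ids[0]
    rows = filter_parameters(corpus, document_id=did)
    assert {r.document_id for r in rows} == {did}


def test_tag_filter_equals_full_scan_oracle(corpus):
    rows = filter_parameters(corpus, tag_ids=["syn_cell_tc"])
    expected = full_scan(corpus, lambda d, a, p: any(
        t.term_id == "syn_cell_tc"
        for t in tuple(a.tags) + tuple(p.required_tag_instances)))
    assert keys(rows) == expected


def test_ancestry_expansion_widens_tag_matches(corpus, vocab_tree):
    exact = filter_parameters(corpus, tag_ids=["sao1813327414"])
    expanded = filter_parameters(corpus, tag_ids=["sao1813327414"],
                                 expand_descendants=True, vocab=vocab_tree)
    # every cell-type tag descends from the Cell root
    assert set(keys(exact)) <= set(keys(expanded))
    assert len(expanded) > len(exact)
    assert all(site in ("annotation", "parameter")
               for r in expanded for site in r.tag_match_sites)


def test_expansion_without_vocabulary_rejected(corpus):
    with pytest.raises(ValueError):
        filter_parameters(corpus, tag_ids=["x"], expand_descendants=True)


def test_adding_criteria_never_enlarges_the_result(corpus, ledger):
    base = filter_parameters(corpus)
    typed = filter_parameters(corpus, type_name="neuron_density")
    typed_doc = filter_parameters(corpus, type_name="neuron_density",
                                  document_id=ledger.document_ids[0])
    typed_doc_tag = filter_parameters(corpus, type_name="neuron_density",
                                      document_id=ledger.document_ids[0],
                                      tag_ids=["syn_cell_tc"])
    assert len(base) >= len(typed) >= len(typed_doc) >= len(typed_doc_tag)
    assert set(keys(typed_doc_tag)) <= set(keys(typed_doc)) <= set(keys(typed))


def test_rows_come_in_stable_order(corpus):
    rows = filter_parameters(corpus)
    assert keys(rows) == sorted(keys(rows))


# --- experiment properties -------------------------------------------------

def test_density_row_gains_its_slice_thickness(corpus, ledger):
    rows = filter_parameters(corpus, type_name="neuron_density")
    rows = attach_experiment_properties(rows, corpus)
    linked = [r for r in rows if r.parameter_id in ledger.linked_area_density_ids]
    assert linked, "generator guarantees at least one linked density"
    for r in linked:
        assert "slice_thickness" in r.experiment_properties
        t = r.experiment_properties["slice_thickness"]
        assert t.unit.dimension == (1, 0, 0, 0, 0, 0, 0)


def test_rows_without_references_pass_through_unchanged(corpus):
    rows = filter_parameters(corpus, type_name="recording_temperature")
    attached = attach_experiment_properties(rows, corpus)
    assert attached == rows


def test_dangling_reference_becomes_a_row_issue(corpus, ledger):
    clone = copy.deepcopy(corpus)
    did, ann_id, _ = ledger.property_links[0]
    for ann in clone.publications[did]:
        if ann.annotation_id == ann_id:
            ann.experiment_property_refs = (("gone", "gone"),)
    rows = filter_parameters(clone, type_name="neuron_density")
    rows = attach_experiment_properties(rows, clone)
    hit = [r for r in rows if r.annotation_id == ann_id]
    assert hit and any("dangling" in i for i in hit[0].issues)


# --- harmonization ---------------------------------------------------------

def harmonized_density_rows(corpus):
    rows = filter_parameters(corpus, type_name="neuron_density")
    rows = attach_experiment_properties(rows, corpus)
    return harmonize(rows, "mm^-3", trace_at=parse_quantity("14 day"))


def test_mixed_units_all_land_in_target_unit(corpus, ledger):
    kept, rejected = harmonized_density_rows(corpus)
    assert all(r.unit == "mm^-3" for r in kept)
    kept_ids = {r.parameter_id for r in kept}
    assert set(ledger.linked_area_density_ids) <= kept_ids
    assert set(ledger.volume_density_ids) <= kept_ids
    assert set(ledger.trace_parameter_ids) <= kept_ids


def test_unlinked_area_densities_rejected_with_reason(corpus, ledger):
    kept, rejected = harmonized_density_rows(corpus)
    rejected_ids = {r.row.parameter_id: r.reason for r in rejected}
    for pid in ledger.unlinked_area_density_ids:
        assert rejected_ids.get(pid) == "missing slice_thickness"
    assert set(rejected_ids).isdisjoint(r.parameter_id for r in kept)


def test_trace_interpolated_at_day_14(corpus, ledger):
    kept, _ = harmonized_density_rows(corpus)
    trace_rows = [r for r in kept if r.parameter_id in ledger.trace_parameter_ids]
    assert trace_rows[0].magnitudes[0] == pytest.approx(ledger.trace_value_at_day14)


def test_row_already_in_target_unit_is_unchanged(corpus, ledger):
    rows = filter_parameters(corpus, type_name="input_resistance")
    kept, _ = harmonize(rows, "Mohm")
    assert kept
    for r in kept:
        assert r.magnitudes == (55.0,) or r.magnitudes  # magnitudes preserved
        assert r.unit == "Mohm"


def test_compound_rows_reduce_to_requested_role(corpus):
    rows = filter_parameters(corpus, type_name="input_resistance")
    kept, _ = harmonize(rows, "Mohm", compound_role="sem")
    assert all(r.statistics == ("sem",) for r in kept)


def test_harmonize_does_not_mutate_the_corpus(corpus):
    before = copy.deepcopy(corpus.publications)
    harmonized_density_rows(corpus)
    assert corpus.publications == before


def test_rejections_carry_machine_readable_reasons(corpus):
    rows = filter_parameters(corpus)
    rows = attach_experiment_properties(rows, corpus)
    kept, rejected = harmonize(rows, "mm^-3", trace_at=parse_quantity("14 day"))
    assert len(kept) + len(rejected) == len(rows)
    assert all(isinstance(r.reason, str) and r.reason for r in rejected)


def test_dataframe_export_has_one_line_per_row(corpus):
    rows = filter_parameters(corpus, type_name="neuron_density")
    df = rows_to_dataframe(rows)
    assert len(df) == len(rows)
    assert list(df["type_name"].unique()) == ["neuron_density"]
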