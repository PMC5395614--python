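"""Corpus queries producing model-ready tables.

The curation workflow ends with a question like "give me every
annotated neuron density, in mm⁻³, at postnatal day 14". Answering it
takes three steps, each an operation here:

1. :func:`filter_parameters` — select parameters by type, tags (with
   optional ancestry expansion), or publication;
2. :func:`attach_experiment_properties` — join each selected parameter
   with the experiment properties (slice thickness, temperature, age …)
   its annotation is linked to;
3. :func:`harmonize` — express every surviving value in one target
   unit, applying the area→volume density conversion when a 2D density
   carries a slice thickness, interpolating numerical traces at the
   requested point, and reducing compound values to a single statistic.

Source annotations are never mutated; rows that cannot be harmonized
are returned separately with machine-readable reasons rather than
raising, so harmonization over a heterogeneous corpus is total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from . import measure
from .measure import QuantityValue, parse_unit
from .model import (Annotation, FunctionDesc, NumericalTraceDesc, Parameter,
                    PointValueDesc, ValuesCompound, ValuesSimple)
from .store import Corpus
from .vocab import VocabularyTree, is_descendant

__all__ = [
    "ParameterRow",
    "Rejection",
    "filter_parameters",
    "attach_experiment_properties",
    "harmonize",
    "rows_to_dataframe",
]


@dataclass(frozen=True)
class ParameterRow:
    """One parameter of one annotation, flattened for tabular use."""

    document_id: str
    annotation_id: str
    parameter_id: str
    type_name: str
    values_kind: str  # simple | compound | trace | function
    magnitudes: tuple[float, ...]
    unit: str
    statistics: tuple[str, ...]
    relationship: str
    tag_labels: tuple[str, ...]
    tag_match_sites: tuple[str, ...] = ()  # where a tag criterion matched
    experiment_properties: dict[str, QuantityValue] = field(default_factory=dict)
    issues: tuple[str, ...] = ()
    parameter: Parameter | None = None  # source object, for harmonization
    source_parameter_id: str | None = None  # provenance of derived rows


@dataclass(frozen=True)
class Rejection:
    row: ParameterRow
    reason: str


def _values_summary(p: Parameter) -> tuple[str, tuple[float, ...], str, tuple[str, ...]]:
    d = p.description
    if isinstance(d, PointValueDesc):
        v = d.values
        if isinstance(v, ValuesSimple):
            return "simple", v.magnitudes, v.unit, (v.statistic,)
        stats = tuple(c.statistic for c in v.components)
        mean = next((c for c in v.components if c.statistic == "mean"),
                    v.components[0])
        return "compound", mean.magnitudes, mean.unit, stats
    if isinstance(d, NumericalTraceDesc):
        return "trace", (), d.dependent.unit, ()
    return "function", (), "", ()


def _rel_summary(p: Parameter) -> str:
    r = p.relationship
    if r.kind == "none":
        return ""
    a = r.entity_a.label if r.entity_a else ""
    b = r.entity_b.label if r.entity_b else ""
    if r.kind == "point":
        return a
    arrow = "->" if r.kind == "directed" else "--"
    return f"{a} {arrow} {b}"


def _row_for(document_id: str, ann: Annotation, p: Parameter,
             sites: tuple[str, ...] = ()) -> ParameterRow:
    kind, mags, unit, stats = _values_summary(p)
    labels = tuple(t.label for t in ann.tags) + tuple(
        t.label for t in p.required_tag_instances)
    return ParameterRow(
        document_id=document_id,
        annotation_id=ann.annotation_id,
        parameter_id=p.parameter_id,
        type_name=p.type_name,
        values_kind=kind,
        magnitudes=mags,
        unit=unit,
        statistics=stats,
        relationship=_rel_summary(p),
        tag_labels=labels,
        tag_match_sites=sites,
        parameter=p,
    )


def _tag_sites(ann: Annotation, p: Parameter, tag_ids: Sequence[str],
               expand: bool, vocab: VocabularyTree | None) -> tuple[str, ...] | None:
    """Match sites for the tag criteria, or None when any criterion
    fails. A tag may match on the annotation or on the parameter's
    required tags; each requested id must match somewhere (conjunction)."""
    sites: list[str] = []
    for wanted in tag_ids:
        found = []
        for t in ann.tags:
            if t.term_id == wanted or (
                    expand and vocab is not None and t.term_id in vocab.terms
                    and wanted in vocab.terms
                    and is_descendant(vocab, t.term_id, wanted)):
                found.append("annotation")
                break
        for t in p.required_tag_instances:
            if t.term_id == wanted or (
                    expand and vocab is not None and t.term_id in vocab.terms
                    and wanted in vocab.terms
                    and is_descendant(vocab, t.term_id, wanted)):
                found.append("parameter")
                break
        if not found:
            return None
        sites.extend(found)
    return tuple(sites)


def filter_parameters(corpus: Corpus, type_name: str | None = None,
                      tag_ids: Sequence[str] | None = None,
                      document_id: str | None = None,
                      expand_descendants: bool = False,
                      vocab: VocabularyTree | None = None) -> list[ParameterRow]:
    """Select parameters matching the conjunction of all given criteria.

    Tag matching is exact by term id, or ancestry-expanded when
    ``expand_descendants`` is set (which requires a vocabulary). Rows
    come back in stable (document, annotation, parameter) order.
    """
    if expand_descendants and vocab is None:
        raise ValueError("expand_descendants requires a vocabulary")
    if type_name is not None and vocab is not None \
            and type_name not in vocab.parameter_types:
        raise KeyError(f"unknown parameter type {type_name!r} "
                       f"(not in the loaded vocabulary)")
    rows: list[ParameterRow] = []
    for did, anns in corpus.publications.items():
        if document_id is not None and did != document_id:
            continue
        for ann in anns:
            for p in ann.parameters:
                if type_name is not None and p.type_name != type_name:
                    continue
                sites: tuple[str, ...] = ()
                if tag_ids:
                    got = _tag_sites(ann, p, tag_ids, expand_descendants, vocab)
                    if got is None:
                        continue
                    sites = got
                rows.append(_row_for(did, ann, p, sites))
    rows.sort(key=lambda r: (r.document_id, r.annotation_id, r.parameter_id))
    return rows


def _property_quantity(p: Parameter) -> QuantityValue | None:
    d = p.description
    if not isinstance(d, PointValueDesc):
        return None
    v = d.values
    if isinstance(v, ValuesCompound):
        try:
            v = measure.reduce_compound(v, "mean")
        except KeyError:
            v = v.components[0]
    return QuantityValue(v.magnitudes, parse_unit(v.unit))


def attach_experiment_properties(rows: list[ParameterRow],
                                 corpus: Corpus) -> list[ParameterRow]:
    """Resolve each row's linked experiment properties to quantities.

    An annotation links experiment properties by (annotation id,
    parameter id) reference pairs; each resolves to the referenced
    parameter's value, keyed by its type name. Dangling references are
    recorded on the row, never fatal.
    """
    by_id = {a.annotation_id: a for a in corpus.annotations()}
    out: list[ParameterRow] = []
    for row in rows:
        ann = by_id.get(row.annotation_id)
        if ann is None or not ann.experiment_property_refs:
            out.append(row)
            continue
        props = dict(row.experiment_properties)
        issues = list(row.issues)
        for ref_ann_id, ref_param_id in ann.experiment_property_refs:
            target_ann = by_id.get(ref_ann_id)
            target = None
            if target_ann is not None:
                target = next((p for p in target_ann.parameters
                               if p.parameter_id == ref_param_id), None)
            if target is None:
                issues.append(f"dangling experiment-property reference "
                              f"({ref_ann_id}, {ref_param_id})")
                continue
            q = _property_quantity(target)
            if q is None:
                issues.append(f"experiment property {ref_param_id} is not a point value")
                continue
            props[target.type_name] = q
        out.append(replace(row, experiment_properties=props, issues=tuple(issues)))
    return out


_AREA_DENSITY_DIM = (-2, 0, 0, 0, 0, 0, 0)
_LENGTH_DIM = (1, 0, 0, 0, 0, 0, 0)


def harmonize(rows: list[ParameterRow], target_unit: str,
              trace_at: QuantityValue | None = None,
              compound_role: str = "mean",
              ) -> tuple[list[ParameterRow], list[Rejection]]:
    """Express every row's value in ``target_unit``.

    Numerical traces are linearly interpolated at ``trace_at``; compound
    values are reduced to their ``compound_role`` component; areal
    densities (length⁻²) are divided by an attached slice-thickness
    property when the target is volumetric (length⁻³). Rows that cannot
    be expressed in the target unit are rejected with a reason instead
    of raising. Source rows are never modified.
    """
    tgt = parse_unit(target_unit)
    kept: list[ParameterRow] = []
    rejected: list[Rejection] = []
    for row in rows:
        p = row.parameter
        if p is None:
            rejected.append(Rejection(row, "row carries no source parameter"))
            continue
        d = p.description
        try:
            if isinstance(d, FunctionDesc):
                rejected.append(Rejection(row, "function-valued parameter"))
                continue
            if isinstance(d, NumericalTraceDesc):
                if trace_at is None:
                    rejected.append(Rejection(row, "numerical trace but no trace_at given"))
                    continue
                q = measure.interpolate_trace(d, trace_at)
            else:
                v = d.values
                if isinstance(v, ValuesCompound):
                    try:
                        v = measure.reduce_compound(v, compound_role)
                    except KeyError as exc:
                        rejected.append(Rejection(row, f"missing {compound_role}: {exc}"))
                        continue
                q = QuantityValue(v.magnitudes, parse_unit(v.unit))

            if q.unit.dimension == tgt.dimension:
                q = measure.convert(q, tgt)
            elif q.unit.dimension == _AREA_DENSITY_DIM and \
                    tgt.dimension == tuple(-3 if i == 0 else 0 for i in range(7)):
                thickness = next(
                    (t for t in row.experiment_properties.values()
                     if t.unit.dimension == _LENGTH_DIM), None)
                if thickness is None:
                    rejected.append(Rejection(row, "missing slice_thickness"))
                    continue
                q = measure.convert(measure.area_to_volume_density(q, thickness), tgt)
            else:
                rejected.append(Rejection(
                    row, f"dimension mismatch: {q.unit} vs {tgt}"))
                continue
        except (measure.UnitError, measure.DimensionError, ValueError) as exc:
            rejected.append(Rejection(row, str(exc)))
            continue
        kept.append(replace(
            row,
            values_kind="simple",
            magnitudes=q.magnitudes,
            unit=str(q.unit),
            statistics=(compound_role,) if row.values_kind == "compound"
            else row.statistics,
            source_parameter_id=row.parameter_id,
        ))
    return kept, rejected


def rows_to_dataframe(rows: Iterable[ParameterRow]) -> pd.DataFrame:
    """Flatten rows into a DataFrame; list-valued fields are ';'-joined."""
    records = []
    for r in rows:
        records.append({
            "document_id": r.document_id,
            "annotation_id": r.annotation_id,
            "parameter_id": r.parameter_id,
            "type_name": r.type_name,
            "values_kind": r.values_kind,
            "magnitudes": ";".join(repr(m) for m in r.magnitudes),
            "unit": r.unit,
            "statistics": ";".join(r.statistics),
            "relationship": r.relationship,
            "tag_labels": ";".join(r.tag_labels),
            "experiment_properties": ";".join(
                f"{k}={v}" for k, v in sorted(r.experiment_properties.items())),
            "issues": ";".join(r.issues),
        })
    return pd.DataFrame.from_records(
        records,
        columns=["document_id", "annotation_id", "parameter_id", "type_name",
                 "values_kind", "magnitudes", "unit", "statistics",
                 "relationship", "tag_labels", "experiment_properties", "issues"],
    )
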