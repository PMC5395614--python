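"""The annotation record and its recursive value-type hierarchy.

An annotation is one localized, tagged, commented record tied to a
publication. It may carry modeling parameters — typed experimental
values that are point values, fitted functions, or numerical traces,
each either a simple value (magnitudes + unit + statistic role) or a
compound value (interdependent statistics such as mean ± sem with a
sample size). Exactly one localizer pins the annotation inside the
document: a text snippet with character offset, a figure / equation /
table number, or a page + bounding box.

Serialization is canonical on purpose: fixed field order, 4-space
indent, LF newlines, records sorted by annotation id. Corpora live in
version control, and a canonical text form keeps diffs minimal and
merges tractable.
"""

from __future__ import annotations

import json
import random
import re
import uuid
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence, Union

from . import measure
from .vocab import OntologyTerm, VocabularyTree, validate_tag_choice

__all__ = [
    "FORMAT_VERSION",
    "STATISTIC_ROLES",
    "Annotation",
    "Parameter",
    "Relationship",
    "ValuesSimple",
    "ValuesCompound",
    "PointValueDesc",
    "NumericalTraceDesc",
    "TraceAxis",
    "DependentAxis",
    "FunctionDesc",
    "TextLocalizer",
    "FigureLocalizer",
    "EquationLocalizer",
    "TableLocalizer",
    "PositionLocalizer",
    "Localizer",
    "Issue",
    "IdFactory",
    "new_id",
    "serialize",
    "deserialize",
    "validate",
    "SerializationError",
    "DeserializationError",
]

FORMAT_VERSION = "1.0"

# Closed vocabulary of statistic roles a simple value may carry.
# "raw" is a published number that is not a sample statistic;
# "deviation" covers an unlabeled "±" whose nature (sd vs sem) the
# source does not state.
STATISTIC_ROLES = frozenset({
    "raw", "mean", "median", "sd", "sem", "var", "min", "max",
    "ci_lower", "ci_upper", "sample_size", "deviation",
})


class SerializationError(ValueError):
    def __init__(self, issues: list["Issue"]):
        self.issues = issues
        super().__init__(
            "refusing to serialize invalid annotations:\n"
            + "\n".join(f"  {i}" for i in issues)
        )


class DeserializationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Value types

@dataclass(frozen=True)
class ValuesSimple:
    """One or more magnitudes with a unit and a statistic role."""

    magnitudes: tuple[float, ...]
    unit: str
    statistic: str = "raw"

    def quantity(self) -> measure.QuantityValue:
        return measure.QuantityValue(self.magnitudes, measure.parse_unit(self.unit))


@dataclass(frozen=True)
class ValuesCompound:
    """Interdependent simple values, e.g. mean ± sem with sample size."""

    components: tuple[ValuesSimple, ...]


Values = Union[ValuesSimple, ValuesCompound]


@dataclass(frozen=True)
class PointValueDesc:
    """A value not part of a functional relationship or trace."""

    values: Values


@dataclass(frozen=True)
class TraceAxis:
    type_name: str
    unit: str
    magnitudes: tuple[float, ...]


@dataclass(frozen=True)
class DependentAxis:
    type_name: str
    unit: str
    values: tuple[Values, ...]


@dataclass(frozen=True)
class NumericalTraceDesc:
    """Paired independent/dependent series stored as one parameter
    (e.g. neuron density tabulated against animal age)."""

    independent: TraceAxis
    dependent: DependentAxis


@dataclass(frozen=True)
class FunctionDesc:
    """A fitted analytical function with its fitted parameter values,
    e.g. a Boltzmann steady-state inactivation curve
    ``1/(1+exp((V-V_half)/k))`` with fitted V_half and k."""

    expression: str
    dependent_name: str
    independent_names: tuple[str, ...]
    fitted_parameters: tuple[tuple[str, Values], ...]


Description = Union[PointValueDesc, NumericalTraceDesc, FunctionDesc]


# ---------------------------------------------------------------------------
# Relationship and localizers

@dataclass(frozen=True)
class Relationship:
    """Entities a parameter relates: none, a single entity, or two
    entities linked directionally (entity_a is the source) or not."""

    kind: str = "none"  # none | point | directed | undirected
    entity_a: OntologyTerm | None = None
    entity_b: OntologyTerm | None = None


@dataclass(frozen=True)
class TextLocalizer:
    snippet: str
    start_offset: int  # 0-based code-point index into the reference text


@dataclass(frozen=True)
class FigureLocalizer:
    number: str


@dataclass(frozen=True)
class EquationLocalizer:
    number: str


@dataclass(frozen=True)
class TableLocalizer:
    number: str
    row: int | None = None  # 1-based
    column: int | None = None  # 1-based


@dataclass(frozen=True)
class PositionLocalizer:
    page: int  # 1-based
    box: tuple[float, float, float, float]  # x, y, w, h in PDF points, origin bottom-left


Localizer = Union[TextLocalizer, FigureLocalizer, EquationLocalizer,
                  TableLocalizer, PositionLocalizer]

_LOCALIZER_KINDS = {
    TextLocalizer: "text",
    FigureLocalizer: "figure",
    EquationLocalizer: "equation",
    TableLocalizer: "table",
    PositionLocalizer: "position",
}


# ---------------------------------------------------------------------------
# Parameter and annotation

@dataclass(frozen=True)
class Parameter:
    parameter_id: str
    type_name: str
    description: Description
    relationship: Relationship = Relationship()
    required_tag_instances: tuple[OntologyTerm, ...] = ()
    is_experiment_property: bool = False


@dataclass
class Annotation:
    annotation_id: str
    publication_id: str
    localizer: Localizer | None
    tags: tuple[OntologyTerm, ...] = ()
    authors: tuple[str, ...] = ()
    format_version: str = FORMAT_VERSION
    comment: str = ""
    parameters: tuple[Parameter, ...] = ()
    experiment_property_refs: tuple[tuple[str, str], ...] = ()
    extra: dict[str, Any] = field(default_factory=dict)  # unknown fields, preserved


# ---------------------------------------------------------------------------
# Identifiers

class IdFactory:
    """RFC-4122 id generator; seeded mode is reproducible for tests and
    synthetic corpora, default mode uses system entropy."""

    def __init__(self, seed: int | None = None):
        self._rng = random.Random(seed) if seed is not None else None

    def __call__(self) -> str:
        if self._rng is None:
            return str(uuid.uuid4())
        return str(uuid.UUID(int=self._rng.getrandbits(128), version=4))


def new_id(factory: IdFactory | None = None) -> str:
    """A fresh RFC-4122 identifier (8-4-4-4-12 hex)."""
    return (factory or IdFactory())()


# ---------------------------------------------------------------------------
# Issues and validation

@dataclass(frozen=True)
class Issue:
    """One validation finding. Issues are data, not exceptions."""

    code: str
    path: str
    message: str
    severity: str = "error"  # error | warning

    def __str__(self) -> str:
        return f"[{self.severity}] {self.path}: {self.code} — {self.message}"


def _check_values(values: Values, path: str, issues: list[Issue]) -> None:
    if isinstance(values, ValuesSimple):
        if len(values.magnitudes) < 1:
            issues.append(Issue("empty-magnitudes", path,
                                "magnitudes must hold one or more values"))
        if values.statistic not in STATISTIC_ROLES:
            issues.append(Issue("unknown-statistic", path,
                                f"unknown statistic role {values.statistic!r}"))
        if values.statistic == "sample_size":
            for m in values.magnitudes:
                if m <= 0 or m != int(m):
                    issues.append(Issue("bad-sample-size", path,
                                        f"sample_size must be a positive integer, got {m}"))
            try:
                if not measure.parse_unit(values.unit).is_dimensionless:
                    issues.append(Issue("bad-sample-size", path,
                                        "sample_size must be dimensionless"))
            except measure.UnitError:
                pass
        return
    # compound
    if len(values.components) < 2:
        issues.append(Issue("compound-too-small", path,
                            "compound values need at least 2 components"))
    roles = [c.statistic for c in values.components]
    for role in sorted({r for r in roles if roles.count(r) > 1}):
        issues.append(Issue("duplicate-statistic-role", path,
                            f"duplicate statistic role {role!r} in compound value"))
    dims = set()
    for j, comp in enumerate(values.components):
        _check_values(comp, f"{path}.components[{j}]", issues)
        if comp.statistic == "sample_size":
            continue
        try:
            dims.add(measure.parse_unit(comp.unit).dimension)
        except measure.UnitError:
            issues.append(Issue("unparseable-unit", f"{path}.components[{j}]",
                                f"cannot parse unit {comp.unit!r}", severity="warning"))
    if len(dims) > 1:
        issues.append(Issue("mixed-dimensions", path,
                            "compound components must share one dimension "
                            "(sample_size excepted)"))


def _check_localizer(loc: Localizer | None, path: str, issues: list[Issue]) -> None:
    if loc is None:
        issues.append(Issue("missing-localizer", path,
                            "an annotation carries exactly one localizer"))
        return
    if isinstance(loc, TextLocalizer):
        if not loc.snippet:
            issues.append(Issue("empty-snippet", path, "text snippet must be non-empty"))
        if loc.start_offset < 0:
            issues.append(Issue("bad-offset", path,
                                f"start_offset must be >= 0, got {loc.start_offset}"))
    elif isinstance(loc, (FigureLocalizer, EquationLocalizer, TableLocalizer)):
        if not isinstance(loc.number, str) or not loc.number:
            issues.append(Issue("bad-number", path,
                                "figure/equation/table numbers are non-empty strings"))
        if isinstance(loc, TableLocalizer):
            for attr in ("row", "column"):
                v = getattr(loc, attr)
                if v is not None and v < 1:
                    issues.append(Issue("bad-table-index", path,
                                        f"{attr} is 1-based, got {v}"))
    elif isinstance(loc, PositionLocalizer):
        if loc.page < 1:
            issues.append(Issue("bad-page", path, f"page is 1-based, got {loc.page}"))
        x, y, w, h = loc.box
        if w <= 0 or h <= 0:
            issues.append(Issue("bad-box", path,
                                f"box width/height must be positive, got ({w}, {h})"))


def _check_relationship(rel: Relationship, path: str, issues: list[Issue]) -> None:
    if rel.kind not in ("none", "point", "directed", "undirected"):
        issues.append(Issue("bad-relationship-kind", path,
                            f"unknown relationship kind {rel.kind!r}"))
        return
    if rel.kind == "none":
        if rel.entity_a is not None or rel.entity_b is not None:
            issues.append(Issue("relationship-entities", path,
                                "kind 'none' carries no entities"))
    elif rel.kind == "point":
        if rel.entity_a is None or rel.entity_b is not None:
            issues.append(Issue("relationship-entities", path,
                                "kind 'point' carries exactly entity_a"))
    else:
        if rel.entity_a is None or rel.entity_b is None:
            issues.append(Issue("relationship-entities", path,
                                f"kind {rel.kind!r} needs entity_a and entity_b"))


def _check_description(desc: Description, path: str, issues: list[Issue]) -> None:
    if isinstance(desc, PointValueDesc):
        _check_values(desc.values, f"{path}.values", issues)
    elif isinstance(desc, NumericalTraceDesc):
        n_ind = len(desc.independent.magnitudes)
        n_dep = len(desc.dependent.values)
        if n_ind != n_dep:
            issues.append(Issue("trace-length-mismatch", path,
                                f"independent ({n_ind}) and dependent ({n_dep}) lengths differ"))
        if n_ind < 2:
            issues.append(Issue("trace-too-short", path,
                                "a trace needs at least 2 points"))
        mags = desc.independent.magnitudes
        if any(b <= a for a, b in zip(mags, mags[1:])):
            issues.append(Issue("trace-not-monotone", path,
                                "independent magnitudes must be strictly increasing"))
        for j, v in enumerate(desc.dependent.values):
            _check_values(v, f"{path}.dependent[{j}]", issues)
    elif isinstance(desc, FunctionDesc):
        try:
            free = measure.free_symbols(desc.expression)
        except measure.ExpressionError as exc:
            issues.append(Issue("bad-expression", path, str(exc)))
            return
        bound = set(desc.independent_names) | {s for s, _ in desc.fitted_parameters}
        for sym in sorted(free - bound):
            issues.append(Issue("unbound-function-symbol", path,
                                f"expression symbol {sym!r} is neither an independent "
                                f"variable nor a fitted parameter"))
        for j, (sym, values) in enumerate(desc.fitted_parameters):
            _check_values(values, f"{path}.fitted[{sym}]", issues)
    else:  # pragma: no cover - typing guards this
        issues.append(Issue("bad-description", path,
                            f"unknown description type {type(desc).__name__}"))


def validate(annotation: Annotation, vocab: VocabularyTree | None = None) -> list[Issue]:
    """Structural validation, plus required-tag conformance when a
    vocabulary is supplied. Returns an empty list iff the annotation is
    valid; findings are returned, never raised.
    """
    issues: list[Issue] = []
    a = annotation
    path = f"annotation[{a.annotation_id}]"

    if not a.annotation_id:
        issues.append(Issue("missing-id", path, "annotation_id must be non-empty"))
    if not a.publication_id:
        issues.append(Issue("missing-publication", path,
                            "publication_id must be non-empty"))
    if not a.format_version:
        issues.append(Issue("missing-format-version", path,
                            "format_version must be non-empty"))
    _check_localizer(a.localizer, f"{path}.localizer", issues)

    seen_pids: set[str] = set()
    for i, p in enumerate(a.parameters):
        ppath = f"{path}.parameters[{i}]"
        if p.parameter_id in seen_pids:
            issues.append(Issue("duplicate-parameter-id", ppath,
                                f"parameter id {p.parameter_id!r} repeats within the annotation"))
        seen_pids.add(p.parameter_id)
        _check_description(p.description, ppath, issues)
        _check_relationship(p.relationship, f"{ppath}.relationship", issues)

        if vocab is not None:
            if p.type_name not in vocab.parameter_types:
                issues.append(Issue("unknown-parameter-type", ppath,
                                    f"type {p.type_name!r} absent from the vocabulary",
                                    severity="warning"))
            else:
                spec = vocab.parameter_types[p.type_name].required_tags
                for root_id, root_label in spec:
                    checks = [validate_tag_choice((root_id, root_label), t, vocab)
                              for t in p.required_tag_instances]
                    if not any(c.ok for c in checks):
                        issues.append(Issue(
                            "missing-required-tag", ppath,
                            f"no tag descending from required root {root_id!r} "
                            f"({root_label})"))
                for t in p.required_tag_instances:
                    if t.term_id not in vocab.terms:
                        issues.append(Issue("unknown-term", ppath,
                                            f"tag {t.term_id!r} not in the local term store",
                                            severity="warning"))
    if vocab is not None:
        for t in a.tags:
            if t.term_id not in vocab.terms:
                issues.append(Issue("unknown-term", f"{path}.tags",
                                    f"tag {t.term_id!r} not in the local term store",
                                    severity="warning"))
    return issues


# ---------------------------------------------------------------------------
# Canonical serialization

def _term_to_json(t: OntologyTerm) -> dict:
    return {"term_id": t.term_id, "label": t.label}


def _values_to_json(v: Values) -> dict:
    if isinstance(v, ValuesSimple):
        return {
            "kind": "simple",
            "magnitudes": list(v.magnitudes),
            "unit": v.unit,
            "statistic": v.statistic,
        }
    return {"kind": "compound",
            "components": [_values_to_json(c) for c in v.components]}


def _desc_to_json(d: Description) -> dict:
    if isinstance(d, PointValueDesc):
        return {"kind": "point_value", "values": _values_to_json(d.values)}
    if isinstance(d, NumericalTraceDesc):
        return {
            "kind": "numerical_trace",
            "independent": {
                "type_name": d.independent.type_name,
                "unit": d.independent.unit,
                "magnitudes": list(d.independent.magnitudes),
            },
            "dependent": {
                "type_name": d.dependent.type_name,
                "unit": d.dependent.unit,
                "values": [_values_to_json(v) for v in d.dependent.values],
            },
        }
    return {
        "kind": "function",
        "expression": d.expression,
        "dependent_name": d.dependent_name,
        "independent_names": list(d.independent_names),
        "fitted_parameters": [[sym, _values_to_json(v)]
                              for sym, v in d.fitted_parameters],
    }


def _rel_to_json(r: Relationship) -> dict:
    out: dict[str, Any] = {"kind": r.kind}
    if r.entity_a is not None:
        out["entity_a"] = _term_to_json(r.entity_a)
    if r.entity_b is not None:
        out["entity_b"] = _term_to_json(r.entity_b)
    return out


def _loc_to_json(loc: Localizer) -> dict:
    kind = _LOCALIZER_KINDS[type(loc)]
    if isinstance(loc, TextLocalizer):
        return {"kind": kind, "snippet": loc.snippet, "start_offset": loc.start_offset}
    if isinstance(loc, TableLocalizer):
        out: dict[str, Any] = {"kind": kind, "number": loc.number}
        if loc.row is not None:
            out["row"] = loc.row
        if loc.column is not None:
            out["column"] = loc.column
        return out
    if isinstance(loc, PositionLocalizer):
        return {"kind": kind, "page": loc.page, "box": list(loc.box)}
    return {"kind": kind, "number": loc.number}


def _param_to_json(p: Parameter) -> dict:
    return {
        "parameter_id": p.parameter_id,
        "type_name": p.type_name,
        "description": _desc_to_json(p.description),
        "relationship": _rel_to_json(p.relationship),
        "required_tag_instances": [_term_to_json(t) for t in p.required_tag_instances],
        "is_experiment_property": p.is_experiment_property,
    }


def _annotation_to_json(a: Annotation) -> dict:
    out = {
        "annotation_id": a.annotation_id,
        "publication_id": a.publication_id,
        "format_version": a.format_version,
        "authors": list(a.authors),
        "comment": a.comment,
        "tags": [_term_to_json(t) for t in a.tags],
        "localizer": _loc_to_json(a.localizer),
        "parameters": [_param_to_json(p) for p in a.parameters],
        "experiment_property_refs": [list(r) for r in a.experiment_property_refs],
    }
    for key in sorted(a.extra):
        if key not in out:
            out[key] = a.extra[key]
    return out


def serialize(annotations: Iterable[Annotation], *, check: bool = True) -> str:
    """Canonical text form: a pretty-printed JSON list, 4-space indent,
    LF newlines, records sorted by annotation id, fixed field order.

    Refuses to serialize invalid records (structural validation),
    reporting every issue; byte-identical output for structurally equal
    inputs regardless of in-memory order.
    """
    annotations = list(annotations)
    if check:
        issues: list[Issue] = []
        for a in annotations:
            issues.extend(i for i in validate(a) if i.severity == "error")
        if issues:
            raise SerializationError(issues)
    records = sorted(annotations, key=lambda a: a.annotation_id)
    text = json.dumps([_annotation_to_json(a) for a in records],
                      indent=4, ensure_ascii=False)
    return text + "\n"


# --- deserialization -------------------------------------------------------

_KNOWN_FIELDS = {
    "annotation_id", "publication_id", "format_version", "authors", "comment",
    "tags", "localizer", "parameters", "experiment_property_refs",
}


def _need(obj: dict, key: str, where: str):
    if key not in obj:
        raise DeserializationError(f"{where}: {key}")
    return obj[key]


def _term_from_json(obj: dict, where: str) -> OntologyTerm:
    return OntologyTerm(_need(obj, "term_id", where), obj.get("label", ""))


def _values_from_json(obj: dict, where: str) -> Values:
    kind = _need(obj, "kind", where)
    if kind == "simple":
        return ValuesSimple(tuple(float(x) for x in _need(obj, "magnitudes", where)),
                            _need(obj, "unit", where),
                            obj.get("statistic", "raw"))
    if kind == "compound":
        return ValuesCompound(tuple(_values_from_json(c, where)
                                    for c in _need(obj, "components", where)))
    raise DeserializationError(f"{where}: unknown values kind {kind!r}")


def _desc_from_json(obj: dict, where: str) -> Description:
    kind = _need(obj, "kind", where)
    if kind == "point_value":
        return PointValueDesc(_values_from_json(_need(obj, "values", where), where))
    if kind == "numerical_trace":
        ind = _need(obj, "independent", where)
        dep = _need(obj, "dependent", where)
        mags = [float(x) for x in _need(ind, "magnitudes", where)]
        vals = [_values_from_json(v, where) for v in _need(dep, "values", where)]
        if len(mags) == len(vals):  # sort by independent value on load
            order = sorted(range(len(mags)), key=lambda i: mags[i])
            mags = [mags[i] for i in order]
            vals = [vals[i] for i in order]
        return NumericalTraceDesc(
            TraceAxis(_need(ind, "type_name", where), _need(ind, "unit", where),
                      tuple(mags)),
            DependentAxis(_need(dep, "type_name", where), _need(dep, "unit", where),
                          tuple(vals)),
        )
    if kind == "function":
        return FunctionDesc(
            _need(obj, "expression", where),
            _need(obj, "dependent_name", where),
            tuple(_need(obj, "independent_names", where)),
            tuple((sym, _values_from_json(v, where))
                  for sym, v in _need(obj, "fitted_parameters", where)),
        )
    raise DeserializationError(f"{where}: unknown description kind {kind!r}")


def _rel_from_json(obj: dict, where: str) -> Relationship:
    kind = obj.get("kind", "none")
    ea = obj.get("entity_a")
    eb = obj.get("entity_b")
    return Relationship(
        kind,
        _term_from_json(ea, where) if ea is not None else None,
        _term_from_json(eb, where) if eb is not None else None,
    )


def _loc_from_json(obj: dict, where: str) -> Localizer:
    kind = _need(obj, "kind", where)
    if kind == "text":
        return TextLocalizer(_need(obj, "snippet", where),
                             int(_need(obj, "start_offset", where)))
    if kind == "figure":
        return FigureLocalizer(_need(obj, "number", where))
    if kind == "equation":
        return EquationLocalizer(_need(obj, "number", where))
    if kind == "table":
        return TableLocalizer(_need(obj, "number", where),
                              obj.get("row"), obj.get("column"))
    if kind == "position":
        box = _need(obj, "box", where)
        return PositionLocalizer(int(_need(obj, "page", where)),
                                 tuple(float(x) for x in box))
    raise DeserializationError(f"{where}: unknown localizer kind {kind!r}")


def _param_from_json(obj: dict, where: str) -> Parameter:
    return Parameter(
        parameter_id=_need(obj, "parameter_id", where),
        type_name=_need(obj, "type_name", where),
        description=_desc_from_json(_need(obj, "description", where), where),
        relationship=_rel_from_json(obj.get("relationship", {"kind": "none"}), where),
        required_tag_instances=tuple(_term_from_json(t, where)
                                     for t in obj.get("required_tag_instances", [])),
        is_experiment_property=bool(obj.get("is_experiment_property", False)),
    )


def deserialize(text: str) -> list[Annotation]:
    """Parse the canonical text form back into typed annotations.

    Unknown top-level fields are kept in the record's ``extra`` bag so a
    newer writer's additions survive a round trip through an older
    reader. Missing mandatory fields name the record index and field.
    """
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DeserializationError(f"malformed JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(raw, list):
        raise DeserializationError("annotation file must contain a JSON list")
    out: list[Annotation] = []
    for i, obj in enumerate(raw):
        where = f"record {i}"
        if not isinstance(obj, dict):
            raise DeserializationError(f"{where}: not a JSON object")
        ann = Annotation(
            annotation_id=_need(obj, "annotation_id", where),
            publication_id=_need(obj, "publication_id", where),
            format_version=_need(obj, "format_version", where),
            authors=tuple(obj.get("authors", [])),
            comment=obj.get("comment", ""),
            tags=tuple(_term_from_json(t, where) for t in obj.get("tags", [])),
            localizer=_loc_from_json(_need(obj, "localizer", where), where),
            parameters=tuple(_param_from_json(p, f"{where}.parameters")
                             for p in obj.get("parameters", [])),
            experiment_property_refs=tuple(
                (r[0], r[1]) for r in obj.get("experiment_property_refs", [])),
            extra={k: v for k, v in obj.items() if k not in _KNOWN_FIELDS},
        )
        out.append(ann)
    return out
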