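"""Controlled vocabularies: the parameter-type tree and ontology terms.

Two CSV files define the vocabularies used when curating modeling
parameters:

* a parameter-type file (columns ``id,name,parent_id,required_tag_ids,
  required_tag_labels``; the required-tag columns are ``;``-separated and
  aligned) defining the tree of annotatable parameter types, each with the
  ontology roots its tags must descend from;
* an ontology-term file (columns ``term_id,label,parent_ids``; parents are
  ``;``-separated) holding the terms available for tagging, with their
  ancestry.

For example the maximal ionic conductance type requires one tag under the
"Transmembrane ionic current" root and one under the "Cell" root, so that
every annotated conductance states which current and which cell type it
describes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "OntologyTerm",
    "ParameterTypeDef",
    "VocabularyTree",
    "VocabularyError",
    "load_vocabulary",
    "is_descendant",
    "validate_tag_choice",
    "TagCheck",
]


class VocabularyError(ValueError):
    """Raised when a vocabulary file is malformed or inconsistent."""


@dataclass(frozen=True)
class OntologyTerm:
    """A term from a controlled ontology, identified by an opaque id
    (curie-like, e.g. ``nifext_8054``) with a human-readable label and
    zero or more parent terms."""

    term_id: str
    label: str
    parent_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class ParameterTypeDef:
    """One node of the parameter-type tree.

    ``required_tags`` lists (root term id, root label) pairs: an
    annotation of this type must carry one tag descending from each root.
    """

    type_id: str
    name: str
    parent_id: str | None
    required_tags: tuple[tuple[str, str], ...] = ()


@dataclass
class VocabularyTree:
    """The loaded vocabularies: parameter types by name, terms by id."""

    parameter_types: dict[str, ParameterTypeDef] = field(default_factory=dict)
    terms: dict[str, OntologyTerm] = field(default_factory=dict)

    def parameter_type(self, name: str) -> ParameterTypeDef:
        try:
            return self.parameter_types[name]
        except KeyError:
            raise KeyError(f"unknown parameter type {name!r}") from None

    def term(self, term_id: str) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise KeyError(f"unknown ontology term {term_id!r}") from None


def _read_csv(path: Path, expected: list[str]) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise VocabularyError(f"{path}: empty CSV")
        missing = [c for c in expected if c not in reader.fieldnames]
        if missing:
            raise VocabularyError(f"{path}: missing columns {missing}")
        return [dict(row) for row in reader]


def _split(cell: str | None) -> list[str]:
    if not cell:
        return []
    return [p.strip() for p in cell.split(";") if p.strip()]


def load_vocabulary(param_csv_path, terms_csv_path) -> VocabularyTree:
    """Load and cross-validate the two vocabulary CSV files.

    Raises :class:`VocabularyError` naming the offending row when a
    parent reference does not resolve, a name is duplicated, or a cycle
    exists; every required-tag root must resolve in the term store.
    """
    param_csv_path = Path(param_csv_path)
    terms_csv_path = Path(terms_csv_path)

    tree = VocabularyTree()

    for i, row in enumerate(_read_csv(terms_csv_path, ["term_id", "label", "parent_ids"])):
        tid = (row["term_id"] or "").strip()
        if not tid:
            raise VocabularyError(f"{terms_csv_path} row {i}: empty term_id")
        if tid in tree.terms:
            raise VocabularyError(f"{terms_csv_path} row {i}: duplicate term_id {tid!r}")
        tree.terms[tid] = OntologyTerm(tid, row["label"].strip(), tuple(_split(row["parent_ids"])))

    for tid, term in tree.terms.items():
        for pid in term.parent_ids:
            if pid not in tree.terms:
                raise VocabularyError(
                    f"{terms_csv_path}: term {tid!r} cites undefined parent {pid!r}"
                )

    rows = _read_csv(
        param_csv_path,
        ["id", "name", "parent_id", "required_tag_ids", "required_tag_labels"],
    )
    by_id: dict[str, str] = {}
    for i, row in enumerate(rows):
        name = (row["name"] or "").strip()
        type_id = (row["id"] or "").strip()
        if not name or not type_id:
            raise VocabularyError(f"{param_csv_path} row {i}: empty id or name")
        if name in tree.parameter_types:
            raise VocabularyError(f"{param_csv_path} row {i}: duplicate name {name!r}")
        if type_id in by_id:
            raise VocabularyError(f"{param_csv_path} row {i}: duplicate id {type_id!r}")
        parent = (row["parent_id"] or "").strip() or None
        req_ids = _split(row["required_tag_ids"])
        req_labels = _split(row["required_tag_labels"])
        if len(req_ids) != len(req_labels):
            raise VocabularyError(
                f"{param_csv_path} row {i}: required_tag_ids and "
                f"required_tag_labels differ in length"
            )
        ptd = ParameterTypeDef(type_id, name, parent, tuple(zip(req_ids, req_labels)))
        tree.parameter_types[name] = ptd
        by_id[type_id] = name

    for name, ptd in tree.parameter_types.items():
        if ptd.parent_id is not None and ptd.parent_id not in by_id:
            raise VocabularyError(
                f"{param_csv_path}: type {name!r} cites undefined parent {ptd.parent_id!r}"
            )
        for root_id, _root_label in ptd.required_tags:
            if root_id not in tree.terms:
                raise VocabularyError(
                    f"{param_csv_path}: type {name!r} requires tag root {root_id!r} "
                    f"absent from {terms_csv_path.name}"
                )

    _assert_acyclic_types(tree, by_id, param_csv_path)
    _assert_acyclic_terms(tree, terms_csv_path)
    return tree


def _assert_acyclic_types(tree: VocabularyTree, by_id: dict[str, str], path: Path) -> None:
    for name, ptd in tree.parameter_types.items():
        seen = set()
        cur = ptd
        while cur.parent_id is not None:
            if cur.type_id in seen:
                raise VocabularyError(f"{path}: cycle in parameter-type tree at {name!r}")
            seen.add(cur.type_id)
            cur = tree.parameter_types[by_id[cur.parent_id]]


def _assert_acyclic_terms(tree: VocabularyTree, path: Path) -> None:
    # iterative DFS cycle check over the (multi-parent) term DAG
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(tid: str, stack: list[str]) -> None:
        if state.get(tid) == 1:
            return
        if state.get(tid) == 0:
            raise VocabularyError(f"{path}: ancestry cycle through term {tid!r}")
        state[tid] = 0
        for pid in tree.terms[tid].parent_ids:
            visit(pid, stack + [tid])
        state[tid] = 1

    for tid in tree.terms:
        visit(tid, [])


def _ancestors_of_term(tree: VocabularyTree, term_id: str) -> set[str]:
    out: set[str] = set()
    frontier = [term_id]
    while frontier:
        tid = frontier.pop()
        for pid in tree.terms[tid].parent_ids:
            if pid not in out:
                out.add(pid)
                frontier.append(pid)
    return out


def is_descendant(tree: VocabularyTree, child_id: str, ancestor_id: str) -> bool:
    """True iff ``ancestor_id`` lies on the ancestry chain of ``child_id``.

    Reflexive: a node is its own descendant, so a required-tag root may
    itself be chosen. Works for both ontology terms and parameter types
    (ids resolved against whichever store contains them).
    """
    if child_id in tree.terms:
        if ancestor_id == child_id:
            return True
        return ancestor_id in _ancestors_of_term(tree, child_id)
    # parameter types: ids live in the type_id namespace
    types_by_id = {p.type_id: p for p in tree.parameter_types.values()}
    if child_id not in types_by_id:
        raise KeyError(f"unknown id {child_id!r}")
    if child_id == ancestor_id:
        return True
    cur = types_by_id[child_id]
    while cur.parent_id is not None:
        if cur.parent_id == ancestor_id:
            return True
        cur = types_by_id[cur.parent_id]
    return False


@dataclass(frozen=True)
class TagCheck:
    """Outcome of checking a chosen tag against a required-tag root."""

    ok: bool
    code: str  # "ok" | "unknown-term" | "wrong-branch"
    message: str = ""


def validate_tag_choice(spec: tuple[str, str], chosen: OntologyTerm,
                        tree: VocabularyTree) -> TagCheck:
    """Check a chosen tag against a required-tag specification.

    Passes iff the chosen term is the spec root itself or any descendant
    of it. An unknown term and a term from the wrong branch are reported
    with distinct codes so callers can warn vs. reject.
    """
    root_id, root_label = spec
    if root_id not in tree.terms:
        raise KeyError(f"required-tag root {root_id!r} absent from vocabulary")
    if chosen.term_id not in tree.terms:
        return TagCheck(False, "unknown-term",
                        f"term {chosen.term_id!r} not in the local term store")
    if is_descendant(tree, chosen.term_id, root_id):
        return TagCheck(True, "ok")
    return TagCheck(False, "wrong-branch",
                    f"term {chosen.term_id!r} is not a descendant of "
                    f"{root_id!r} ({root_label})")
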