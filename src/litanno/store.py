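"""Corpus storage: one annotation file per publication.

A corpus is a directory of ``*.pcr`` files (plus, by convention, a
``references/`` subdirectory of plain-text reference documents and the
two vocabulary CSVs). Each publication is keyed by its document id —
the DOI when one exists, otherwise ``PMID_<pubmed id>`` — and stored in
a file whose name is a reversible encoding of that id. Files are
written canonically and atomically so that version control shows
minimal, meaningful diffs; committing and pushing are left to the
surrounding git tooling.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import quote, unquote

from .model import Annotation, Issue, deserialize, serialize, validate
from .vocab import VocabularyTree

__all__ = [
    "SUFFIX",
    "Corpus",
    "CorpusStats",
    "LoadFailure",
    "UnsupportedDocumentError",
    "doc_id",
    "annotation_filename",
    "decode_filename",
    "load_corpus",
    "save_corpus",
    "corpus_stats",
]

SUFFIX = ".pcr"


class UnsupportedDocumentError(ValueError):
    pass


def doc_id(doi: str | None = None, pmid: int | None = None) -> str:
    """Derive the unique document id: the DOI verbatim when present,
    else ``PMID_`` + the PubMed id. Documents with neither cannot
    currently be managed by this system."""
    if doi:
        return doi
    if pmid is not None:
        if pmid <= 0:
            raise UnsupportedDocumentError(f"PMID must be positive, got {pmid}")
        return f"PMID_{pmid}"
    raise UnsupportedDocumentError(
        "documents with neither a DOI nor a PMID cannot currently be "
        "managed by this system"
    )


def annotation_filename(document_id: str) -> str:
    """Encode a document id into a safe file name (+ ``.pcr``).

    Percent-encodes every character outside ``[A-Za-z0-9_.~-]`` — in
    particular ``/`` (ubiquitous in DOIs) and ``%`` itself — so the
    mapping is reversible: ``decode_filename(annotation_filename(x)) == x``.
    """
    if not document_id:
        raise ValueError("document id must be non-empty")
    return quote(document_id, safe="") + SUFFIX


def decode_filename(filename: str) -> str:
    """Invert :func:`annotation_filename`."""
    name = Path(filename).name
    if not name.endswith(SUFFIX):
        raise ValueError(f"not an annotation file name: {filename!r}")
    return unquote(name[: -len(SUFFIX)])


@dataclass(frozen=True)
class LoadFailure:
    path: Path
    error: str


@dataclass
class Corpus:
    root: Path
    publications: dict[str, list[Annotation]] = field(default_factory=dict)
    load_failures: list[LoadFailure] = field(default_factory=list)

    def annotations(self):
        """Iterate over every annotation in the corpus."""
        for anns in self.publications.values():
            yield from anns

    def find_annotation(self, annotation_id: str) -> Annotation | None:
        for ann in self.annotations():
            if ann.annotation_id == annotation_id:
                return ann
        return None


@dataclass(frozen=True)
class CorpusStats:
    n_annotations: int
    n_parameters: int
    n_publications: int
    per_type_counts: dict[str, int]


def load_corpus(root) -> Corpus:
    """Load every ``*.pcr`` file under ``root`` (non-recursive).

    Files that fail to parse are collected in ``corpus.load_failures``
    rather than aborting the load: a shared corpus should degrade
    gracefully when one contributor's file is broken.
    """
    root = Path(root)
    if not root.is_dir():
        raise NotADirectoryError(f"corpus root {root} is not a directory")
    corpus = Corpus(root=root)
    for path in sorted(root.iterdir()):
        if not path.is_file() or path.suffix != SUFFIX:
            continue
        try:
            did = decode_filename(path.name)
            anns = deserialize(path.read_text(encoding="utf-8"))
            corpus.publications[did] = anns
        except Exception as exc:  # noqa: BLE001 - isolation is the point
            corpus.load_failures.append(LoadFailure(path, str(exc)))
    return corpus


def save_corpus(corpus: Corpus, vocab: VocabularyTree | None = None) -> None:
    """Write every publication's annotation file canonically.

    All-or-nothing: every annotation in the corpus is validated first
    and nothing is written if any is invalid. Each file is written via a
    temp file + atomic rename; unchanged publications produce
    byte-identical files, so repeated saves create no spurious diffs.
    """
    issues: list[Issue] = []
    for anns in corpus.publications.values():
        for a in anns:
            issues.extend(i for i in validate(a, vocab) if i.severity == "error")
    if issues:
        from .model import SerializationError

        raise SerializationError(issues)

    corpus.root.mkdir(parents=True, exist_ok=True)
    for did, anns in corpus.publications.items():
        target = corpus.root / annotation_filename(did)
        payload = serialize(anns, check=False)
        if target.exists() and target.read_text(encoding="utf-8") == payload:
            continue
        fd, tmp = tempfile.mkstemp(dir=corpus.root, suffix=".tmp")
        try:
            with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
                fh.write(payload)
            os.replace(tmp, target)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise


def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Summary counts: annotations, parameters, publications, and the
    per-parameter-type histogram (the source of "most annotated types"
    summaries)."""
    n_ann = 0
    per_type: dict[str, int] = {}
    for anns in corpus.publications.values():
        n_ann += len(anns)
        for a in anns:
            for p in a.parameters:
                per_type[p.type_name] = per_type.get(p.type_name, 0) + 1
    return CorpusStats(
        n_annotations=n_ann,
        n_parameters=sum(per_type.values()),
        n_publications=len(corpus.publications),
        per_type_counts=dict(sorted(per_type.items())),
    )
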