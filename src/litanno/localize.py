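"""Anchoring text annotations inside reference documents.

Each curated publication has an immutable plain-text reference document;
a text annotation stores the annotated snippet plus the 0-based
character (code point) offset where it starts. This module searches
reference texts for snippets, verifies stored offsets against the
reference, and extracts the annotated span with its surrounding
context.

Normalization is deliberately minimal and platform-stable: Unicode NFC
and LF newlines, nothing else. Offsets count code points of the
normalized text. When an exact search fails, a whitespace-tolerant
fallback collapses runs of whitespace on both sides; anything fuzzier
is out of scope.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path

from .model import TextLocalizer
from .store import annotation_filename, SUFFIX

__all__ = [
    "ReferenceText",
    "Match",
    "VerificationResult",
    "normalize_text",
    "find_text",
    "verify",
    "context",
    "reference_path",
    "load_reference",
]


def normalize_text(text: str) -> str:
    """Unicode NFC + LF newlines; the only transformations applied."""
    return unicodedata.normalize("NFC", text.replace("\r\n", "\n").replace("\r", "\n"))


@dataclass(frozen=True)
class ReferenceText:
    """The immutable plain-text stand-in for a publication's PDF."""

    document_id: str
    text: str

    @staticmethod
    def from_raw(document_id: str, raw: str) -> "ReferenceText":
        return ReferenceText(document_id, normalize_text(raw))


@dataclass(frozen=True)
class Match:
    offset: int  # 0-based code-point index
    matched: str  # the substring actually found in the reference
    exact: bool


@dataclass(frozen=True)
class VerificationResult:
    status: str  # "pass" | "warn" | "fail"
    code: str  # "exact" | "whitespace" | "mismatch" | "out-of-range"
    expected: str = ""
    found: str = ""

    @property
    def ok(self) -> bool:
        return self.status in ("pass", "warn")


def _collapse_ws(s: str) -> str:
    return re.sub(r"\s+", " ", s).strip()


def find_text(ref: ReferenceText, snippet: str) -> list[Match]:
    """All occurrences of ``snippet`` in the reference, in document order.

    Exact matches (including overlapping ones) are returned first; when
    there are none, a whitespace-normalized search is attempted — runs
    of whitespace on either side count as a single space — and any hits
    are flagged ``exact=False``. An empty result is a valid outcome.
    Multiple matches are never auto-resolved; the caller chooses.
    """
    if not snippet:
        raise ValueError("snippet must be non-empty")
    text = ref.text
    matches: list[Match] = []
    start = 0
    while True:
        pos = text.find(snippet, start)
        if pos < 0:
            break
        matches.append(Match(pos, snippet, exact=True))
        start = pos + 1  # allow overlapping occurrences
    if matches:
        return matches
    # whitespace-tolerant fallback
    tokens = snippet.split()
    if not tokens:
        return []
    pattern = r"[ \t\n]+".join(re.escape(t) for t in tokens)
    for m in re.finditer(pattern, text):
        matches.append(Match(m.start(), m.group(0), exact=False))
    return matches


def verify(loc: TextLocalizer, ref: ReferenceText) -> VerificationResult:
    """Check a stored text localizer against the reference document.

    Passes when the reference text at ``start_offset`` equals the stored
    snippet exactly; agreement up to whitespace collapsing is a
    warning-level pass (the snippet was transcribed across a line break,
    say); anything else fails, reporting both strings. An offset beyond
    the document end fails with its own code.
    """
    text = ref.text
    if loc.start_offset < 0 or loc.start_offset > len(text):
        return VerificationResult("fail", "out-of-range", expected=loc.snippet)
    found = text[loc.start_offset: loc.start_offset + len(loc.snippet)]
    if found == loc.snippet:
        return VerificationResult("pass", "exact", expected=loc.snippet, found=found)
    # allow the in-document span to be longer/shorter once whitespace collapses
    for slack in range(0, max(10, len(loc.snippet) // 4)):
        for length in (len(loc.snippet) + slack, len(loc.snippet) - slack):
            if length <= 0:
                continue
            cand = text[loc.start_offset: loc.start_offset + length]
            if _collapse_ws(cand) == _collapse_ws(loc.snippet):
                return VerificationResult("warn", "whitespace",
                                          expected=loc.snippet, found=cand)
    return VerificationResult("fail", "mismatch", expected=loc.snippet, found=found)


def context(loc: TextLocalizer, ref: ReferenceText,
            window: int = 400) -> tuple[str, str, str]:
    """The annotated span with up to ``window`` characters of context on
    each side (the 400-character default mirrors how annotated text is
    conventionally displayed in place).

    Returns ``(before, target, after)``; their concatenation is a
    contiguous slice of the reference. Verification must pass first.
    """
    result = verify(loc, ref)
    if not result.ok:
        raise ValueError(f"localizer fails verification ({result.code}); "
                         f"cannot display context")
    target = result.found
    start = loc.start_offset
    end = start + len(target)
    before = ref.text[max(0, start - window): start]
    after = ref.text[end: end + window]
    return before, target, after


def reference_path(references_dir, document_id: str) -> Path:
    """Path of the reference text for a document: the encoded id with a
    ``.txt`` suffix inside the references directory."""
    name = annotation_filename(document_id)
    return Path(references_dir) / (name[: -len(SUFFIX)] + ".txt")


def load_reference(references_dir, document_id: str) -> ReferenceText:
    path = reference_path(references_dir, document_id)
    return ReferenceText.from_raw(document_id, path.read_text(encoding="utf-8"))
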