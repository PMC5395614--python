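"""Anchor an annotation in its reference document and show its context.

Searches a reference text for a snippet, verifies the stored offset,
and prints the annotated span with 400 characters of context on each
side — how a curator reviews an existing annotation in place.
"""

from litanno import fixtures, load_corpus
from litanno.localize import context, find_text, load_reference, verify
from litanno.model import TextLocalizer

ledger = fixtures.generate_corpus(seed=42, n_publications=3, out="scratch_demo")
corpus = load_corpus("scratch_demo")

planted = next(p for p in ledger.planted_texts if p.n_occurrences == 1)
did = next(d for d, anns in corpus.publications.items()
           if any(a.annotation_id == planted.annotation_id for a in anns))
ref = load_reference(ledger.references_dir, did)

# A snippet search returns every candidate offset; a unique hit can be
# turned directly into a localizer.
matches = find_text(ref, planted.snippet)
print(f"snippet found at offsets: {[m.offset for m in matches]}")

loc = TextLocalizer(matches[0].matched, matches[0].offset)
print(f"verification: {verify(loc, ref).status}")  # pass — built from a match

before, target, after = context(loc, ref)
print(f"\n…{before[-80:]}<<{target}>>{after[:80]}…")
print(f"\ncontext window: {len(before)} chars before, {len(after)} after")
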