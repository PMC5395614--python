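# Methods

## The data model

An annotation is one curated fact: a localized, tagged, commented
record tied to a single publication. The format is *standoff* — records
live in a separate plain-text file per publication rather than inside
the document — because curation is collaborative and version-controlled:
one file per paper keeps merge conflicts local, and a canonical text
form (fixed field order, 4-space indent, LF newlines, records sorted by
annotation id) makes diffs minimal and the writer idempotent. The
serializer refuses invalid records outright; the loader, conversely,
isolates per-file failures so a shared corpus degrades gracefully when
one contributor's file is broken.

Parameters attached to an annotation are typed three ways:

- **point value** — a quantity outside any functional relationship;
- **function** — a fitted analytical expression with its fitted
  parameter values. Expressions are stored as strings in a restricted
  grammar (numbers, identifiers, `+ − * /`, unary minus, parentheses,
  `^`/`**`, and calls to `exp`, `log`, `ln`, `pow`) and evaluated by a
  purpose-built recursive-descent interpreter — never by the host
  language's `eval` — so a corpus file can never execute code.
  Fitted-parameter symbols are plain identifiers (`V_half`, not the
  typographic "V½", which is not lexable under the grammar);
- **numerical trace** — paired independent/dependent series. The
  independent axis must be strictly increasing; it is sorted on load,
  and a residual duplicate is a validation error.

Every value is either *simple* — a non-empty magnitude list, a unit
string as published, and one of twelve closed statistic roles (`raw`,
`mean`, `median`, `sd`, `sem`, `var`, `min`, `max`, `ci_lower`,
`ci_upper`, `sample_size`, `deviation`) — or *compound*: ≥ 2 simple
components with distinct roles and a shared dimension (`sample_size`,
dimensionless, excepted). The role vocabulary is closed deliberately:
an open set invites unqueryable spellings. `deviation` exists for the
published "±" whose nature (SD vs SEM) the source does not state; the
curator must not guess.

Five localizer variants pin a record in its document: text
(snippet + 0-based offset), figure, equation, table (numbers kept as
strings — "S1" and "3b" are numbers in the wild), and position
(1-based page, bounding box in PDF points, origin bottom-left,
positive extents). Exactly one localizer per annotation; multi-anchor
records are out of scope.

Unknown top-level fields survive a round trip through an `extra` bag,
so files written by a newer version are not destroyed by an older one.

## Localization

Reference documents are plain-text stand-ins for the publication,
normalized once (Unicode NFC, LF newlines — nothing else) and treated
as immutable thereafter; offsets count code points of that normalized
text. Snippet search returns *every* occurrence, including overlapping
ones, in document order; ambiguity is surfaced, never auto-resolved.
When an exact search fails, a fallback collapses whitespace runs on
both sides (tokens joined by `\s+` in a regex over the original text,
so returned offsets still index the reference). Verification of a
stored offset passes exactly, passes at warning level when the stored
snippet and the in-document span agree after whitespace collapsing
(the span is rescanned over a small length slack, since collapsing
changes lengths), and otherwise fails reporting both strings; an
offset past the document end has its own failure code. Context
display returns up to 400 characters on each side by default,
truncated at document boundaries, and guarantees the three pieces
concatenate to a contiguous slice of the reference.

## Quantities and harmonization

Units are handled by a compact dimensional-analysis engine: a unit is
a product of SI-prefixed symbols with integer exponents carrying a
7-component dimension vector (m, kg, s, A, K, mol, cd) and a scale
factor to coherent SI. The registry covers the units that occur in
neurophysiological curation (V, Ω, S, Hz, L, day/h/min, percent, and
all SI prefixes); micro accepts `u`, `µ`, and `μ`; exponents accept
`^`, `**`, bare digits, and Unicode superscripts. Conversion requires
exact dimension equality and multiplies by a scale ratio, so round
trips are accurate to ~1 ulp (tested at ≤ 1e−12 relative).

Harmonization never mutates stored values — published magnitudes are
transcribed verbatim and all conversions return new objects, with the
source parameter id kept on derived rows. The specific operations:

- **area → volume density**: an areal count (length⁻²) from a
  stereological slice divided by the slice thickness (converted to the
  density's own length unit first, so mm⁻² with a 25 µm slice yields
  mm⁻³). Zero or negative thickness is an error.
- **compound reduction**: select the unique component with a requested
  role; a missing role errors listing the roles available. The default
  role for harmonization is `mean`.
- **trace interpolation**: piecewise linear, exact at knots, refusing
  extrapolation outside the tabulated range. Linear is the minimal
  assumption-free scheme for sparse published tables; the evaluation
  point is converted to the independent axis's unit first. Dependent
  values that are compounds reduce to their mean; repeated-measure
  magnitude lists are averaged.
- **function evaluation**: fitted parameters are bound from the stored
  description (means of compounds), independent variables from the
  caller; unbound symbols and disallowed tokens are errors.

Query-level harmonization is total over heterogeneous corpora: rows
that cannot be expressed in the target unit (a function-valued
parameter, a trace without an evaluation point, an areal density with
no linked slice thickness, a plain dimension mismatch) come back in a
rejection list with machine-readable reasons rather than raising.

## Vocabularies

Two UTF-8 CSVs define the controlled vocabularies. Parameter types
(`id,name,parent_id,required_tag_ids,required_tag_labels`, the tag
columns `;`-separated and aligned) form a tree; ontology terms
(`term_id,label,parent_ids`) form a DAG (multiple parents allowed).
Loading cross-validates everything — unresolved parents and duplicate
names error naming the offending row, cycles are rejected, and every
required-tag root must resolve in the term store. Descendant checks
are reflexive: a required-tag root may itself be chosen as the tag,
the permissive reading of "children of" the root. Terms used in
annotations but absent from the local store are warnings, not errors,
since local stores typically lag the upstream ontologies they mirror;
a tag from the wrong branch is an error with a distinct code.

## The synthetic corpus generator

`fixtures.generate_corpus(seed, n_publications, out)` emulates the
artifacts of a real curation effort — vocabulary CSVs, reference texts,
annotation files — with an exact ledger of what was planted, which the
test suite uses as its oracle. Reference texts are built from a seeded
word pool; planted snippets are re-checked to be unique in their
document (one sentence is deliberately planted twice to exercise
multi-match behavior). Publication 0 always carries the coverage
guarantees: all five localizer variants, all three description types,
simple and compound values, an areal density linked to a 25 µm slice
thickness, an unlinked areal density (so harmonization has something to
reject), a volumetric density, a density-vs-age trace with knots at
days 7 and 21 (value at day 14 is therefore determined by linear
interpolation), and a fitted Boltzmann function. Parameter magnitudes
are plausible for rodent thalamic electrophysiology (resting potentials
−75…−55 mV, input resistances 30–300 MΩ, conductance densities
1–40 pS/µm²) but carry no statistical realism — no measurement noise,
no realistic inter-study variance, no PDF-extraction artifacts — so
green tests demonstrate format and algebra correctness, not robustness
to messy real-world extraction. Identical seeds give byte-identical
directories.

`fixtures.seeded_violations` mutates a chosen number of records, each
breaking exactly one named invariant (duplicate statistic role, missing
required tag, corrupted offset, empty magnitudes, empty format version,
non-monotone trace), rotating through the violation kinds and skipping
records where a kind does not apply. The missing-required-tag break is
restricted to single-required-root parameter types so that exactly one
issue results. Mutated files are written through the unchecked
serializer, since the validated writer refuses them by design.

## Problem sizes and numerical choices

The default test run exercises round trips over a generated corpus of
340 publications (≈ 1 000 annotations), 200-case randomized oracles for
text search, unit conversion, and expression evaluation, and property
tests (hypothesis, derandomized) for filename-encoding bijectivity and
ancestry checks on random DAGs of ≤ 50 nodes — sizes at which every
oracle is exhaustive yet the whole suite runs in a few seconds.
Conversion and evaluation agreement is asserted at 1e−12 relative;
interpolation and reduction results are exact at knots and components
by construction. Tie-breaks: when a compound lacks a `mean` component
in a display context, the first component stands in; duplicate
statistic roles are reported once per role, not per pair.

## Known limitations

- No PDF parsing: reference texts must be supplied (or generated) as
  plain text.
- No live ontology service: the term store is local CSV; unknown terms
  warn rather than resolve on demand.
- No git automation: the canonical writer makes files merge-friendly,
  but committing is the caller's concern.
- Offsets count code points of the normalized text; corpora produced
  by tools that count bytes need re-anchoring via snippet search.
- Harmonization chains are single-step (unit conversion + one
  area→volume transform); cross-publication normalization pipelines
  are out of scope.
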