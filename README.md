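# litanno

Collaborative curation of quantitative facts from the scientific
literature, aimed at data-driven modeling in neuroscience (and any
field where models are instantiated from numbers scattered across
papers).

Building a biophysically detailed model means tracking down hundreds of
published values — cell densities, membrane potentials, conductances,
fitted activation curves — and recording not just the numbers but where
they came from, what they describe, and under which experimental
conditions they were measured. `litanno` provides the data model and
operations for that workflow:

- **Standoff annotations.** Each publication gets one plain-text file of
  canonical, pretty-printed JSON records. An annotation carries a unique
  id, ontology-term tags, authors, a comment, optional typed parameters,
  and exactly one *localizer* pinning it inside the document (text
  snippet + character offset, figure/equation/table number, or page +
  bounding box). Serialization is deterministic — fixed field order,
  4-space indent, records sorted by id — so corpora live comfortably in
  git with minimal diffs.
- **Typed experimental values.** A parameter is a *point value*, a
  *fitted function* (e.g. a Boltzmann inactivation curve
  `f = 1/(1+exp((V−V½)/k))` stored as a safely evaluable expression with
  its fitted V½ and k), or a *numerical trace* (paired series, e.g.
  density vs. age). Values are *simple* (magnitudes + unit + statistic
  role) or *compound* — interdependent statistics like
  mean ± SEM (n), which are meaningless stored apart. Published
  magnitudes are transcribed verbatim and never transformed in place.
- **Controlled vocabularies.** A CSV-defined tree of parameter types
  assigns each type *required tags* (e.g. a maximal conductance needs an
  ionic-current term and a cell-type term, both descendants of their
  ontology roots), and validation checks every record against them.
- **Query and harmonization.** Filter parameters by type, tag (with
  ancestry expansion), or document; join linked *experiment properties*
  (slice thickness, temperature, age); and harmonize heterogeneous
  values to one target unit — converting areal cell densities (mm⁻²) to
  volumetric ones (mm⁻³) via the slice thickness, interpolating traces
  at a chosen age, reducing compounds to their mean. Rows that cannot be
  harmonized are rejected with machine-readable reasons, never silently
  dropped.

## Worked example

```sh
python examples/05_quantities_and_functions.py
```

```
parsed: 5.0 pS*um^-2  (equals 5.0 S*m^-2)
areal 50000 mm^-2 on a 25 um slice -> 2000000.0 mm^-3
f(-100.0 mV) = 0.9511
f( -81.0 mV) = 0.5000
f( -60.0 mV) = 0.0362
```

The first line parses a published conductance-density string verbatim
(1 pS/µm² happens to equal 1 S/m²). The second divides an areal neuron
density by a 25 µm slice thickness: 50 000/0.025 = 2 000 000 cells per
mm³. The last three evaluate a stored Boltzmann inactivation curve with
fitted V½ = −81 mV, k = 6.4 mV: by definition f = 0.5 at V = V½.

`examples/04_harmonize_densities.py` runs the full pipeline on a
synthetic corpus — 7 annotated neuron densities in mixed units become a
homogeneous mm⁻³ table of 3 rows (the linked areal density, the
interpolated trace at day 14, the converted µm⁻³ value), with the 4
unlinked areal densities rejected as `missing slice_thickness`.

The other examples cover record creation and canonical serialization
(`01`), corpus statistics (`02`), and snippet search / offset
verification / context display (`03`). A thin CLI wraps the same
operations: `litanno init --demo`, `validate`, `stats`, `query`,
`localize`, `context`.

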