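"""Query neuron densities and harmonize them to one unit.

The corpus mixes areal densities (mm^-2, from stereological counts on
slices), volumetric ones (um^-3), and a density-vs-age numerical
trace. Harmonization expresses every usable row in mm^-3: areal
densities are divided by their linked slice thickness, the trace is
interpolated at postnatal day 14, compound values contribute their
mean. Rows with no slice thickness attached cannot be converted and
are rejected with a reason — they stay visible, not silently dropped.
"""

from litanno import fixtures, load_corpus
from litanno.measure import parse_quantity
from litanno.query import (attach_experiment_properties, filter_parameters,
                           harmonize, rows_to_dataframe)

fixtures.generate_corpus(seed=42, n_publications=5, out="scratch_demo")
corpus = load_corpus("scratch_demo")

rows = filter_parameters(corpus, type_name="neuron_density")
print(f"neuron_density parameters found: {len(rows)}")

rows = attach_experiment_properties(rows, corpus)
kept, rejected = harmonize(rows, "mm^-3", trace_at=parse_quantity("14 day"))

print(f"harmonized to mm^-3: {len(kept)}; rejected: {len(rejected)}")
for r in rejected:
    print(f"  rejected {r.row.parameter_id[:8]}…: {r.reason}")

df = rows_to_dataframe(kept)
print("\nhomogeneous table (every value in mm^-3):")
print(df[["document_id", "type_name", "magnitudes", "unit"]].to_string(index=False))
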