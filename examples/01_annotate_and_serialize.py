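"""Create an annotation with a compound parameter and serialize it.

Builds the record for a published input-resistance measurement
(55 ± 19 MΩ, n = 94) anchored to a text snippet, validates it, and
prints the canonical JSON file content. The three compound components
are stored together because a standard error is meaningless without
its mean and sample size.
"""

from litanno import (Annotation, IdFactory, Parameter, PointValueDesc,
                     TextLocalizer, ValuesCompound, ValuesSimple, serialize,
                     validate)
from litanno.vocab import OntologyTerm

ids = IdFactory(seed=1)

input_resistance = ValuesCompound((
    ValuesSimple((55.0,), "Mohm", "mean"),
    ValuesSimple((19.0,), "Mohm", "sem"),
    ValuesSimple((94.0,), "", "sample_size"),
))

annotation = Annotation(
    annotation_id=ids(),
    publication_id="PMID_12626627",
    localizer=TextLocalizer("input resistance (55 +/- 19 MOhm; n = 94)", 1240),
    tags=(OntologyTerm("syn_cell_tc", "Thalamocortical relay cell"),),
    authors=("curator_a",),
    comment="Passive membrane properties, whole-cell recordings.",
    parameters=(Parameter(
        parameter_id=ids(),
        type_name="input_resistance",
        description=PointValueDesc(input_resistance),
        required_tag_instances=(
            OntologyTerm("syn_cell_tc", "Thalamocortical relay cell"),),
    ),),
)

issues = validate(annotation)
print(f"validation issues: {len(issues)}")  # 0 — the record is well-formed
print(serialize([annotation]))
# The JSON below is what gets committed to the corpus repository:
# canonical field order and indentation keep diffs minimal.
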