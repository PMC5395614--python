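"""Deterministic synthetic corpora for testing and demos.

:func:`generate_corpus` emits a complete corpus — vocabulary CSVs,
plain-text reference documents, and one annotation file per synthetic
publication — together with a :class:`GeneratorLedger` that records
exactly what was planted (counts per publication and type, localizer
variants, experiment-property links, planted text offsets). The ledger
is the ground truth the test suite compares library output against.

Coverage guarantees, independent of the seed: every localizer variant,
every description type, simple and compound values, at least one areal
neuron density linked to a slice-thickness experiment property, one
areal density left unlinked (so harmonization has something to reject),
one volumetric density, one density-vs-age numerical trace spanning
postnatal day 14, one fitted Boltzmann inactivation function, and one
snippet deliberately planted twice to exercise multi-match behavior.

Identical seeds produce byte-identical directories. The values are
plausible for rodent thalamic electrophysiology but carry no
statistical realism — they exist to exercise the format.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path

from .model import (Annotation, DependentAxis, EquationLocalizer, FigureLocalizer,
                    FunctionDesc, IdFactory, NumericalTraceDesc, Parameter,
                    PointValueDesc, PositionLocalizer, Relationship, TableLocalizer,
                    TextLocalizer, TraceAxis, ValuesCompound, ValuesSimple, serialize)
from .store import annotation_filename, doc_id
from .vocab import OntologyTerm

__all__ = ["GeneratorLedger", "PlantedViolation", "generate_corpus",
           "seeded_violations", "write_vocabulary_csvs"]

# --- fixed synthetic vocabulary -------------------------------------------

_TERMS = [
    # (term_id, label, parents)
    ("nifext_8054", "Transmembrane ionic current", ""),
    ("syn_curr_na", "Voltage-gated sodium current", "nifext_8054"),
    ("syn_curr_kdr", "Delayed rectifier potassium current", "nifext_8054"),
    ("syn_curr_t", "Low-threshold calcium current", "nifext_8054"),
    ("sao1813327414", "Cell", ""),
    ("syn_cell_tc", "Thalamocortical relay cell", "sao1813327414"),
    ("syn_cell_re", "Reticular nucleus cell", "sao1813327414"),
    ("syn_cell_in", "Local interneuron", "sao1813327414"),
    ("syn_region", "Brain region", ""),
    ("syn_region_thal", "Thalamus", "syn_region"),
    ("syn_region_vpm", "Ventral posteromedial nucleus", "syn_region_thal"),
    ("syn_species_rat", "Rat", ""),
]

_PARAM_TYPES = [
    # (id, name, parent_id, required_tag_ids, required_tag_labels)
    ("pt_root", "parameter", "", "", ""),
    ("pt_dens", "neuron_density", "pt_root", "sao1813327414", "Cell"),
    ("pt_gmax", "conductance_ion_curr_max", "pt_root",
     "nifext_8054;sao1813327414", "Transmembrane ionic current;Cell"),
    ("pt_rin", "input_resistance", "pt_root", "sao1813327414", "Cell"),
    ("pt_vrest", "resting_membrane_potential", "pt_root", "sao1813327414", "Cell"),
    ("pt_spike", "spike_amplitude", "pt_root", "sao1813327414", "Cell"),
    ("pt_thick", "slice_thickness", "pt_root", "", ""),
    ("pt_temp", "recording_temperature", "pt_root", "", ""),
    ("pt_age", "animal_age", "pt_root", "", ""),
    ("pt_inact", "inactivation_steady_state", "pt_root",
     "nifext_8054", "Transmembrane ionic current"),
]

_TERM_OBJS = {tid: OntologyTerm(tid, label, tuple(p for p in parents.split(";") if p))
              for tid, label, parents in _TERMS}

_CELL_TERMS = ["syn_cell_tc", "syn_cell_re", "syn_cell_in"]
_CURRENT_TERMS = ["syn_curr_na", "syn_curr_kdr", "syn_curr_t"]

_WORDS = (
    "the recorded neurons showed a membrane potential near rest while "
    "slices were maintained in oxygenated solution at controlled "
    "temperature and cells of the ventrobasal complex were filled with "
    "dye for morphological identification whereas passive properties "
    "were estimated from hyperpolarizing current steps and densities "
    "were counted using stereological sampling across serial sections "
    "of thalamic tissue obtained from juvenile animals under deep "
    "anesthesia following standard procedures"
).split()


def write_vocabulary_csvs(out: Path) -> tuple[Path, Path]:
    """Write the synthetic parameter-type and ontology-term CSVs."""
    param_path = out / "parameter_types.csv"
    terms_path = out / "ontology_terms.csv"
    lines = ["id,name,parent_id,required_tag_ids,required_tag_labels"]
    for row in _PARAM_TYPES:
        lines.append(",".join(row))
    param_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    lines = ["term_id,label,parent_ids"]
    for tid, label, parents in _TERMS:
        lines.append(f"{tid},{label},{parents}")
    terms_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return param_path, terms_path


@dataclass
class PlantedText:
    annotation_id: str
    offset: int
    snippet: str
    n_occurrences: int  # 1 except for the deliberate duplicate


@dataclass
class GeneratorLedger:
    """Exact bookkeeping of a generated corpus."""

    seed: int
    n_publications: int
    root: Path
    references_dir: Path
    param_csv: Path
    terms_csv: Path
    document_ids: list[str] = field(default_factory=list)
    per_publication: dict[str, int] = field(default_factory=dict)  # doc -> n annotations
    per_type_counts: dict[str, int] = field(default_factory=dict)
    localizer_counts: dict[str, int] = field(default_factory=dict)
    value_form_counts: dict[str, int] = field(default_factory=dict)
    planted_texts: list[PlantedText] = field(default_factory=list)
    property_links: list[tuple[str, str, str]] = field(default_factory=list)
    # harmonization scenario bookkeeping (all neuron_density rows):
    linked_area_density_ids: list[str] = field(default_factory=list)
    unlinked_area_density_ids: list[str] = field(default_factory=list)
    volume_density_ids: list[str] = field(default_factory=list)
    trace_parameter_ids: list[str] = field(default_factory=list)
    trace_value_at_day14: float = 0.0  # mm^-3, for the guaranteed trace
    boltzmann_annotation_id: str = ""
    duplicate_snippet: str = ""

    @property
    def n_annotations(self) -> int:
        return sum(self.per_publication.values())

    @property
    def n_parameters(self) -> int:
        return sum(self.per_type_counts.values())


class _Builder:
    def __init__(self, seed: int, out: Path):
        self.rng = random.Random(seed)
        self.ids = IdFactory(self.rng.getrandbits(31))
        self.out = out

    def text_document(self, n_sentences: int, duplicate_sentence: str | None = None) -> str:
        parts = []
        for _ in range(n_sentences):
            k = self.rng.randint(6, 12)
            words = [self.rng.choice(_WORDS) for _ in range(k)]
            parts.append(" ".join(words).capitalize() + ".")
        if duplicate_sentence:
            parts.insert(len(parts) // 3, duplicate_sentence)
            parts.append(duplicate_sentence)
        return " ".join(parts)

    def unique_snippet(self, text: str, length: int = 45) -> tuple[int, str]:
        for _ in range(200):
            off = self.rng.randrange(0, max(1, len(text) - length))
            snip = text[off:off + length]
            if text.count(snip) == 1 and "\n" not in snip:
                return off, snip
        raise RuntimeError("could not plant a unique snippet")  # pragma: no cover

    def term(self, tid: str) -> OntologyTerm:
        t = _TERM_OBJS[tid]
        return OntologyTerm(t.term_id, t.label)


def _simple(mags, unit, stat="raw") -> ValuesSimple:
    return ValuesSimple(tuple(float(m) for m in mags), unit, stat)


def _compound(mean, dev, n, unit, dev_role="sem") -> ValuesCompound:
    return ValuesCompound((
        _simple([mean], unit, "mean"),
        _simple([dev], unit, dev_role),
        _simple([n], "", "sample_size"),
    ))


def generate_corpus(seed: int, n_publications: int, out) -> GeneratorLedger:
    """Emit a complete synthetic corpus under ``out`` and return its
    ledger. At least one publication is required; publication 0 carries
    the guaranteed-coverage structures."""
    if n_publications < 1:
        raise ValueError("need at least one publication")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    refs_dir = out / "references"
    refs_dir.mkdir(exist_ok=True)
    param_csv, terms_csv = write_vocabulary_csvs(out)

    b = _Builder(seed, out)
    ledger = GeneratorLedger(seed=seed, n_publications=n_publications, root=out,
                             references_dir=refs_dir, param_csv=param_csv,
                             terms_csv=terms_csv)
    for k in ("text", "figure", "equation", "table", "position"):
        ledger.localizer_counts[k] = 0
    for k in ("simple", "compound", "trace", "function"):
        ledger.value_form_counts[k] = 0

    for i in range(n_publications):
        if i % 2 == 0:
            did = doc_id(doi=f"10.1000/synthetic.{seed % 1000}.{i:03d}")
        else:
            did = doc_id(pmid=20000000 + seed % 100000 + i)
        ledger.document_ids.append(did)
        anns = (_guaranteed_publication(b, ledger, did) if i == 0
                else _random_publication(b, ledger, did))
        ledger.per_publication[did] = len(anns)
        name = annotation_filename(did)
        (out / name).write_text(serialize(anns), encoding="utf-8", newline="\n")
    return ledger


def _count(ledger: GeneratorLedger, p: Parameter, form: str) -> Parameter:
    ledger.per_type_counts[p.type_name] = ledger.per_type_counts.get(p.type_name, 0) + 1
    ledger.value_form_counts[form] += 1
    return p


def _text_loc(b: _Builder, ledger: GeneratorLedger, text: str,
              ann_id: str) -> TextLocalizer:
    off, snip = b.unique_snippet(text)
    ledger.planted_texts.append(PlantedText(ann_id, off, snip, 1))
    ledger.localizer_counts["text"] += 1
    return TextLocalizer(snip, off)


def _guaranteed_publication(b: _Builder, ledger: GeneratorLedger,
                            did: str) -> list[Annotation]:
    dup_sentence = "Counts were repeated twice for the same reference frame."
    text = b.text_document(70, duplicate_sentence=dup_sentence)
    (ledger.references_dir / (annotation_filename(did)[:-4] + ".txt")).write_text(
        text, encoding="utf-8", newline="\n")
    ledger.duplicate_snippet = dup_sentence
    cell = b.term("syn_cell_tc")
    anns: list[Annotation] = []

    # slice-thickness experiment property (target of the link)
    thick_ann_id, thick_param_id = b.ids(), b.ids()
    p_thick = _count(ledger, Parameter(
        thick_param_id, "slice_thickness",
        PointValueDesc(_simple([25.0], "um")),
        is_experiment_property=True), "simple")
    ledger.localizer_counts["figure"] += 1
    anns.append(Annotation(thick_ann_id, did, FigureLocalizer("2"),
                           tags=(b.term("syn_region_vpm"),),
                           authors=("curator_a",), parameters=(p_thick,),
                           comment="Sectioning described in the methods figure."))

    # areal neuron density linked to the thickness (harmonizable)
    a_id = b.ids()
    p_dens = _count(ledger, Parameter(
        b.ids(), "neuron_density",
        PointValueDesc(_simple([51000.0], "mm^-2")),
        required_tag_instances=(cell,)), "simple")
    anns.append(Annotation(
        a_id, did, _text_loc(b, ledger, text, a_id),
        tags=(b.term("syn_region_vpm"), b.term("syn_species_rat")),
        authors=("curator_a",), parameters=(p_dens,),
        experiment_property_refs=((thick_ann_id, thick_param_id),)))
    ledger.property_links.append((did, a_id, thick_param_id))
    ledger.linked_area_density_ids.append(p_dens.parameter_id)

    # areal density with no thickness link (harmonization must reject it)
    a_id = b.ids()
    p_dens2 = _count(ledger, Parameter(
        b.ids(), "neuron_density",
        PointValueDesc(_simple([43000.0], "mm^-2")),
        required_tag_instances=(b.term("syn_cell_in"),)), "simple")
    ledger.localizer_counts["equation"] += 1
    anns.append(Annotation(a_id, did, EquationLocalizer("3"),
                           authors=("curator_b",), parameters=(p_dens2,)))
    ledger.unlinked_area_density_ids.append(p_dens2.parameter_id)

    # volumetric density, already in um^-3
    a_id = b.ids()
    p_dens3 = _count(ledger, Parameter(
        b.ids(), "neuron_density",
        PointValueDesc(_simple([8.8e-5], "um^-3")),
        required_tag_instances=(cell,)), "simple")
    ledger.localizer_counts["table"] += 1
    anns.append(Annotation(a_id, did, TableLocalizer("1", row=2, column=3),
                           authors=("curator_a",), parameters=(p_dens3,)))
    ledger.volume_density_ids.append(p_dens3.parameter_id)

    # density-vs-age numerical trace spanning day 14
    a_id = b.ids()
    trace = NumericalTraceDesc(
        TraceAxis("animal_age", "day", (7.0, 21.0)),
        DependentAxis("neuron_density", "mm^-3",
                      (_simple([90000.0], "mm^-3"),
                       _compound(150000.0, 12000.0, 6, "mm^-3"))))
    p_trace = _count(ledger, Parameter(
        b.ids(), "neuron_density", trace,
        required_tag_instances=(b.term("syn_cell_re"),)), "trace")
    ledger.localizer_counts["position"] += 1
    anns.append(Annotation(a_id, did, PositionLocalizer(4, (72.0, 540.0, 180.0, 120.0)),
                           authors=("curator_b",), parameters=(p_trace,)))
    ledger.trace_parameter_ids.append(p_trace.parameter_id)
    ledger.trace_value_at_day14 = 90000.0 + (150000.0 - 90000.0) * (14 - 7) / (21 - 7)

    # compound electrophysiology values (mean ± sem with sample size)
    a_id = b.ids()
    p_rin = _count(ledger, Parameter(
        b.ids(), "input_resistance",
        PointValueDesc(_compound(55.0, 19.0, 94, "Mohm")),
        required_tag_instances=(cell,)), "compound")
    p_vr = _count(ledger, Parameter(
        b.ids(), "resting_membrane_potential",
        PointValueDesc(_compound(-60.0, 4.0, 67, "mV")),
        required_tag_instances=(cell,)), "compound")
    anns.append(Annotation(a_id, did, _text_loc(b, ledger, text, a_id),
                           authors=("curator_a",), parameters=(p_rin, p_vr),
                           comment="Passive properties of relay cells."))

    # fitted Boltzmann steady-state inactivation function
    a_id = b.ids()
    fn = FunctionDesc(
        expression="1/(1+exp((V-V_half)/k))",
        dependent_name="f",
        independent_names=("V",),
        fitted_parameters=(
            ("V_half", _compound(-81.0, 2.0, 12, "mV")),
            ("k", _simple([6.4], "mV")),
        ))
    p_fn = _count(ledger, Parameter(
        b.ids(), "inactivation_steady_state", fn,
        relationship=Relationship("point", b.term("syn_curr_t")),
        required_tag_instances=(b.term("syn_curr_t"),)), "function")
    anns.append(Annotation(a_id, did, _text_loc(b, ledger, text, a_id),
                           authors=("curator_b",), parameters=(p_fn,)))
    ledger.boltzmann_annotation_id = a_id

    # annotation anchored on the deliberately duplicated sentence
    a_id = b.ids()
    first = text.find(dup_sentence)
    ledger.planted_texts.append(PlantedText(a_id, first, dup_sentence, 2))
    ledger.localizer_counts["text"] += 1
    anns.append(Annotation(a_id, did, TextLocalizer(dup_sentence, first),
                           authors=("curator_a",),
                           comment="Anchored on a repeated sentence."))
    return anns


def _random_publication(b: _Builder, ledger: GeneratorLedger,
                        did: str) -> list[Annotation]:
    text = b.text_document(b.rng.randint(40, 70))
    (ledger.references_dir / (annotation_filename(did)[:-4] + ".txt")).write_text(
        text, encoding="utf-8", newline="\n")
    anns: list[Annotation] = []
    for _ in range(b.rng.randint(2, 4)):
        a_id = b.ids()
        kind = b.rng.choice(["vrest", "rin", "gmax", "density", "temp", "spike"])
        cell = b.term(b.rng.choice(_CELL_TERMS))
        if kind == "vrest":
            v = round(b.rng.uniform(-75, -55), 1)
            if b.rng.random() < 0.5:
                values = _simple([v], "mV", "mean")
                form = "simple"
            else:
                values = _compound(v, round(b.rng.uniform(1, 6), 1),
                                   b.rng.randint(5, 120), "mV")
                form = "compound"
            p = Parameter(b.ids(), "resting_membrane_potential",
                          PointValueDesc(values), required_tag_instances=(cell,))
        elif kind == "rin":
            values = _compound(round(b.rng.uniform(30, 300), 1),
                               round(b.rng.uniform(5, 40), 1),
                               b.rng.randint(5, 100), "Mohm")
            form = "compound"
            p = Parameter(b.ids(), "input_resistance",
                          PointValueDesc(values), required_tag_instances=(cell,))
        elif kind == "gmax":
            curr = b.term(b.rng.choice(_CURRENT_TERMS))
            values = _simple([round(b.rng.uniform(1, 40), 2)], "pS/um^2")
            form = "simple"
            p = Parameter(b.ids(), "conductance_ion_curr_max",
                          PointValueDesc(values),
                          relationship=Relationship("point", curr),
                          required_tag_instances=(curr, cell))
        elif kind == "density":
            values = _simple([round(b.rng.uniform(2e4, 9e4), 0)], "mm^-2")
            form = "simple"
            p = Parameter(b.ids(), "neuron_density",
                          PointValueDesc(values), required_tag_instances=(cell,))
            ledger.unlinked_area_density_ids.append(p.parameter_id)
        elif kind == "spike":
            values = _compound(round(b.rng.uniform(50, 90), 1),
                               round(b.rng.uniform(2, 10), 1),
                               b.rng.randint(5, 100), "mV")
            form = "compound"
            p = Parameter(b.ids(), "spike_amplitude",
                          PointValueDesc(values), required_tag_instances=(cell,))
        else:
            values = _simple([round(b.rng.uniform(20, 36), 1)], "K")
            form = "simple"
            p = Parameter(b.ids(), "recording_temperature",
                          PointValueDesc(values), is_experiment_property=True)
        _count(ledger, p, form)
        loc_kind = b.rng.choice(["text", "text", "figure", "table"])
        if loc_kind == "text":
            loc = _text_loc(b, ledger, text, a_id)
        elif loc_kind == "figure":
            loc = FigureLocalizer(str(b.rng.randint(1, 8)))
            ledger.localizer_counts["figure"] += 1
        else:
            loc = TableLocalizer(str(b.rng.randint(1, 4)))
            ledger.localizer_counts["table"] += 1
        anns.append(Annotation(a_id, did, loc,
                               tags=(b.term("syn_region_thal"),),
                               authors=(b.rng.choice(["curator_a", "curator_b"]),),
                               parameters=(p,)))
    return anns


# --- seeded invariant violations ------------------------------------------

@dataclass(frozen=True)
class PlantedViolation:
    file: Path
    invariant: str
    annotation_id: str


_VIOLATION_ROTATION = [
    "duplicate-statistic-role",
    "missing-required-tag",
    "bad-offset",
    "empty-magnitudes",
    "missing-format-version",
    "trace-not-monotone",
]


def _applicable(ann: Annotation, name: str) -> bool:
    from .model import NumericalTraceDesc as Trace, PointValueDesc as Point
    if name == "duplicate-statistic-role":
        return any(isinstance(p.description, Point) for p in ann.parameters)
    if name == "missing-required-tag":
        # restricted to single-required-root types so exactly one issue results
        return any(p.type_name in ("neuron_density", "input_resistance",
                                   "resting_membrane_potential", "spike_amplitude")
                   and p.required_tag_instances for p in ann.parameters)
    if name == "bad-offset":
        return isinstance(ann.localizer, TextLocalizer)
    if name == "empty-magnitudes":
        return any(isinstance(p.description, Point)
                   and isinstance(p.description.values, ValuesSimple)
                   for p in ann.parameters)
    if name == "missing-format-version":
        return True
    if name == "trace-not-monotone":
        return any(isinstance(p.description, Trace) for p in ann.parameters)
    return False


def _apply_violation(ann: Annotation, name: str) -> Annotation:
    from .model import NumericalTraceDesc as Trace, PointValueDesc as Point
    params = list(ann.parameters)
    if name == "duplicate-statistic-role":
        for i, p in enumerate(params):
            if isinstance(p.description, Point):
                unit = "mV"
                v = p.description.values
                if isinstance(v, ValuesSimple):
                    unit = v.unit
                elif isinstance(v, ValuesCompound):
                    unit = v.components[0].unit
                bad = ValuesCompound((_simple([1.0], unit, "mean"),
                                      _simple([2.0], unit, "mean")))
                params[i] = replace(p, description=PointValueDesc(bad))
                break
        ann.parameters = tuple(params)
    elif name == "missing-required-tag":
        for i, p in enumerate(params):
            if p.type_name in ("neuron_density", "input_resistance",
                               "resting_membrane_potential", "spike_amplitude") \
                    and p.required_tag_instances:
                params[i] = replace(p, required_tag_instances=())
                break
        ann.parameters = tuple(params)
    elif name == "bad-offset":
        loc = ann.localizer
        ann.localizer = TextLocalizer(loc.snippet, loc.start_offset + 3)
    elif name == "empty-magnitudes":
        for i, p in enumerate(params):
            if isinstance(p.description, Point) and \
                    isinstance(p.description.values, ValuesSimple):
                v = p.description.values
                params[i] = replace(p, description=PointValueDesc(
                    ValuesSimple((), v.unit, v.statistic)))
                break
        ann.parameters = tuple(params)
    elif name == "missing-format-version":
        ann.format_version = ""
    elif name == "trace-not-monotone":
        for i, p in enumerate(params):
            if isinstance(p.description, Trace):
                t = p.description
                mags = list(t.independent.magnitudes)
                mags[-1] = mags[0]  # duplicate knot survives the load-time sort
                params[i] = replace(p, description=NumericalTraceDesc(
                    TraceAxis(t.independent.type_name, t.independent.unit,
                              tuple(mags)),
                    t.dependent))
                break
        ann.parameters = tuple(params)
    return ann


def seeded_violations(corpus_dir, seed: int, n: int) -> list[PlantedViolation]:
    """Mutate ``n`` annotations in a generated corpus, each breaking
    exactly one named invariant, and return the ledger of breaks.

    The corpus must have been produced by :func:`generate_corpus` (the
    mutations assume its structure). Files are rewritten through the
    unchecked serializer, since the validated writer refuses broken
    records by design.
    """
    from .model import deserialize
    corpus_dir = Path(corpus_dir)
    files = sorted(corpus_dir.glob("*.pcr"))
    pool: list[tuple[Path, int, Annotation]] = []
    per_file: dict[Path, list[Annotation]] = {}
    for f in files:
        anns = deserialize(f.read_text(encoding="utf-8"))
        per_file[f] = anns
        for idx, a in enumerate(anns):
            pool.append((f, idx, a))
    if n > len(pool):
        raise ValueError(f"cannot plant {n} violations in {len(pool)} annotations")
    rng = random.Random(seed)
    rng.shuffle(pool)
    planted: list[PlantedViolation] = []
    rotation = 0
    used: set[tuple[Path, int]] = set()
    for f, idx, ann in pool:
        if len(planted) == n:
            break
        if (f, idx) in used:
            continue
        # pick the next applicable violation in rotation order
        name = None
        for step in range(len(_VIOLATION_ROTATION)):
            cand = _VIOLATION_ROTATION[(rotation + step) % len(_VIOLATION_ROTATION)]
            if _applicable(ann, cand):
                name = cand
                rotation = (rotation + step + 1) % len(_VIOLATION_ROTATION)
                break
        if name is None:
            continue
        _apply_violation(ann, name)
        used.add((f, idx))
        planted.append(PlantedViolation(f, name, ann.annotation_id))
    if len(planted) < n:
        raise ValueError(f"only {len(planted)} of {n} violations were applicable")
    for f, anns in per_file.items():
        f.write_text(serialize(anns, check=False), encoding="utf-8", newline="\n")
    return planted
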