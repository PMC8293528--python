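"""Deterministic synthetic corpora with planted gold mentions and distractors.

Real full-text evaluation corpora are collections of complete journal
articles and cannot be shipped; this module emulates their statistically
relevant features at desk scale so the precision/recall behavior of
every pattern library can be exercised against an exact, machine-known
gold standard:

* planted residue/mutation mentions across the nomenclature variants
  that occur in articles (no-space and spaced, 1-letter / 3-letter /
  full-name codes, wNm and arrow mutations, single-digit positions);
* distractor fragments drawn from the classes of text that regex
  extraction is known to mistake for mentions (motif names like "S4",
  equipment like a "C18 column", bibliography entries, protein and
  strain names like "T7" or "W3110", short names, PDF-conversion
  artifacts like "P 450", chemical formulas like "C18H27NO3");
* an optional bibliography tail containing citation-style distractors
  and no gold mentions, so the effect of bibliography stripping on FP
  versus TP/FN is directly measurable;
* filler prose from a fixed lowercase word list that cannot collide
  with any capital-letter+digit pattern.

Planted positions are drawn from 101-999 (minus a small exclusion set)
and distractor tokens use numbers outside that range, so a distractor
can never alias a planted gold key.  A single seeded random stream
drives all choices: identical config + seed gives byte-identical output.

The generator makes no attempt to mimic real journal layout, genuine PDF
conversion, or the (unknown) real-world frequency distribution of
mention formats — the default form mix is uniform and documented as an
arbitrary choice.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

from .aminoacids import AMINO_ACIDS, Document, ResidueMention
from .evaluate import GoldStandard, save_gold_file

__all__ = [
    "FORMS",
    "FORM_COVERAGE",
    "DISTRACTOR_CLASSES",
    "CorpusConfig",
    "CorpusLedger",
    "PlantedSpan",
    "DistractorSpan",
    "plant_forms",
    "generate",
    "write_corpus",
]

#: Mention nomenclature variants the generator can plant.
FORMS: tuple[str, ...] = (
    "one_letter",
    "one_letter_spaced",
    "three_letter",
    "three_letter_spaced",
    "full_name",
    "wnm",
    "arrow",
    "single_digit",
)

_RESIDUE_FORMS = frozenset(
    {"one_letter", "one_letter_spaced", "three_letter", "three_letter_spaced",
     "full_name", "single_digit"}
)
_MUTATION_FORMS = frozenset({"wnm", "arrow"})

#: Which planted forms each library recovers with the exact gold key.
#: The cut residue libraries keep the common no-space/spaced notations
#: (with optional wNm mutant); only the full Regex 3 handles arrows; the
#: mutation-only lineage sees nothing but wNm.
FORM_COVERAGE: dict[str, frozenset[str]] = {
    "mf": frozenset({"wnm"}),
    "mf_cut": frozenset({"wnm"}),
    "rf1": frozenset({"one_letter", "three_letter", "wnm", "single_digit"}),
    "rf1_cut": frozenset({"one_letter", "three_letter", "wnm", "single_digit"}),
    "rf2": frozenset(
        {"one_letter", "one_letter_spaced", "three_letter", "three_letter_spaced",
         "full_name", "wnm", "single_digit"}
    ),
}
FORM_COVERAGE["rf2_cut"] = FORM_COVERAGE["rf2"]
FORM_COVERAGE["rf3"] = frozenset(FORMS)
FORM_COVERAGE["rf3_cut"] = FORM_COVERAGE["rf2"]

DISTRACTOR_CLASSES: tuple[str, ...] = (
    "motif_name",
    "equipment_substrate",
    "bibliography_reference",
    "protein_ground_name",
    "short_name",
    "pdf_artifact",
    "formula_nomenclature",
)

# Template fragments per distractor class.  Numbers are kept outside the
# planted-position range 101-999 (or carry no capital-letter prefix) so
# distractor hits never alias a gold key; every class has at least one
# member the full Regex 3 turns into a false positive.
_DISTRACTOR_TEMPLATES: dict[str, tuple[str, ...]] = {
    "motif_name": (
        "the S4 voltage sensor segment moved outward",
        "within the S5 pore helix region",
        "near the S6 bundle crossing",
    ),
    "equipment_substrate": (
        "purified on a C18 reverse phase column",
        "transcribed with T7 polymerase in vitro",
        "desalted over a G 25 column",
    ),
    "bibliography_reference": (
        "j. gen. physiol. 438, no. 2 (1999): 141-146.",
        "proc. natl. acad. sci. U S A 96, 1234-1239 (1999).",
        "biophys. j. 77, 1999-2013 (1999).",
    ),
    "protein_ground_name": (
        "binding of histone H3 at the promoter",
        "transfected into HEK293 cells",
        "infection with bacteriophage T7",
    ),
    "short_name": (
        "the S100 cytosolic fraction was retained",
        "strain W3110 served as the wild type host",
    ),
    "pdf_artifact": (
        "cytochrome P 450 activity was monitored",
        "caption rendered as T able after conversion",
    ),
    "formula_nomenclature": (
        "oxidized by H2O2 treatment",
        "the compound C18H27NO3 was dissolved",
        "precipitated with CaCl2 on ice",
    ),
}

# Lowercase filler vocabulary: no digits, no capitals, no amino-acid
# names, hence no way to collide with any pattern.
_FILLER_WORDS: tuple[str, ...] = (
    "the", "mutant", "channel", "binding", "was", "measured", "during",
    "gating", "and", "current", "amplitude", "membrane", "potential",
    "shifted", "between", "recordings", "results", "showed", "that",
    "activation", "kinetics", "under", "control", "conditions", "were",
    "compared", "across", "independent", "experiments", "with", "similar",
    "voltage", "dependence", "of", "steady", "state", "inactivation",
)

# Planted positions: 101-999 minus values a distractor token could
# produce ("HEK293", "P 450") plus the bibliography page range.
_POSITION_EXCLUSIONS = frozenset({141, 146, 293, 450})
# Single-digit plantings avoid the letters of the short distractor keys
# (S4/S5/S6, T7, H2/H3) so gold never collides with a distractor.
_SINGLE_DIGIT_LETTERS = tuple(
    a.one_letter for a in AMINO_ACIDS if a.one_letter not in {"S", "T", "H", "F", "C"}
)

_BY_ONE = {a.one_letter: a for a in AMINO_ACIDS}


def plant_forms(mention: ResidueMention, form: str) -> str:
    """Render a mention in one nomenclature variant.

    The fragment re-extracts to exactly the planted mention under the
    full Regex 3 library.  Residue forms require ``mention.mutant`` to be
    absent, mutation forms require it present; mismatches raise.
    """
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}; expected one of {FORMS}")
    if form in _MUTATION_FORMS and mention.mutant is None:
        raise ValueError(f"form {form!r} requires a mutation mention, got {mention.key}")
    if form in _RESIDUE_FORMS and mention.mutant is not None:
        raise ValueError(f"form {form!r} requires a residue mention, got {mention.key}")
    acid = _BY_ONE[mention.wild_type]
    pos = mention.position
    if form == "one_letter":
        return f"{acid.one_letter}{pos}"
    if form == "one_letter_spaced":
        return f"{acid.one_letter} {pos}"
    if form == "three_letter":
        return f"{acid.three_letter}{pos}"
    if form == "three_letter_spaced":
        return f"{acid.three_letter} {pos}"
    if form == "full_name":
        return f"{acid.full_name} {pos}"
    if form == "single_digit":
        if pos > 9:
            raise ValueError(f"form 'single_digit' requires position <= 9, got {pos}")
        return f"{acid.one_letter}{pos}"
    if form == "wnm":
        return f"{acid.one_letter}{pos}{mention.mutant}"
    return f"{acid.one_letter}{pos}→{mention.mutant}"  # arrow


@dataclass(frozen=True)
class CorpusConfig:
    """Study conditions for one synthetic corpus.

    ``form_mix`` and ``distractor_mix`` are non-negative weights; zero
    weight removes a variant.  ``mentions_per_doc`` and
    ``distractors_per_doc`` are inclusive ranges sampled uniformly.
    """

    n_docs: int = 20
    seed: int = 0
    mentions_per_doc: tuple[int, int] = (3, 8)
    distractors_per_doc: tuple[int, int] = (2, 5)
    form_mix: dict[str, float] = field(
        default_factory=lambda: {form: 1.0 for form in FORMS}
    )
    distractor_mix: dict[str, float] = field(
        default_factory=lambda: {cls: 1.0 for cls in DISTRACTOR_CLASSES}
    )
    include_bibliography: bool = False

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        for mix, valid, label in (
            (self.form_mix, FORMS, "form_mix"),
            (self.distractor_mix, DISTRACTOR_CLASSES, "distractor_mix"),
        ):
            for key, weight in mix.items():
                if key not in valid:
                    raise ValueError(f"{label}: unknown key {key!r}")
                if weight < 0:
                    raise ValueError(f"{label}: negative weight for {key!r}")
        if self.mentions_per_doc[1] > 0 and not any(v > 0 for v in self.form_mix.values()):
            raise ValueError("mentions requested but form_mix has no positive weight")


@dataclass(frozen=True)
class PlantedSpan:
    doc_id: str
    span: tuple[int, int]
    key: str
    form: str


@dataclass(frozen=True)
class DistractorSpan:
    doc_id: str
    span: tuple[int, int]
    cls: str


@dataclass
class CorpusLedger:
    """Exact record of everything the generator put into the corpus."""

    planted: list[PlantedSpan] = field(default_factory=list)
    distractors: list[DistractorSpan] = field(default_factory=list)


def _weighted_choice(rng: random.Random, mix: dict[str, float]) -> str:
    items = [(k, w) for k, w in mix.items() if w > 0]
    keys = [k for k, _ in items]
    weights = [w for _, w in items]
    return rng.choices(keys, weights=weights, k=1)[0]


def _sample_mention(rng: random.Random, form: str) -> ResidueMention:
    if form == "single_digit":
        wild_type = rng.choice(_SINGLE_DIGIT_LETTERS)
        position = rng.randint(1, 9)
    else:
        wild_type = rng.choice(AMINO_ACIDS).one_letter
        position = rng.randint(101, 999)
        while position in _POSITION_EXCLUSIONS:
            position = rng.randint(101, 999)
    mutant = None
    if form in _MUTATION_FORMS:
        mutant = rng.choice(AMINO_ACIDS).one_letter
    return ResidueMention(wild_type, position, mutant)


class _DocBuilder:
    """Accumulates text pieces while tracking character offsets."""

    def __init__(self) -> None:
        self.pieces: list[str] = []
        self.length = 0

    def add(self, piece: str) -> tuple[int, int]:
        start = self.length
        self.pieces.append(piece)
        self.length += len(piece)
        return (start, self.length)

    @property
    def text(self) -> str:
        return "".join(self.pieces)


def _add_filler(builder: _DocBuilder, rng: random.Random, low: int = 2, high: int = 6) -> None:
    words = [rng.choice(_FILLER_WORDS) for _ in range(rng.randint(low, high))]
    builder.add(" ".join(words))


def generate(config: CorpusConfig) -> tuple[list[Document], GoldStandard, CorpusLedger]:
    """Generate a corpus: documents, the gold standard, and the ledger.

    Gold maps doc_id -> key -> occurrence count (single-count scoring
    uses the key set, full-count the counts).  The ledger holds exact
    spans for every planted mention and every distractor, including
    those in the bibliography tail.
    """
    rng = random.Random(config.seed)
    documents: list[Document] = []
    gold: GoldStandard = {}
    ledger = CorpusLedger()

    distractors_enabled = any(w > 0 for w in config.distractor_mix.values())

    for doc_index in range(config.n_docs):
        doc_id = f"synth{doc_index:04d}"
        n_mentions = rng.randint(*config.mentions_per_doc)
        n_distractors = (
            rng.randint(*config.distractors_per_doc) if distractors_enabled else 0
        )

        events: list[tuple[str, Optional[str]]] = [("mention", None)] * n_mentions
        events += [("distractor", None)] * n_distractors
        rng.shuffle(events)

        builder = _DocBuilder()
        counts: dict[str, int] = {}
        pending: list = []  # spans recorded relative to this doc
        n_abstract = max(1, math.ceil(len(events) * 0.25)) if events else 0

        _add_filler(builder, rng)
        for event_index, (kind, _) in enumerate(events):
            builder.add(" ")
            if kind == "mention":
                form = _weighted_choice(rng, config.form_mix)
                mention = _sample_mention(rng, form)
                span = builder.add(plant_forms(mention, form))
                counts[mention.key] = counts.get(mention.key, 0) + 1
                pending.append(PlantedSpan(doc_id, span, mention.key, form))
            else:
                cls = _weighted_choice(rng, config.distractor_mix)
                span = builder.add(rng.choice(_DISTRACTOR_TEMPLATES[cls]))
                pending.append(DistractorSpan(doc_id, span, cls))
            builder.add(" ")
            _add_filler(builder, rng)
            if event_index + 1 == n_abstract and event_index + 1 < len(events):
                abstract_end = builder.length
                builder.add("\n\n")
            elif event_index + 1 == len(events):
                builder.add(".")
        if not events or n_abstract >= len(events):
            abstract_end = builder.length

        section_map: dict[str, tuple[int, int]] = {"abstract": (0, abstract_end)}

        if config.include_bibliography:
            bib_lines: list[tuple[str, str]] = []
            for _ in range(rng.randint(3, 6)):
                bib_lines.append(
                    ("bibliography_reference",
                     rng.choice(_DISTRACTOR_TEMPLATES["bibliography_reference"]))
                )
            bib_length = sum(len(line) + 4 for _, line in bib_lines)
            # Keep the heading inside the first half of the text so the
            # stripper's 50% guard recognizes the tail.
            while builder.length < bib_length + 20:
                builder.add(" ")
                _add_filler(builder, rng)
            body_end = builder.length
            builder.add("\n\nReferences\n")
            for ref_index, (cls, line) in enumerate(bib_lines, start=1):
                builder.add(f"{ref_index}. ")
                span = builder.add(line)
                pending.append(DistractorSpan(doc_id, span, cls))
                builder.add("\n")
            section_map["body"] = (section_map["abstract"][1], body_end)
            section_map["bibliography"] = (body_end + 2, builder.length)

        text = builder.text
        documents.append(Document(doc_id, text, section_map))
        gold[doc_id] = counts
        for item in pending:
            start, end = item.span
            assert text[start:end], "ledger span must be non-empty"
            if isinstance(item, PlantedSpan):
                ledger.planted.append(item)
            else:
                ledger.distractors.append(item)

    return documents, gold, ledger


def write_corpus(
    documents: list[Document],
    gold: GoldStandard,
    ledger: CorpusLedger,
    out_dir: Union[str, Path],
) -> None:
    """Write per-document text files plus gold and ledger TSVs.

    Layout: ``<doc_id>.txt`` per document, ``gold.tsv`` in the standard
    gold-file dialect, ``distractors.tsv`` (doc_id, start, end, class)
    and ``planted.tsv`` (doc_id, start, end, key, form).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for document in documents:
        (out_dir / f"{document.doc_id}.txt").write_text(
            document.text, encoding="utf-8", newline="\n"
        )
    save_gold_file(gold, out_dir / "gold.tsv")
    with (out_dir / "distractors.tsv").open("w", encoding="utf-8", newline="\n") as handle:
        for item in ledger.distractors:
            handle.write(f"{item.doc_id}\t{item.span[0]}\t{item.span[1]}\t{item.cls}\n")
    with (out_dir / "planted.tsv").open("w", encoding="utf-8", newline="\n") as handle:
        for item in ledger.planted:
            handle.write(
                f"{item.doc_id}\t{item.span[0]}\t{item.span[1]}\t{item.key}\t{item.form}\n"
            )


def restricted_to_forms(config: CorpusConfig, forms: frozenset[str]) -> CorpusConfig:
    """A copy of ``config`` whose form mix is restricted to ``forms``."""
    mix = {f: w for f, w in config.form_mix.items() if f in forms and w > 0}
    if not mix:
        mix = {f: 1.0 for f in forms}
    return replace(config, form_mix=mix)
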