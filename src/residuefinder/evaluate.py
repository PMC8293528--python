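"""Score extraction output against a gold standard; precision, recall, F_beta.

The extractor is treated as a binary classifier over normalized mention
keys: per document, each key is either returned or not.  True negatives
are never counted — "this residue was not mentioned and we did not
return it" is not a useful event when the key universe is unbounded.

Counting rules, summed over documents:

* single mode — TP = |extracted ∩ gold|, FP = |extracted \\ gold|,
  FN = |gold \\ extracted| on the per-document key *sets*;
* full mode — per key, TP += min(extracted count, gold count), the
  excess on either side goes to FP or FN (multiset intersection).

F_beta = ((beta^2 + 1) * P * R) / (beta^2 * P + R).  beta = 1 balances
precision and recall; beta > 1 weights recall more heavily — the usual
choice for literature retrieval, where a false positive can be discarded
on inspection but a false negative is lost for good; beta = 0 collapses
to precision.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .aminoacids import InvalidMentionError, parse_mention_key

__all__ = [
    "GoldStandard",
    "EvalResult",
    "score",
    "precision_recall",
    "f_beta",
    "error_breakdown",
    "FP_CLASSES",
    "FN_CLASSES",
    "load_gold_file",
    "save_gold_file",
    "format_report",
]

#: Analyst vocabulary for false-positive causes (what a matched string
#: actually was: a motif name like "S4", lab equipment like a "C18
#: column", a bibliography entry, a protein/strain name like "T7" or
#: "H3", a short name, a PDF-conversion artifact, or chemical-formula
#: nomenclature like "C18H27NO3").
FP_CLASSES: tuple[str, ...] = (
    "motif_name",
    "equipment_substrate",
    "bibliography_reference",
    "protein_ground_name",
    "short_name",
    "pdf_artifact",
    "formula_nomenclature",
)

#: False-negative causes: the mention was embedded in a non-readable
#: image, or no pattern in the library covered its format.
FN_CLASSES: tuple[str, ...] = ("in_image", "regex_not_found")

#: Per-document expected mentions: doc_id -> key -> count.  Single-count
#: gold uses count 1 everywhere.
GoldStandard = dict[str, dict[str, int]]


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """Precision and recall from raw counts.

    Degenerate denominators follow the usual conventions: with nothing
    extracted, precision is 1.0 if there was also nothing to find and
    0.0 otherwise; with nothing to find, recall is 1.0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("tp, fp, fn must be non-negative")
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision = 1.0 if fn == 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 1.0
    return precision, recall


def f_beta(precision: float, recall: float, beta: float) -> float:
    """F_beta = ((beta^2+1) P R) / (beta^2 P + R); 0.0 when the denominator is 0."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    denominator = beta * beta * precision + recall
    if denominator == 0:
        return 0.0
    return (beta * beta + 1) * precision * recall / denominator


@dataclass
class EvalResult:
    """TP/FP/FN counts with the derived statistics."""

    tp: int
    fp: int
    fn: int
    betas: tuple[float, ...] = (1.0, 2.0)
    precision: float = field(init=False)
    recall: float = field(init=False)
    f_scores: dict[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.precision, self.recall = precision_recall(self.tp, self.fp, self.fn)
        self.f_scores = {b: f_beta(self.precision, self.recall, b) for b in self.betas}

    def rounded(self, digits: int = 3) -> dict[str, float]:
        """Display rounding (round-half-even, 3 decimals by default)."""
        out = {"P": round(self.precision, digits), "R": round(self.recall, digits)}
        for b in self.betas:
            label = f"F{int(b)}" if float(b).is_integer() else f"F{b}"
            out[label] = round(self.f_scores[b], digits)
        return out


def _as_counts(mentions: Union[Mapping[str, int], Iterable[str]], doc_id: str) -> Counter:
    if isinstance(mentions, Mapping):
        counts = Counter({k: int(v) for k, v in mentions.items()})
    else:
        counts = Counter(mentions)
    for key in counts:
        try:
            parse_mention_key(key)
        except InvalidMentionError as exc:
            raise InvalidMentionError(f"document {doc_id!r}: bad mention key {key!r}") from exc
    return counts


def score(
    extracted: Mapping[str, Union[Mapping[str, int], Iterable[str]]],
    gold: Mapping[str, Union[Mapping[str, int], Iterable[str]]],
    mode: str = "single",
    betas: Sequence[float] = (1.0, 2.0),
) -> EvalResult:
    """Score per-document extracted mentions against gold.

    Both arguments map doc_id to either an iterable of keys or a
    key -> count mapping; documents missing on one side count as empty.
    """
    if mode not in ("single", "full"):
        raise ValueError(f"mode must be 'single' or 'full', got {mode!r}")
    tp = fp = fn = 0
    for doc_id in set(extracted) | set(gold):
        found = _as_counts(extracted.get(doc_id, {}), doc_id)
        expected = _as_counts(gold.get(doc_id, {}), doc_id)
        if mode == "single":
            found = Counter(dict.fromkeys(found, 1))
            expected = Counter(dict.fromkeys(expected, 1))
        for key in set(found) | set(expected):
            overlap = min(found[key], expected[key])
            tp += overlap
            fp += found[key] - overlap
            fn += expected[key] - overlap
    return EvalResult(tp, fp, fn, tuple(float(b) for b in betas))


def error_breakdown(
    labeled: Iterable[Union[str, Sequence[str]]],
    classes: Sequence[str],
) -> dict[str, tuple[int, float]]:
    """Tally analyst cause labels into class -> (count, percent).

    ``labeled`` holds one label, or one sequence of labels, per record;
    multi-label records contribute one incidence to each of their
    classes, so the counts can sum to more than the number of records.
    Percentages are of total labeled incidences.  Unknown labels raise.
    """
    valid = set(classes)
    counts: dict[str, int] = {}
    for labels in labeled:
        if isinstance(labels, str):
            labels = [labels]
        for label in labels:
            if label not in valid:
                raise ValueError(f"unknown error class {label!r}; expected one of {sorted(valid)}")
            counts[label] = counts.get(label, 0) + 1
    total = sum(counts.values())
    return {
        cls: (counts[cls], 100.0 * counts[cls] / total)
        for cls in classes
        if cls in counts
    }


# --------------------------------------------------------------------------
# Gold-file and report IO
# --------------------------------------------------------------------------

def load_gold_file(path: Union[str, Path]) -> GoldStandard:
    """Read a gold file: per line ``doc_id<TAB>key[:count][,key[:count]...]``.

    A bare ``doc_id`` line declares a document with no expected mentions;
    ``#`` lines are comments.  Every key must parse as a canonical
    mention rendering.
    """
    path = Path(path)
    gold: GoldStandard = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            doc_id, _, rest = line.partition("\t")
            counts: dict[str, int] = {}
            if rest.strip():
                for item in rest.strip().split(","):
                    key, _, n = item.strip().partition(":")
                    try:
                        parse_mention_key(key)
                    except InvalidMentionError as exc:
                        raise InvalidMentionError(
                            f"{path.name}:{lineno}: document {doc_id!r}: bad gold key {key!r}"
                        ) from exc
                    counts[key] = counts.get(key, 0) + (int(n) if n else 1)
            gold[doc_id] = counts
    return gold


def save_gold_file(gold: GoldStandard, path: Union[str, Path]) -> None:
    lines = []
    for doc_id in sorted(gold):
        items = ",".join(
            f"{key}:{count}" if count != 1 else key
            for key, count in sorted(gold[doc_id].items())
        )
        lines.append(f"{doc_id}\t{items}" if items else doc_id)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def format_report(result: EvalResult, label: str = "run") -> str:
    """One TSV report block: header plus a row of TP FP FN P R F columns."""
    stats = result.rounded()
    header = ["run", "TP", "FP", "FN", *stats.keys()]
    row = [label, str(result.tp), str(result.fp), str(result.fn)]
    row += [f"{v:.3f}" for v in stats.values()]
    return "\t".join(header) + "\n" + "\t".join(row) + "\n"
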