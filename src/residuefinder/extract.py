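"""Apply a pattern library to documents and produce normalized mentions.

The scanning contract:

* spans are 0-based, half-open character offsets into the document text;
* every pattern is scanned for *all* of its match start positions (the
  scan restarts one character after each hit, so overlapping occurrences
  of the same pattern are not lost);
* a candidate that fails normalization (unknown identifier, position 0,
  leading zero, single-digit position when disallowed) is discarded;
* at a given start offset, the longest parse wins — "S56A" yields the
  mutation S56A, not additionally the embedded residue S56, because both
  describe one textual event;
* a record whose span is contained in another record's span with the
  same mention key is dropped (e.g. the bare "A64" inside "ALA64");
* surviving records are reported in ascending span order.

Single-count versus full-count reporting happens after scanning: single
count registers each unique normalized key at most once per document
(the default — "residue X is mentioned in this article"), full count
keeps every textual occurrence.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Union

from .aminoacids import Document, InvalidMentionError, ResidueMention, UnrecognizedResidueError, normalize_mention
from .library import RegexLibrary

__all__ = [
    "MatchRecord",
    "ExtractionResult",
    "extract",
    "count_mentions",
    "strip_bibliography",
    "abstract_of",
    "read_document",
    "read_documents",
    "read_corpus_file",
]

CountMode = Literal["single", "full"]


@dataclass(frozen=True)
class MatchRecord:
    """One library hit: where it was found, what matched, what it means."""

    doc_id: str
    span: tuple[int, int]
    raw_text: str
    pattern_id: str
    mention: ResidueMention


@dataclass
class ExtractionResult:
    """All surviving matches of one document plus the unique-key view."""

    doc_id: str
    matches: list[MatchRecord] = field(default_factory=list)

    @property
    def unique_mentions(self) -> set[str]:
        return {m.mention.key for m in self.matches}

    def keys_in_order(self) -> list[str]:
        """Unique keys in first-occurrence order (single-count output order)."""
        seen: list[str] = []
        for m in self.matches:
            if m.mention.key not in seen:
                seen.append(m.mention.key)
        return seen


def _parse_candidate(
    m: re.Match[str], allow_single_digit: bool
) -> Optional[ResidueMention]:
    groups = m.groupdict()
    pos_token = groups.get("pos")
    wt_token = groups.get("wt_res")
    if not pos_token or not wt_token:
        return None
    if not allow_single_digit and len(pos_token) < 2:
        return None
    try:
        return normalize_mention(wt_token, pos_token, groups.get("mut_res"))
    except (InvalidMentionError, UnrecognizedResidueError):
        return None


def extract(
    document: Document,
    library: RegexLibrary,
    allow_single_digit: Optional[bool] = None,
) -> ExtractionResult:
    """Scan one document with one library.

    ``allow_single_digit`` defaults per lineage: the residue libraries
    accept single-digit positions (they are real residues near the start
    of the sequence), the ``mf`` lineage keeps its historical two-or-more
    digit requirement.  Pass an explicit boolean to override.
    """
    if allow_single_digit is None:
        allow_single_digit = not library.is_mutation_only
    text = document.text
    candidates: list[tuple[int, int, int, ResidueMention]] = []
    for index, rx in enumerate(library.compiled):
        pos = 0
        while (m := rx.search(text, pos)) is not None:
            pos = m.start() + 1
            mention = _parse_candidate(m, allow_single_digit)
            if mention is not None:
                candidates.append((m.start(), m.end(), index, mention))

    # Longest parse per start offset; prefer a mutation over a residue,
    # then earlier library order, when lengths tie.
    best: dict[int, tuple[int, int, int, ResidueMention]] = {}
    for cand in candidates:
        start, end, index, mention = cand
        held = best.get(start)
        if held is None:
            best[start] = cand
            continue
        rank = (-end, not mention.is_mutation, index)
        held_rank = (-held[1], not held[3].is_mutation, held[2])
        if rank < held_rank:
            best[start] = cand

    ordered = sorted(best.values(), key=lambda c: (c[0], c[1]))
    # Drop records nested inside a longer record with the same key.
    kept: list[tuple[int, int, int, ResidueMention]] = []
    for cand in ordered:
        start, end, _, mention = cand
        contained = any(
            s <= start and end <= e and mention.key == held.key and (s, e) != (start, end)
            for s, e, _, held in ordered
        )
        if not contained:
            kept.append(cand)

    records = [
        MatchRecord(document.doc_id, (s, e), text[s:e], library.entries[i].pattern_id, mention)
        for s, e, i, mention in kept
    ]
    return ExtractionResult(document.doc_id, records)


def count_mentions(result: ExtractionResult, mode: CountMode = "single") -> dict[str, int]:
    """Mention-key -> count mapping in single- or full-count mode."""
    if mode not in ("single", "full"):
        raise ValueError(f"mode must be 'single' or 'full', got {mode!r}")
    counts: dict[str, int] = {}
    for record in result.matches:
        key = record.mention.key
        counts[key] = counts.get(key, 0) + 1
    if mode == "single":
        return {key: 1 for key in counts}
    return counts


# --------------------------------------------------------------------------
# Document sectioning
# --------------------------------------------------------------------------

_BIB_HEADING = re.compile(
    r"^[ \t]*(references|bibliography|literature cited)[ \t.:]*$",
    re.IGNORECASE | re.MULTILINE,
)


def strip_bibliography(document: Document) -> Document:
    """Remove a trailing bibliography section, if one is recognizable.

    If a heading line ("References", "Bibliography", "Literature Cited")
    occurs on its own line in the final 50% of the text, everything from
    that heading onward is removed; the returned document's section map
    records the retained body.  Otherwise the document is returned
    unchanged.  Bibliographies yield almost no true mentions, so this
    trades a little text handling for a precision gain at no recall cost.
    """
    text = document.text
    half = len(text) / 2
    for m in _BIB_HEADING.finditer(text):
        if m.start() >= half:
            body = text[: m.start()]
            section_map = {
                label: span
                for label, span in document.section_map.items()
                if span[1] <= len(body)
            }
            if not section_map:
                section_map["body"] = (0, len(body))
            return Document(document.doc_id, body, section_map)
    return document


def abstract_of(document: Document) -> Document:
    """The abstract-only view of a document.

    Uses the labeled ``abstract`` region when present, otherwise the text
    before the first blank line (a serviceable heuristic for plain-text
    articles).  Used to compare abstract-only against full-text runs.
    """
    region = document.region("abstract")
    if region is None:
        head, sep, _ = document.text.partition("\n\n")
        region = head if sep else document.text
    return Document(document.doc_id, region, {"abstract": (0, len(region))})


# --------------------------------------------------------------------------
# Input readers
# --------------------------------------------------------------------------

def _clean(text: str) -> str:
    return unicodedata.normalize("NFC", text)


def read_document(path: Union[str, Path]) -> Document:
    """Read one UTF-8 plain-text file; the document id is the file stem."""
    path = Path(path)
    return Document(path.stem, _clean(path.read_text(encoding="utf-8")))


def read_documents(paths: Iterable[Union[str, Path]]) -> list[Document]:
    return [read_document(p) for p in paths]


def read_corpus_file(path: Union[str, Path]) -> list[Document]:
    """Read a delimited corpus file: one ``doc_id<TAB>text`` record per line.

    Literal ``\\n`` / ``\\t`` escapes in the text field are unescaped, so
    multi-line documents survive the one-record-per-line framing.
    """
    path = Path(path)
    documents: list[Document] = []
    with path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            doc_id, sep, text = line.partition("\t")
            if not sep:
                raise ValueError(f"{path.name}:{lineno}: expected 'doc_id<TAB>text'")
            text = text.replace("\\n", "\n").replace("\\t", "\t")
            documents.append(Document(doc_id, _clean(text)))
    return documents
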