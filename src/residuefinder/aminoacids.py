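"""Amino-acid nomenclature tables and the normalized mention data model.

A *residue mention* is a textual reference to a specific amino acid at a
specific sequence position in a protein ("Ser56", "S 56", "serine 56"); a
*mutation mention* additionally names the substituting acid in the wNm
style ("A64G" = alanine 64 replaced by glycine).  Every downstream module
normalizes what it finds in text to the canonical one-letter rendering
defined here, so that "Ser56", "S56" and "serine 56" all score as the same
event.

Only the 20 canonical proteinogenic amino acids are modelled.  Ambiguity
codes (B, Z, X) and the non-canonical acids (selenocysteine, pyrrolysine)
are deliberately outside the alphabet: a capital U followed by a number is
never a residue mention here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional

__all__ = [
    "AminoAcid",
    "AMINO_ACIDS",
    "ONE_LETTER_CODES",
    "UnrecognizedResidueError",
    "InvalidMentionError",
    "to_one_letter",
    "ResidueMention",
    "normalize_mention",
    "parse_mention_key",
    "Document",
]


@dataclass(frozen=True)
class AminoAcid:
    """One canonical amino acid with its three standard namings."""

    one_letter: str
    three_letter: str
    full_name: str


#: The 20 canonical amino acids.  one_letter / three_letter / full_name are
#: pairwise bijections; the one-letter codes are 20 of the 26 capitals
#: (B, J, O, U, X, Z are unused).
AMINO_ACIDS: tuple[AminoAcid, ...] = (
    AminoAcid("A", "Ala", "alanine"),
    AminoAcid("R", "Arg", "arginine"),
    AminoAcid("N", "Asn", "asparagine"),
    AminoAcid("D", "Asp", "aspartic acid"),
    AminoAcid("C", "Cys", "cysteine"),
    AminoAcid("Q", "Gln", "glutamine"),
    AminoAcid("E", "Glu", "glutamic acid"),
    AminoAcid("G", "Gly", "glycine"),
    AminoAcid("H", "His", "histidine"),
    AminoAcid("I", "Ile", "isoleucine"),
    AminoAcid("L", "Leu", "leucine"),
    AminoAcid("K", "Lys", "lysine"),
    AminoAcid("M", "Met", "methionine"),
    AminoAcid("F", "Phe", "phenylalanine"),
    AminoAcid("P", "Pro", "proline"),
    AminoAcid("S", "Ser", "serine"),
    AminoAcid("T", "Thr", "threonine"),
    AminoAcid("W", "Trp", "tryptophan"),
    AminoAcid("Y", "Tyr", "tyrosine"),
    AminoAcid("V", "Val", "valine"),
)

ONE_LETTER_CODES: frozenset[str] = frozenset(a.one_letter for a in AMINO_ACIDS)

# Common carboxylate synonyms accepted on input (canonical names stay the
# "-ic acid" forms so the tables remain bijective).
_NAME_SYNONYMS: Mapping[str, str] = {
    "aspartate": "D",
    "glutamate": "E",
}

_BY_ONE: Mapping[str, AminoAcid] = {a.one_letter: a for a in AMINO_ACIDS}
_BY_THREE: Mapping[str, str] = {a.three_letter: a.one_letter for a in AMINO_ACIDS}
_BY_NAME: Mapping[str, str] = {a.full_name: a.one_letter for a in AMINO_ACIDS}


class InvalidMentionError(ValueError):
    """Tokens do not assemble into a valid residue/mutation mention."""


class UnrecognizedResidueError(InvalidMentionError):
    """Token is not a recognized amino-acid identifier."""


def to_one_letter(token: str) -> str:
    """Map a residue-identifier token to its canonical one-letter code.

    Case policy: one-letter codes match uppercase only ("A" yes, "a" no);
    three-letter codes match title case and all-uppercase ("Ser", "SER");
    full names match case-insensitively.  Internal whitespace in full
    names ("aspartic acid") is collapsed to a single space.

    Raises :class:`UnrecognizedResidueError` for anything else — callers
    scanning text treat that as "this candidate match does not parse".
    """
    if not token:
        raise UnrecognizedResidueError("empty residue token")
    if len(token) == 1:
        if token in _BY_ONE:
            return token
        raise UnrecognizedResidueError(f"not an amino-acid code: {token!r}")
    if len(token) == 3:
        code = _BY_THREE.get(token) or _BY_THREE.get(token.capitalize() if token.isupper() else "")
        if code:
            return code
    name = " ".join(token.lower().split())
    if name in _BY_NAME:
        return _BY_NAME[name]
    if name in _NAME_SYNONYMS:
        return _NAME_SYNONYMS[name]
    raise UnrecognizedResidueError(f"not an amino-acid identifier: {token!r}")


@dataclass(frozen=True, order=True)
class ResidueMention:
    """A normalized residue or point-mutation mention.

    ``wild_type`` and (optionally) ``mutant`` are one-letter codes;
    ``position`` is the 1-based sequence location.  The canonical key is
    ``wild_type + position`` ("S56") for residue mentions and
    ``wild_type + position + mutant`` ("A64G") for mutation mentions.
    A mutation and a residue mention at the same site are distinct keys:
    "A64G" does not also register "A64".
    """

    wild_type: str
    position: int
    mutant: Optional[str] = None

    def __post_init__(self) -> None:
        if self.wild_type not in ONE_LETTER_CODES:
            raise InvalidMentionError(f"bad wild-type code {self.wild_type!r}")
        if not isinstance(self.position, int) or self.position < 1:
            raise InvalidMentionError(f"position must be a positive integer, got {self.position!r}")
        if self.mutant is not None and self.mutant not in ONE_LETTER_CODES:
            raise InvalidMentionError(f"bad mutant code {self.mutant!r}")

    @property
    def is_mutation(self) -> bool:
        return self.mutant is not None

    @property
    def key(self) -> str:
        """Canonical rendering, e.g. ``"S56"`` or ``"A64G"``."""
        if self.mutant is None:
            return f"{self.wild_type}{self.position}"
        return f"{self.wild_type}{self.position}{self.mutant}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key


def normalize_mention(
    wt_token: str, pos_token: str, mut_token: Optional[str] = None
) -> ResidueMention:
    """Assemble raw captured tokens into a canonical :class:`ResidueMention`.

    ``pos_token`` must be all digits with no leading zeros and denote a
    position >= 1 (protein numbering starts at 1; "S0" and "S07" are
    format noise, not mentions).  Single-digit positions are accepted —
    residues near the start of a sequence are real mentions.
    """
    wt = to_one_letter(wt_token)
    if not pos_token.isdigit():
        raise InvalidMentionError(f"position token is not numeric: {pos_token!r}")
    if pos_token[0] == "0":
        raise InvalidMentionError(f"position has a leading zero or is zero: {pos_token!r}")
    mut = to_one_letter(mut_token) if mut_token else None
    return ResidueMention(wt, int(pos_token), mut)


_KEY_RE = re.compile(r"^(?P<wt>[A-Z])(?P<pos>[1-9][0-9]*)(?P<mut>[A-Z])?$")


def parse_mention_key(key: str) -> ResidueMention:
    """Parse a canonical key ("S56", "A64G") back into a mention.

    Inverse of :attr:`ResidueMention.key`; used when reading gold-standard
    and extraction-output files.
    """
    m = _KEY_RE.match(key)
    if m is None:
        raise InvalidMentionError(f"not a canonical mention key: {key!r}")
    return normalize_mention(m.group("wt"), m.group("pos"), m.group("mut"))


@dataclass
class Document:
    """A plain-text document with optional labeled regions.

    ``section_map`` maps region labels ("abstract", "body", ...) to
    0-based half-open character ranges within ``text``.  Ranges must lie
    within bounds and not overlap.
    """

    doc_id: str
    text: str
    section_map: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spans = sorted(self.section_map.values())
        n = len(self.text)
        for start, end in spans:
            if not (0 <= start <= end <= n):
                raise ValueError(f"section range {(start, end)} outside document {self.doc_id!r}")
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping section ranges in document {self.doc_id!r}")

    def region(self, label: str) -> Optional[str]:
        """The text of one labeled region, or None if unlabeled."""
        if label not in self.section_map:
            return None
        start, end = self.section_map[label]
        return self.text[start:end]
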