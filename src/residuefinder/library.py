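"""Build, load, save and "cut" the residue/mutation regex pattern libraries.

Eight libraries are provided, named ``mf``, ``mf_cut``, ``rf1``, ``rf1_cut``,
``rf2``, ``rf2_cut``, ``rf3`` and ``rf3_cut``.  They form two lineages:

* ``mf`` holds mutation-only patterns in the MutationFinder style — a
  wild-type identifier immediately followed by a position immediately
  followed by a mutant identifier (wNm, "A64G" / "Ala64Gly").
* ``rf1`` is the residue analog: the mutant identifier is no longer
  required, so plain residue mentions ("S56", "Ser56") are found too.
* ``rf2`` is ``rf1`` plus variants allowing a single space between the
  wild-type identifier and the position number ("Ser 56") — standard
  nomenclature says no space, but published full text is full of them.
* ``rf3`` is ``rf2`` plus arrow-style substitutions ("S56→A", "S56-->A")
  and bare capital-letter+number patterns that ignore surrounding
  context entirely.  The bare patterns are what make Regex 3 highly
  sensitive and also what produce its characteristic false positives
  ("T7" as bacteriophage rather than threonine 7, "C18" columns, motif
  names like "S4"): context is deliberately not consulted.

The libraries here are rule-based **reconstructions**: they are generated
from an explicit combinatorial scheme rather than shipped as opaque
pattern files.  The scheme is chosen so the full Regex 3 reconstruction
has exactly 1518 expressions and its cut exactly 6:

====================================================  =====
22 wild-type forms x 22 mutant forms x 3 connectors    1452
residue patterns, no space (3 generic + 20 per-name)     23
residue patterns, single space (ditto)                   23
bare capital+number, one per amino-acid letter           20
total (rf3)                                            1518
====================================================  =====

The 22 identifier forms are: the one-letter character class, the
three-letter alternation (title case or all caps), and the 20 individual
full names (case-insensitive).  The three connectors are immediate (wNm),
spaced (space between wild type and position), and arrow.

"Cutting" a library keeps only the entries flagged as reflecting the most
common nomenclature.  For the residue libraries these are the six generic
residue patterns — {1-letter, 3-letter, full-name} x {no space, one
space} — each with an *optional* trailing mutant, so the cut libraries
still recover wNm mutations.  For ``mf`` the cut keeps the four
{1-letter, 3-letter}^2 immediate mutation patterns.

Pattern files use the MutationFinder-compatible dialect: one extended
regex per line with named groups ``wt_res``, ``pos`` and optionally
``mut_res``; ``#`` lines are comments; a trailing ``[CASE_SENSITIVE]``
token makes the line case-sensitive (lines are case-insensitive
otherwise).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Union

from .aminoacids import AMINO_ACIDS

__all__ = [
    "PatternEntry",
    "RegexLibrary",
    "LibraryError",
    "LIBRARY_NAMES",
    "get_library",
    "cut",
    "load_pattern_file",
    "save_pattern_file",
]

LIBRARY_NAMES: tuple[str, ...] = (
    "mf",
    "mf_cut",
    "rf1",
    "rf1_cut",
    "rf2",
    "rf2_cut",
    "rf3",
    "rf3_cut",
)

CASE_SENSITIVE_MARKER = "[CASE_SENSITIVE]"


class LibraryError(ValueError):
    """A pattern library could not be built or loaded."""


@dataclass(frozen=True)
class PatternEntry:
    """One expression of a library.

    ``provenance`` records the lineage tier that introduced the entry
    (``mf``, ``rf1``, ``rf2``, ``rf3`` or ``custom``); ``cut_member``
    flags membership in the library's cut subset.
    """

    pattern_id: str
    expression: str
    case_sensitive: bool = True
    provenance: str = "custom"
    cut_member: bool = False

    def compile(self) -> re.Pattern[str]:
        flags = 0 if self.case_sensitive else re.IGNORECASE
        try:
            return re.compile(self.expression, flags)
        except re.error as exc:  # pragma: no cover - builder output always compiles
            raise LibraryError(f"pattern {self.pattern_id!r} does not compile: {exc}") from exc


class RegexLibrary:
    """An ordered collection of :class:`PatternEntry`.

    Compiled patterns are cached on first use; entry order is
    significant (it is the tie-break of last resort during extraction).
    """

    def __init__(self, name: str, entries: Iterable[PatternEntry]):
        self.name = name
        self.entries: tuple[PatternEntry, ...] = tuple(entries)
        self._compiled: tuple[re.Pattern[str], ...] | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RegexLibrary({self.name!r}, {len(self.entries)} entries)"

    @property
    def compiled(self) -> tuple[re.Pattern[str], ...]:
        if self._compiled is None:
            self._compiled = tuple(e.compile() for e in self.entries)
        return self._compiled

    @property
    def is_mutation_only(self) -> bool:
        """True for the MutationFinder lineage (every pattern requires a mutant)."""
        return self.name.startswith("mf")


# --------------------------------------------------------------------------
# Reconstruction atoms
# --------------------------------------------------------------------------

# Left/right boundary guards: a mention must not start or end inside a
# longer alphanumeric token ("pH7" is not H7).  The rf3 bare patterns
# deliberately omit both guards.
_LG = r"(?<![A-Za-z0-9])"
_RG = r"(?![A-Za-z0-9])"

_ONE = "[" + "".join(sorted(a.one_letter for a in AMINO_ACIDS)) + "]"
_THREE = "(?:" + "|".join(f"{a.three_letter}|{a.three_letter.upper()}" for a in AMINO_ACIDS) + ")"


def _name_atom(acid) -> str:
    # Full names are case-insensitive via a scoped inline flag so they can
    # coexist with the case-sensitive letter codes in one expression.
    name = acid.full_name.replace(" ", "[ ]")
    if acid.one_letter == "D":
        return r"(?i:aspartic[ ]acid|aspartate)"
    if acid.one_letter == "E":
        return r"(?i:glutamic[ ]acid|glutamate)"
    return f"(?i:{name})"


_NAMES = "(?i:" + "|".join(
    [a.full_name.replace(" ", "[ ]") for a in AMINO_ACIDS] + ["aspartate", "glutamate"]
) + ")"

#: The 22 wild-type/mutant identifier forms: generic one-letter class,
#: generic three-letter alternation, and the 20 individual full names.
_FORMS: tuple[tuple[str, str], ...] = (
    ("one", _ONE),
    ("three", _THREE),
) + tuple((f"name_{a.one_letter.lower()}", _name_atom(a)) for a in AMINO_ACIDS)

_POS = r"(?P<pos>[0-9]+)"
_ARROW = r"[ ]?(?:-->|->|→)[ ]?"
# Optional trailing mutant for residue patterns: immediate attachment only
# (wNm style), any nomenclature.
_OPT_MUT = f"(?P<mut_res>{_THREE}|{_NAMES}|{_ONE})?"


def _mutation_expr(wt_atom: str, mut_atom: str, style: str) -> str:
    wt = f"(?P<wt_res>{wt_atom})"
    mut = f"(?P<mut_res>{mut_atom})"
    if style == "imm":
        return f"{_LG}{wt}{_POS}{mut}{_RG}"
    if style == "sp":
        return f"{_LG}{wt}[ ]{_POS}{mut}{_RG}"
    if style == "arrow":
        return f"{_LG}{wt}{_POS}{_ARROW}{mut}{_RG}"
    raise LibraryError(f"unknown mutation style {style!r}")


def _residue_expr(wt_atom: str, spaced: bool) -> str:
    sep = "[ ]" if spaced else ""
    return f"{_LG}(?P<wt_res>{wt_atom}){sep}{_POS}{_OPT_MUT}{_RG}"


def _mutation_entries(style: str, provenance: str, cut_pairs: frozenset = frozenset()):
    for wt_id, wt_atom in _FORMS:
        for mut_id, mut_atom in _FORMS:
            yield PatternEntry(
                pattern_id=f"mut:{wt_id}:{mut_id}:{style}",
                expression=_mutation_expr(wt_atom, mut_atom, style),
                case_sensitive=True,
                provenance=provenance,
                cut_member=(wt_id, mut_id) in cut_pairs,
            )


def _residue_entries(spaced: bool, provenance: str):
    sep_id = "sp" if spaced else "imm"
    generic = {"one", "three"}
    # The six cut expressions are the generic {1-letter, 3-letter,
    # full-name} x {no space, space} residue patterns; the per-name
    # entries are redundant specializations kept for fidelity to the
    # enumerated structure of the original files.
    yield PatternEntry(
        f"res:one:{sep_id}", _residue_expr(_ONE, spaced), True, provenance, True
    )
    yield PatternEntry(
        f"res:three:{sep_id}", _residue_expr(_THREE, spaced), True, provenance, True
    )
    yield PatternEntry(
        f"res:name:{sep_id}", _residue_expr(_NAMES, spaced), True, provenance, True
    )
    for form_id, atom in _FORMS:
        if form_id in generic:
            continue
        yield PatternEntry(
            f"res:{form_id}:{sep_id}", _residue_expr(atom, spaced), True, provenance, False
        )


def _bare_entries(provenance: str):
    # "Essentially any expression that includes a capital letter followed
    # by a number": no boundary guards, but the capital is restricted to
    # the 20-acid alphabet.
    for acid in AMINO_ACIDS:
        yield PatternEntry(
            f"bare:{acid.one_letter}",
            f"(?P<wt_res>{acid.one_letter})(?P<pos>[0-9]+)",
            True,
            provenance,
            False,
        )


def _build_mf() -> RegexLibrary:
    cut_pairs = frozenset(
        (w, m) for w in ("one", "three") for m in ("one", "three")
    )
    return RegexLibrary("mf", _mutation_entries("imm", "mf", cut_pairs))


def _build_rf(level: int) -> RegexLibrary:
    entries: list[PatternEntry] = []
    entries.extend(_mutation_entries("imm", "rf1"))
    entries.extend(_residue_entries(spaced=False, provenance="rf1"))
    if level >= 2:
        entries.extend(_mutation_entries("sp", "rf2"))
        entries.extend(_residue_entries(spaced=True, provenance="rf2"))
    if level >= 3:
        entries.extend(_mutation_entries("arrow", "rf3"))
        entries.extend(_bare_entries("rf3"))
    return RegexLibrary(f"rf{level}", entries)


def cut(library: RegexLibrary) -> RegexLibrary:
    """The cut of a library: only the entries flagged as cut members.

    The result is a subset of the input and cutting is idempotent; an
    empty result is allowed for custom libraries with no flagged entries.
    """
    name = library.name if library.name.endswith("_cut") else f"{library.name}_cut"
    if library.name == "custom":
        name = "custom"
    return RegexLibrary(name, (e for e in library.entries if e.cut_member))


@lru_cache(maxsize=None)
def get_library(name: str) -> RegexLibrary:
    """Return one of the eight built-in libraries by name."""
    if name not in LIBRARY_NAMES:
        raise LibraryError(
            f"unknown library {name!r}; valid names: {', '.join(LIBRARY_NAMES)}"
        )
    if name.endswith("_cut"):
        return cut(get_library(name[: -len("_cut")]))
    if name == "mf":
        return _build_mf()
    return _build_rf(int(name[2]))


# --------------------------------------------------------------------------
# Pattern-file round trip
# --------------------------------------------------------------------------

def load_pattern_file(path: Union[str, Path], name: str = "custom") -> RegexLibrary:
    """Load a MutationFinder-dialect pattern file into a library.

    One expression per non-comment, non-blank line, order preserved.
    Every expression must compile and define named groups ``wt_res`` and
    ``pos`` (``mut_res`` is optional); violations raise
    :class:`LibraryError` naming the line number.
    """
    path = Path(path)
    entries: list[PatternEntry] = []
    with path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            case_sensitive = False
            if line.rstrip().endswith(CASE_SENSITIVE_MARKER):
                case_sensitive = True
                line = line.rstrip()[: -len(CASE_SENSITIVE_MARKER)].rstrip("\t ")
            try:
                rx = re.compile(line, 0 if case_sensitive else re.IGNORECASE)
            except re.error as exc:
                raise LibraryError(f"{path.name}:{lineno}: expression does not compile: {exc}")
            missing = {"wt_res", "pos"} - set(rx.groupindex)
            if missing:
                raise LibraryError(
                    f"{path.name}:{lineno}: missing required named group(s) {sorted(missing)}"
                )
            entries.append(
                PatternEntry(f"{path.stem}:{lineno}", line, case_sensitive, "custom", False)
            )
    return RegexLibrary(name, entries)


def save_pattern_file(library: RegexLibrary, path: Union[str, Path]) -> None:
    """Serialize a library to the pattern-file dialect (UTF-8, LF)."""
    path = Path(path)
    lines = [
        f"# {library.name}: {len(library.entries)} expressions "
        f"(rule-based reconstruction, generated by residuefinder)"
    ]
    for entry in library.entries:
        suffix = f"\t{CASE_SENSITIVE_MARKER}" if entry.case_sensitive else ""
        lines.append(f"{entry.expression}{suffix}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
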