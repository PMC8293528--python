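# Methods

## Mention model and normalization

The unit of analysis is the normalized mention key: wild-type one-letter
code + decimal position (`S56`), with an optional mutant code for point
mutations (`A64G`). Normalization is total over the 20 canonical amino
acids; the case policy is asymmetric by design: one-letter codes match
uppercase only (lowercase single letters are prose), three-letter codes
match title case and all caps, full names match case-insensitively
(with `aspartate`/`glutamate` accepted as synonyms of the canonical
"-ic acid" names). Position 0 and leading-zero tokens (`S07`) are
rejected as format noise — protein numbering starts at 1 — and there is
no upper bound on the position. A mutation key and the residue key at
the same site are distinct (`A64G` does not imply `A64`): a mutation
statement and a plain residue statement are different textual events,
and conflating them would double-count one string against set-valued
gold. This choice affects FP/FN bookkeeping whenever gold annotates one
reading and the extractor returns the other, and is applied consistently
on both sides.

## Library reconstruction

The eight pattern libraries are generated from an explicit combinatorial
scheme rather than shipped as opaque files, and are labeled as
reconstructions throughout. The generating atoms are 22 identifier
forms — the one-letter character class `[ACDEFGHIKLMNPQRSTVWY]`, the
three-letter alternation (title case or all caps), and the 20 individual
full names — and three mutation connectors: immediate (`A64G`), spaced
(`Ser 56Ala` style, i.e. a space between wild type and position), and
arrow (`S56→A`, with `-->` and `->` accepted as ASCII renderings). The
full Regex 3 library then decomposes as

* 22 × 22 × 3 = 1452 mutation patterns,
* 46 residue patterns (3 generic + 20 per-name, each in no-space and
  spaced variants) carrying an *optional* immediate mutant group,
* 20 bare capital+number patterns, one per amino-acid letter,

for exactly 1518 expressions; its cut is the 6 generic residue patterns
({1-letter, 3-letter, full-name} × {no space, one space}). `rf1` is the
immediate tier (507), `rf2` adds the spaced tier (1014), and the
lineage is nested by construction: rf1 ⊆ rf2 ⊆ rf3 as entry sets, and
every cut is a subset of its full library. The per-name residue entries
are redundant specializations of the generic name pattern; the
redundancy is retained deliberately to reflect the enumerated structure
of pattern files in this tool family. The `mf` library is the 484
immediate mutation patterns with the mutant group required; its cut is
the four {1-letter, 3-letter}² combinations.

Cut membership is a per-library flag, not a property of the expression
text: the residue libraries' cut keeps the six common residue notations
(whose optional mutant still recovers wNm mutations — essential for the
observation that cutting costs only modest recall), while the
mutation-only library's cut keeps its four most common mutation
notations.

Boundary guards are `(?<![A-Za-z0-9])` on the left and `(?![A-Za-z0-9])`
on the right, so mentions cannot start or end inside a longer
alphanumeric token (`pH7` is not H7). The Regex 3 bare patterns omit
both guards on purpose — "a capital letter followed by a number,
context be damned" — which is simultaneously the source of its recall
and of its characteristic false positives (`T7`, `C18`, `H3`,
`HEK293` → K293). The bare capital is restricted to the 20-acid
alphabet; the false-positive classes observed in practice are consistent
with that restriction, and admitting all 26 letters would add noise with
no recoverable mentions. Tolerance for PDF-conversion artifacts is
carried by the arrow connector's flexible spacing and by the context-free
bare patterns (which recover mentions whose left context was mangled),
rather than by dedicated junk-character entries.

Single-digit positions are handled at parse time, not in the pattern
text: all patterns share a `[0-9]+` position atom, and the extractor
filters one-digit positions when `allow_single_digit` is false — the
default for the `mf` lineage (its historical two-digit behavior) and
enabled for the residue libraries, where discarding every residue near
the start of a sequence would be a systematic recall hole.

## Extraction semantics

Spans are 0-based half-open character offsets; input text is NFC-
normalized by the file readers. Each pattern is scanned for all of its
match start positions (the scan restarts one character past each hit).
Selection is then:

1. longest parse per start offset, preferring a mutation over a residue
   and earlier library order on ties — so `S56A` yields the mutation
   only, and `S101→A` under the cut library (which has no arrow
   patterns) degrades to the residue reading `S101`, a by-design
   recall/precision cost of cutting;
2. removal of records nested inside a longer record with the same key
   (the bare `A64` inside `ALA64`), so full counts count textual events,
   not pattern overlaps;
3. ascending span order.

Consequence for monotonicity: adding patterns never loses a matched
*site* (every match of a smaller library is matched at the same span
start by its supersets), but at an arrow site a superset library may
extend a residue match into the mutation key. The test suite therefore
checks (start, key) containment on arrow-free text and span-start
containment in general; on short texts extraction is verified equivalent
to a brute-force per-offset oracle.

Bibliography stripping removes everything from a heading line
("References", "Bibliography", "Literature Cited" on its own line,
case-insensitive) onward, provided the heading starts in the final 50%
of the text — an early heading is assumed to be body prose. The
abstract-only view uses the labeled `abstract` region when present and
otherwise the text before the first blank line.

## Scoring

Single-count mode clamps both sides to key sets per document (a mention
verified "at least once per article"); full-count mode scores multisets
with per-key `min` intersection. Undefined precision (nothing
extracted) is 1.0 when gold is empty and 0.0 otherwise; undefined
recall (empty gold) is 1.0 — conventional choices that keep F defined;
benchmark-scale inputs never hit them. Report display rounds to 3
decimals, round-half-even; the default β set is {1, 2}, arbitrary β ≥ 0
is accepted.

Error breakdowns tally analyst cause labels (seven FP classes, two FN
classes) with multi-label records contributing one incidence per class;
percentages are of total labeled incidences. With the published FP class
counts (94, 73, 180, 104, 12, 26, 132; total 621) this denominator
reproduces six of the seven published percentages exactly; the
bibliography class computes 29.0 against a published 30 — the published
row is internally inconsistent with any single denominator, and the
discrepancy is documented rather than resolved.

## Synthetic corpora

The generator emulates annotated full-text article sets: each document
is lowercase filler prose (a fixed vocabulary that cannot collide with
any capital+digit pattern) interleaved with planted mentions in eight
nomenclature forms and distractor fragments in the seven FP classes,
with an abstract region, an optional reference tail, and exact span
ledgers for everything planted. One `random.Random(seed)` stream drives
all choices, so identical config + seed is byte-identical.

Planted positions are drawn uniformly from 101–999 (excluding the few
values a distractor token could produce, e.g. 293 from "HEK293") and
single-digit plantings avoid the letters of short distractor keys
(S4/S5/S6, T7, H2/H3), so a distractor can never alias a gold key and
recall/precision against the ledger are exact. The per-document mention
count (default 3–8) and distractor count (2–5) are chosen as plausible
densities for residue-focused articles; the form mix is uniform by
default because the real-world distribution of nomenclature variants is
not known — this is an arbitrary, documented choice, and experiments
that depend on form composition should set `form_mix` explicitly.
`FORM_COVERAGE` records which forms each library recovers exactly;
restricting a corpus to a library's covered set with distractors off
yields recall exactly 1.0, and spaced-only corpora separate `rf1`
(recall 0.0) from `rf2`/`rf3` (recall 1.0) — the desk-scale analog of
the full-text recall gap between the libraries.

What passing these tests does **not** show: performance on real
articles. The generator does not simulate genuine PDF conversion,
journal layout, tables/figures (mentions inside images are a known FN
class that no text-level method can reach), hyphenation or line-break
noise, nor realistic frequencies of nomenclature variants or of
distractor text. Synthetic precision numbers in particular depend
directly on the chosen distractor density.

## Problem sizes and numerics

The test suite exercises the monotonicity properties on 1,000 short
synthetic documents (≈200 characters each) against all library pairs,
the per-offset oracle on texts ≤ 200 characters, and recall-recovery on
30-document corpora; the acceptance script uses 30–50 document corpora.
These sizes give exact (not asymptotic) checks of the set-theoretic
properties, which do not depend on scale. All comparisons of derived
statistics are exact to the 3-decimal display rounding; there is no
floating-point fitting anywhere in the package.

## Known limitations

* No context modeling: `T7` is returned even when it is a phage, by
  design; disambiguation is out of scope.
* No protein association or database grounding (UniProt/dbSNP); no
  sentence splitting or tokenization.
* Three-letter codes in lowercase ("ser56") and two-letter or otherwise
  non-standard identifier spellings are not matched.
* The pattern libraries are reconstructions: entry-for-entry identity
  with any previously distributed pattern files is not claimed — only
  the documented combinatorial structure and entry counts.
* The simplified output format (`doc_id<TAB>key...`) is this package's
  own line format, not identical to any earlier tool's output files.
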