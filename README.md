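# residuefinder

Regular-expression extraction of **individual amino-acid residue mentions**
and **point-mutation mentions** from biomedical text, with selectable
pattern libraries, single-count / full-count reporting, and an
F<sub>β</sub> evaluation harness.

Research articles routinely attribute function to single residues —
"phosphorylation of Ser 56", "the A64G mutant shifted activation" — but
no comprehensive database of such mentions exists, and the nomenclature
in full text is far messier than in abstracts: one-letter and
three-letter codes, full names, spaces before the position number,
single-digit positions, arrow-style substitutions, and PDF-conversion
noise. `residuefinder` is for text miners and protein scientists who
want to pull those mentions out of plain-text articles at scale and to
quantify, precisely, the trade-off between precision, recall and speed
that the choice of pattern set implies.

## The model

A **residue mention** is normalized to `wNN` (wild-type one-letter code +
1-based position, e.g. `S56`); a **mutation mention** to `wNm`
(`A64G` = alanine 64 → glycine). `Ser56`, `S 56` and `serine 56` all
normalize to the same key; `A64G` and `A64` are distinct keys.

Extraction is treated as a binary classifier per (document, key): TP if
a returned mention is really mentioned, FP if not, FN if a real mention
is missed (true negatives are not a useful concept here). Quality is
summarized by

P = TP/(TP+FP), R = TP/(TP+FN), F<sub>β</sub> = ((β²+1)·P·R)/(β²·P + R)

with β > 1 weighting recall — the usual preference for literature
retrieval, since false positives can be filtered by later inspection but
false negatives are lost.

Eight built-in libraries ladder recall against precision and speed:

| library | patterns | contents |
|---|---|---|
| `mf` / `mf_cut` | 484 / 4 | wNm mutations only (two-or-more-digit positions) |
| `rf1` / `rf1_cut` | 507 / 3 | + plain residues, no space, single digits allowed |
| `rf2` / `rf2_cut` | 1014 / 6 | + a space between identifier and position |
| `rf3` / `rf3_cut` | 1518 / 6 | + arrow mutations and context-free capital+number |

The `*_cut` libraries keep only the most common nomenclature patterns —
hundreds of times fewer expressions (scan cost is proportional to the
pattern count) for a modest recall loss. The libraries are rule-based
reconstructions generated from an explicit combinatorial scheme (see
`docs/methods.md`); they can be serialized to, and loaded from,
MutationFinder-compatible pattern files, and custom pattern files with
named groups `wt_res`, `pos`, `mut_res` are accepted everywhere.

Because real annotated full-text corpora cannot be redistributed, the
package ships a deterministic synthetic-corpus generator that plants
gold mentions across all nomenclature variants and distractor text from
the empirically observed false-positive classes (motif names like "S4",
equipment like a "C18 column", bibliography entries, protein/strain
names like "T7" and "W3110", chemical formulas like "C18H27NO3"), with
an optional bibliography tail for testing reference-section stripping.

## Worked example

```python
from residuefinder import Document, count_mentions, extract, get_library

text = ("The A64G mutant abolished inactivation, while phosphorylation of "
        "Ser 56 was unchanged. Residue G2 and the S101→A substitution were "
        "probed with T7 polymerase.")
for name in ("mf", "rf1", "rf2", "rf3"):
    print(name, count_mentions(extract(Document("ex", text), get_library(name)), "full"))
```

prints

```
mf {'A64G': 1}
rf1 {'A64G': 1, 'G2': 1, 'S101': 1, 'T7': 1}
rf2 {'A64G': 1, 'S56': 1, 'G2': 1, 'S101': 1, 'T7': 1}
rf3 {'A64G': 1, 'S56': 1, 'G2': 1, 'S101A': 1, 'T7': 1}
```

The mutation-only library sees just `A64G`. `rf1` adds the plain residue
`G2` (single-digit position), the residue reading `S101`, and `T7` —
which here is bacteriophage T7, a deliberate false positive that only
context could resolve. `rf2` adds the spaced `Ser 56`; `rf3` upgrades
`S101` to the arrow mutation `S101A`. Scoring against a gold standard:

```python
from residuefinder import EvalResult
EvalResult(tp=66, fp=3, fn=102).rounded()
# {'P': 0.957, 'R': 0.393, 'F1': 0.557, 'F2': 0.445}
```

The scripts in `examples/` walk through each capability (library
comparison on a synthetic corpus, bibliography stripping, F_β
arithmetic). The same workflow is available from the shell:

```sh
residuefinder generate --out corpus --seed 9 --n-docs 8
residuefinder extract corpus/*.txt --library rf3 --out extracted.tsv
residuefinder evaluate --extracted extracted.tsv --gold corpus/gold.tsv
residuefinder libraries
```

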