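"""Extract residue and mutation mentions from a snippet of article text.

Runs the same text through four pattern libraries to show how the
precision/recall trade-off moves as patterns are added: the
mutation-only library sees just wNm mutations, Regex 1 adds plain
residues, Regex 2 adds spaced nomenclature, and Regex 3 adds arrows and
context-free capital+number matches (including deliberate false
positives like "T7").
"""

from residuefinder import Document, count_mentions, extract, get_library

TEXT = (
    "The A64G mutant abolished inactivation, while phosphorylation of "
    "Ser 56 was unchanged. Residue G2 and the S101→A substitution were "
    "probed with T7 polymerase."
)

document = Document("example", TEXT)
for name in ("mf", "rf1", "rf2", "rf3"):
    result = extract(document, get_library(name))
    counts = count_mentions(result, "full")
    print(f"{name:4s} -> {counts}")

# mf finds only the A64G mutation; rf1 adds G2, the residue reading
# S101, and T7 — which is bacteriophage T7, a by-design false positive
# that only context could resolve; rf2 adds the spaced S56; rf3
# upgrades S101 to the arrow mutation S101A.
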