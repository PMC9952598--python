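"""Generate a two-breed synthetic sequencing panel with known truth.

Builds the study-shaped dataset — nine adrenergic-receptor genes, three
Shaver Brown and three Shamo individuals, a wild-type reference and five
outgroup species — and writes FASTA alignments plus truth tables.
"""

from breeddiff import synthdata

spec = synthdata.paper_shaped_spec(seed=42)
result = synthdata.generate(spec)
result.write("scratch_example_panel")

print(f"genes generated        : {len(result.alignments)}")
print(f"planted mutation sites : {len(result.truth_mutations)}")
by_class = {}
for t in result.truth_mutations:
    by_class[t.breed_class] = by_class.get(t.breed_class, 0) + 1
print(f"  by breed class       : {by_class}")
print(f"segregating sites/gene : {result.truth_segregating}")

# The truth table pins down every planted mutation: its residues, carriers,
# breed class, ancestry and topology region, so every downstream stage can
# be checked exactly against what was planted.
t = result.truth_mutations[0]
print(f"example truth row      : {t.gene} {t.ref_aa}{t.aa_pos}{t.alt_aa} "
      f"carriers={dict(t.carriers)} class={t.breed_class}")
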