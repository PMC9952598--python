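"""Per-gene N_ST: how differentiated are two breeds at each locus?

A tiny hand-built alignment shows the index at its extremes: a site where
one breed is fixed while the pool is polymorphic gives N_ST = 1 for that
breed; a site where a breed is *more* diverse than the pool goes negative.
"""

from breeddiff.popdiff import gene_nst, nst_report_frame
from breeddiff.seqio import GeneAlignment, SampleSequence

# Breed A fixed for A at the only variable site; breed B heterozygous (R = A/G)
members = tuple(
    SampleSequence(s, pop, "ingroup", "DEMO", seq)
    for s, pop, seq in [
        ("a1", "BreedA", "ATGAAA"), ("a2", "BreedA", "ATGAAA"),
        ("a3", "BreedA", "ATGAAA"),
        ("b1", "BreedB", "ATGRAA"), ("b2", "BreedB", "ATGRAA"),
        ("b3", "BreedB", "ATGRAA"),
    ]
)
aln = GeneAlignment("DEMO", members, tuple(range(1, 7)))

report = gene_nst(aln)
print(nst_report_frame([report]).to_string(index=False))
site_nst = report.nst_by_pop
print(f"\nN_ST BreedA = {site_nst['BreedA']:+.3f}  "
      "(fixed within the breed, polymorphic pool: maximal differentiation)")
print(f"N_ST BreedB = {site_nst['BreedB']:+.3f}  "
      "(breed more heterozygous than the pool: negative, ~no differentiation)")
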