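"""Amino-acid mutation calling, breed classification, and candidate selection.

Runs the variant stages on a generated panel: heterozygous codons (IUPAC
two-base codes) are expanded to residue sets, compared against the
wild-type reference, classified by which breed carries them, screened
against outgroups for ancestral presence, and filtered by membrane
topology.  The selected set keeps breed-fixed or shared, derived,
non-extracellular mutations — the candidates for artificial selection.
"""

from breeddiff import mutscan, seqio, synthdata

result = synthdata.generate(synthdata.paper_shaped_spec(seed=42))
partition = result.partition()

all_muts = []
for gene, aln in result.alignments.items():
    muts = mutscan.call_aa_mutations(aln, reference="REF")
    outgroups = aln.with_roles("outgroup")
    for m in muts:
        mutscan.classify_mutation(m, partition)
        mutscan.screen_ancestral(m, outgroups)
        mutscan.annotate_region(m, result.topology[gene])
    mutscan.select_candidates(muts)
    all_muts.extend(muts)

table = mutscan.mutation_frame(all_muts)
print(table[["gene", "label", "n_carriers", "breed_class",
             "ancestry", "region", "selected"]].to_string(index=False))
selected = table[table.selected]
print(f"\n{len(table)} mutation sites called; {len(selected)} retained as "
      "artificial-selection candidates")
print("dropped: single-individual carriers, partial breed sharing, "
      "alleles present in outgroups (ancestral), extracellular sites")
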