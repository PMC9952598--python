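# breeddiff

Signatures of artificial selection in small two-breed sequencing panels.

`breeddiff` analyses per-gene, multi-sample coding alignments produced by
direct Sanger sequencing of diploid individuals — the setting of candidate-gene
studies in domesticated animals, where a handful of individuals per breed are
sequenced over a panel of receptor genes and heterozygous positions appear as
IUPAC two-base ambiguity codes (R = A/G, Y = C/T, M = A/C, K = G/T, S = C/G,
W = A/T). The motivating use case is comparing an egg-laying breed (Shaver
Brown) with a gamecock breed (Shamo) of chicken over the nine adrenergic
receptor genes, asking which amino-acid variants were fixed by human breeding
rather than inherited from wild ancestors.

## What it computes

**Nucleotide differentiation (N_ST).** At each segregating site *i*, allele
frequencies are estimated over diploid allele copies (a heterozygote code
contributes one copy of each base). With

H<sub>Ti</sub> = 1 − (P²<sub>Ai</sub> + P²<sub>Ti</sub> + P²<sub>Gi</sub> + P²<sub>Ci</sub>)

for the pooled ingroup and H<sub>Sij</sub> the same quantity within
subpopulation *j*,

N<sub>STij</sub> = (H<sub>Ti</sub> − H<sub>Sij</sub>) / H<sub>Ti</sub>,
  N<sub>STj</sub> = (1/n) Σᵢ N<sub>STij</sub>

averaged over the gene's *n* segregating sites. N_ST = 1 means the
subpopulation is fixed where the pool is polymorphic (maximal
differentiation); negative values (subpopulation more diverse than the pool)
are reported unmodified; a gene without segregating sites reports 0.

**Amino-acid mutation calling.** Heterozygous codons (one ambiguous
position) expand to a residue set under the standard genetic code; each
sample is compared to a designated wild-type reference sample, yielding
ref→alt calls such as S365G with het/hom zygosity per carrier. Calls are
classified **breed-A-specific / breed-B-specific / common**, screened
against user-supplied outgroup sequences (a variant found in an outgroup is
ancestral, not a product of recent selection), and assigned a membrane
topology region (inside / TMhelix / outside) from an annotation table. The
candidate set retains variants that are breed-fixed (all samples of a breed)
or shared by both breeds, derived, and not extracellular.

**Phylogenies.** Kimura two-parameter distances
d = −½·ln((1 − 2P − Q)·√(1 − 2Q)) with pairwise deletion of ambiguous
sites, UPGMA trees, and column-resampling bootstrap supports, written as
Newick.

**Synthetic panels.** `breeddiff.synthdata` generates two-breed panels with
*planted*, exactly known mutation structure and truth tables (including an
independent brute-force N_ST evaluator), so every stage is testable without
any sequence download.

## Worked example

```python
from breeddiff.popdiff import gene_nst, nst_report_frame
from breeddiff.seqio import GeneAlignment, SampleSequence

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
print(nst_report_frame([gene_nst(aln)]).to_string(index=False))
```

prints

```
gene  length_bp  segregating_sites  heterozygous_sites mutation_rate_pct  nst_BreedA  nst_BreedB
DEMO          6                  1                   1             16.67         1.0      -0.333
```

Column 4 is the only segregating site: breed A is fixed for A while breed B
is uniformly heterozygous A/G. The pooled frequencies are P_A = 0.75,
P_G = 0.25, so H_T = 0.375; breed A has H_S = 0 (N_ST = 1, complete
differentiation from the pool) and breed B has H_S = 0.5, more diverse than
the pool, giving the small negative value −1/3.

The scripts in `examples/` walk through each capability (synthetic panel
generation, N_ST, mutation calling and candidate selection, bootstrap UPGMA,
the end-to-end pipeline); each prints the numbers it computes with a line of
interpretation. The same stages are available from the shell:

```bash
breeddiff synth --seed 42 --out panel/
breeddiff run --config run.yaml
breeddiff nst --fasta panel/ADRA1A.fasta --samples panel/samples.tsv
breeddiff tree --fasta panel/ADRA1A.fasta --samples panel/samples.tsv --bootstrap 1000 --seed 7
```

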