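# Methods

## Data model

Input is one pre-aligned FASTA per gene (coding sequence, all records the
same length) plus a TSV sample sheet assigning each `sample_id` a
`population` and a `role` (`ingroup`, `reference`, `outgroup`). Sequences
are direct-sequencing reads of diploid individuals: an unambiguous base is
a homozygous genotype (two copies of that allele), a two-base IUPAC code
(R, Y, M, K, S, W) a heterozygous one (one copy of each), `N` a missing
genotype, `-` an alignment gap. Parsing is case-insensitive, `U` is
normalized to `T`, and any other letter is rejected with its column number.
The package does not run an aligner: the panels it targets are same-length
CDS per gene, and alignment construction is treated as upstream
preparation.

Before analysis every column containing a gap in *any* member is excluded
(complete deletion). The surviving columns keep a map back to original
1-based alignment coordinates, and all reports cite original coordinates.
Amino-acid positions are 1-based codon indices from the initiator Met.

## N_ST

Per-site allele frequencies are estimated over allele copies: each
non-missing sample contributes weight 1 split across its symbol's
expansion; `N` samples are dropped and the frequencies renormalized over
the remainder. Heterozygosity is H = 1 − ΣP², bounded by 0.75 (four
equifrequent alleles). A site is *segregating* when the pooled expanded
allele set of the ingroup (ignoring `N`) holds at least two bases — so a
site at which every individual is identically heterozygous still
segregates — and *heterozygous* when at least one ingroup sample shows a
two-base code there.

N_STij = (H_Ti − H_Sij)/H_Ti per segregating site and subpopulation;
the per-gene N_STj averages over segregating sites only. Averaging over all
columns instead would bound the index by S/L (≈ 0.005 for typical panels)
and could not produce gene-level values of the observed magnitude, so the
segregating-site average is the only consistent reading. Negative values
are reported as computed — they mean the subpopulation is more diverse than
the pool and are expected to be small; nothing is clamped. A monomorphic
gene reports N_STj = 0 for every subpopulation rather than NaN. If a
subpopulation is entirely missing (`N`) at a segregating site the run
aborts with an undefined-frequency error rather than guessing. The
reported mutation rate is 100·S/L, printed with two decimals and trailing
zeros trimmed to a minimum of one decimal place (0.9972 → 1.0,
1.6479 → 1.65, 0.0746 → 0.07).

The reference sample and outgroups never enter frequency computations:
segregating sites, heterozygosity and N_ST are ingroup-only quantities.

## Mutation calling and the candidate set

Codons with one ambiguous position expand to the residues of both
unambiguous codons; codons with two or more ambiguous positions are flagged
and excluded from calls rather than combinatorially expanded (silent
expansion risks phantom double-mutants; such codons do not occur in clean
direct-sequencing data). The reference sample must be unambiguous at every
called codon. A sample carries `ref→alt` when its residue set contains a
non-reference residue; zygosity is `het` when the set also contains the
reference residue or the codon is ambiguous, `hom` otherwise. One record is
emitted per (codon, alt residue), aggregating carriers.

Classification over a two-breed partition: carriers confined to one breed
give that breed's specific class, carriers in both give `common`;
single-carrier mutations are additionally marked individual-level, and a
`complete_in_breed` flag records whether every sample of each carrying
breed is a carrier. The ancestral screen declares a mutation
`ancestral_present` when any outgroup sequence's (fully expanded) codon at
that position encodes the alt residue, `derived` when outgroups cover the
position but none does, and `unscreened` when none covers it. Topology
regions come from a user-supplied interval table (running a transmembrane
predictor is out of scope; its output is consumed, not produced).

The candidate set retains mutations that are (breed-specific and complete
in their breed) or common, **and** derived, **and** not extracellular
(`outside`); stop gains are never selected. `unscreened` deliberately fails
the ancestry requirement — without outgroup evidence a variant cannot be
called derived — so runs without outgroup sequences yield an empty
candidate set and a warning, not a silently optimistic one. A missing
topology table leaves regions `unannotated`, which passes the region
criterion (only a positive extracellular annotation excludes).

## Phylogenies

K2P distance with transition proportion P and transversion proportion Q
over sites where both sequences show an unambiguous base (pairwise deletion
of ambiguity codes and gaps): d = −½·ln((1 − 2P − Q)·√(1 − 2Q)). A
non-positive log argument raises a saturation error instead of returning a
complex or infinite value. Heterozygotes are not split into
pseudo-haplotypes — pairwise deletion is the conventional default of the
distance-tool family this mirrors, and with ≤ 2% polymorphic sites the
information loss is negligible.

UPGMA merges the closest pair of clusters, with size-weighted average
linkage and node height d/2; among tied minima the lexicographically
smallest (row, column) pair in the current cluster list is merged, so
output is deterministic and reruns are byte-identical. Bootstrap resamples
columns with replacement (`numpy` Generator seeded from the run seed),
rebuilds K2P + UPGMA per replicate, and scores each internal node by the
percentage of successful replicates containing its leaf set as a clade;
replicates with saturated distances are discarded and counted, and more
than 50% discarded aborts. Newick output carries branch lengths and integer
supports as internal-node labels. Trees include all roles — each individual,
the reference and the outgroups appear as leaves; the only rooting is
UPGMA's inherent one.

## Synthetic panels

The generator's defaults are the emulated study's conditions: two breeds ×
three diploid individuals, nine genes of 1038–1536 bp, five outgroups at
0.05 expected substitutions per site, predominantly heterozygous planted
mutations. A reference CDS is drawn with an ATG start and sense codons
only; each planted mutation pins the reference codon to one that reaches
the alt residue in a single base change, then writes the het ambiguity
symbol (or the hom alt base) into its carriers. Background polymorphism is
confined to synonymous third positions of codons away from planted ones, so
the amino-acid truth table is exact; background sites are heterozygous in a
random nonempty subset of individuals, or homozygous-alternate in one
individual for the `background_hom` sites. Outgroups substitute sites
i.i.d. at probability 0.75·(1 − e^(−4d/3)) (transitions twice as likely as
either transversion), never touching planted codons except to plant the alt
allele when a mutation is declared ancestral. Truth N_ST values come from a
brute-force per-site transcription of the formulas that counts allele
copies directly and shares no code with the analysis path.

`paper_shaped_spec()` reproduces the emulated study's published *shape*:
24 planted mutations split 4/13/7 across the breed classes, 23
heterozygous, carrier patterns, two extracellular sites and five
ancestrally present alleles arranged so the retention rules leave exactly
eight candidates, and per-gene background sized so segregating-site and
heterozygous-site counts match the published per-gene totals. Sequence
content is random; only the combinatorial structure is pinned. Gene-level
N_ST *values* on synthetic panels therefore vary with the seed — matching
them to published values would require the deposited sequences themselves.

The generator does not model coalescent structure, recombination,
selection dynamics, alignment error, or indels (alignments are gap-free
unless a gap fraction is requested explicitly, and gap handling is
exercised in isolation because gap exclusion breaks codon phase for the
calling stages). Recovery tests on these panels demonstrate correctness of
the machinery, not robustness to real-data artifacts.

## Numerical and design choices

- Frequencies renormalize over non-missing weight; sums are exact to
  1e−12 and tested as such.
- Oracle-equivalence tests compare the pipeline against the brute-force
  evaluator at 1e−12 absolute tolerance on ≥1000 random small alignments.
- Ultrametricity of UPGMA output is asserted to 1e−9; Newick round-trips
  preserve depths to 1e−9 (branch lengths print with 10 significant
  digits).
- Bootstrap defaults to B = 1000 (the conventional replicate count);
  tests use B = 20–100 and the acceptance script B = 200 for the pipeline
  genes and B = 1000 for the clean-split support, sizes chosen to keep the
  default runs fast while leaving the statistics stable.
- All randomness flows through `numpy.random.default_rng` seeded from a
  single user-supplied seed; the same seed regenerates byte-identical
  panels, reports and trees.
- Module boundaries: standard steps lean on established libraries
  (Biopython for FASTA and the codon table, pandas for tabular I/O), while
  the quantities this package exists for — the N_ST estimator over IUPAC
  genotypes, the calling/classification/screening rules, K2P, UPGMA and
  bootstrap supports — are implemented here and cross-checked in tests
  against independent references (scipy average linkage, dendropy Newick
  parsing, closed-form K2P values).
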