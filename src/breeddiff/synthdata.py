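"""Synthetic two-breed sequencing panels with planted, fully known truth.

The generator emulates the shape of a direct-sequencing study of two
domesticated chicken breeds: per gene, a reference CDS (wild-type
background), three diploid individuals per breed whose heterozygous
positions are written as IUPAC two-base codes, a handful of outgroup
species derived from the reference by random substitution, and an optional
membrane-topology annotation.  Every amino-acid mutation is planted
explicitly — breed-fixed, shared, or single-individual; het or hom;
ancestrally present in an outgroup or not — and background polymorphism is
restricted to synonymous third-codon positions away from planted codons, so
the truth table (mutation tuples, segregating-site counts, N_ST values from
an internal brute-force evaluator) is exact by construction.

What this emulates and what it does not: alignments are gap-free unless a
gap fraction is requested, there is no recombination or coalescent
structure, and outgroup divergence is i.i.d. per site.  Passing recovery
tests therefore demonstrates correctness of the calling/classification
machinery, not robustness to alignment error in real data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .mutscan import CODON_TO_AA, TopologyAnnotation
from .seqio import (
    AMBIGUITY_OF_PAIR,
    GeneAlignment,
    PopulationPartition,
    SampleSequence,
    expansion_of,
    write_gene_fasta,
)

__all__ = [
    "PlantedMutation",
    "SynthSpec",
    "TruthMutation",
    "SynthResult",
    "SynthSpecError",
    "generate",
    "paper_shaped_spec",
    "bruteforce_gene_nst",
]

_SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
_STOPS = {c for c, aa in CODON_TO_AA.items() if aa == "*"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class SynthSpecError(ValueError):
    """Invalid or internally inconsistent synthetic-data specification."""


@dataclasses.dataclass(frozen=True)
class PlantedMutation:
    """One amino-acid mutation to plant, with its intended truth.

    ``target_class`` is breedA_specific / breedB_specific / common /
    individual; carrier counts per breed default to the class's natural
    reading (all of breed A, all of breed B, everyone, one sample of breed
    A) and may be overridden, e.g. (2, 0) for a breed-A mutation carried by
    two of three samples.
    """

    gene: str
    aa_pos: int
    ref_aa: str
    alt_aa: str
    target_class: str
    carrier_counts: tuple[int, int] | None = None
    zygosity: str = "het"
    ancestral_in_outgroup: bool = False
    region: str = "TMhelix"

    def counts(self, n_a: int, n_b: int) -> tuple[int, int]:
        if self.carrier_counts is not None:
            return self.carrier_counts
        return {
            "breedA_specific": (n_a, 0),
            "breedB_specific": (0, n_b),
            "common": (n_a, n_b),
            "individual": (1, 0),
        }[self.target_class]


@dataclasses.dataclass(frozen=True)
class SynthSpec:
    """Study-shaped generator settings.

    Defaults mirror the emulated study design: two breeds of three diploid
    individuals, five Galliformes-like outgroups at 5% expected divergence
    from the wild-type reference, gap-free CDS alignments.
    """

    genes: Mapping[str, int]  # gene -> aligned CDS length (bp, multiple of 3)
    breeds: tuple[str, str] = ("ShaverBrown", "Shamo")
    samples_per_breed: int = 3
    sample_names: Mapping[str, Sequence[str]] | None = None
    planted: tuple[PlantedMutation, ...] = ()
    background_het: Mapping[str, int] = dataclasses.field(default_factory=dict)
    background_hom: Mapping[str, int] = dataclasses.field(default_factory=dict)
    n_outgroups: int = 5
    outgroup_divergence: float = 0.05
    gap_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for gene, length in self.genes.items():
            if length <= 3 or length % 3:
                raise SynthSpecError(f"gene {gene}: length {length} not a multiple of 3")
        if len(self.breeds) != 2 or self.breeds[0] == self.breeds[1]:
            raise SynthSpecError("exactly two distinct breed labels required")
        if not 0.0 <= self.outgroup_divergence <= 0.3:
            raise SynthSpecError("outgroup divergence must lie in [0, 0.3]")
        seen: set[tuple[str, int]] = set()
        for p in self.planted:
            if p.gene not in self.genes:
                raise SynthSpecError(f"planted mutation in unknown gene {p.gene}")
            n_aa = self.genes[p.gene] // 3
            if not 2 <= p.aa_pos <= n_aa:
                raise SynthSpecError(
                    f"{p.gene}: aa_pos {p.aa_pos} outside codons 2..{n_aa}"
                )
            if (p.gene, p.aa_pos) in seen:
                raise SynthSpecError(f"{p.gene}: duplicate planted codon {p.aa_pos}")
            seen.add((p.gene, p.aa_pos))
            if p.ref_aa == p.alt_aa:
                raise SynthSpecError(f"{p.gene}:{p.aa_pos}: ref and alt residues equal")
            if _single_step_codons(p.ref_aa, p.alt_aa) is None:
                raise SynthSpecError(
                    f"{p.gene}: no single-base codon change gives "
                    f"{p.ref_aa}->{p.alt_aa}"
                )

    def names_for(self, breed: str) -> list[str]:
        if self.sample_names and breed in self.sample_names:
            names = list(self.sample_names[breed])
            if len(names) != self.samples_per_breed:
                raise SynthSpecError(f"{breed}: {len(names)} names for "
                                     f"{self.samples_per_breed} samples")
            return names
        return [f"{breed}-{k}" for k in range(1, self.samples_per_breed + 1)]


@dataclasses.dataclass(frozen=True)
class TruthMutation:
    """Expected call for one planted mutation."""

    gene: str
    aa_pos: int
    ref_aa: str
    alt_aa: str
    carriers: tuple[tuple[str, str], ...]  # (sample_id, zygosity), sorted
    breed_class: str  # breedA_specific | breedB_specific | common
    individual_level: bool
    ancestry: str
    region: str
    selected: bool


@dataclasses.dataclass
class SynthResult:
    spec: SynthSpec
    alignments: dict[str, GeneAlignment]
    sample_sheet: pd.DataFrame
    truth_mutations: list[TruthMutation]
    truth_segregating: dict[str, int]
    truth_heterozygous: dict[str, int]
    truth_nst: dict[str, dict[str, float]]
    topology: dict[str, TopologyAnnotation]

    def partition(self) -> PopulationPartition:
        ingroup = self.sample_sheet[self.sample_sheet.role == "ingroup"]
        return PopulationPartition(
            dict(zip(ingroup.sample_id, ingroup.population))
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for gene, aln in self.alignments.items():
            write_gene_fasta(aln, outdir / f"{gene}.fasta")
        self.sample_sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        truth = pd.DataFrame(
            [dataclasses.asdict(t) for t in self.truth_mutations],
            columns=[f.name for f in dataclasses.fields(TruthMutation)],
        )
        truth["carriers"] = truth["carriers"].map(
            lambda cs: ",".join(f"{s}:{z}" for s, z in cs)
        )
        truth.to_csv(outdir / "truth_mutations.tsv", sep="\t", index=False)
        rows = [
            {"gene": g, "aa_start": s, "aa_end": e, "region": r}
            for g, topo in self.topology.items()
            for s, e, r in topo.segments
        ]
        pd.DataFrame(rows).to_csv(outdir / "topology.tsv", sep="\t", index=False)
        nst_rows = []
        for gene, by_pop in self.truth_nst.items():
            nst_rows.append({"gene": gene, **{f"nst_{p}": v for p, v in by_pop.items()},
                             "segregating_sites": self.truth_segregating[gene]})
        pd.DataFrame(nst_rows).to_csv(outdir / "truth_nst.tsv", sep="\t", index=False)
        echo = dataclasses.asdict(self.spec)
        echo["genes"] = dict(self.spec.genes)
        with open(outdir / "spec_echo.yaml", "w") as fh:
            yaml.safe_dump(echo, fh, sort_keys=False)


def _single_step_codons(ref_aa: str, alt_aa: str) -> list[tuple[str, int, str]] | None:
    """All (ref_codon, position, alt_base) one-substitution paths ref->alt."""
    out = []
    for codon in _SENSE_CODONS:
        if CODON_TO_AA[codon] != ref_aa:
            continue
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1 :]
                if CODON_TO_AA.get(alt) == alt_aa and alt not in _STOPS:
                    out.append((codon, pos, base))
    return out or None


def _synonymous_third(codon: str) -> list[str]:
    """Alternative third-position bases keeping the residue (and sense)."""
    return [
        b
        for b in "ACGT"
        if b != codon[2]
        and CODON_TO_AA.get(codon[:2] + b) == CODON_TO_AA[codon]
    ]


def _het_symbol(a: str, b: str) -> str:
    return AMBIGUITY_OF_PAIR[frozenset((a, b))]


def generate(spec: SynthSpec) -> SynthResult:
    """Generate alignments, sample sheet, topology and truth from a spec.

    Deterministic: the same spec (including its seed) regenerates
    byte-identical sequences and truth tables.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    breed_a, breed_b = spec.breeds
    names_a, names_b = spec.names_for(breed_a), spec.names_for(breed_b)
    ingroup_names = names_a + names_b
    outgroup_names = [f"OG{k}" for k in range(1, spec.n_outgroups + 1)]

    sheet_rows = (
        [{"sample_id": s, "population": breed_a, "role": "ingroup"} for s in names_a]
        + [{"sample_id": s, "population": breed_b, "role": "ingroup"} for s in names_b]
        + [{"sample_id": "REF", "population": "reference", "role": "reference"}]
        + [{"sample_id": s, "population": "outgroup", "role": "outgroup"}
           for s in outgroup_names]
    )
    sample_sheet = pd.DataFrame(sheet_rows)

    alignments: dict[str, GeneAlignment] = {}
    truth_mutations: list[TruthMutation] = []
    truth_segregating: dict[str, int] = {}
    truth_heterozygous: dict[str, int] = {}
    truth_nst: dict[str, dict[str, float]] = {}
    topology: dict[str, TopologyAnnotation] = {}
    partition = PopulationPartition(
        {**{s: breed_a for s in names_a}, **{s: breed_b for s in names_b}}
    )

    for gene, length in spec.genes.items():
        n_codons = length // 3
        planted_here = [p for p in spec.planted if p.gene == gene]
        # --- reference CDS: ATG start, sense codons elsewhere
        codons = ["ATG"] + [
            _SENSE_CODONS[i]
            for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 1)
        ]
        planted_codon_idx = {p.aa_pos for p in planted_here}
        # pin each planted codon to a ref codon that can reach alt in one step
        plant_detail: dict[int, tuple[str, int, str]] = {}
        for p in planted_here:
            paths = _single_step_codons(p.ref_aa, p.alt_aa)
            ref_codon, pos, alt_base = paths[rng.integers(0, len(paths))]
            codons[p.aa_pos - 1] = ref_codon
            plant_detail[p.aa_pos] = (ref_codon, pos, alt_base)

        ingroup_codons = {s: list(codons) for s in ingroup_names}
        expected_het_cols: set[int] = set()
        expected_seg_cols: set[int] = set()

        # --- planted amino-acid mutations
        for p in planted_here:
            ref_codon, pos, alt_base = plant_detail[p.aa_pos]
            n_car_a, n_car_b = p.counts(len(names_a), len(names_b))
            if n_car_a > len(names_a) or n_car_b > len(names_b):
                raise SynthSpecError(f"{gene}:{p.aa_pos}: carrier counts exceed breed size")
            carriers = [str(s) for s in rng.choice(names_a, size=n_car_a, replace=False)]
            carriers += [str(s) for s in rng.choice(names_b, size=n_car_b, replace=False)]
            if not carriers:
                raise SynthSpecError(f"{gene}:{p.aa_pos}: mutation with no carriers")
            col = 3 * (p.aa_pos - 1) + pos + 1  # original 1-based column
            for s in carriers:
                codon = ingroup_codons[s][p.aa_pos - 1]
                if p.zygosity == "het":
                    new = codon[:pos] + _het_symbol(codon[pos], alt_base) + codon[pos + 1 :]
                    expected_het_cols.add(col)
                else:
                    new = codon[:pos] + alt_base + codon[pos + 1 :]
                ingroup_codons[s][p.aa_pos - 1] = new
            # a hom mutation carried by every ingroup sample leaves the
            # column monomorphic within the ingroup: called, not segregating
            if not (p.zygosity == "hom" and len(carriers) == len(ingroup_names)):
                expected_seg_cols.add(col)
            if p.target_class == "common":
                breed_class = "common"
            elif p.target_class == "breedB_specific" or (
                p.target_class == "individual" and n_car_b
            ):
                breed_class = "breedB_specific"
            else:
                breed_class = "breedA_specific"
            if spec.n_outgroups == 0:
                ancestry = "unscreened"
            elif p.ancestral_in_outgroup:
                ancestry = "ancestral_present"
            else:
                ancestry = "derived"
            complete = (
                (breed_class == "common")
                or (breed_class == "breedA_specific" and n_car_a == len(names_a))
                or (breed_class == "breedB_specific" and n_car_b == len(names_b))
            )
            truth_mutations.append(
                TruthMutation(
                    gene=gene,
                    aa_pos=p.aa_pos,
                    ref_aa=p.ref_aa,
                    alt_aa=p.alt_aa,
                    carriers=tuple(sorted((s, p.zygosity) for s in carriers)),
                    breed_class=breed_class,
                    individual_level=len(carriers) == 1,
                    ancestry=ancestry,
                    region=p.region,
                    selected=(
                        complete
                        and ancestry == "derived"
                        and p.region != "outside"
                    ),
                )
            )

        # --- synonymous background polymorphism away from planted codons
        free_codons = [
            i for i in range(2, n_codons + 1)
            if i not in planted_codon_idx and _synonymous_third(codons[i - 1])
        ]
        n_bg_het = spec.background_het.get(gene, 0)
        n_bg_hom = spec.background_hom.get(gene, 0)
        if n_bg_het + n_bg_hom > len(free_codons):
            raise SynthSpecError(
                f"{gene}: {n_bg_het + n_bg_hom} background sites requested but only "
                f"{len(free_codons)} free synonymous codons available"
            )
        bg_codons = rng.choice(free_codons, size=n_bg_het + n_bg_hom, replace=False)
        for rank, codon_idx in enumerate(bg_codons):
            codon_idx = int(codon_idx)
            ref_codon = codons[codon_idx - 1]
            alts = _synonymous_third(ref_codon)
            alt_base = alts[rng.integers(0, len(alts))]
            col = 3 * (codon_idx - 1) + 3
            is_het = rank < n_bg_het
            if is_het:
                n_poly = int(rng.integers(1, len(ingroup_names)))
                chosen = [str(s) for s in
                          rng.choice(ingroup_names, size=n_poly, replace=False)]
                sym = _het_symbol(ref_codon[2], alt_base)
                for s in chosen:
                    c = ingroup_codons[s][codon_idx - 1]
                    ingroup_codons[s][codon_idx - 1] = c[:2] + sym
                expected_het_cols.add(col)
            else:
                s = ingroup_names[int(rng.integers(0, len(ingroup_names)))]
                c = ingroup_codons[s][codon_idx - 1]
                ingroup_codons[s][codon_idx - 1] = c[:2] + alt_base
            expected_seg_cols.add(col)

        # --- outgroups: reference + random substitution off planted codons
        p_sub = 0.75 * (1.0 - np.exp(-4.0 * spec.outgroup_divergence / 3.0))
        outgroup_seqs: dict[str, list[str]] = {}
        for og_rank, og in enumerate(outgroup_names):
            og_codons = list(codons)
            for codon_idx in range(2, n_codons + 1):
                if codon_idx in planted_codon_idx:
                    continue
                codon = og_codons[codon_idx - 1]
                new = list(codon)
                for pos in range(3):
                    if rng.random() >= p_sub:
                        continue
                    base = new[pos]
                    if rng.random() < 0.5:
                        new[pos] = _TRANSITION[base]
                    else:
                        targets = ("C", "T") if base in "AG" else ("A", "G")
                        new[pos] = targets[int(rng.random() < 0.5)]
                og_codons[codon_idx - 1] = "".join(new)
            if og_rank == 0:
                for p in planted_here:
                    if p.ancestral_in_outgroup:
                        ref_codon, pos, alt_base = plant_detail[p.aa_pos]
                        og_codons[p.aa_pos - 1] = (
                            ref_codon[:pos] + alt_base + ref_codon[pos + 1 :]
                        )
            outgroup_seqs[og] = og_codons

        members = [
            SampleSequence(s, partition.assignment[s], "ingroup", gene,
                           "".join(ingroup_codons[s]))
            for s in ingroup_names
        ]
        members.append(SampleSequence("REF", "reference", "reference", gene,
                                      "".join(codons)))
        members += [
            SampleSequence(og, "outgroup", "outgroup", gene,
                           "".join(outgroup_seqs[og]))
            for og in outgroup_names
        ]

        # --- optional gap columns (each gapped in one random ingroup member)
        if spec.gap_fraction > 0.0:
            n_gaps = int(round(spec.gap_fraction * length))
            forbidden = expected_seg_cols | {
                c for i in planted_codon_idx for c in (3 * i - 2, 3 * i - 1, 3 * i)
            } | {1, 2, 3}
            candidates = [c for c in range(1, length + 1) if c not in forbidden]
            gap_cols = rng.choice(candidates, size=min(n_gaps, len(candidates)),
                                  replace=False)
            new_members = []
            for rank, m in enumerate(members):
                bases = list(m.bases)
                for c in gap_cols:
                    if int(rng.integers(0, len(members))) == rank:
                        bases[int(c) - 1] = "-"
                new_members.append(dataclasses.replace(m, bases="".join(bases)))
            members = new_members

        aln = GeneAlignment(gene, tuple(members), tuple(range(1, length + 1)))
        alignments[gene] = aln
        truth_segregating[gene] = len(expected_seg_cols)
        truth_heterozygous[gene] = len(expected_het_cols)
        truth_nst[gene] = bruteforce_gene_nst(aln, partition)

        # --- topology covering every planted position with its region
        segments: list[tuple[int, int, str]] = []
        cursor = 1
        for p in sorted(planted_here, key=lambda p: p.aa_pos):
            if p.aa_pos > cursor:
                segments.append((cursor, p.aa_pos - 1, "inside"))
            segments.append((p.aa_pos, p.aa_pos, p.region))
            cursor = p.aa_pos + 1
        if cursor <= n_codons:
            segments.append((cursor, n_codons, "inside"))
        topology[gene] = TopologyAnnotation(gene=gene, segments=tuple(segments))

    return SynthResult(
        spec=spec,
        alignments=alignments,
        sample_sheet=sample_sheet,
        truth_mutations=truth_mutations,
        truth_segregating=truth_segregating,
        truth_heterozygous=truth_heterozygous,
        truth_nst=truth_nst,
        topology=topology,
    )


def bruteforce_gene_nst(
    aln: GeneAlignment,
    partition: PopulationPartition,
) -> dict[str, float]:
    """Literal per-site transcription of the N_ST formulas (truth oracle).

    Counts allele copies directly (two per sample, one of each for a
    heterozygote), evaluates H = 1 - sum p^2 for the pool and each
    subpopulation, N_STij = (H_Ti - H_Sij)/H_Ti at every segregating site i,
    and averages over segregating sites.  Independent of the analysis
    implementation by design.
    """
    ingroup = [m for m in aln.members if m.role == "ingroup"]
    pops = partition.subpopulations

    def copy_counts(members, k):
        counts = {b: 0 for b in "ATGC"}
        for m in members:
            exp = sorted(expansion_of(m.bases[k]))
            if len(exp) == 1:
                counts[exp[0]] += 2
            elif len(exp) == 2:
                counts[exp[0]] += 1
                counts[exp[1]] += 1
            # N (4 bases) and gap: missing, contributes nothing
        return counts

    def het(counts):
        total = sum(counts.values())
        if total == 0:
            return None
        return 1.0 - sum((c / total) ** 2 for c in counts.values())

    per_pop_sums = {p: 0.0 for p in pops}
    n_seg = 0
    for k in range(aln.length):
        pooled = copy_counts(ingroup, k)
        if sum(1 for c in pooled.values() if c > 0) < 2:
            continue
        h_t = het(pooled)
        if h_t is None or h_t == 0.0:
            continue
        n_seg += 1
        for pop in pops:
            sub = [m for m in ingroup if partition.assignment[m.sample_id] == pop]
            h_s = het(copy_counts(sub, k))
            per_pop_sums[pop] += (h_t - h_s) / h_t
    if n_seg == 0:
        return {p: 0.0 for p in pops}
    return {p: per_pop_sums[p] / n_seg for p in pops}


def paper_shaped_spec(seed: int = 0) -> SynthSpec:
    """A spec mirroring the emulated study's published shape.

    Nine adrenergic-receptor genes at their analyzed lengths; two breeds of
    three individuals (Shaver Brown N5-N7, Shamo S6/S7/S9); 24 planted
    amino-acid mutations split 4 Shaver-specific / 13 Shamo-specific / 7
    shared, 23 of them heterozygous; per-gene background polymorphism sized
    so segregating-site and heterozygous-site totals match the study's
    per-gene counts; two extracellular sites and several
    ancestrally-present alleles so the retention rules leave the study's
    eight candidate sites.
    """
    A, B, C, IND = "breedA_specific", "breedB_specific", "common", "individual"
    P = PlantedMutation
    planted = (
        # Shaver Brown-specific (4)
        P("ADRA1A", 365, "S", "G", A),
        P("ADRA1B", 258, "R", "Q", A, carrier_counts=(2, 0)),
        P("ADRA1B", 494, "V", "A", A, carrier_counts=(2, 0)),
        P("ADRB1", 444, "G", "S", IND, carrier_counts=(1, 0),
          zygosity="hom", ancestral_in_outgroup=True),
        # Shamo-specific (13)
        P("ADRA1D", 58, "L", "W", IND, carrier_counts=(0, 1)),
        P("ADRA1D", 440, "T", "N", B),
        P("ADRA2A", 296, "V", "I", IND, carrier_counts=(0, 1)),
        P("ADRA2B", 138, "R", "Q", B, carrier_counts=(0, 2)),
        P("ADRA2B", 210, "R", "H", IND, carrier_counts=(0, 1)),
        P("ADRA2B", 292, "V", "M", B, region="outside"),
        P("ADRB1", 443, "N", "S", B),
        P("ADRB1", 445, "S", "N", B),
        P("ADRB1", 466, "R", "C", B, ancestral_in_outgroup=True),
        P("ADRB2", 15, "A", "T", B, region="outside"),
        P("ADRB2", 44, "T", "I", B, carrier_counts=(0, 2),
          ancestral_in_outgroup=True),
        P("ADRB2", 232, "Q", "R", B, carrier_counts=(0, 2),
          ancestral_in_outgroup=True),
        P("ADRB2", 277, "T", "M", B, carrier_counts=(0, 2)),
        # common to both breeds (7)
        P("ADRA2A", 58, "V", "I", C, ancestral_in_outgroup=True),
        P("ADRA2A", 273, "D", "E", C),
        P("ADRB1", 403, "R", "Q", C, ancestral_in_outgroup=True),
        P("ADRB3", 342, "R", "C", C),
        P("ADRB3", 396, "S", "P", C, ancestral_in_outgroup=True),
        P("ADRB3", 404, "Q", "L", C),
        P("ADRB3", 406, "P", "S", C),
    )
    return SynthSpec(
        genes={
            "ADRA1A": 1404, "ADRA1B": 1524, "ADRA1D": 1536,
            "ADRA2A": 1335, "ADRA2B": 1038, "ADRA2C": 1341,
            "ADRB1": 1434, "ADRB2": 1194, "ADRB3": 1314,
        },
        breeds=("ShaverBrown", "Shamo"),
        sample_names={"ShaverBrown": ("N5", "N6", "N7"),
                      "Shamo": ("S6", "S7", "S9")},
        planted=planted,
        background_het={
            "ADRA1A": 13, "ADRA1B": 4, "ADRA1D": 4, "ADRA2A": 19,
            "ADRA2B": 6, "ADRA2C": 1, "ADRB1": 2, "ADRB2": 5, "ADRB3": 5,
        },
        background_hom={
            "ADRA1B": 3, "ADRA1D": 1, "ADRA2B": 1, "ADRB1": 1,
        },
        n_outgroups=5,
        outgroup_divergence=0.05,
        seed=seed,
    )
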