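"""Amino-acid mutation calling, breed classification, ancestral screening,
and membrane-topology filtering.

A heterozygous codon (one IUPAC two-base position) encodes two residues;
comparing each sample's expanded residue set against a designated reference
sample yields ref->alt calls such as S365G.  Calls are classified by which
breed(s) carry them, screened against outgroup species for presence of the
alt residue (an allele found in an outgroup is ancestral, not a product of
recent artificial selection), and assigned a membrane-topology region from a
user-supplied annotation (inside / TMhelix / outside).  The candidate set
retains mutations fixed in a breed (all its samples carry them) or shared by
both breeds, derived with respect to the outgroups, and not extracellular.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .seqio import GeneAlignment, PopulationPartition, TWO_BASE_CODES, expansion_of

__all__ = [
    "AaMutation",
    "TopologyAnnotation",
    "MultiAmbiguityError",
    "ReferenceAmbiguityError",
    "FrameError",
    "expand_codon",
    "call_aa_mutations",
    "classify_mutation",
    "screen_ancestral",
    "annotate_region",
    "select_candidates",
    "read_topology_table",
    "mutation_frame",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter residue, stop codons as '*'
CODON_TO_AA: Mapping[str, str] = {
    **_STANDARD.forward_table,
    **{c: "*" for c in _STANDARD.stop_codons},
}

BREED_CLASSES = ("breedA_specific", "breedB_specific", "common")
REGIONS = ("inside", "TMhelix", "outside", "unannotated")


class MultiAmbiguityError(ValueError):
    """Codon with two or more ambiguous positions: flagged, not expanded."""


class ReferenceAmbiguityError(ValueError):
    """The reference sample's codon is ambiguous; calls need a fixed ref."""


class FrameError(ValueError):
    """Alignment length incompatible with the requested reading frame."""


@dataclasses.dataclass
class AaMutation:
    """One amino-acid mutation site aggregated over its carriers."""

    gene: str
    aa_pos: int  # 1-based codon index from the initiator Met
    ref_aa: str
    alt_aa: str
    carriers: dict[str, str]  # sample_id -> "het" | "hom"
    breed_class: str = "unclassified"
    individual_level: bool = False  # exactly one carrier
    complete_in_breed: bool = False  # carried by every sample of its breed(s)
    ancestry: str = "unscreened"  # derived | ancestral_present | unscreened
    region: str = "unannotated"  # inside | TMhelix | outside | unannotated
    selected: bool = False

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.aa_pos}{self.alt_aa}"


@dataclasses.dataclass(frozen=True)
class TopologyAnnotation:
    """Ordered, non-overlapping 1-based residue intervals with their region."""

    gene: str
    segments: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, region in self.segments:
            if region not in ("inside", "TMhelix", "outside"):
                raise ValueError(f"gene {self.gene}: unknown region {region!r}")
            if start > end or start <= prev_end:
                raise ValueError(
                    f"gene {self.gene}: segments must be ascending and "
                    f"non-overlapping; offending interval ({start}, {end})"
                )
            prev_end = end

    def region_of(self, aa_pos: int) -> str:
        for start, end, region in self.segments:
            if start <= aa_pos <= end:
                return region
        return "unannotated"


def expand_codon(codon: str) -> frozenset[str]:
    """Residues encoded by a codon with at most one ambiguous position.

    Stop codons appear as '*'.  Codons with >=2 ambiguous positions raise
    :class:`MultiAmbiguityError` rather than being combinatorially expanded;
    gaps are rejected.
    """
    if len(codon) != 3:
        raise ValueError(f"codon {codon!r} is not 3 bases")
    if "-" in codon:
        raise ValueError(f"codon {codon!r} contains a gap")
    n_ambiguous = sum(1 for b in codon if len(expansion_of(b)) != 1)
    if n_ambiguous >= 2:
        raise MultiAmbiguityError(
            f"codon {codon!r} has {n_ambiguous} ambiguous positions"
        )
    return _expand_codon_full(codon)


def _expand_codon_full(codon: str) -> frozenset[str]:
    """Residues of every unambiguous codon in the full expansion (lenient)."""
    residues = set()
    for b0 in expansion_of(codon[0]):
        for b1 in expansion_of(codon[1]):
            for b2 in expansion_of(codon[2]):
                residues.add(CODON_TO_AA[b0 + b1 + b2])
    if not residues:
        raise ValueError(f"codon {codon!r} has an empty expansion")
    return frozenset(residues)


def _codon_at(bases: str, codon_index: int, frame_start: int) -> str:
    k = frame_start - 1 + 3 * (codon_index - 1)
    return bases[k : k + 3]


def _n_codons(aln: GeneAlignment, frame_start: int) -> int:
    usable = aln.length - (frame_start - 1)
    if usable <= 0 or usable % 3 != 0:
        raise FrameError(
            f"gene {aln.gene}: {usable} columns from frame start "
            f"{frame_start} is not a whole number of codons"
        )
    return usable // 3


def call_aa_mutations(
    aln: GeneAlignment,
    reference: str,
    frame_start: int = 1,
) -> list[AaMutation]:
    """Call ref->alt amino-acid mutations for every ingroup sample.

    A sample carries a mutation at a codon if its expanded residue set
    contains a residue other than the reference's; zygosity is het when the
    set also contains the reference residue or the codon is ambiguous, hom
    otherwise.  One call is emitted per (codon, alt residue), aggregating
    carriers.  Codons with >=2 ambiguous positions in a sample are skipped
    for that sample (flagged upstream, never silently resolved).
    """
    ref_seq = aln.member(reference)
    n_codons = _n_codons(aln, frame_start)
    calls: dict[tuple[int, str], AaMutation] = {}
    for codon_index in range(1, n_codons + 1):
        ref_codon = _codon_at(ref_seq.bases, codon_index, frame_start)
        if "N" in ref_codon or "-" in ref_codon:
            continue  # reference unknown here; no call possible
        if any(b in TWO_BASE_CODES for b in ref_codon):
            raise ReferenceAmbiguityError(
                f"gene {aln.gene}: reference {reference!r} is heterozygous at "
                f"codon {codon_index} ({ref_codon}); calls need a fixed reference"
            )
        ref_aa = CODON_TO_AA[ref_codon]
        for m in aln.ingroup:
            codon = _codon_at(m.bases, codon_index, frame_start)
            if "N" in codon or "-" in codon:
                continue
            try:
                residues = expand_codon(codon)
            except MultiAmbiguityError:
                continue  # flagged site; excluded from calls
            ambiguous = any(b in TWO_BASE_CODES for b in codon)
            for alt_aa in residues - {ref_aa}:
                zygosity = "het" if (ref_aa in residues or ambiguous) else "hom"
                key = (codon_index, alt_aa)
                if key not in calls:
                    calls[key] = AaMutation(
                        gene=aln.gene,
                        aa_pos=codon_index,
                        ref_aa=ref_aa,
                        alt_aa=alt_aa,
                        carriers={},
                    )
                calls[key].carriers[m.sample_id] = zygosity
    return [calls[k] for k in sorted(calls)]


def classify_mutation(
    mut: AaMutation,
    partition: PopulationPartition,
) -> str:
    """Assign breed class from the carriers' subpopulations (two breeds).

    Carriers confined to one breed give that breed's *_specific class (breed
    A = first subpopulation label, breed B = second); carriers in both give
    "common".  The mutation is additionally marked individual-level when it
    has exactly one carrier, and complete_in_breed when every sample of each
    carrying breed is a carrier — the retention rule for the candidate set.
    """
    if not mut.carriers:
        raise ValueError(f"{mut.label}: no carriers to classify")
    pops = partition.subpopulations
    if len(pops) != 2:
        raise ValueError(f"classification needs exactly 2 subpopulations, got {len(pops)}")
    unknown = [s for s in mut.carriers if s not in partition.assignment]
    if unknown:
        raise ValueError(f"{mut.label}: carriers outside the partition: {unknown}")
    counts = dict.fromkeys(pops, 0)
    for sample in mut.carriers:
        counts[partition.assignment[sample]] += 1
    n_j = partition.n_j
    if counts[pops[0]] and counts[pops[1]]:
        mut.breed_class = "common"
        mut.complete_in_breed = all(counts[p] == n_j[p] for p in pops)
    elif counts[pops[0]]:
        mut.breed_class = "breedA_specific"
        mut.complete_in_breed = counts[pops[0]] == n_j[pops[0]]
    else:
        mut.breed_class = "breedB_specific"
        mut.complete_in_breed = counts[pops[1]] == n_j[pops[1]]
    mut.individual_level = len(mut.carriers) == 1
    return mut.breed_class


def screen_ancestral(
    mut: AaMutation,
    outgroups: GeneAlignment | Sequence,
    frame_start: int = 1,
) -> str:
    """Screen one mutation against outgroup sequences for the alt residue.

    ancestral_present if any outgroup sample's residue set at the codon
    contains alt_aa (outgroup codons are expanded fully, however ambiguous);
    derived if outgroups cover the codon but none shows alt_aa; unscreened
    if no outgroup covers the position.
    """
    if isinstance(outgroups, GeneAlignment):
        members = outgroups.with_roles("outgroup") or outgroups.members
    else:
        members = tuple(outgroups)
    covered = False
    for m in members:
        codon = _codon_at(m.bases, mut.aa_pos, frame_start)
        if len(codon) < 3 or "N" in codon or "-" in codon:
            continue
        covered = True
        if mut.alt_aa in _expand_codon_full(codon):
            mut.ancestry = "ancestral_present"
            return mut.ancestry
    mut.ancestry = "derived" if covered else "unscreened"
    return mut.ancestry


def annotate_region(mut: AaMutation, topo: TopologyAnnotation | None) -> str:
    """Attach the membrane-topology region containing the mutation."""
    mut.region = topo.region_of(mut.aa_pos) if topo is not None else "unannotated"
    return mut.region


def select_candidates(muts: Iterable[AaMutation]) -> list[AaMutation]:
    """Retention rule for artificial-selection candidates.

    Keeps mutations that are (i) breed-specific and carried by every sample
    of that breed, or shared by both breeds; (ii) derived with respect to
    the outgroups; (iii) not extracellular; and (iv) not a stop gain.
    Sets ``selected`` on every input mutation and returns the retained ones.
    """
    kept = []
    for mut in muts:
        breed_ok = (
            mut.breed_class == "common"
            or (mut.breed_class in ("breedA_specific", "breedB_specific")
                and mut.complete_in_breed)
        )
        mut.selected = (
            breed_ok
            and mut.ancestry == "derived"
            and mut.region != "outside"
            and mut.alt_aa != "*"
        )
        if mut.selected:
            kept.append(mut)
    return kept


def read_topology_table(path: str | Path) -> dict[str, TopologyAnnotation]:
    """Load per-gene topology segments from TSV (gene, aa_start, aa_end, region)."""
    table = pd.read_csv(path, sep="\t")
    required = {"gene", "aa_start", "aa_end", "region"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"topology table {path}: missing columns {sorted(missing)}")
    out = {}
    for gene, rows in table.groupby("gene", sort=False):
        segments = tuple(
            (int(r.aa_start), int(r.aa_end), str(r.region))
            for r in rows.sort_values("aa_start").itertuples()
        )
        out[str(gene)] = TopologyAnnotation(gene=str(gene), segments=segments)
    return out


def mutation_frame(muts: Iterable[AaMutation]) -> pd.DataFrame:
    """Flat mutation table (all calls; filter on `selected` for candidates)."""
    rows = []
    for m in muts:
        rows.append(
            {
                "gene": m.gene,
                "label": m.label,
                "aa_pos": m.aa_pos,
                "ref_aa": m.ref_aa,
                "alt_aa": m.alt_aa,
                "carriers": ",".join(
                    f"{s}:{z}" for s, z in sorted(m.carriers.items())
                ),
                "n_carriers": len(m.carriers),
                "zygosity": ";".join(sorted(set(m.carriers.values()))),
                "breed_class": m.breed_class,
                "individual_level": m.individual_level,
                "ancestry": m.ancestry,
                "region": m.region,
                "selected": m.selected,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "label", "aa_pos", "ref_aa", "alt_aa", "carriers",
            "n_carriers", "zygosity", "breed_class", "individual_level",
            "ancestry", "region", "selected",
        ],
    )
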