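"""Sequence I/O and alignment handling for IUPAC-coded diploid genotypes.

Direct Sanger sequencing of a diploid individual yields one sequence per
sample in which heterozygous positions appear as IUPAC two-base ambiguity
codes (R = A/G, Y = C/T, M = A/C, K = G/T, S = C/G, W = A/T).  This module
models such sequences, assembles per-gene multi-sample alignments with
population labels and role tags (ingroup / reference / outgroup), and
applies complete deletion of gap-containing columns while preserving a map
back to original alignment coordinates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_EXPANSION",
    "AMBIGUITY_OF_PAIR",
    "SampleSequence",
    "GeneAlignment",
    "PopulationPartition",
    "AlignmentError",
    "SequenceParseError",
    "read_gene_fasta",
    "read_sample_sheet",
    "write_gene_fasta",
    "exclude_gap_columns",
]

#: Expansion of each accepted symbol into unambiguous bases.  Gap expands to
#: nothing; N denotes a fully missing genotype at the site.
IUPAC_EXPANSION: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "M": frozenset("AC"),
    "K": frozenset("GT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "N": frozenset("ACGT"),
    "-": frozenset(),
}

#: Reverse lookup: unordered base pair -> two-base ambiguity symbol.
AMBIGUITY_OF_PAIR: Mapping[frozenset[str], str] = {
    expansion: symbol
    for symbol, expansion in IUPAC_EXPANSION.items()
    if len(expansion) == 2
}

TWO_BASE_CODES = frozenset("RYMKSW")
VALID_SYMBOLS = frozenset(IUPAC_EXPANSION)


class AlignmentError(ValueError):
    """Raised for structurally invalid alignments (ragged, empty, all-gap)."""


class SequenceParseError(ValueError):
    """Raised when a sequence contains a symbol outside the IUPAC set."""


def expansion_of(symbol: str) -> frozenset[str]:
    """Unambiguous bases denoted by ``symbol``; each carries weight 1/|set|."""
    try:
        return IUPAC_EXPANSION[symbol]
    except KeyError:
        raise SequenceParseError(f"illegal symbol {symbol!r}") from None


def _normalize(raw: str, record_id: str) -> str:
    """Uppercase, map U->T, and validate every symbol."""
    seq = raw.upper().replace("U", "T")
    for col, sym in enumerate(seq, start=1):
        if sym not in VALID_SYMBOLS:
            raise SequenceParseError(
                f"record {record_id!r}: illegal symbol {sym!r} at column {col}"
            )
    return seq


@dataclasses.dataclass(frozen=True)
class SampleSequence:
    """One sample's IUPAC-coded sequence for one gene."""

    sample_id: str
    population: str
    role: str  # ingroup | reference | outgroup
    gene: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise AlignmentError(f"sample {self.sample_id!r}: empty sequence")
        if self.role not in ("ingroup", "reference", "outgroup"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclasses.dataclass(frozen=True)
class GeneAlignment:
    """Equal-length IUPAC sequences for one gene across samples.

    ``retained_columns[k]`` is the original 1-based alignment column behind
    post-exclusion column index ``k`` (0-based).  A freshly loaded alignment
    carries the identity map.
    """

    gene: str
    members: tuple[SampleSequence, ...]
    retained_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise AlignmentError(f"gene {self.gene}: no sequences")
        lengths = {len(m.bases) for m in self.members}
        if len(lengths) != 1:
            bad = min(self.members, key=lambda m: len(m.bases))
            raise AlignmentError(
                f"gene {self.gene}: ragged alignment, record {bad.sample_id!r} "
                f"has length {len(bad.bases)} (others {sorted(lengths)})"
            )
        if len(self.retained_columns) != self.length:
            raise AlignmentError(
                f"gene {self.gene}: column map length "
                f"{len(self.retained_columns)} != alignment length {self.length}"
            )

    @property
    def length(self) -> int:
        return len(self.members[0].bases)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(m.sample_id for m in self.members)

    def member(self, sample_id: str) -> SampleSequence:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise KeyError(f"sample {sample_id!r} not in gene {self.gene}")

    def with_roles(self, *roles: str) -> tuple[SampleSequence, ...]:
        return tuple(m for m in self.members if m.role in roles)

    @property
    def ingroup(self) -> tuple[SampleSequence, ...]:
        return self.with_roles("ingroup")

    def index_of_site(self, site: int) -> int:
        """Post-exclusion column index of original 1-based column ``site``."""
        try:
            return self._site_index[site]
        except AttributeError:
            object.__setattr__(
                self,
                "_site_index",
                {orig: k for k, orig in enumerate(self.retained_columns)},
            )
            return self.index_of_site(site)
        except KeyError:
            raise KeyError(
                f"gene {self.gene}: column {site} not retained"
            ) from None

    def column(self, site: int) -> dict[str, str]:
        """Symbols at original 1-based column ``site``, keyed by sample."""
        k = self.index_of_site(site)
        return {m.sample_id: m.bases[k] for m in self.members}

    def subset(self, sample_ids: Iterable[str]) -> "GeneAlignment":
        wanted = set(sample_ids)
        kept = tuple(m for m in self.members if m.sample_id in wanted)
        missing = wanted - {m.sample_id for m in kept}
        if missing:
            raise KeyError(f"gene {self.gene}: unknown samples {sorted(missing)}")
        return GeneAlignment(self.gene, kept, self.retained_columns)


@dataclasses.dataclass(frozen=True)
class PopulationPartition:
    """Assignment of ingroup samples to subpopulations (breeds)."""

    assignment: Mapping[str, str]

    @property
    def m(self) -> int:
        return len(self.subpopulations)

    @property
    def subpopulations(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for pop in self.assignment.values():
            seen.setdefault(pop)
        return tuple(seen)

    @property
    def n_j(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for pop in self.assignment.values():
            counts[pop] = counts.get(pop, 0) + 1
        return counts

    def members_of(self, subpopulation: str) -> tuple[str, ...]:
        return tuple(
            s for s, p in self.assignment.items() if p == subpopulation
        )

    @classmethod
    def from_alignment(cls, aln: GeneAlignment) -> "PopulationPartition":
        return cls({m.sample_id: m.population for m in aln.ingroup})


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the TSV sidecar with columns sample_id, population, role."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "population", "role"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"sample sheet {path}: duplicate sample ids {dupes}")
    return sheet


def read_gene_fasta(
    path: str | Path,
    metadata: pd.DataFrame,
    gene: str | None = None,
) -> GeneAlignment:
    """Load one gene's pre-aligned FASTA, attaching roles and populations.

    FASTA headers must contain a sample_id from ``metadata`` as a
    whitespace/pipe-delimited token; header decoration beyond that token is
    ignored.  Symbols are validated against the IUPAC set; lengths must agree.
    """
    path = Path(path)
    gene = gene or path.stem
    by_id = metadata.set_index("sample_id")
    members = []
    for record in SeqIO.parse(str(path), "fasta"):
        tokens = record.description.replace("|", " ").split()
        sample_id = next((t for t in tokens if t in by_id.index), None)
        if sample_id is None:
            raise AlignmentError(
                f"{path.name}: header {record.description!r} does not contain "
                "a sample_id from the sample sheet"
            )
        row = by_id.loc[sample_id]
        members.append(
            SampleSequence(
                sample_id=sample_id,
                population=str(row["population"]),
                role=str(row["role"]),
                gene=gene,
                bases=_normalize(str(record.seq), sample_id),
            )
        )
    if not members:
        raise AlignmentError(f"{path}: no FASTA records")
    length = len(members[0].bases)
    return GeneAlignment(gene, tuple(members), tuple(range(1, length + 1)))


def write_gene_fasta(aln: GeneAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(m.bases), id=m.sample_id, description="")
        for m in aln.members
    ]
    SeqIO.write(records, str(path), "fasta")


def write_column_map(aln: GeneAlignment, path: str | Path) -> None:
    """TSV mapping post-exclusion column index (1-based) to original column."""
    pd.DataFrame(
        {
            "retained_index": range(1, len(aln.retained_columns) + 1),
            "original_column": aln.retained_columns,
        }
    ).to_csv(path, sep="\t", index=False)


def exclude_gap_columns(aln: GeneAlignment) -> GeneAlignment:
    """Complete deletion: drop every column gapped in any member.

    Idempotent; the returned alignment's ``retained_columns`` composes with
    the input's so reports always cite original 1-based coordinates.
    """
    keep = [
        k
        for k in range(aln.length)
        if all(m.bases[k] != "-" for m in aln.members)
    ]
    if not keep:
        raise AlignmentError(
            f"gene {aln.gene}: every column contains a gap; nothing retained"
        )
    if len(keep) == aln.length:
        return aln
    members = tuple(
        dataclasses.replace(m, bases="".join(m.bases[k] for k in keep))
        for m in aln.members
    )
    retained = tuple(aln.retained_columns[k] for k in keep)
    return GeneAlignment(aln.gene, members, retained)
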