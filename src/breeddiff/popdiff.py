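"""Nucleotide differentiation (N_ST) between subpopulations.

Each sample is one diploid genotype read by direct sequencing: an
unambiguous base contributes two copies of that allele, a two-base IUPAC
code one copy of each.  Per-site heterozygosity is

    H = 1 - (P_A^2 + P_T^2 + P_G^2 + P_C^2)

and the per-site index of nucleotide differentiation for subpopulation j is

    N_STij = (H_Ti - H_Sij) / H_Ti

with H_Ti from the pooled ingroup and H_Sij from subpopulation j alone.
The per-gene index N_STj averages N_STij over the gene's segregating sites.
Negative values (a subpopulation more diverse than the pool) are reported
unmodified; a gene with no segregating site reports 0 for every
subpopulation.

N counts as missing data for that sample at that site: it contributes no
allele weight and frequencies are renormalized over the remaining samples.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import (
    GeneAlignment,
    PopulationPartition,
    SampleSequence,
    TWO_BASE_CODES,
    expansion_of,
)

__all__ = [
    "SiteFrequencies",
    "SiteNst",
    "SegregatingSite",
    "NstReport",
    "MonomorphicSiteError",
    "UndefinedFrequencyError",
    "site_allele_frequencies",
    "heterozygosity",
    "nst_at_site",
    "segregating_sites",
    "gene_nst",
    "format_mutation_rate",
    "nst_report_frame",
]

BASES = ("A", "T", "G", "C")


class UndefinedFrequencyError(ValueError):
    """All samples missing (N) at the site: frequencies undefined."""


class MonomorphicSiteError(ValueError):
    """N_ST requested at a site with H_T = 0."""


@dataclasses.dataclass(frozen=True)
class SiteFrequencies:
    """Allele frequency vector at one site for one (sub)population."""

    site: int  # original 1-based alignment column
    population: str  # subpopulation label, or "TOTAL" for the pooled ingroup
    P_A: float
    P_T: float
    P_G: float
    P_C: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.P_A, self.P_T, self.P_G, self.P_C)


@dataclasses.dataclass(frozen=True)
class SiteNst:
    site: int
    H_T: float
    H_S: Mapping[str, float]
    nst: Mapping[str, float]


@dataclasses.dataclass(frozen=True)
class SegregatingSite:
    site: int
    alleles: frozenset[str]
    heterozygous: bool  # >=1 sample carries a two-base code here


@dataclasses.dataclass(frozen=True)
class NstReport:
    """Per-gene summary: lengths, site counts, mutation rate, N_ST per breed."""

    gene: str
    length_bp: int
    segregating_sites: int
    heterozygous_sites: int
    mutation_rate_pct: float
    nst_by_pop: Mapping[str, float]


def site_allele_frequencies(
    aln: GeneAlignment,
    site: int,
    members: Sequence[SampleSequence] | None = None,
    population: str = "TOTAL",
) -> SiteFrequencies:
    """Diploid allele frequencies at an original 1-based column.

    Each non-missing sample contributes total weight 1, split equally over
    its symbol's expansion (0.5 + 0.5 for a heterozygote).  Samples showing
    N are excluded and the frequencies renormalized.
    """
    if members is None:
        members = aln.ingroup
    if not members:
        raise ValueError("empty member subset")
    k = aln.index_of_site(site)
    weights = dict.fromkeys("ACGT", 0.0)
    total = 0.0
    for m in members:
        sym = m.bases[k]
        if sym == "N":
            continue
        expansion = expansion_of(sym)
        if not expansion:
            raise ValueError(
                f"gene {aln.gene} column {site}: gap in {m.sample_id!r}; "
                "exclude gap columns first"
            )
        share = 1.0 / len(expansion)
        for base in expansion:
            weights[base] += share
        total += 1.0
    if total == 0.0:
        raise UndefinedFrequencyError(
            f"gene {aln.gene} column {site}: all samples missing (N)"
        )
    return SiteFrequencies(
        site=site,
        population=population,
        P_A=weights["A"] / total,
        P_T=weights["T"] / total,
        P_G=weights["G"] / total,
        P_C=weights["C"] / total,
    )


def heterozygosity(freqs: SiteFrequencies) -> float:
    """H = 1 - sum of squared allele frequencies; in [0, 0.75]."""
    return 1.0 - sum(p * p for p in freqs.as_tuple())


def nst_at_site(
    aln: GeneAlignment,
    site: int,
    partition: PopulationPartition | None = None,
) -> SiteNst:
    """Per-site N_ST for every subpopulation at a segregating column."""
    if partition is None:
        partition = PopulationPartition.from_alignment(aln)
    ingroup = [m for m in aln.ingroup if m.sample_id in partition.assignment]
    h_t = heterozygosity(site_allele_frequencies(aln, site, ingroup))
    if h_t == 0.0:
        raise MonomorphicSiteError(
            f"gene {aln.gene} column {site}: monomorphic (H_T = 0); "
            "N_ST is defined at segregating sites only"
        )
    h_s: dict[str, float] = {}
    nst: dict[str, float] = {}
    for pop in partition.subpopulations:
        pop_members = [m for m in ingroup if partition.assignment[m.sample_id] == pop]
        freqs = site_allele_frequencies(aln, site, pop_members, population=pop)
        h_s[pop] = heterozygosity(freqs)
        nst[pop] = (h_t - h_s[pop]) / h_t
    return SiteNst(site=site, H_T=h_t, H_S=h_s, nst=nst)


def segregating_sites(aln: GeneAlignment) -> list[SegregatingSite]:
    """Columns whose pooled expanded allele set (ignoring N) has >=2 bases.

    Operates on the ingroup members only; each site is flagged heterozygous
    if at least one ingroup sample carries a two-base code there.
    """
    ingroup = aln.ingroup
    out: list[SegregatingSite] = []
    for k, orig in enumerate(aln.retained_columns):
        alleles: set[str] = set()
        het = False
        for m in ingroup:
            sym = m.bases[k]
            if sym == "N":
                continue
            alleles |= expansion_of(sym)
            het = het or sym in TWO_BASE_CODES
        if len(alleles) >= 2:
            out.append(
                SegregatingSite(site=orig, alleles=frozenset(alleles), heterozygous=het)
            )
    return out


def gene_nst(
    aln: GeneAlignment,
    partition: PopulationPartition | None = None,
) -> NstReport:
    """Per-gene N_ST report: counts, mutation rate, mean N_ST per breed.

    N_STj averages the per-site values over segregating sites only (n = the
    segregating-site count); a gene without segregating sites reports 0 for
    every subpopulation.  mutation_rate_pct = 100 * S / L.
    """
    if partition is None:
        partition = PopulationPartition.from_alignment(aln)
    sites = segregating_sites(aln)
    length = aln.length
    if length == 0:
        raise ValueError(f"gene {aln.gene}: empty alignment")
    pops = partition.subpopulations
    if sites:
        sums = dict.fromkeys(pops, 0.0)
        for s in sites:
            per_site = nst_at_site(aln, s.site, partition)
            for pop in pops:
                sums[pop] += per_site.nst[pop]
        nst_by_pop = {pop: sums[pop] / len(sites) for pop in pops}
    else:
        nst_by_pop = dict.fromkeys(pops, 0.0)
    return NstReport(
        gene=aln.gene,
        length_bp=length,
        segregating_sites=len(sites),
        heterozygous_sites=sum(s.heterozygous for s in sites),
        mutation_rate_pct=100.0 * len(sites) / length,
        nst_by_pop=nst_by_pop,
    )


def format_mutation_rate(rate_pct: float) -> str:
    """Render a mutation rate the way the per-gene report prints it.

    Rounded to two decimals, trailing zeros trimmed down to a minimum of one
    decimal place: 0.9972 -> "1.0", 1.6479 -> "1.65", 0.0746 -> "0.07".
    """
    text = f"{rate_pct:.2f}"
    if text.endswith("0") and not text.endswith(".00"):
        text = text[:-1]
    elif text.endswith(".00"):
        text = text[:-1]
    return text


def nst_report_frame(reports: Iterable[NstReport]) -> pd.DataFrame:
    """Tabular per-gene report (one N_ST column per subpopulation)."""
    rows = []
    for r in reports:
        row = {
            "gene": r.gene,
            "length_bp": r.length_bp,
            "segregating_sites": r.segregating_sites,
            "heterozygous_sites": r.heterozygous_sites,
            "mutation_rate_pct": format_mutation_rate(r.mutation_rate_pct),
        }
        for pop, value in r.nst_by_pop.items():
            row[f"nst_{pop}"] = round(value, 3)
        rows.append(row)
    return pd.DataFrame(rows)
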