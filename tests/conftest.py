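"""Shared fixtures and alignment-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from breeddiff.seqio import GeneAlignment, PopulationPartition, SampleSequence


def make_alignment(
    seqs: dict[str, str],
    populations: dict[str, str] | None = None,
    roles: dict[str, str] | None = None,
    gene: str = "GENE",
) -> GeneAlignment:
    """Build a GeneAlignment from sample_id -> bases (ingroup by default)."""
    members = tuple(
        SampleSequence(
            sample_id=s,
            population=(populations or {}).get(s, "pop"),
            role=(roles or {}).get(s, "ingroup"),
            gene=gene,
            bases=bases,
        )
        for s, bases in seqs.items()
    )
    length = len(members[0].bases)
    return GeneAlignment(gene, members, tuple(range(1, length + 1)))


def random_iupac_alignment(
    rng: np.random.Generator,
    n_samples: int | None = None,
    length: int | None = None,
    symbols: str = "ACGTRYMKSW",
) -> tuple[GeneAlignment, PopulationPartition]:
    """Random small two-subpopulation alignment of IUPAC genotypes."""
    n = n_samples or int(rng.integers(2, 7))
    L = length or int(rng.integers(1, 31))
    ids = [f"s{k}" for k in range(n)]
    pops = {s: ("X" if k < max(1, n // 2) else "Y") for k, s in enumerate(ids)}
    sym = np.array(list(symbols))
    seqs = {
        s: "".join(sym[rng.integers(0, len(sym), size=L)]) for s in ids
    }
    aln = make_alignment(seqs, populations=pops)
    return aln, PopulationPartition(pops)


@pytest.fixture(scope="session")
def paper_shaped_result():
    """One study-shaped synthetic dataset shared across the session."""
    from breeddiff import synthdata

    return synthdata.generate(synthdata.paper_shaped_spec(seed=20230169))
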