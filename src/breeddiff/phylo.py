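"""Kimura two-parameter distances, UPGMA clustering, bootstrap supports.

Distances are corrected for multiple hits under Kimura's two-parameter
model,

    d = -(1/2) * ln((1 - 2P - Q) * sqrt(1 - 2Q)),

with P and Q the transition and transversion proportions over sites where
both sequences show an unambiguous base (pairwise deletion of ambiguity
codes and gaps, after global gap-column exclusion).  Trees are built with
UPGMA — size-weighted average linkage producing a rooted ultrametric tree —
and internal-node confidence comes from bootstrap resampling of alignment
columns: support is the percentage of replicate trees containing the node's
leaf set as a clade.

Tie-breaking in UPGMA is deterministic: among equally close pairs the one
with the lexicographically smallest (row, column) index pair in the current
cluster list is merged, so reruns give byte-identical Newick strings.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np

from .seqio import GeneAlignment

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "SaturationError",
    "k2p_distance",
    "k2p_matrix",
    "upgma",
    "bootstrap_upgma",
    "to_newick",
]

# base -> integer code; anything ambiguous or gapped -> 4 (excluded pairwise)
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}
_PURINES = (0, 1)


class SaturationError(ValueError):
    """Distance undefined: too many substitutions for the K2P correction."""


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")


@dataclasses.dataclass
class TreeNode:
    """Rooted ultrametric tree node; height is distance to any descendant leaf."""

    height: float
    children: tuple["TreeNode", ...] = ()
    label: str | None = None  # leaf label
    support: float | None = None  # bootstrap percentage, internal nodes only
    size: int = 1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset((self.label,))
        return frozenset().union(*(c.leaves() for c in self.children))

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes."""
        return {n.leaves() for n in self.walk() if not n.is_leaf}


def _encode(bases: str) -> np.ndarray:
    return np.fromiter((_CODE.get(b, 4) for b in bases), dtype=np.int8, count=len(bases))


def _k2p_from_counts(n: int, transitions: int, transversions: int) -> float:
    if n == 0:
        raise SaturationError("no comparable sites after pairwise deletion")
    p = transitions / n
    q = transversions / n
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0.0 or b <= 0.0:
        raise SaturationError(
            f"substitutions saturated (P={p:.3f}, Q={q:.3f}); "
            "K2P correction undefined"
        )
    # + 0.0 normalizes the -0.0 that -0.5*log(1) produces
    return -0.5 * math.log(a * math.sqrt(b)) + 0.0


def _pair_counts(c1: np.ndarray, c2: np.ndarray) -> tuple[int, int, int]:
    valid = (c1 < 4) & (c2 < 4)
    n = int(valid.sum())
    diff = valid & (c1 != c2)
    # transition: both purines or both pyrimidines (codes 0,1 vs 2,3)
    transitions = int((diff & ((c1 < 2) == (c2 < 2))).sum())
    transversions = int(diff.sum()) - transitions
    return n, transitions, transversions


def k2p_distance(s1: str, s2: str) -> float:
    """K2P distance between two equal-length IUPAC sequences.

    Sites where either symbol is not an unambiguous A/C/G/T are excluded
    (pairwise deletion).  Raises :class:`SaturationError` when the log
    argument is non-positive or no comparable site remains.
    """
    if len(s1) != len(s2):
        raise ValueError(f"length mismatch: {len(s1)} vs {len(s2)}")
    n, ts, tv = _pair_counts(_encode(s1), _encode(s2))
    return _k2p_from_counts(n, ts, tv)


def k2p_matrix(aln: GeneAlignment) -> DistanceMatrix:
    """Pairwise K2P distance matrix over all members of an alignment."""
    labels = aln.sample_ids
    codes = [_encode(m.bases) for m in aln.members]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance_codes(codes[i], codes[j])
    return DistanceMatrix(labels=labels, d=d)


def k2p_distance_codes(c1: np.ndarray, c2: np.ndarray) -> float:
    n, ts, tv = _pair_counts(c1, c2)
    return _k2p_from_counts(n, ts, tv)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """UPGMA: iteratively merge the closest pair of clusters.

    Cluster-to-cluster distances are arithmetic averages weighted by cluster
    sizes; a merge at distance d places the new node at height d/2.  Ties
    are broken by the smallest (row, column) index pair.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    nodes: list[TreeNode] = [
        TreeNode(height=0.0, label=lab, size=1) for lab in dm.labels
    ]
    dist = dm.d.astype(float).copy()
    active = list(range(n))  # indices into rows of `dist`
    while len(active) > 1:
        best = (math.inf, -1, -1)
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                val = dist[active[ii], active[jj]]
                if val < best[0]:
                    best = (val, ii, jj)
        d_min, ii, jj = best
        i, j = active[ii], active[jj]
        a, b = nodes[i], nodes[j]
        merged = TreeNode(
            height=d_min / 2.0, children=(a, b), size=a.size + b.size
        )
        # size-weighted average of distances to every other active cluster
        for kk in range(len(active)):
            k = active[kk]
            if k in (i, j):
                continue
            dist[i, k] = dist[k, i] = (
                a.size * dist[i, k] + b.size * dist[j, k]
            ) / (a.size + b.size)
        nodes[i] = merged
        del active[jj]  # i keeps the lower slot; j retires
    return nodes[active[0]]


def bootstrap_upgma(
    aln: GeneAlignment,
    B: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, int]:
    """UPGMA tree with bootstrap supports from column resampling.

    The returned topology and branch lengths come from the original
    alignment; each internal node's support is the percentage of successful
    replicates (columns resampled with replacement, K2P + UPGMA rebuilt)
    whose tree contains the node's leaf set as a clade.  Replicates with
    saturated distances are discarded; more than 50% discarded is an error.
    Returns (tree, number of discarded replicates).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    codes = np.vstack([_encode(m.bases) for m in aln.members])
    labels = aln.sample_ids
    n, L = codes.shape
    tree = upgma(k2p_matrix(aln))
    rng = np.random.default_rng(seed)
    clade_hits: dict[frozenset[str], int] = {c: 0 for c in tree.clades()}
    discarded = 0
    kept = 0
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        sample = codes[:, cols]
        try:
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = k2p_distance_codes(sample[i], sample[j])
            rep = upgma(DistanceMatrix(labels=labels, d=d))
        except SaturationError:
            discarded += 1
            continue
        kept += 1
        rep_clades = rep.clades()
        for clade in clade_hits:
            if clade in rep_clades:
                clade_hits[clade] += 1
    if discarded > B / 2:
        raise SaturationError(
            f"{discarded}/{B} bootstrap replicates discarded for saturation"
        )
    for node in tree.walk():
        if not node.is_leaf:
            node.support = 100.0 * clade_hits[node.leaves()] / max(kept, 1)
    return tree, discarded


def to_newick(node: TreeNode, parent_height: float | None = None) -> str:
    """Newick with branch lengths and integer supports as internal labels."""
    if node.is_leaf:
        body = node.label
    else:
        inner = ",".join(to_newick(c, node.height) for c in node.children)
        support = "" if node.support is None else str(int(round(node.support)))
        body = f"({inner}){support}"
    if parent_height is None:
        return f"{body};"
    return f"{body}:{parent_height - node.height:.10g}"
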