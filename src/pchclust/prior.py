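"""Must-link prior pair sets and the partition/indicator structures they induce.

A prior pair set collects sample pairs asserted in advance to share a
cluster (at both the rough and the refined level).  Internally indices are
0-based; the 1-based convention of input files and printed reports is
handled at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components


@dataclass(frozen=True)
class PriorPairSet:
    """Transitively closed set of must-link pairs over ``n`` samples.

    ``pairs`` holds 0-based ``(j, m)`` tuples with ``j < m``.  Closure under
    transitivity means the pairs are exactly the within-block pairs of a
    partition of a subset of the samples.
    """

    n: int
    pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("sample count must be positive")
        for j, m in self.pairs:
            if not (0 <= j < m < self.n):
                raise ValueError(f"invalid pair ({j}, {m}) for n={self.n}")

    def __len__(self):
        return len(self.pairs)

    @property
    def is_empty(self) -> bool:
        return len(self.pairs) == 0


@dataclass(frozen=True)
class PriorPartition:
    """Blocks F_1..F_K induced by a prior pair set, plus the n x K indicator L.

    Blocks are disjoint, cover all samples (unpaired samples are singleton
    blocks), and are ordered by smallest member.  ``L[i, k] = 1`` iff sample
    ``i`` lies in block ``k``.
    """

    n: int
    blocks: tuple  # tuple of tuples of 0-based indices
    labels: np.ndarray  # n-vector of block indices

    @property
    def K(self) -> int:
        return len(self.blocks)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(b) for b in self.blocks])

    @property
    def L(self) -> np.ndarray:
        L = np.zeros((self.n, self.K))
        L[np.arange(self.n), self.labels] = 1.0
        return L


@dataclass(frozen=True)
class PairIndex:
    """Lexicographic enumeration of all n(n-1)/2 pairs with prior flags.

    ``j_idx``/``m_idx`` give the endpoints of each pair; ``is_prior`` marks
    membership in the prior set.  ``D`` is the signed incidence matrix with
    rows e_j - e_m (sparse); the Kronecker expansions L (x) I and D (x) I are
    never materialized -- they act as implicit operators in the solver.
    """

    n: int
    j_idx: np.ndarray
    m_idx: np.ndarray
    is_prior: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.j_idx)

    @property
    def D(self) -> sparse.csr_matrix:
        rows = np.repeat(np.arange(self.n_pairs), 2)
        cols = np.column_stack([self.j_idx, self.m_idx]).ravel()
        vals = np.tile([1.0, -1.0], self.n_pairs)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n_pairs, self.n))


def validate_and_close(raw_pairs, n: int) -> PriorPairSet:
    """Normalize, deduplicate and transitively close raw must-link pairs.

    ``raw_pairs`` is an iterable of 0-based index pairs.  Closure is the
    unique minimal consistent completion: pairs sharing an endpoint pull
    their third pair in, i.e. the closed set is the union of all
    within-component pairs of the pair graph.
    """
    norm = set()
    for j, m in raw_pairs:
        j, m = int(j), int(m)
        if j == m:
            raise ValueError(f"pair ({j}, {m}) links a sample to itself")
        if not (0 <= j < n and 0 <= m < n):
            raise ValueError(f"pair ({j}, {m}) out of range for n={n}")
        norm.add((min(j, m), max(j, m)))
    if not norm:
        return PriorPairSet(n=n, pairs=frozenset())
    # transitive closure = all pairs within each connected component
    part = _components(n, norm)
    closed = set()
    for block in part:
        for a_i in range(len(block)):
            for b_i in range(a_i + 1, len(block)):
                closed.add((block[a_i], block[b_i]))
    return PriorPairSet(n=n, pairs=frozenset(closed))


def _components(n, pairs):
    """Connected components (size >= 2 only) of the pair graph, each sorted."""
    if not pairs:
        return []
    arr = np.array(sorted(pairs))
    g = sparse.csr_matrix(
        (np.ones(len(arr)), (arr[:, 0], arr[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(g, directed=False)
    blocks = {}
    touched = np.zeros(n, dtype=bool)
    touched[arr[:, 0]] = True
    touched[arr[:, 1]] = True
    for i in np.flatnonzero(touched):
        blocks.setdefault(labels[i], []).append(int(i))
    return [sorted(b) for b in blocks.values()]


def to_partition(prior: PriorPairSet) -> PriorPartition:
    """Blocks = connected components of the pair graph plus singletons.

    Ordered by smallest member; for an empty prior every sample is its own
    block and L is the identity.
    """
    n = prior.n
    multi = _components(n, prior.pairs)
    in_multi = set()
    for b in multi:
        in_multi.update(b)
    blocks = multi + [[i] for i in range(n) if i not in in_multi]
    blocks.sort(key=lambda b: b[0])
    labels = np.empty(n, dtype=np.int64)
    for k, b in enumerate(blocks):
        for i in b:
            labels[i] = k
    return PriorPartition(n=n, blocks=tuple(tuple(b) for b in blocks), labels=labels)


def partition_to_pairs(partition: PriorPartition) -> PriorPairSet:
    """All within-block pairs of a partition (inverse of ``to_partition``)."""
    pairs = set()
    for b in partition.blocks:
        for a_i in range(len(b)):
            for b_i in range(a_i + 1, len(b)):
                pairs.add((b[a_i], b[b_i]))
    return PriorPairSet(n=partition.n, pairs=frozenset(pairs))


def build_pair_index(n: int, prior: PriorPairSet | None = None) -> PairIndex:
    """Enumerate all n(n-1)/2 pairs lexicographically and flag prior members."""
    if n < 2:
        raise ValueError("need at least two samples")
    j_idx, m_idx = np.triu_indices(n, k=1)
    is_prior = np.zeros(len(j_idx), dtype=bool)
    if prior is not None and prior.pairs:
        # pair (j, m) sits at offset j*n - j(j+1)/2 + (m - j - 1)
        pj, pm = np.array(sorted(prior.pairs)).T
        pos = pj * n - pj * (pj + 1) // 2 + (pm - pj - 1)
        is_prior[pos] = True
    return PairIndex(n=n, j_idx=j_idx, m_idx=m_idx, is_prior=is_prior)
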