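"""Pairwise sequence identity and hierarchical OTU partitions over a threshold grid.

Identity is defined from a global (Needleman-Wunsch) alignment with match +1,
mismatch -1 and a linear gap penalty of -2 per gap column, as

    identity = matched columns / alignment length (gap columns included).

Among co-optimal alignments the one maximising matched columns and, on a
further tie, minimising alignment length is used — i.e. match/mismatch moves
are preferred over gaps — so identities are fully deterministic.

OTUs at a similarity level ``s`` (percent) come from cutting one
average-linkage tree at distance ``(100 - s)/100`` with an inclusive cut, so
partitions across the grid are nested and the OTU count is non-decreasing in
``s``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_seq import SequenceTypeTable

_MAX_LEN = 2000  # packed-key DP fields sized for n + m <= 4094

# Per-move deltas for the packed (score, matches, -length) key.  Each cell
# holds ((score + 8192) << 24) + (matches << 12) + (4095 - length); the three
# fields cannot over/underflow for sequences up to _MAX_LEN, so an integer max
# over keys is a lexicographic max over (score, matches, -length).
_D_MATCH = (1 << 24) + (1 << 12) - 1
_D_MISMATCH = -(1 << 24) - 1
_D_GAP = -(2 << 24) - 1
_KEY_INIT = (8192 << 24) + 4095


@njit(cache=True)
def _align_key(a: np.ndarray, b: np.ndarray) -> np.int64:  # pragma: no cover
    n, m = a.size, b.size
    prev = np.empty(m + 1, dtype=np.int64)
    cur = np.empty(m + 1, dtype=np.int64)
    prev[0] = _KEY_INIT
    for j in range(1, m + 1):
        prev[j] = prev[j - 1] + _D_GAP
    for i in range(1, n + 1):
        cur[0] = prev[0] + _D_GAP
        ai = a[i - 1]
        for j in range(1, m + 1):
            v = prev[j - 1] + (_D_MATCH if ai == b[j - 1] else _D_MISMATCH)
            u = prev[j] + _D_GAP
            if u > v:
                v = u
            w = cur[j - 1] + _D_GAP
            if w > v:
                v = w
            cur[j] = v
        prev, cur = cur, prev
    return prev[m]


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def align_stats(a: str, b: str) -> tuple[int, int, int]:
    """Optimal global alignment (score, matched columns, alignment length)."""
    if not a or not b:
        raise ValueError("empty sequence")
    if len(a) > _MAX_LEN or len(b) > _MAX_LEN:
        raise ValueError(f"sequences longer than {_MAX_LEN} bases not supported")
    key = int(_align_key(_as_bytes(a), _as_bytes(b)))
    alen = 4095 - (key & 0xFFF)
    matches = (key >> 12) & 0xFFF
    score = (key >> 24) - 8192
    return score, matches, alen


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching columns in the optimal global alignment of a and b."""
    if a == b:
        if not a:
            raise ValueError("empty sequence")
        return 1.0
    _, matches, alen = align_stats(a, b)
    return matches / alen


@dataclass
class DistanceMatrix:
    """Condensed pairwise distances (1 - identity) among n sequence types."""

    n: int
    d: np.ndarray  # condensed, length n*(n-1)//2, values in [0, 1]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (self.n * (self.n - 1) // 2,):
            raise ValueError("condensed length inconsistent with n")
        if self.d.size and ((self.d < 0) | (self.d > 1)).any():
            raise ValueError("distances must lie in [0, 1]")

    def square(self) -> np.ndarray:
        return squareform(self.d) if self.n > 1 else np.zeros((self.n, self.n))


def compute_distances(table: SequenceTypeTable) -> DistanceMatrix:
    """All-pairs alignment distances d_ij = 1 - identity for a table's types."""
    n = table.n_types
    if n < 1:
        raise ValueError("need at least one sequence type")
    seqs = [_as_bytes(s) for s in table.sequences]
    d = np.empty(n * (n - 1) // 2, dtype=float)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            key = int(_align_key(seqs[i], seqs[j]))
            alen = 4095 - (key & 0xFFF)
            matches = (key >> 12) & 0xFFF
            d[idx] = 1.0 - matches / alen
            idx += 1
    return DistanceMatrix(n, d)


def write_distances(dm: DistanceMatrix, path: str | Path) -> None:
    """Cache a condensed distance matrix as TSV with an ``n`` header line."""
    with open(path, "w") as fh:
        fh.write(f"n\t{dm.n}\n")
        for v in dm.d:
            fh.write(f"{float(v):.17g}\n")


def read_distances(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        header = fh.readline().split("\t")
        if len(header) != 2 or header[0] != "n":
            raise ValueError(f"{path}:1: malformed distance header")
        n = int(header[1])
        d = np.array([float(line) for line in fh if line.strip()], dtype=float)
    return DistanceMatrix(n, d)


@dataclass
class Partition:
    """Assignment of sequence types to OTUs at one similarity threshold.

    OTU ids are ordered by decreasing OTU total abundance (ties by the
    smallest member row index, which the table's canonical row order makes
    lexicographic).  The representative of an OTU is its most abundant member,
    ties broken by the lexicographically smallest sequence.
    """

    threshold_pct: int
    assignment: np.ndarray  # (S,) OTU id in 0..k-1
    k: int
    representatives: np.ndarray  # (k,) row index of representative type

    def members(self, otu_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == otu_id)


def _relabel(raw: np.ndarray, table: SequenceTypeTable, threshold_pct: int) -> Partition:
    totals = table.totals()
    ids = np.unique(raw)
    otus = []
    for cid in ids:
        members = np.flatnonzero(raw == cid)
        otus.append((-int(totals[members].sum()), int(members.min()), members))
    otus.sort(key=lambda t: (t[0], t[1]))
    assignment = np.empty(raw.size, dtype=np.int64)
    reps = np.empty(len(otus), dtype=np.int64)
    for new_id, (_, _, members) in enumerate(otus):
        assignment[members] = new_id
        best = min(members, key=lambda s: (-int(totals[s]), table.sequences[s]))
        reps[new_id] = best
    return Partition(threshold_pct, assignment, len(otus), reps)


def _linkage_tree(dm: DistanceMatrix) -> np.ndarray | None:
    return linkage(dm.d, method="average") if dm.n > 1 else None


def _cut(tree: np.ndarray | None, n: int, similarity_pct: int) -> np.ndarray:
    if not 0 < similarity_pct <= 100:
        raise ValueError("similarity_pct must be in (0, 100]")
    if tree is None:
        return np.zeros(n, dtype=np.int64)
    cut = (100 - similarity_pct) / 100
    return fcluster(tree, t=cut, criterion="distance")


def cluster_at(
    dm: DistanceMatrix, similarity_pct: int, table: SequenceTypeTable
) -> Partition:
    """Average-linkage OTUs at one similarity level (inclusive distance cut)."""
    raw = _cut(_linkage_tree(dm), dm.n, similarity_pct)
    return _relabel(raw, table, similarity_pct)


DEFAULT_GRID: tuple[int, ...] = tuple(range(74, 100))


@dataclass
class ClusterScan:
    """Nested partitions over a strictly increasing similarity grid."""

    partitions: list[Partition]

    def __post_init__(self) -> None:
        ts = [p.threshold_pct for p in self.partitions]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly increasing")

    def __iter__(self):
        return iter(self.partitions)

    def __len__(self) -> int:
        return len(self.partitions)


def scan(
    dm: DistanceMatrix,
    table: SequenceTypeTable,
    grid: Sequence[int] = DEFAULT_GRID,
) -> ClusterScan:
    """Cut one average-linkage tree at every grid threshold (nesting guaranteed)."""
    if not len(grid):
        raise ValueError("grid must be non-empty")
    tree = _linkage_tree(dm)
    parts = [_relabel(_cut(tree, dm.n, s), table, s) for s in grid]
    return ClusterScan(parts)


def write_partition(partition: Partition, path: str | Path, append: bool = False) -> None:
    """Export TSV with columns sequence_index, otu_id, threshold_pct."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            fh.write("sequence_index\totu_id\tthreshold_pct\n")
        for s, otu in enumerate(partition.assignment):
            fh.write(f"{s}\t{int(otu)}\t{partition.threshold_pct}\n")
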