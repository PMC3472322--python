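"""De novo assembly of equal-length reads into locus clusters (stacks).

Follows the ustacks-style two-stage procedure: reads are first grouped into
exactly-matching stacks (stacks below a minimum depth are discarded as
error-like), then stacks whose consensus sequences lie within a small Hamming
distance are merged iteratively until a fixed point. An optional filter
excludes clusters whose depth exceeds the mean by a chosen number of standard
deviations, the classical heuristic for removing repeat-derived clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_qc import BASES, ReadRecord

_BYTE2COL = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BYTE2COL[ord(_b)] = _i


class ClusterError(ValueError):
    pass


@dataclass
class ReadCluster:
    """One de novo locus: per-position base counts over its member reads."""

    cluster_id: int
    member_read_ids: list[str]
    counts: np.ndarray          # (length, 4) int counts for A, C, G, T
    consensus: str
    depth: int

    @property
    def length(self) -> int:
        return self.counts.shape[0]


def _consensus(counts: np.ndarray) -> str:
    # argmax returns the first maximal column; column order A<C<G<T is the tie-break
    return "".join(BASES[i] for i in counts.argmax(axis=1))


def build_stacks(reads: list[ReadRecord], min_depth: int = 2) -> list[ReadCluster]:
    """Group reads into exactly-matching stacks; drop stacks below ``min_depth``.

    All reads must share one length (trim first otherwise). Cluster IDs are
    assigned in lexicographic order of the stack sequence, so the output is
    deterministic regardless of read order.
    """
    groups: dict[str, list[str]] = {}
    length = None
    for r in reads:
        if length is None:
            length = len(r.sequence)
        elif len(r.sequence) != length:
            raise ClusterError(
                "mixed read lengths; trim reads to a common length before clustering"
            )
        groups.setdefault(r.sequence, []).append(r.id)

    clusters: list[ReadCluster] = []
    cid = 0
    for seq in sorted(groups):
        ids = groups[seq]
        if len(ids) < min_depth:
            continue
        cols = _BYTE2COL[np.frombuffer(seq.encode(), dtype=np.uint8)]
        counts = np.zeros((len(seq), 4), dtype=np.int64)
        valid = cols >= 0  # non-ACGT bases contribute depth but no counts
        counts[np.flatnonzero(valid), cols[valid]] = len(ids)
        clusters.append(ReadCluster(cid, list(ids), counts, _consensus(counts), len(ids)))
        cid += 1
    return clusters


def _hamming_components(seqs: list[str], max_distance: int) -> list[list[int]]:
    """Connected components of the <=max_distance Hamming graph over ``seqs``."""
    n = len(seqs)
    if n == 0:
        return []
    L = len(seqs[0])
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, L)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    block = max(1, int(4e7 // max(1, n * L)))
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        dist = (mat[lo:hi, None, :] != mat[None, :, :]).sum(axis=2)
        ii, jj = np.nonzero(dist <= max_distance)
        for i, j in zip(ii + lo, jj):
            if i < j:
                ri, rj = find(int(i)), find(int(j))
                if ri != rj:
                    parent[rj] = ri
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def merge_stacks(stacks: list[ReadCluster], max_distance: int = 2) -> list[ReadCluster]:
    """Merge stacks whose consensuses are within ``max_distance`` mismatches.

    Merging is by connected components over consensus Hamming distance,
    repeated until no further merges occur (the merged consensus can move
    closer to another cluster). Counts are element-wise sums; the consensus is
    recomputed with ties broken A<C<G<T; output is sorted by consensus.
    """
    current = stacks
    while True:
        if len(current) <= 1:
            break
        lengths = {c.length for c in current}
        if len(lengths) != 1:
            raise ClusterError("stacks of differing lengths cannot be merged")
        comps = _hamming_components([c.consensus for c in current], max_distance)
        if all(len(c) == 1 for c in comps):
            break
        merged: list[ReadCluster] = []
        for comp in comps:
            members = [current[i] for i in comp]
            counts = sum(c.counts for c in members)
            ids = [rid for c in members for rid in c.member_read_ids]
            merged.append(ReadCluster(0, ids, counts, _consensus(counts),
                                      sum(c.depth for c in members)))
        current = merged
    out = sorted(current, key=lambda c: c.consensus)
    return [ReadCluster(i, c.member_read_ids, c.counts, c.consensus, c.depth)
            for i, c in enumerate(out)]


def depth_sd_filter(clusters: list[ReadCluster], n_sd: float = 2.0
                    ) -> tuple[list[ReadCluster], list[ReadCluster]]:
    """Exclude clusters deeper than mean + n_sd * SD of all cluster depths.

    The mean and (population) SD are computed once on the full input; returns
    (kept, excluded).
    """
    if len(clusters) < 2:
        raise ClusterError("depth_sd_filter needs at least 2 clusters")
    depths = np.array([c.depth for c in clusters], dtype=float)
    threshold = depths.mean() + n_sd * depths.std(ddof=0)
    kept = [c for c in clusters if not c.depth > threshold]
    excluded = [c for c in clusters if c.depth > threshold]
    return kept, excluded
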