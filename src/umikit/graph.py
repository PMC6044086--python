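"""Directional UMI graph for error correction.

Within one read group, observed UMIs become nodes holding their read
counts.  For each pair of UMIs at Hamming distance 1, a directed edge
a→b is added when ``n_a >= 2*n_b - 1``: b's reads are then consistent with
b being a PCR/sequencing error derived from a (the twofold bound is the
worst case of an error in the first PCR cycle; the ``- 1`` lets singleton
pairs 1-vs-1 connect, where the error most likely arose at sequencing).
Clusters are claimed from the most abundant unvisited node outward, so a
chain a→b→c collapses onto a when the intermediate UMI is observed.

Distance is Hamming (substitution-only): UMIs are fixed-length by
construction, and reads with indels in the UMI region were already
discarded by locator validation at extraction.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np


def _as_count_dict(counts: Iterable) -> dict[str, int]:
    if isinstance(counts, Mapping):
        items = counts.items()
    else:
        items = list(counts)
    out: dict[str, int] = {}
    for umi, n in items:
        if n < 1:
            raise ValueError(f"UMI {umi!r} has non-positive count {n}")
        if umi in out:
            raise ValueError(f"duplicate UMI {umi!r}")
        out[umi] = int(n)
    if out:
        lengths = {len(u) for u in out}
        if len(lengths) != 1:
            raise ValueError(f"mixed UMI lengths {sorted(lengths)}")
    return out


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("UMIs of unequal length")
    return sum(1 for x, y in zip(a, b) if x != y)


def _directional_edges(counts: dict[str, int]) -> list[tuple[str, str]]:
    """All edges (a, b) with Hamming(a,b) == 1 and n_a >= 2*n_b - 1.

    Pairwise Hamming distances are computed on a byte matrix; for the
    group sizes seen in practice (tens to a few hundred UMIs) this is a
    single vectorised pass.
    """
    umis = list(counts)
    k = len(umis)
    if k < 2:
        return []
    mat = np.frombuffer("".join(umis).encode(), dtype=np.uint8).reshape(k, -1)
    # pairwise Hamming distance, k x k
    dist = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    n = np.array([counts[u] for u in umis], dtype=np.int64)
    ii, jj = np.nonzero((dist == 1) & (n[:, None] >= 2 * n[None, :] - 1))
    return [(umis[i], umis[j]) for i, j in zip(ii.tolist(), jj.tolist())]


def build_umi_graph(counts: Iterable) -> nx.DiGraph:
    """Build the directional graph over a read group's UMI counts.

    ``counts`` is a mapping or iterable of (umi, read_count).  Node
    attribute ``count`` holds the read count.
    """
    cdict = _as_count_dict(counts)
    g = nx.DiGraph()
    for umi, n in cdict.items():
        g.add_node(umi, count=n)
    g.add_edges_from(_directional_edges(cdict))
    return g


@dataclass(frozen=True)
class UmiCluster:
    """One inferred molecule: a representative UMI and its error cloud."""

    representative: str
    members: frozenset[str]
    total_count: int


def _visit_order(counts: dict[str, int]) -> list[str]:
    return sorted(counts, key=lambda u: (-counts[u], u))


def _claim_clusters(
    counts: dict[str, int], successors: Mapping[str, list[str]]
) -> list[UmiCluster]:
    """Breadth-first single-claim traversal shared by both graph backends.

    Nodes are visited most-abundant first (ties lexicographic); each
    unvisited node seeds a cluster and claims everything reachable from it
    through unvisited nodes.
    """
    visited: set[str] = set()
    clusters: list[UmiCluster] = []
    for seed in _visit_order(counts):
        if seed in visited:
            continue
        members = {seed}
        visited.add(seed)
        queue = deque([seed])
        while queue:
            node = queue.popleft()
            for nxt in sorted(successors.get(node, ()), key=lambda u: (-counts[u], u)):
                if nxt not in visited:
                    visited.add(nxt)
                    members.add(nxt)
                    queue.append(nxt)
        clusters.append(
            UmiCluster(seed, frozenset(members), sum(counts[u] for u in members))
        )
    return clusters


def resolve_clusters(graph: nx.DiGraph) -> list[UmiCluster]:
    """Partition a directional UMI graph into clusters.

    Each cluster's representative is its seed — the most abundant UMI not
    yet claimed by an earlier cluster.
    """
    counts = {u: graph.nodes[u]["count"] for u in graph.nodes}
    succ = {u: list(graph.successors(u)) for u in graph.nodes}
    return _claim_clusters(counts, succ)


def cluster_umis(counts: Iterable) -> list[UmiCluster]:
    """Cluster a read group's UMI counts directly (no networkx container)."""
    cdict = _as_count_dict(counts)
    succ: dict[str, list[str]] = {}
    for a, b in _directional_edges(cdict):
        succ.setdefault(a, []).append(b)
    return _claim_clusters(cdict, succ)


def count_unique(counts: Iterable, correct_errors: bool = False) -> int:
    """Number of distinct molecules inferred from a group's UMI counts.

    Without correction this is simply the number of distinct UMI strings;
    with correction it is the number of directional-graph clusters.
    """
    cdict = _as_count_dict(counts)
    if not cdict:
        return 0
    if not correct_errors:
        return len(cdict)
    return len(cluster_umis(cdict))


def umi_counter(umis: Iterable[str]) -> Counter:
    """Convenience: tally observed UMI strings into a count mapping."""
    return Counter(umis)
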