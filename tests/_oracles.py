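"""Independent brute-force reference implementations used across test modules."""


def brute_clusters(counts: dict[str, int]) -> list[tuple[str, frozenset]]:
    """Directional UMI clustering straight from the definition.

    Enumerates the edge relation (Hamming distance 1 and n_a >= 2*n_b - 1)
    pair by pair and replays the most-abundant-first single-claim
    traversal.  Deliberately naive: O(n^2) string comparisons, no shared
    code with the package.
    """
    umis = list(counts)
    edges = {
        (a, b)
        for a in umis
        for b in umis
        if a != b
        and sum(x != y for x, y in zip(a, b)) == 1
        and counts[a] >= 2 * counts[b] - 1
    }
    visited: set[str] = set()
    out = []
    for seed in sorted(counts, key=lambda u: (-counts[u], u)):
        if seed in visited:
            continue
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        while frontier:
            nxt = []
            for a in frontier:
                for b in sorted(counts, key=lambda u: (-counts[u], u)):
                    if (a, b) in edges and b not in visited:
                        visited.add(b)
                        members.add(b)
                        nxt.append(b)
            frontier = nxt
        out.append((seed, frozenset(members)))
    return out
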