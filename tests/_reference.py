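"""Independent brute-force reference implementations used as test oracles.

Plain-Python re-derivations of the trajectory distance and the greedy
focal-SNV clustering, written from the rule statements (no numpy
vectorisation, no code shared with the package), for cross-checking the
production implementations on small instances.
"""

import math


def ref_distance(fi, fj, di, dj, min_depth=10, min_overlap=3):
    """Polarised trajectory distance, scalar loops only."""

    def one_orientation(fb_seq):
        terms = []
        for a, b, p, q in zip(fi, fb_seq, di, dj):
            if p < min_depth or q < min_depth:
                continue
            if math.isnan(a) or math.isnan(b):
                continue
            num = 2.0 * (p + q) * (a - b) ** 2
            den = (a + b) * ((1.0 - a) + (1.0 - b))
            terms.append(0.0 if den <= 0 else num / den)
        return terms

    straight = one_orientation(list(fj))
    flipped = one_orientation([1.0 - b for b in fj])
    if len(straight) < min_overlap:
        return float("nan")
    return min(
        sum(straight) / len(straight), sum(flipped) / len(flipped)
    )


def ref_adjacency(freqs, depths, d_max=3.5, min_depth=10, min_overlap=3):
    """Boolean adjacency dict-of-sets over site indices."""
    n = len(freqs)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            d = ref_distance(
                freqs[i], freqs[j], depths[i], depths[j], min_depth, min_overlap
            )
            if not math.isnan(d) and d < d_max:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def ref_greedy_clusters(adj, min_cluster, intra_connect=0.25):
    """Greedy focal extraction with the same tie-break and prune rules:

    focal = max-degree active node (ties to the lowest index); members are
    the focal plus its active neighbours; members are visited once in
    ascending index order and dropped when connected to fewer than
    ``intra_connect`` of the other current members (focal exempt); the
    cluster is emitted if it still has ``min_cluster`` members, and the
    process stops the first time it does not.
    """
    active = set(adj)
    clusters = []
    while active:
        deg = {i: len(adj[i] & active) for i in active}
        focal = min(active, key=lambda i: (-deg[i], i))
        members = {focal} | (adj[focal] & active)
        for i in sorted(members - {focal}):
            others = members - {i}
            conn = len(adj[i] & others)
            if conn < intra_connect * len(others):
                members.discard(i)
        if len(members) < min_cluster:
            break
        clusters.append(sorted(members))
        active -= members
    return clusters
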