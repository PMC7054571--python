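"""Independent brute-force oracles used to cross-check the mesh operators.

Deliberately naive (pure-Python BFS over neighbour lists, literal
definitions) and kept independent of the implementation code paths they
verify.
"""

from collections import deque

import numpy as np


def edge_set_from_faces(faces) -> set[tuple[int, int]]:
    edges = set()
    for a, b, c in np.asarray(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            edges.add((min(u, v), max(u, v)))
    return edges


def neighbour_lists(n: int, faces) -> list[set[int]]:
    adj = [set() for _ in range(n)]
    for u, v in edge_set_from_faces(faces):
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bfs_distances(adj: list[set[int]], sources) -> dict[int, int]:
    dist = {int(s): 0 for s in sources}
    queue = deque(dist)
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def components_oracle(members, adj) -> list[list[int]]:
    member_set = set(int(v) for v in members)
    seen: set[int] = set()
    comps = []
    for start in sorted(member_set):
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                if w in member_set and w not in comp:
                    comp.add(w)
                    queue.append(w)
        seen |= comp
        comps.append(sorted(comp))
    return comps


def opening_oracle(members, adj, depth: int) -> list[int]:
    """Literal erosion (hop distance to complement ≤ depth) then dilation
    (hop distance from core ≤ depth) intersected with the original set."""
    n = len(adj)
    member_set = set(int(v) for v in members)
    complement = [v for v in range(n) if v not in member_set]
    if not complement:
        return sorted(member_set)
    dist = bfs_distances(adj, complement)
    core = [v for v in member_set if dist.get(v, n + 1) > depth]
    if not core:
        return []
    dist_core = bfs_distances(adj, core)
    return sorted(
        v for v in member_set if dist_core.get(v, n + 1) <= depth
    )


def region_grow_oracle(seeds, allowed, adj) -> list[int]:
    """Components of *allowed* that intersect *seeds*."""
    seed_set = set(int(v) for v in seeds)
    out: set[int] = set()
    for comp in components_oracle(allowed, adj):
        if seed_set & set(comp):
            out |= set(comp)
    return sorted(out)


def dice(a, b) -> float:
    a, b = set(map(int, a)), set(map(int, b))
    if not a and not b:
        return 1.0
    return 2 * len(a & b) / (len(a) + len(b))
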