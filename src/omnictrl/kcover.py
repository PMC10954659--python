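"""Shortest-superstring k-mer covers with forbidden motifs.

A sequence containing every allowed k-mer at least once is an Eulerian walk
on the de Bruijn multigraph whose nodes are (k-1)-mers and whose edges are
the allowed k-mers.  With no exclusions the graph is Eulerian and the unique
optimum has length 4^k + k - 1.  Excluding motifs (restriction enzyme sites)
unbalances a handful of nodes; the walk is then completed with virtual
balancing edges, and the circuit is split at those edges into the minimum
number of path segments, which are finally re-joined end-to-end wherever the
junction does not create a forbidden k-mer.
"""

from __future__ import annotations

import numpy as np

from .dna import all_kmers
from .enzymes import Enzyme, forbidden_motifs


def build_kmer_universe(k: int, enzymes: list[Enzyme] | tuple[Enzyme, ...] = ()) -> set[str]:
    """All 4^k k-mers minus the recognition sites (and reverse complements)
    of every enzyme.

    Only sites of length exactly ``k`` can be excluded from the cover; an
    enzyme with a different site length is rejected (longer sites must be
    screened post hoc instead).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    for e in enzymes:
        if len(e.site) != k:
            raise ValueError(
                f"enzyme {e.name} has a {len(e.site)} bp site; only sites of "
                f"length k={k} can be excluded from the k-mer cover"
            )
    return set(all_kmers(k)) - forbidden_motifs(enzymes)


def _euler_segments(allowed: set[str], rng: np.random.Generator) -> list[str]:
    """Minimum set of walks covering every allowed k-mer exactly once."""
    k = len(next(iter(allowed)))
    adj: dict[str, list[tuple[str, bool]]] = {}
    indeg: dict[str, int] = {}
    nodes: set[str] = set()
    for m in sorted(allowed):
        u, v = m[:-1], m[1:]
        adj.setdefault(u, []).append((v, False))
        indeg[v] = indeg.get(v, 0) + 1
        nodes.update((u, v))

    # weakly connected components
    comp: dict[str, int] = {}
    cid = 0
    undirected: dict[str, set[str]] = {n: set() for n in nodes}
    for u, lst in adj.items():
        for v, _ in lst:
            undirected[u].add(v)
            undirected[v].add(u)
    for n in sorted(nodes):
        if n in comp:
            continue
        stack = [n]
        comp[n] = cid
        while stack:
            x = stack.pop()
            for y in undirected[x]:
                if y not in comp:
                    comp[y] = cid
                    stack.append(y)
        cid += 1

    # balance each component with virtual edges (deficit-out -> surplus-out)
    starts_by_comp: dict[int, str] = {}
    for c in range(cid):
        members = sorted(n for n in nodes if comp[n] == c)
        neg, pos = [], []
        for n in members:
            d = len(adj.get(n, [])) - indeg.get(n, 0)
            if d > 0:
                pos.extend([n] * d)
            elif d < 0:
                neg.extend([n] * (-d))
        for u, v in zip(neg, pos):
            adj.setdefault(u, []).append((v, True))
        starts_by_comp[c] = pos[0] if pos else members[0]

    for lst in adj.values():
        rng.shuffle(lst)

    segments: list[str] = []
    ptr = {n: 0 for n in adj}
    for c in range(cid):
        start = starts_by_comp[c]
        # Hierholzer, iterative
        stack: list[tuple[str, bool]] = [(start, False)]
        circuit: list[tuple[str, bool]] = []  # (node, arrived_via_virtual)
        while stack:
            node, via = stack[-1]
            lst = adj.get(node, [])
            if ptr.get(node, 0) < len(lst):
                nxt, virtual = lst[ptr[node]]
                ptr[node] += 1
                stack.append((nxt, virtual))
            else:
                circuit.append(stack.pop())
        circuit.reverse()
        # split the circuit at virtual edges into real-edge path segments
        pieces: list[list[str]] = []
        cur = [circuit[0][0]]
        for node, via in circuit[1:]:
            if via:
                pieces.append(cur)
                cur = [node]
            else:
                cur.append(node)
        pieces.append(cur)
        if len(pieces) > 1:
            # the circuit wraps: its last node equals its first, so the final
            # and initial pieces are one contiguous real walk
            last = pieces.pop()
            pieces[0] = last + pieces[0][1:]
        for piece in pieces:
            if len(piece) > 1:
                segments.append(piece[0] + "".join(p[-1] for p in piece[1:]))
    return segments


def _junction_ok(a: str, b: str, allowed: set[str], k: int) -> bool:
    junction = a[-(k - 1):] + b[: k - 1]
    return all(
        junction[j : j + k] in allowed for j in range(len(junction) - k + 1)
    )


def _join_segments(segments: list[str], allowed: set[str], k: int) -> list[str]:
    """Concatenate segments wherever every junction-spanning k-mer is allowed
    (duplicated occurrences are fine; total length is unchanged).

    For small segment counts (<= 6) all orderings are searched so a single
    walk is found whenever one exists by plain concatenation; larger sets fall
    back to a greedy pass.
    """
    if len(segments) <= 1:
        return list(segments)
    if len(segments) <= 6:
        from itertools import permutations

        best = None
        for perm in permutations(range(len(segments))):
            out: list[str] = []
            cur = segments[perm[0]]
            for i in perm[1:]:
                if _junction_ok(cur, segments[i], allowed, k):
                    cur += segments[i]
                else:
                    out.append(cur)
                    cur = segments[i]
            out.append(cur)
            if best is None or len(out) < len(best):
                best = out
            if len(best) == 1:
                break
        return best
    remaining = list(segments)
    out = []
    while remaining:
        cur = remaining.pop(0)
        progress = True
        while progress:
            progress = False
            for i, seg in enumerate(remaining):
                if _junction_ok(cur, seg, allowed, k):
                    cur += remaining.pop(i)
                    progress = True
                    break
        out.append(cur)
    return out


def generate_kmer_cover(allowed: set[str], seed: int = 0) -> str | list[str]:
    """Near-shortest DNA containing every allowed k-mer as a substring and no
    other (forbidden) k-mer.

    Returns a single string when the cover can be expressed as (or joined
    into) one walk, else a list of strings.  Total length is at most
    ``len(allowed) + (k-1) * n_segments``; for the full alphabet it is exactly
    ``4**k + k - 1``.  Edge tie-breaking is seeded and reproducible.
    """
    if not allowed:
        raise ValueError("allowed k-mer set is empty")
    lens = {len(m) for m in allowed}
    if len(lens) != 1:
        raise ValueError("allowed k-mers have mixed lengths")
    k = lens.pop()
    if k == 1:
        return "".join(sorted(allowed))
    rng = np.random.default_rng(seed)
    segments = _euler_segments(set(allowed), rng)
    segments = _join_segments(segments, set(allowed), k)
    return segments[0] if len(segments) == 1 else segments
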