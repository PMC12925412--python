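"""Independent oracles used by the test suite.

Everything here is deliberately written brute-force / first-principles and
does not call into the package's own implementations, so that package
results can be checked against an independent computation path.
"""

from __future__ import annotations

import itertools

import numpy as np


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def mst_length(seqs: list[str]) -> int:
    """Prim's algorithm on Hamming distances, O(n^2)."""
    n = len(seqs)
    if n <= 1:
        return 0
    in_tree = [0]
    total = 0
    dist = [hamming(seqs[0], s) for s in seqs]
    used = [False] * n
    used[0] = True
    for _ in range(n - 1):
        best = None
        for i in range(n):
            if not used[i] and (best is None or dist[i] < dist[best]):
                best = i
        total += dist[best]
        used[best] = True
        for i in range(n):
            if not used[i]:
                d = hamming(seqs[best], seqs[i])
                if d < dist[i]:
                    dist[i] = d
    return total


def steiner_minimal_length(seqs: list[str], max_extra: int | None = None) -> int:
    """Exhaustive Steiner-minimal network length over sequence space.

    Candidate Steiner points are every sequence in the product of observed
    per-column states (sufficient for Hamming Steiner trees); subsets of up
    to ``len(seqs) - 2`` extra points are enumerated exhaustively.  Only
    usable for tiny instances.
    """
    seqs = list(seqs)
    cols = [sorted({s[i] for s in seqs}) for i in range(len(seqs[0]))]
    candidates = sorted({"".join(p) for p in itertools.product(*cols)} - set(seqs))
    if max_extra is None:
        max_extra = max(len(seqs) - 2, 0)
    best = mst_length(seqs)
    for k in range(1, max_extra + 1):
        for extra in itertools.combinations(candidates, k):
            best = min(best, mst_length(seqs + list(extra)))
    return best


def p_distance(s1: str, s2: str) -> float:
    """Proportion of differing sites among unambiguous A/C/G/T pairs."""
    n = d = 0
    for a, b in zip(s1, s2):
        if a in "ACGT" and b in "ACGT":
            n += 1
            d += a != b
    return d / n


def floyd_warshall(nodes: list[str], edges: list[tuple[str, str, int]]) -> dict:
    """All-pairs shortest paths, brute force."""
    inf = float("inf")
    d = {(a, b): (0 if a == b else inf) for a in nodes for b in nodes}
    for a, b, w in edges:
        d[(a, b)] = min(d[(a, b)], w)
        d[(b, a)] = min(d[(b, a)], w)
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if d[(i, k)] + d[(k, j)] < d[(i, j)]:
                    d[(i, j)] = d[(i, k)] + d[(k, j)]
    return d


def ols_estimates(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Ordinary least squares via normal equations (lstsq)."""
    return np.linalg.lstsq(X, y, rcond=None)[0]


#: Toy median-joining instances whose Steiner-minimal length the network
#: must reach (each <= 6 haplotypes x <= 8 sites, small candidate spaces).
MJ_TOY_INSTANCES = [
    ["000", "100", "110"],  # chain, no medians needed
    ["100", "010", "001"],  # star around absent 000
    ["0000", "1100", "1010"],  # one inferred median 1000
    ["00", "01", "10", "11"],  # cycle, no improvement possible
    ["CAA", "AGA", "AAT", "CGA"],  # DNA alphabet, median AAA/CAA region
    # two absent star centres (00000 and 00011) joined by a 2-step bridge
    ["10000", "01000", "00100", "10011", "01011", "00111"],
]
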