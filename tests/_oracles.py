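"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own algorithms: the mapper is checked
against an exhaustive Hamming scan, the clusterer against a naive O(n^3)
agglomeration, the hypergeometric tail against complete enumeration over
draws, and the codon-generation logic against a 64-codon sweep.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

RNA = "ACGU"


def hamming_scan(targets: dict[str, str], tag: str) -> list[tuple[str, int, int, int]]:
    """All (target, 1-based start, n_mismatches, mismatch_offset|-1) with <=1 mm.

    Exhaustive position-by-position scan, vectorised per target.
    """
    L = len(tag)
    tag_arr = np.frombuffer(tag.encode(), dtype=np.uint8)
    hits = []
    for tid in sorted(targets):
        seq = targets[tid]
        if len(seq) < L:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        mism = (windows != tag_arr)
        counts = mism.sum(axis=1)
        for p in np.nonzero(counts <= 1)[0]:
            if counts[p] == 0:
                hits.append((tid, int(p) + 1, 0, -1))
            else:
                hits.append((tid, int(p) + 1, 1, int(np.argmax(mism[p]))))
    return hits


def classify_tags_bruteforce(
    targets: dict[str, str], tags: list[str]
) -> dict[str, dict]:
    """Partition tags into perfect / unique-1mm / ambiguous / unmapped."""
    out = {}
    for tag in tags:
        hits = hamming_scan(targets, tag)
        perfect = [h for h in hits if h[2] == 0]
        near = [h for h in hits if h[2] == 1]
        if perfect:
            out[tag] = {"kind": "perfect", "hits": sorted(perfect)}
        elif len(near) == 1:
            tid, start, _, off = near[0]
            pos = start + off
            out[tag] = {
                "kind": "mismatch",
                "target": tid,
                "position": pos,
                "ref": targets[tid][pos - 1],
                "read": tag[off],
            }
        elif len(near) > 1:
            out[tag] = {"kind": "ambiguous"}
        else:
            out[tag] = {"kind": "unmapped"}
    return out


def naive_average_linkage(dist: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) agglomeration: merge the closest pair under average linkage.

    Cluster-to-cluster distance is the mean of all original pairwise
    distances (UPGMA). Returns the merge sequence as (set_a, set_b, height).
    """
    n = dist.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = float(
                    np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] by complete enumeration over all C(N, n) draws."""
    population = [1] * K + [0] * (N - K)
    favourable = sum(
        1 for draw in itertools.combinations(population, n) if sum(draw) >= k
    )
    return favourable / comb(N, n)


def feasible_sources_bruteforce(target_codon: str, pattern: str) -> set[str]:
    """Source codons convertible into target by one from->to substitution."""
    src, dst = pattern.split("-to-")
    sources = set()
    for codon in ("".join(c) for c in itertools.product(RNA, repeat=3)):
        for i in range(3):
            if codon[i] == src:
                edited = codon[:i] + dst + codon[i + 1 :]
                if edited == target_codon:
                    sources.add(codon)
    return sources
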