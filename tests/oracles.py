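"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the implementation's code paths: digestion is
re-derived by fragment enumeration, uniqueness by a per-peptide ``in``
scan, and complete linkage by recomputing max inter-member distances
from the original matrix at every step.
"""

from __future__ import annotations

import itertools

import numpy as np


def tryptic_sites(seq: str, cleave_before_proline: bool = False) -> list[int]:
    return [
        i
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and (cleave_before_proline or seq[i + 1] != "P")
    ]


def brute_force_digest(
    seq: str,
    max_mc: int,
    min_len: int = 1,
    max_len: int = 10**9,
    cleave_before_proline: bool = False,
) -> set[tuple[int, int, int]]:
    """All (start0, end0-exclusive, missed_cleavages) tryptic fragments.

    Enumerates every substring and keeps those whose boundaries are valid
    cleavage boundaries and whose internal site count is within limits.
    """
    sites = set(tryptic_sites(seq, cleave_before_proline))
    n = len(seq)
    out = set()
    for i in range(n):
        if not (i == 0 or (i - 1) in sites):
            continue
        for j in range(i + 1, n + 1):
            if not (j == n or (j - 1) in sites):
                continue
            mc = sum(1 for s in sites if i <= s < j - 1)
            if mc <= max_mc and min_len <= j - i <= max_len:
                out.add((i, j, mc))
    return out


def naive_parents(peptide: str, proteome: dict[str, str]) -> tuple[str, ...]:
    """O(proteins x length) substring scan."""
    return tuple(sorted(acc for acc, seq in proteome.items() if peptide in seq))


def brute_force_complete_linkage(
    scaled: np.ndarray,
) -> list[tuple[int, int, float]]:
    """Complete linkage recomputing max pairwise distance from scratch.

    Cluster ids follow the same scheme as the implementation (leaves
    0..n-1, merge i creates id n+i; ties -> smallest (a, b) id pair).
    """
    n = scaled.shape[0]
    dist = np.sqrt(
        ((scaled[:, None, :] - scaled[None, :, :]) ** 2).sum(axis=2)
    )
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or (d, a, b) < best:
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b, float(d)))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges
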