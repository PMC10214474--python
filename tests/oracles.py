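"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the implementation's algorithms: folding by
exhaustive structure enumeration, motif scans by explicit backtracking,
hypergeometric p by combinatorial enumeration.
"""
from __future__ import annotations

from itertools import combinations

_PAIR_SCORES = {frozenset("GC"): 3.0, frozenset("AU"): 2.0, frozenset("GU"): 1.0}
_STOPS = {"TAA", "TAG", "TGA"}


def brute_fold_energy(seq: str, min_loop: int = 3) -> float:
    """Max pair-score over all nested structures by explicit enumeration."""
    s = seq.upper().replace("T", "U")

    def best(i: int, j: int) -> float:
        # best score for s[i..j] inclusive; no memoization on purpose
        if j - i < min_loop + 1:
            return 0.0
        top = best(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            sc = _PAIR_SCORES.get(frozenset((s[i], s[k])))
            if sc is None or s[i] == s[k]:
                continue
            top = max(top, sc + best(i + 1, k - 1) + best(k + 1, j))
        return top

    return -best(0, len(s) - 1) if s else 0.0


def brute_uorfs(utr: str, min_codons: int = 2):
    """All uORFs by scanning every position and frame explicitly."""
    s = utr.upper().replace("U", "T")
    found = []
    for p in range(len(s) - 2):
        if s[p] == "A" and s[p + 1] == "T" and s[p + 2] == "G":
            stop_at = None
            q = p + 3
            while q + 3 <= len(s):
                if s[q:q + 3] in _STOPS:
                    stop_at = q
                    break
                q += 3
            if stop_at is not None:
                if (stop_at - p) // 3 >= min_codons:  # codons before the stop
                    found.append((p, stop_at + 3, False))
            else:
                if (len(s) - p) // 3 >= min_codons:
                    found.append((p, len(s), True))
    return found


def brute_pg4(seq: str, g_run: int = 3, loop_max: int = 7):
    """Greedy-backtracking PG4 matcher mirroring regex semantics.

    Quantifiers are tried longest-first with backtracking; scanning is
    leftmost, non-overlapping.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)

    def run_ends(start: int):
        j = start
        while j < n and s[j] == "G":
            j += 1
        return [start + L for L in range(j - start, g_run - 1, -1)]

    def rec(pos: int, repeats: int):
        if repeats == 0:
            return pos
        for loop in range(loop_max, 0, -1):
            nxt = pos + loop
            if nxt >= n:
                continue
            for end in run_ends(nxt):
                got = rec(end, repeats - 1)
                if got is not None:
                    return got
        return None

    matches = []
    i = 0
    while i < n:
        hit = None
        for end in run_ends(i):
            got = rec(end, 3)
            if got is not None:
                hit = got
                break
        if hit is not None:
            matches.append((i, hit, s[i:hit]))
            i = hit
        else:
            i += 1
    return matches


def brute_hypergeom_p(universe_size: int, set_size: int, query_size: int,
                      observed_overlap: int) -> float:
    """P(overlap >= observed) by enumerating every possible query draw."""
    universe = list(range(universe_size))
    inset = set(range(set_size))
    total = hits = 0
    for query in combinations(universe, query_size):
        total += 1
        if len(inset.intersection(query)) >= observed_overlap:
            hits += 1
    return hits / total
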