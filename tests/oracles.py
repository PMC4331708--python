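"""Independent brute-force oracles used by the tests.

These deliberately re-derive quantities by exhaustive enumeration or naive
scanning, sharing no code with the implementation paths they check.
"""

import math


def enumerate_structures(s: str, score_of, min_loop: int = 3):
    """All nested structures of ``s`` as lists of (i, j, score), 0-based.

    ``score_of(a, b)`` returns a pair score or None.  Enumerates by "first
    position unpaired or paired with k", which generates each structure
    exactly once.
    """

    def rec(i: int, j: int):
        if i >= j:
            yield []
            return
        yield from rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            sc = score_of(s[i], s[k])
            if sc is None:
                continue
            for inner in rec(i + 1, k - 1):
                for right in rec(k + 1, j):
                    yield [(i, k, sc)] + inner + right

    yield from rec(0, len(s) - 1)


def brute_force_fold(s: str, score_of, min_loop: int = 3) -> float:
    """Optimal total pair score by exhaustive enumeration."""
    return max(
        sum(sc for *_, sc in st)
        for st in enumerate_structures(s, score_of, min_loop)
    )


def brute_force_ensemble(s: str, score_of, min_loop: int = 3, kT: float = 1.0):
    """(Z, best_score, pair-probability dict with 0-based keys) by enumeration."""
    Z = 0.0
    best = -math.inf
    weighted_pairs: dict[tuple[int, int], float] = {}
    for st in enumerate_structures(s, score_of, min_loop):
        score = sum(sc for *_, sc in st)
        w = math.exp(score / kT)
        Z += w
        best = max(best, score)
        for i, j, _ in st:
            weighted_pairs[(i, j)] = weighted_pairs.get((i, j), 0.0) + w
    probs = {key: w / Z for key, w in weighted_pairs.items()}
    return Z, best, probs


def stem_runs_by_scan(pairs: list[tuple[int, int]]) -> list[int]:
    """Maximal stacked runs by walking all pairs sorted by opening position."""
    pair_set = set(pairs)
    runs = []
    for i, j in sorted(pairs):
        if (i - 1, j + 1) in pair_set:
            continue  # not the outermost pair of its run
        length = 0
        a, b = i, j
        while (a, b) in pair_set:
            length += 1
            a, b = a + 1, b - 1
        runs.append(length)
    return runs


def triplet_count_by_windows(seq: str, dotbracket: str) -> dict[str, int]:
    """Sliding-window triplet tally; '(' for any paired position."""
    state = "".join("." if c == "." else "(" for c in dotbracket)
    counts: dict[str, int] = {}
    for m in range(1, len(seq) - 1):
        key = seq[m] + state[m - 1 : m + 2]
        counts[key] = counts.get(key, 0) + 1
    return counts
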