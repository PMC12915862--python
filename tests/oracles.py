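"""Independent reference implementations used only by the test suite.

These deliberately share no code with the package: the BPE oracle re-counts
every adjacent pair from scratch at every iteration, and the rank-sum
oracle enumerates all labelings exhaustively.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

MERGEABLE = set("ACGT")


def naive_bpe_merges(words: list[str], num_merges: int) -> list[tuple[str, str, int]]:
    """Greedy BPE by full pair re-count each iteration (quadratic, tiny n).

    Overlapping occurrences each count; ties break to the lexicographically
    smallest pair; stops when the best pair occurs fewer than 2 times.
    Pairs touching a non-ACGT character are skipped.
    """
    seqs = [list(w) for w in words]
    merges = []
    for _ in range(num_merges):
        counts: dict[tuple[str, str], int] = {}
        for seq in seqs:
            for a, b in zip(seq, seq[1:]):
                if set(a) <= MERGEABLE and set(b) <= MERGEABLE:
                    counts[(a, b)] = counts.get((a, b), 0) + 1
        if not counts:
            break
        best = min(counts, key=lambda p: (-counts[p], p))
        if counts[best] < 2:
            break
        merges.append((best[0], best[1], counts[best]))
        a, b = best
        new_seqs = []
        for seq in seqs:
            out, i = [], 0
            while i < len(seq):
                if i + 1 < len(seq) and seq[i] == a and seq[i + 1] == b:
                    out.append(a + b)
                    i += 2
                else:
                    out.append(seq[i])
                    i += 1
            new_seqs.append(out)
        seqs = new_seqs
    return merges


def exhaustive_rank_sum_p(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all C(n+m, n) labelings.

    Only valid for tie-free pooled samples.  Returns (U of x, p).
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    n, m = len(x), len(y)

    def u_of(idx: tuple[int, ...]) -> int:
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in set(idx)]
        return sum(1 for a in xs for b in ys if a > b)

    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) // 2
    us = [u_of(idx) for idx in combinations(range(n + m), n)]
    us = np.array(us)
    p = 2.0 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return float(u_obs), float(min(1.0, p))
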