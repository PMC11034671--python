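"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths (and libraries' test functions)
they are checking: exact-test p-values come from direct enumeration with
binomial coefficients, nearest-TSS links from an all-pairs search, interval
unions from boolean masks.
"""

import math


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    probs = [
        math.comb(r1, x) * math.comb(r2, c1 - x) / denom
        for x in range(lo, hi + 1)
    ]
    p_obs = probs[a - lo]
    return sum(p for p in probs if p <= p_obs * (1 + 1e-9))


def hypergeom_upper_oracle(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X hypergeometric(N, K, n), by enumeration."""
    denom = math.comb(N, n)
    total = 0.0
    for j in range(k, min(n, K) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j) / denom
    return min(1.0, total)


def nearest_tss_all_pairs(position: int, tss_list):
    """(gene_id, |distance|) minimising |position - tss|, ties by gene_id.

    ``tss_list`` is a list of (gene_id, tss) on the same chromosome.
    """
    best = None
    for gene_id, tss in tss_list:
        key = (abs(position - tss), gene_id)
        if best is None or key < best:
            best = key
    return best[1], best[0]


def interval_union_mask(interval_lists, length: int):
    """Boolean-mask union of 0-based half-open intervals on one chromosome."""
    mask = [False] * length
    for ivs in interval_lists:
        for (s, e) in ivs:
            for i in range(s, e):
                mask[i] = True
    out = []
    i = 0
    while i < length:
        if mask[i]:
            j = i
            while j < length and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out
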