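"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain nested loops over explicit
combinatorial enumerations, deliberately sharing no code with the package's
optimised paths.
"""

from __future__ import annotations

import math
from itertools import combinations, product


def brute_subset_probs(sites, r, pseudocount=0.0):
    """{positions: {tuple_str: prob}} by direct recounting."""
    L = len(sites[0])
    N = len(sites)
    out = {}
    for positions in combinations(range(1, L + 1), r):
        counts = {"".join(t): 0 for t in product("ACGT", repeat=r)}
        for s in sites:
            counts["".join(s[p - 1] for p in positions)] += 1
        denom = N + pseudocount * 4**r
        out[positions] = {t: (c + pseudocount) / denom for t, c in counts.items()}
    return out


def brute_information(tables, sequence, L, r):
    """I_r from a brute probability table; math.inf if any tuple unseen."""
    total = 0.0
    n_sub = 0
    for positions, probs in tables.items():
        p = probs["".join(sequence[i - 1] for i in positions)]
        if p <= 0:
            return math.inf
        total += math.log2(p)
        n_sub += 1
    return -(L / (r * n_sub)) * total


def brute_background(references, L, r):
    """Pooled background tuple probabilities by exhaustive window loops."""
    counts = {"".join(t): 0 for t in product("ACGT", repeat=r)}
    for ref in references:
        for start in range(len(ref) - L + 1):
            window = ref[start : start + L]
            if any(c not in "ACGT" for c in window):
                continue
            for positions in combinations(range(L), r):
                counts["".join(window[i] for i in positions)] += 1
    total = sum(counts.values())
    return {t: c / total for t, c in counts.items()}, total


def brute_is1(q, sequence, r):
    L = len(sequence)
    total = 0.0
    n_sub = 0
    for positions in combinations(range(L), r):
        p = q["".join(sequence[i] for i in positions)]
        if p <= 0:
            return math.inf
        total += math.log2(p)
        n_sub += 1
    return -(L / (n_sub * r)) * total


def brute_ti(tables, q, sequence, L, r):
    """TI_r = (L/(r C)) * sum log2(p/q); -inf if any p zero, +inf if q zero."""
    total = 0.0
    n_sub = 0
    any_p_zero = False
    any_q_zero = False
    for positions, probs in tables.items():
        bases = "".join(sequence[i - 1] for i in positions)
        p = probs[bases]
        qq = q[bases]
        n_sub += 1
        if p <= 0:
            any_p_zero = True
        elif qq <= 0:
            any_q_zero = True
        else:
            total += math.log2(p) - math.log2(qq)
    if any_p_zero:
        return -math.inf
    if any_q_zero:
        return math.inf
    return (L / (r * n_sub)) * total


def brute_cluster_merge(hits):
    """Transitive overlap clustering per (sequence, strand); max-TI, leftmost."""
    out = []
    keys = sorted({(h.sequence_id, h.strand) for h in hits})
    for key in keys:
        ws = sorted(
            (h for h in hits if (h.sequence_id, h.strand) == key),
            key=lambda h: h.start,
        )
        clusters = []
        for w in ws:
            if clusters and w.start < clusters[-1][0]:
                clusters[-1][1].append(w)
                clusters[-1][0] = max(clusters[-1][0], w.end)
            else:
                clusters.append([w.end, [w]])
        for _, members in clusters:
            best = members[0]
            for m in members[1:]:
                if m.ti > best.ti:
                    best = m
            out.append(best)
    out.sort(key=lambda h: (h.sequence_id, h.start, h.strand))
    return out


def brute_max_matching(pairs, n_left, n_right):
    """Maximum bipartite matching cardinality by augmenting paths."""
    adj = [[] for _ in range(n_left)]
    for a, b in pairs:
        adj[a].append(b)
    match_r = [-1] * n_right

    def try_augment(a, seen):
        for b in adj[a]:
            if b in seen:
                continue
            seen.add(b)
            if match_r[b] == -1 or try_augment(match_r[b], seen):
                match_r[b] = a
                return True
        return False

    size = 0
    for a in range(n_left):
        if try_augment(a, set()):
            size += 1
    return size
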