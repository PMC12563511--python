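"""Independent brute-force reference implementations used only by tests.

Everything here is written in the most literal way possible (explicit
loops, stable list sorts, direct counting) and shares no code with the
package, so agreement between the two is meaningful.
"""

from collections import Counter
from math import log


def naive_amplitude_permutation(vector):
    """Literal reading of the rank rule: stably sort ascending, record each
    original element's 1-based position in the sorted list, then give every
    member of a tie group the group's minimum position."""
    m = len(vector)
    order = sorted(range(m), key=lambda k: (vector[k], k))  # stable ascending
    position = [0] * m
    for pos_in_sorted, original_index in enumerate(order, start=1):
        position[original_index] = pos_in_sorted
    ranks = list(position)
    for i in range(m):
        for j in range(m):
            if vector[j] == vector[i] and ranks[j] < ranks[i]:
                ranks[i] = ranks[j]
    return tuple(ranks)


def naive_pattern_counts(x, m, tau):
    counts = Counter()
    n_vec = len(x) - (m - 1) * tau
    for t in range(n_vec):
        window = [x[t + i * tau] for i in range(m)]
        counts[naive_amplitude_permutation(window)] += 1
    return counts, n_vec


def naive_pe(counts, n_vec):
    h = 0.0
    for c in counts.values():
        p = c / n_vec
        if p > 0:
            h -= p * log(p)
    return h


def naive_ptirr(counts, n_vec):
    patterns = set(counts) | {p[::-1] for p in counts}
    total = 0.0
    for p in patterns:
        pf = counts.get(p, 0) / n_vec
        pb = counts.get(p[::-1], 0) / n_vec
        if pf + pb > 0:
            total += pf * abs(pf - pb) / (pf + pb)
    return total


def naive_ptirr_pairwise(counts, n_vec):
    """PTIRR via the unordered-pair identity: sum over {p, reverse(p)} pairs
    of |prob difference| (self-reverse patterns contribute 0)."""
    seen = set()
    total = 0.0
    for p in set(counts) | {q[::-1] for q in counts}:
        pair = frozenset((p, p[::-1]))
        if pair in seen:
            continue
        seen.add(pair)
        if p == p[::-1]:
            continue
        total += abs(counts.get(p, 0) - counts.get(p[::-1], 0)) / n_vec
    return total


def naive_coarse_grain(x, s):
    out = []
    for start in range(0, (len(x) // s) * s, s):
        out.append(sum(x[start : start + s]) / s)
    return out


def naive_index_at_scale(x, s, m, tau, kind):
    coarse = naive_coarse_grain(list(x), s)
    counts, n_vec = naive_pattern_counts(coarse, m, tau)
    return naive_pe(counts, n_vec) if kind == "pe" else naive_ptirr(counts, n_vec)
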