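"""Independent brute-force oracles used by the test suite.

Everything here is written as straightforward exhaustive enumeration,
deliberately sharing no code with the package's detection or alignment
paths, so it can serve as the correctness reference on small instances.
"""

from __future__ import annotations

import math
from collections import Counter


def _window_consensus(chunks: list[str]) -> str:
    """Column-majority consensus; ties resolved by the symbol occurring
    first reading chunks top to bottom."""
    width = max(len(c) for c in chunks)
    out = []
    for col in range(width):
        letters = [c[col] for c in chunks if col < len(c)]
        counts = Counter(letters)
        best = max(counts.items(),
                   key=lambda kv: (kv[1], -letters.index(kv[0])))
        out.append(best[0])
    return "".join(out)


def window_qualifies(seq: str, p: int, s: int, e: int, *,
                     min_copy_number=2.0, min_char_identity=0.7,
                     min_consensus_match=0.8, min_domain_length=12):
    """Evaluate one ungapped (period, start, end) window from scratch.

    Returns (qualifies, consensus, aggregate_identity).
    """
    w = e - s
    if w < min_domain_length or w / p < min_copy_number:
        return False, "", 0.0
    window = seq[s:e]
    chunks = [window[k:k + p] for k in range(0, w, p)]
    cons = _window_consensus(chunks)
    total = 0
    for chunk in chunks:
        m = sum(1 for a, b in zip(chunk, cons) if a == b)
        if m < math.ceil(min_char_identity * len(chunk)):
            return False, cons, 0.0
        total += m
    if total < math.ceil(min_consensus_match * w):
        return False, cons, 0.0
    return True, cons, total / w


def oracle_detect(seq: str, *, min_copy_number=2.0, min_char_identity=0.7,
                  min_consensus_match=0.8, min_domain_length=12,
                  max_period=None):
    """Exhaustive ungapped TR detection.

    Enumerates every (period, start, end) window, keeps qualifying
    windows that are maximal (not extendable by one residue at either
    end at the same period), and resolves overlaps greedily by score
    (copy number x aggregate identity; ties to longer, then leftmost,
    then smaller period).  Returns a list of (start, end, period,
    consensus, score) tuples sorted by start.
    """
    L = len(seq)
    kw = dict(min_copy_number=min_copy_number,
              min_char_identity=min_char_identity,
              min_consensus_match=min_consensus_match,
              min_domain_length=min_domain_length)
    top = max_period or L // 2
    top = min(top, L // 2)
    qualifying = {}
    for p in range(1, top + 1):
        min_w = max(min_domain_length, math.ceil(min_copy_number * p))
        for s in range(0, L - min_w + 1):
            for e in range(s + min_w, L + 1):
                ok, cons, agg = window_qualifies(seq, p, s, e, **kw)
                if ok:
                    qualifying[(p, s, e)] = (cons, agg)
    maximal = []
    for (p, s, e), (cons, agg) in qualifying.items():
        if (p, s - 1, e) in qualifying or (p, s, e + 1) in qualifying:
            continue
        score = (e - s) / p * agg
        maximal.append((s, e, p, cons, score))
    chosen = []
    for cand in sorted(maximal,
                       key=lambda t: (-t[4], -(t[1] - t[0]), t[0], t[2])):
        s, e = cand[0], cand[1]
        if all(e <= c[0] or s >= c[1] for c in chosen):
            chosen.append(cand)
    return sorted(chosen)


def brute_cyclic_score(a: str, b: str) -> int:
    """Best match count over every rotation of b and every sliding
    offset, compared over the shorter length."""
    best = -1
    for k in range(len(b)):
        rb = b[k:] + b[:k]
        short, long_ = (a, rb) if len(a) <= len(rb) else (rb, a)
        for o in range(len(long_) - len(short) + 1):
            sc = sum(1 for x, y in zip(short, long_[o:o + len(short)])
                     if x == y)
            best = max(best, sc)
    return best
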