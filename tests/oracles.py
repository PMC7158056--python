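"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the library paths they check:
the motif oracle enumerates every (start, repeat-assignment) combination,
and the alignment oracle enumerates every local alignment as a monotone
sequence of substitution columns with affine-costed gaps between them.
"""

from __future__ import annotations

import itertools


def brute_force_motif_starts(pattern, seq: str) -> dict[int, int]:
    """start -> minimal span, by enumerating every repeat-count assignment."""
    ranges = [range(el.repeat_min, el.repeat_max + 1) for el in pattern.elements]
    results: dict[int, int] = {}
    for counts in itertools.product(*ranges):
        span = sum(counts)
        for start in range(len(seq) - span + 1):
            pos = start
            ok = True
            for el, r in zip(pattern.elements, counts):
                for k in range(r):
                    if not el.accepts(seq[pos + k]):
                        ok = False
                        break
                if not ok:
                    break
                pos += r
            if ok and (start not in results or span < results[start]):
                results[start] = span
    return results


def brute_force_local_score(a: str, b: str, scheme) -> int:
    """Best local alignment score by exhaustive enumeration.

    Any optimal local alignment starts and ends with a substitution
    column (terminal gaps only lose score), so alignments are enumerated
    as strictly increasing sequences of aligned position pairs; the
    unaligned stretch between consecutive columns costs one affine gap
    per sequence side (open + extend * length).
    """
    n, m = len(a), len(b)
    best = 0

    def gap(k: int) -> int:
        return scheme.gap_open + scheme.gap_extend * k if k else 0

    def rec(i: int, j: int, score: int) -> None:
        nonlocal best
        if score > best:
            best = score
        for i2 in range(i + 1, n):
            for j2 in range(j + 1, m):
                rec(i2, j2, score + scheme.score(a[i2], b[j2])
                    - gap(i2 - i - 1) - gap(j2 - j - 1))

    for i in range(n):
        for j in range(m):
            rec(i, j, scheme.score(a[i], b[j]))
    return best
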