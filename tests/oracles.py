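"""Independent brute-force oracles used by the test suite.

These deliberately re-derive every quantity with the simplest possible
code, sharing nothing with the package implementation.
"""

from __future__ import annotations


def bruteforce_profile(seq: str, scale: dict[str, float], core_len: int, wedge_len: int) -> list[float]:
    """Trapezoid-window hydropathy computed position-by-position."""
    half_core = (core_len - 1) // 2
    w = half_core + wedge_len
    n = len(seq)
    out = []
    for p in range(n):
        num = den = 0.0
        for q in range(n):
            d = abs(q - p)
            if d <= half_core:
                wt = 1.0
            elif d <= w:
                wt = 1.0 - (d - half_core) / (wedge_len + 1)
            else:
                continue
            num += wt * scale[seq[q]]
            den += wt
        out.append(num / den)
    return out


def bruteforce_align_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal global alignment score by exhaustive recursion.

    Gap convention: a gap run of length k scores gap_open + k*gap_extend.
    Exponential — only for tiny sequences.
    """

    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "sub"))
        if i < len(a):  # gap in b
            cost = gap_extend if prev == "gap_b" else gap_open + gap_extend
            best = max(best, cost + rec(i + 1, j, "gap_b"))
        if j < len(b):  # gap in a
            cost = gap_extend if prev == "gap_a" else gap_open + gap_extend
            best = max(best, cost + rec(i, j + 1, "gap_a"))
        return best

    return rec(0, 0, "start")
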