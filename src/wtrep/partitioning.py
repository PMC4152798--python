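"""Maximal repetitions of a plain (certain) string.

A repetition is a triple ``(i, p, e)``: ``e >= 2`` adjacent copies of a
primitive word ``u`` of length ``p`` starting at ``i``, such that
``u^(e+1)`` does not occur at ``i``.  It is *maximal* when additionally
``i - p < 0`` or ``u^e`` does not occur at ``i - p``, i.e. it cannot be
shifted one period to the left.

:func:`maximal_repetitions` is the production implementation: a
divide-and-conquer periodicity search in the Main--Lorentz style,
O(n log n) up to candidate re-extension, producing the identical output
set to classic partitioning by successive refinement of position
classes.  :func:`naive_maximal_repetitions` is the independent
brute-force oracle used to verify it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Set, Tuple

__all__ = [
    "PlainRepetition",
    "is_primitive",
    "maximal_repetitions",
    "naive_maximal_repetitions",
    "split_into_squares",
]


@dataclass(frozen=True, order=True)
class PlainRepetition:
    """Maximal integer power ``u^e`` of a primitive root in a plain string."""

    i: int
    p: int
    e: int


def _failure(u: str) -> List[int]:
    """KMP failure function (length of longest proper border per prefix)."""
    fail = [0] * len(u)
    k = 0
    for i in range(1, len(u)):
        while k and u[i] != u[k]:
            k = fail[k - 1]
        if u[i] == u[k]:
            k += 1
        fail[i] = k
    return fail


def is_primitive(u: str) -> bool:
    """True iff ``u`` is not a proper integer power ``v^e`` with ``e >= 2``."""
    if not u:
        raise ValueError("primitivity is undefined for the empty string")
    n = len(u)
    q = n - _failure(u)[-1]  # smallest period
    return q == n or n % q != 0


def _z_array(s: str) -> List[int]:
    """z[i] = length of the longest common prefix of s and s[i:]."""
    n = len(s)
    z = [0] * n
    if n == 0:
        return z
    z[0] = n
    l = r = 0
    for i in range(1, n):
        if i < r:
            z[i] = min(r - i, z[i - l])
        while i + z[i] < n and s[z[i]] == s[i + z[i]]:
            z[i] += 1
        if i + z[i] > r:
            l, r = i, i + z[i]
    return z


def _periodic_regions(s: str) -> Set[Tuple[int, int, int]]:
    """All maximal periodic regions ``(start, end, p)`` with length >= 2p.

    Divide and conquer: a region contained in the current window and
    crossing its midpoint is detected there via longest-common-extension
    queries (Z-arrays anchored at the midpoint).  Candidates clipped by
    deeper windows are re-extended in the full string, so after
    deduplication every region is maximal: ``s[j] == s[j+p]`` holds on
    ``[start, end - p)`` and fails just outside.
    """
    n = len(s)
    out: Set[Tuple[int, int, int]] = set()
    # below this window size a direct quadratic scan beats the
    # recursion + Z-array machinery by a wide margin
    cutoff = 24

    def emit(start: int, end: int, p: int) -> None:
        while start > 0 and s[start - 1] == s[start - 1 + p]:
            start -= 1
        while end < n and s[end] == s[end - p]:
            end += 1
        if end - start >= 2 * p:
            out.add((start, end, p))

    def cross(l: int, m: int, r: int) -> None:
        w = s[l:r]
        mm = m - l
        v = w[mm:]
        rb = w[::-1]
        ru = rb[len(w) - mm:]  # reversed prefix w[:mm]
        zf = _z_array(v)
        # cp(v, w[k:]) for any window offset k
        zfw = _z_array(v + "\x00" + w)
        # cp(ru, rb[k:]): common suffix of w[:mm] and any window prefix
        zbw = _z_array(ru + "\x00" + rb)

        def lce_fwd(k: int) -> int:  # common prefix of w[mm:] and w[k:]
            return zfw[len(v) + 1 + k]

        def lcs_back(k: int) -> int:  # common suffix of w[:mm] and w[:k]
            if k <= 0:
                return 0
            return zbw[len(ru) + 1 + len(w) - k]

        # period block starting at the midpoint
        for p in range(1, len(v) + 1):
            l2 = zf[p] if p < len(v) else 0
            l1 = lcs_back(mm + p)
            if l1 + l2 >= p:
                emit(l + mm - l1, l + mm + p + l2, p)
        # period block ending at the midpoint
        for p in range(1, mm + 1):
            l2 = lce_fwd(mm - p)
            l1 = lcs_back(mm - p)
            if l1 + l2 >= p:
                emit(l + mm - p - l1, l + mm + l2, p)

    def base(l: int, r: int) -> None:
        # all match runs of s[j] == s[j+p] inside the window; runs of
        # length >= p are periodic regions (re-extended globally by emit)
        w = s[l:r]
        ln = r - l
        for p in range(1, ln // 2 + 1):
            j = 0
            top = ln - p
            while j < top:
                if w[j] != w[j + p]:
                    j += 1
                    continue
                k = j + 1
                while k < top and w[k] == w[k + p]:
                    k += 1
                if k - j >= p:
                    emit(l + j, l + k + p, p)
                j = k + 1

    def rec(l: int, r: int) -> None:
        if r - l < 2:
            return
        if r - l <= cutoff:
            base(l, r)
            return
        m = (l + r) // 2
        rec(l, m)
        rec(m, r)
        cross(l, m, r)

    rec(0, n)
    return out


def maximal_repetitions(s: str) -> List[PlainRepetition]:
    """All maximal repetitions of ``s``, sorted by ``(i, p)``.

    Each maximal p-periodic region of length L hosts one maximal
    repetition per phase ``d in [0, p)`` with ``floor((L - d)/p) >= 2``
    copies, provided the root at that phase is primitive (roots of
    non-smallest-period regions are proper powers and are discarded).
    """
    reps: Set[PlainRepetition] = set()
    for start, end, p in _periodic_regions(s):
        for d in range(p):
            i = start + d
            e = (end - i) // p
            if e >= 2 and is_primitive(s[i:i + p]):
                reps.add(PlainRepetition(i, p, e))
    return sorted(reps)


def naive_maximal_repetitions(s: str) -> List[PlainRepetition]:
    """Brute-force oracle: direct enumeration of all ``(i, p)`` pairs."""
    n = len(s)
    reps: List[PlainRepetition] = []
    for i in range(n):
        for p in range(1, (n - i) // 2 + 1):
            u = s[i:i + p]
            if s[i + p:i + 2 * p] != u:
                continue
            if not is_primitive(u):
                continue
            if i >= p and s[i - p:i] == u:
                continue  # not left-maximal
            e = 2
            while s[i + e * p:i + (e + 1) * p] == u:
                e += 1
            reps.append(PlainRepetition(i, p, e))
    return sorted(reps)


def split_into_squares(rep: PlainRepetition) -> List[PlainRepetition]:
    """Break ``u^e`` into its ``e - 1`` overlapping squares.

    Squares (``e == 2``) pass through unchanged.
    """
    return [PlainRepetition(rep.i + k * rep.p, rep.p, 2) for k in range(rep.e - 1)]
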