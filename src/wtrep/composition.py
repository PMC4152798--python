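"""All tandem repeats whose every copy meets the threshold.

Here a repetition ``v = u^e`` qualifies when *each* occurrence of ``u``
in ``v`` is a valid factor at ``1/z`` -- the whole span may fall below
the threshold.  The solver:

1. runs the whole-span machinery at the relaxed threshold ``1/z**2``
   (guaranteeing that every square whose halves are valid at ``1/z`` is
   found), simultaneously computing ``LF'`` at ``1/z`` on each extended
   factor;
2. splits the maximal extended repetitions into their overlapping
   squares and keeps those whose halves are both valid
   (``LF'[i] >= p`` and ``LF'[i+p] >= p``);
3. buckets the surviving squares by (start, period);
4. composes chains of overlapping compatible squares -- two squares one
   period apart extend each other when their black-position letter
   choices agree on the overlap -- consuming each square exactly once
   and emitting the maximal repetitions;
5. reports, for every maximal repetition, the repetition starting at
   each of its copies (exponent decreasing), which is exactly the
   requested output set.

Black positions (and hence the ``b`` sets of the output quadruples)
refer to the colouring at the working threshold ``1/z**2``: those are
the positions where the machinery actually had a choice of letter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product as iter_product
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

from .factor_generation import compute_lf, generate_extended_factors
from .partitioning import is_primitive, maximal_repetitions, split_into_squares
from .weighted_core import (
    BLACK,
    Threshold,
    WeightedRepetition,
    WeightedString,
    colour,
    filter_letters,
    next_black,
    prob_ge,
    split_unsupported,
)

__all__ = [
    "ValidSquare",
    "PeriodBuckets",
    "generate_valid_squares",
    "bucket_squares",
    "compatible",
    "compose",
    "report_all",
    "solve_problem1",
    "brute_force_problem1",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidSquare:
    """A primitive square ``uu`` whose halves are both valid at ``1/z``.

    ``black`` maps the absolute BLACK positions of the full span
    ``[i, i + 2p)`` to the chosen letters; it is what the compatibility
    check between overlapping squares compares.
    """

    i: int
    p: int
    letters: str  # the concrete word uu
    black: Tuple[Tuple[int, str], ...]  # absolute position -> letter, sorted

    @property
    def root(self) -> str:
        return self.letters[: self.p]

    def black_map(self) -> Dict[int, str]:
        return dict(self.black)

    def first_copy_b(self) -> FrozenSet[Tuple[int, str]]:
        return frozenset((q - self.i, a) for q, a in self.black if q < self.i + self.p)


class PeriodBuckets:
    """Squares grouped by start position and period (the A_i lists).

    A general-purpose hash map stands in for the perfect hash of the
    period set; lookup and delete stay expected constant time.
    """

    def __init__(self) -> None:
        self._by_start: Dict[int, Dict[int, List[ValidSquare]]] = {}

    def add(self, sq: ValidSquare) -> None:
        self._by_start.setdefault(sq.i, {}).setdefault(sq.p, []).append(sq)

    def get(self, i: int, p: int) -> List[ValidSquare]:
        return self._by_start.get(i, {}).get(p, [])

    def remove(self, sq: ValidSquare) -> None:
        self._by_start[sq.i][sq.p].remove(sq)

    def starts(self) -> List[int]:
        return sorted(self._by_start)

    def periods_at(self, i: int) -> List[int]:
        return sorted(self._by_start.get(i, {}))

    def count(self) -> int:
        return sum(
            len(lst) for per in self._by_start.values() for lst in per.values()
        )


def generate_valid_squares(ws: WeightedString, t: Threshold) -> List[ValidSquare]:
    """All primitive squares of ``ws`` whose halves are valid at ``1/z``.

    Runs generation and partitioning at the relaxed threshold
    ``1/z**2``; each maximal extended repetition is split into its
    overlapping squares, and a square at local position ``j`` survives
    when ``LF'[j] >= p`` and ``LF'[j + p] >= p``, where ``LF'`` is the
    longest-valid-factor array of the extended factor at ``1/z``.
    """
    ws.validate_raw()
    relaxed = t.squared()
    filtered = filter_letters(ws, relaxed)
    out: Dict[Tuple[int, int, str], ValidSquare] = {}
    for offset, seg in split_unsupported(filtered, relaxed):
        c = colour(seg, relaxed)
        efs = generate_extended_factors(seg, c, relaxed)
        for ef in efs:
            lf = compute_lf(ef, seg, t.value)
            for rep in maximal_repetitions(ef.letters):
                for sq in split_into_squares(rep):
                    j, p = sq.i, sq.p
                    if lf[j] < p or lf[j + p] < p:
                        continue
                    span = ef.letters[j:j + 2 * p]
                    xi = offset + ef.start + j
                    key = (xi, p, span)
                    if key in out:
                        continue
                    black = tuple(
                        (xi + d, span[d])
                        for d in range(2 * p)
                        if c[ef.start + j + d] == BLACK
                    )
                    out[key] = ValidSquare(xi, p, span, black)
    squares = sorted(out.values(), key=lambda s: (s.i, s.p, s.letters))
    logger.debug("kept %d valid squares", len(squares))
    return squares


def bucket_squares(squares: Sequence[ValidSquare], n: int) -> PeriodBuckets:
    """Exact partition of de-duplicated squares by (start, period)."""
    buckets = PeriodBuckets()
    for sq in squares:
        if sq.i + 2 * sq.p > n:
            raise ValueError(f"square at {sq.i} with period {sq.p} exceeds length {n}")
        buckets.add(sq)
    return buckets


def compatible(first: ValidSquare, second: ValidSquare) -> bool:
    """Do two overlapping squares agree at the black positions they share?

    ``second`` must start exactly one period after ``first`` with the
    same period, so the overlap is the second half of ``first`` and the
    first half of ``second``.  Letters at non-black positions are forced
    and agree automatically; only the black choices need comparing.
    """
    if second.i != first.i + first.p or second.p != first.p:
        raise ValueError("squares are not aligned one period apart")
    fmap = first.black_map()
    limit = second.i + second.p
    for q, a in second.black:
        if q >= limit:
            break
        if fmap.get(q) != a:
            return False
    return True


@dataclass(frozen=True)
class ComposedRepetition:
    """A maximal repetition assembled from a chain of squares."""

    i: int
    p: int
    e: int
    root: str
    black: Tuple[Tuple[int, str], ...]  # absolute position -> letter over the span

    def b_for_copy(self, k: int) -> FrozenSet[Tuple[int, str]]:
        lo = self.i + k * self.p
        hi = lo + self.p
        return frozenset((q - lo, a) for q, a in self.black if lo <= q < hi)


def compose(buckets: PeriodBuckets) -> List[ComposedRepetition]:
    """Grow each surviving square into its maximal repetition chain.

    Start positions are scanned in ascending order (periods ascending
    within a position), so any square extendable to the left has
    already been consumed by the chain that reaches it; chain starts
    are therefore left-maximal.  Extending looks for the unique
    compatible square one period to the right and deletes it as it is
    consumed, so every square belongs to exactly one chain.
    """
    out: List[ComposedRepetition] = []
    for i in buckets.starts():
        for p in buckets.periods_at(i):
            while True:
                bucket = buckets.get(i, p)
                if not bucket:
                    break
                sq = bucket[0]
                buckets.remove(sq)
                chain_black = dict(sq.black)
                cur = sq
                e = 2
                while True:
                    nxt = None
                    for cand in buckets.get(cur.i + p, p):
                        if compatible(cur, cand):
                            if nxt is not None:
                                raise AssertionError(
                                    "two distinct compatible squares in one bucket"
                                )
                            nxt = cand
                    if nxt is None:
                        break
                    buckets.remove(nxt)
                    chain_black.update(nxt.black)
                    cur = nxt
                    e += 1
                out.append(
                    ComposedRepetition(
                        i, p, e, sq.root, tuple(sorted(chain_black.items()))
                    )
                )
    return out


def report_all(maximal: Sequence[ComposedRepetition]) -> List[WeightedRepetition]:
    """Expand maximal repetitions into the repetition at every copy start.

    For ``(i, p, b, e)`` this yields ``(i + k*p, p, b_k, e - k)`` for
    ``0 <= k <= e - 2``, with ``b_k`` recomputed for the black positions
    of the copy starting at ``i + k*p``.
    """
    quads: Set[WeightedRepetition] = set()
    for rep in maximal:
        for k in range(rep.e - 1):
            quads.add(
                WeightedRepetition(
                    rep.i + k * rep.p, rep.p, rep.e - k, rep.b_for_copy(k)
                )
            )
    return sorted(quads, key=lambda r: (r.i, r.p, r.e, sorted(r.b)))


def solve_problem1(
    ws: WeightedString, t: Threshold, report: str = "all"
) -> List[WeightedRepetition]:
    """All repetitions of ``ws`` whose every copy is valid at ``1/z``.

    ``report="maximal"`` returns only the composed maximal repetitions;
    the default ``"all"`` additionally reports the repetition starting
    at each copy, with its exponent and recomputed ``b`` set.
    """
    if report not in ("all", "maximal"):
        raise ValueError(f"report must be 'all' or 'maximal', got {report!r}")
    squares = generate_valid_squares(ws, t)
    buckets = bucket_squares(squares, len(ws))
    n_squares = buckets.count()
    composed = compose(buckets)
    consumed = sum(rep.e - 1 for rep in composed)
    if consumed != n_squares:
        raise AssertionError(
            f"composition consumed {consumed} squares out of {n_squares}"
        )
    if report == "maximal":
        return sorted(
            (
                WeightedRepetition(rep.i, rep.p, rep.e, rep.b_for_copy(0))
                for rep in composed
            ),
            key=lambda r: (r.i, r.p, r.e, sorted(r.b)),
        )
    return report_all(composed)


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_problem1(
    ws: WeightedString, t: Threshold
) -> List[WeightedRepetition]:
    """Oracle by direct enumeration of the per-copy validity definition.

    For every start, period and concrete primitive root, takes the
    maximal ``e`` such that every copy of ``u`` is valid at ``1/z``, and
    keeps all starts (the solver reports every copy's suffix repetition
    as well).  Exponential in ``n``; small instances only.
    """
    filtered = filter_letters(ws, t)
    thr = t.value
    n = len(filtered)
    # b refers to the colouring at the machinery's working threshold
    relaxed_filtered = filter_letters(ws, t.squared())
    marks = ["-"] * n
    for offset, seg in split_unsupported(relaxed_filtered, t.squared()):
        marks[offset:offset + len(seg)] = list(colour(seg, t.squared()).marks)

    def copy_valid(j: int, u: str) -> bool:
        if j < 0 or j + len(u) > n:
            return False
        return prob_ge(filtered.word_probability(j, u), thr)

    quads: Set[WeightedRepetition] = set()
    for i in range(n):
        for p in range(1, (n - i) // 2 + 1):
            choices = [filtered[i + k].entries for k in range(p)]
            for combo in iter_product(*choices):
                u = "".join(s for s, _ in combo)
                if not is_primitive(u):
                    continue
                if not (copy_valid(i, u) and copy_valid(i + p, u)):
                    continue
                e = 2
                while copy_valid(i + e * p, u):
                    e += 1
                b = frozenset(
                    (d, u[d]) for d in range(p) if marks[i + d] == BLACK
                )
                quads.add(WeightedRepetition(i, p, e, b))
    return sorted(quads, key=lambda r: (r.i, r.p, r.e, sorted(r.b)))
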