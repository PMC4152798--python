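"""Valid repetitions: tandem repeats whose whole span meets the threshold.

A *valid repetition* is a repetition ``v = u^e`` whose entire span has
cumulative occurrence probability at least ``1/z``.  The solver runs
the plain-string partitioner over every extended factor (any valid
repetition is a valid factor, hence occurs in some extended factor),
then breaks each maximal extended repetition at the boundary dictated
by the LF array, since extended factors may contain stretches that are
not valid (grey probabilities are ignored during generation but not by
LF).  Finally the black-position letter choices are attached to form
output quadruples ``(i, p, b, e)``.

:func:`brute_force_valid_repetitions` is the independent oracle: it
enumerates every concrete candidate directly from the definition and is
usable for ``n`` up to a dozen or so positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product as iter_product
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

from .factor_generation import ExtendedFactor, LFArray, compute_lf, generate_extended_factors
from .partitioning import PlainRepetition, is_primitive, maximal_repetitions
from .weighted_core import (
    BLACK,
    Colouring,
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
    "ExtendedRepetition",
    "extended_repetitions",
    "attach_b",
    "break_into_valid",
    "solve_problem2",
    "brute_force_valid_repetitions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtendedRepetition:
    """A maximal repetition of an extended factor, tied back to x."""

    factor: ExtendedFactor
    local: PlainRepetition

    @property
    def x_start(self) -> int:
        return self.factor.start + self.local.i

    @property
    def letters(self) -> str:
        lo = self.local.i
        return self.factor.letters[lo:lo + self.local.e * self.local.p]


def extended_repetitions(efs: Sequence[ExtendedFactor]) -> List[ExtendedRepetition]:
    """Maximal repetitions of every extended factor, de-duplicated.

    Two factors may contain the same repetition (same start in x, same
    period, exponent and letter content); only one copy is kept.
    """
    seen: Set[Tuple[int, int, int, str]] = set()
    out: List[ExtendedRepetition] = []
    for ef in efs:
        for rep in maximal_repetitions(ef.letters):
            er = ExtendedRepetition(ef, rep)
            key = (er.x_start, rep.p, rep.e, er.letters)
            if key not in seen:
                seen.add(key)
                out.append(er)
    return out


def attach_b(
    i: int, p: int, letters_at, c: Colouring, nb: Sequence[int]
) -> FrozenSet[Tuple[int, str]]:
    """Black-position letter choices in the first copy ``[i, i + p)``.

    ``letters_at(q)`` must return the concrete letter at absolute
    position ``q``.  Black positions are found by jumping through the
    next-black array ``nb``; a valid root can contain only a bounded
    number of them.
    """
    b: List[Tuple[int, str]] = []
    q = i if c[i] == BLACK else nb[i]
    while q < i + p:
        b.append((q - i, letters_at(q)))
        q = nb[q]
    return frozenset(b)


def break_into_valid(
    rep: ExtendedRepetition, lf: LFArray
) -> List[Tuple[int, int, int]]:
    """Longest valid repetition at each occurrence start of ``rep``.

    Scanning the starts ``i, i + p, ...`` left to right, emit
    ``(local_start, p, e')`` with ``e' = min(LF[start] // p, copies
    remaining)`` whenever ``e' >= 2``, suppressing an emission whose
    span is contained in the previous one (it is a proper suffix with a
    smaller exponent and carries no new information).
    """
    li, p, e = rep.local.i, rep.local.p, rep.local.e
    out: List[Tuple[int, int, int]] = []
    last_end = -1
    for k in range(e - 1):
        j = li + k * p
        ej = min(lf[j] // p, e - k)
        if ej < 2:
            continue
        end = j + ej * p
        if end <= last_end:
            continue
        out.append((j, p, ej))
        last_end = end
    return out


def _segment_valid_repetitions(
    seg: WeightedString, t: Threshold
) -> List[Tuple[int, int, int, FrozenSet[Tuple[int, str]]]]:
    """Valid repetitions of one split segment, in segment coordinates."""
    c = colour(seg, t)
    nb = next_black(c)
    efs = generate_extended_factors(seg, c, t)
    ereps = extended_repetitions(efs)
    logger.debug("segment: %d extended repetitions", len(ereps))
    lf_cache: Dict[Tuple[int, str], LFArray] = {}
    out = []
    for er in ereps:
        key = (er.factor.start, er.factor.letters)
        lf = lf_cache.get(key)
        if lf is None:
            lf = compute_lf(er.factor, seg, t.value)
            lf_cache[key] = lf
        for local_j, p, ej in break_into_valid(er, lf):
            xj = er.factor.start + local_j

            def letter_at(q: int, _f=er.factor) -> str:
                return _f.letters[q - _f.start]

            b = attach_b(xj, p, letter_at, c, nb)
            out.append((xj, p, ej, b))
    return out


def solve_problem2(ws: WeightedString, t: Threshold) -> List[WeightedRepetition]:
    """All valid repetitions of a raw weighted string.

    Pipeline: filter at ``1/z`` -> split -> colour -> generate extended
    factors -> partition each factor -> break at the LF boundary ->
    attach b -> de-duplicate.  Every output's full span has cumulative
    occurrence probability at least ``1/z``.
    """
    ws.validate_raw()
    filtered = filter_letters(ws, t)
    quads: Set[WeightedRepetition] = set()
    for offset, seg in split_unsupported(filtered, t):
        for i, p, e, b in _segment_valid_repetitions(seg, t):
            quads.add(WeightedRepetition(offset + i, p, e, b))
    return sorted(quads, key=lambda r: (r.i, r.p, r.e, sorted(r.b)))


# ---------------------------------------------------------------------------
# brute-force oracle


def _concrete_words(ws: WeightedString, i: int, length: int):
    """All concrete words occurring on ``[i, i + length)`` with their probability."""
    choices = [ws[i + k].entries for k in range(length)]
    for combo in iter_product(*choices):
        word = "".join(s for s, _ in combo)
        prob = 1.0
        for _, p in combo:
            prob *= p
        yield word, prob


def brute_force_valid_repetitions(
    ws: WeightedString, t: Threshold
) -> List[WeightedRepetition]:
    """Oracle for the whole-span problem by exhaustive enumeration.

    Enumerates every ``(i, p, concrete u, e)`` with a primitive root,
    whole-span probability at least ``1/z``, and ``e`` maximal under
    valid extension; a candidate preceded one period to the left by a
    valid occurrence of the same ``u^e`` is dropped (it is the shifted
    remainder of a longer valid repetition).  Exponential in ``n`` --
    intended for small instances only.
    """
    filtered = filter_letters(ws, t)
    thr = t.value
    n = len(filtered)
    marks = _colour_with_gaps(filtered, t)

    def span_prob(i: int, u: str, e: int) -> float:
        if i < 0 or i + e * len(u) > n:
            return 0.0
        return filtered.word_probability(i, u * e)

    quads: Set[WeightedRepetition] = set()
    for i in range(n):
        for p in range(1, (n - i) // 2 + 1):
            for u, _ in _concrete_words(filtered, i, p):
                if not is_primitive(u):
                    continue
                if not prob_ge(span_prob(i, u, 2), thr):
                    continue
                e = 2
                while prob_ge(span_prob(i, u, e + 1), thr):
                    e += 1
                if i >= p and prob_ge(span_prob(i - p, u, e), thr):
                    continue  # not left-maximal under valid extension
                b = frozenset(
                    (q - i, u[q - i])
                    for q in range(i, i + p)
                    if marks[q] == BLACK
                )
                quads.add(WeightedRepetition(i, p, e, b))
    return sorted(quads, key=lambda r: (r.i, r.p, r.e, sorted(r.b)))


def _colour_with_gaps(filtered: WeightedString, t: Threshold) -> str:
    """Colour marks over a filtered string, '-' at emptied positions."""
    marks = ["-"] * len(filtered)
    for offset, seg in split_unsupported(filtered, t):
        seg_marks = colour(seg, t).marks
        marks[offset:offset + len(seg)] = list(seg_marks)
    return "".join(marks)
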