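"""Extended factors and longest-valid-factor (LF) arrays.

An *extended factor* is a concrete string generated around the BLACK
(branching) positions of a filtered, coloured weighted string so that
every valid factor occurs inside at least one of them.  During
generation only the probabilities of the chosen letters at black
positions are multiplied into the running product (grey positions are
treated as certain), and a factor stops growing at the black position
whose inclusion would drop this product below the working threshold.

Seeds, scanning left to right:

* one factor starting at the segment start (unless the segment starts
  black), carried through later branchings;
* at every black position, one factor per stored letter there, plus
  one "empty" factor that starts collecting letters just after it.

The LF array then records, for each start inside an extended factor,
the length of the longest prefix of the corresponding suffix whose
cumulative occurrence probability -- now using the *actual*
probabilities at every position, grey included -- meets a threshold.
It is computed by a two-pointer sweep with a sliding product: end
positions never move left, since the longest valid factor at ``i + 1``
is at least one shorter than the one at ``i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

from .weighted_core import (
    BLACK,
    Colouring,
    Threshold,
    WeightedString,
    prob_ge,
)

__all__ = [
    "ExtendedFactor",
    "LFArray",
    "generate_extended_factors",
    "compute_lf",
    "cumulative_prob",
]

logger = logging.getLogger(__name__)

#: After this many divisions the sliding product is recomputed from
#: scratch over the current window, bounding float drift.
_REFRESH_DIVISIONS = 64


@dataclass(frozen=True)
class ExtendedFactor:
    """A concrete string anchored at ``start`` (segment coordinates).

    ``black_prob`` is the product of the chosen-letter probabilities at
    the BLACK positions in the span; it stays at or above the working
    threshold by construction.  ``origin`` records the generating black
    position (or the segment start, as a negative-free convention the
    earliest seed wins on deduplication).
    """

    start: int
    letters: str
    black_prob: float
    origin: int

    def __len__(self) -> int:
        return len(self.letters)

    @property
    def end(self) -> int:
        return self.start + len(self.letters)


@dataclass(frozen=True)
class LFArray:
    """Per-position longest-valid-factor lengths over one extended factor."""

    values: Tuple[int, ...]
    threshold: float

    def __getitem__(self, i: int) -> int:
        return self.values[i]

    def __len__(self) -> int:
        return len(self.values)


class _Active:
    __slots__ = ("start", "letters", "prob", "origin")

    def __init__(self, start: int, letters: List[str], prob: float, origin: int):
        self.start = start
        self.letters = letters
        self.prob = prob
        self.origin = origin


def generate_extended_factors(
    ws: WeightedString, c: Colouring, t: Threshold
) -> List[ExtendedFactor]:
    """Generate the de-duplicated extended factors of one segment.

    ``ws`` must be filtered and split at the working threshold ``t`` and
    ``c`` must be its colouring at that same threshold, so every
    GREY/WHITE position stores exactly one letter.
    """
    n = len(ws)
    if n == 0:
        return []
    thr = t.value
    actives: List[_Active] = []
    finished: List[_Active] = []

    if c[0] != BLACK:
        actives.append(_Active(0, [], 1.0, 0))

    for pos in range(n):
        wp = ws[pos]
        if c[pos] == BLACK:
            branched: List[_Active] = []
            for f in actives:
                extended = False
                for letter, p in wp.entries:
                    np_ = f.prob * p
                    if prob_ge(np_, thr):
                        branched.append(
                            _Active(f.start, f.letters + [letter], np_, f.origin)
                        )
                        extended = True
                if not extended and f.letters:
                    finished.append(f)
            # seeds at this black position: one per letter, plus the
            # "empty" seed that starts just after it
            for letter, p in wp.entries:
                branched.append(_Active(pos, [letter], p, pos))
            branched.append(_Active(pos + 1, [], 1.0, pos))
            actives = branched
        else:
            letter = wp.letters()[0]
            for f in actives:
                f.letters.append(letter)

    finished.extend(f for f in actives if f.letters)

    # de-duplicate on (start, letters); the earliest origin wins
    best: Dict[Tuple[int, str], _Active] = {}
    for f in finished:
        key = (f.start, "".join(f.letters))
        cur = best.get(key)
        if cur is None or f.origin < cur.origin:
            best[key] = f
    factors = [
        ExtendedFactor(f.start, "".join(f.letters), f.prob, f.origin)
        for f in best.values()
    ]
    factors.sort(key=lambda ef: (ef.start, ef.letters))
    logger.debug(
        "generated %d extended factors, total length %d (segment length %d)",
        len(factors),
        sum(len(ef) for ef in factors),
        n,
    )
    return factors


def _actual_probs(ef: ExtendedFactor, ws: WeightedString) -> List[float]:
    probs = []
    for k, letter in enumerate(ef.letters):
        p = ws[ef.start + k].prob(letter)
        if p == 0.0:
            raise ValueError(
                f"extended factor letter {letter!r} absent at position {ef.start + k}"
            )
        probs.append(p)
    return probs


def compute_lf(ef: ExtendedFactor, ws: WeightedString, thr: float) -> LFArray:
    """Longest-valid-factor lengths for every start inside ``ef``.

    ``LF[i]`` is the largest ``m`` such that the length-``m`` prefix of
    the suffix of ``ef`` at ``i`` has cumulative occurrence probability
    at least ``thr``, using the actual probability of every position
    (grey positions contribute their true, below-1 probability).
    """
    if not (0.0 < thr <= 1.0):
        raise ValueError(f"threshold must lie in (0, 1], got {thr!r}")
    probs = _actual_probs(ef, ws)
    m = len(probs)
    values: List[int] = []
    j = 0
    prod = 1.0
    divisions = 0
    # for positive values prob_ge(a, thr) reduces to a >= thr*(1 - tol)
    thr_eff = thr * (1.0 - 1e-9)
    for i in range(m):
        if j < i:
            j = i
            prod = 1.0
            divisions = 0
        while j < m and prod * probs[j] >= thr_eff:
            prod *= probs[j]
            j += 1
        values.append(j - i)
        if j > i:
            prod /= probs[i]
            divisions += 1
            if divisions >= _REFRESH_DIVISIONS:
                prod = 1.0
                for k in range(i + 1, j):
                    prod *= probs[k]
                divisions = 0
    return LFArray(tuple(values), thr)


def cumulative_prob(
    ef: ExtendedFactor, ws: WeightedString, i: int, length: int
) -> float:
    """Product of the actual probabilities of ``ef``'s letters on ``[i, i+length)``."""
    if i < 0 or length < 0 or i + length > len(ef):
        raise IndexError("range outside the extended factor")
    prod = 1.0
    for k in range(i, i + length):
        prod *= ws[ef.start + k].prob(ef.letters[k])
    return prod
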