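"""Weighted-string data model: filtering, splitting and colouring.

A *weighted string* models a DNA (or other) sequence in which each
position carries a probability distribution over the alphabet rather
than a single certain letter.  Such strings arise from IUPAC-encoded
genomes, SNP annotation, or base-caller uncertainty.  A concrete word
``u`` *occurs* at position ``i`` if every letter of ``u`` has positive
probability there, and the occurrence is *valid* for a cumulative
weight threshold ``1/z`` when the product of the per-position letter
probabilities is at least ``1/z``.

The preprocessing pipeline implemented here:

* :func:`filter_letters` drops letters whose probability is below the
  threshold (no letter below ``1/z`` can take part in a valid factor);
* :func:`split_unsupported` cuts the string around positions left empty
  by the filter, since no valid factor can cross them;
* :func:`colour` classifies each position as WHITE (one certain
  letter), GREY (a single dominant letter with probability greater
  than ``1 - 1/z``) or BLACK (branching: no dominant letter).

Only BLACK positions allow more than one letter choice inside a valid
factor, which is what makes the downstream enumeration tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

__all__ = [
    "BLACK",
    "GREY",
    "WHITE",
    "WeightedPosition",
    "WeightedString",
    "Threshold",
    "Colouring",
    "WeightedRepetition",
    "filter_letters",
    "split_unsupported",
    "colour",
    "next_black",
    "reconstruct_v",
    "prob_ge",
    "prob_gt",
    "prob_close",
]

#: Relative tolerance for probability comparisons.  A value within this
#: tolerance of a bound counts as meeting ">=" (and as failing a strict ">").
TOL = 1e-9

BLACK = "B"
GREY = "G"
WHITE = "W"


def prob_close(a: float, b: float) -> bool:
    """True if two probabilities are equal within relative tolerance."""
    return abs(a - b) <= TOL * max(abs(a), abs(b))


def prob_ge(a: float, b: float) -> bool:
    """Tolerant ``a >= b``."""
    return a >= b or prob_close(a, b)


def prob_gt(a: float, b: float) -> bool:
    """Tolerant strict ``a > b``: values equal within tolerance do not count."""
    return a > b and not prob_close(a, b)


@dataclass(frozen=True)
class WeightedPosition:
    """One position of a weighted string: a letter -> probability map.

    Probabilities are strictly positive; on raw (unfiltered) input they
    must sum to 1 within ``1e-6``.  After filtering the sum may be below
    1 (probability mass of discarded letters is *not* renormalised).
    """

    entries: Tuple[Tuple[str, float], ...]

    def __post_init__(self) -> None:
        seen = set()
        for letter, p in self.entries:
            if letter in seen:
                raise ValueError(f"duplicate letter {letter!r} at a position")
            seen.add(letter)
            if not (0.0 < p <= 1.0 + 1e-6):
                raise ValueError(f"malformed probability {p!r} for letter {letter!r}")

    @classmethod
    def from_dict(cls, probs: Dict[str, float]) -> "WeightedPosition":
        # zero-probability letters are dropped on construction
        return cls(tuple(sorted((s, p) for s, p in probs.items() if p > 0.0)))

    def prob(self, letter: str) -> float:
        """Occurrence probability of ``letter`` (0 if absent)."""
        for s, p in self.entries:
            if s == letter:
                return p
        return 0.0

    def letters(self) -> Tuple[str, ...]:
        return tuple(s for s, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def sum(self) -> float:
        return sum(p for _, p in self.entries)


@dataclass(frozen=True)
class WeightedString:
    """A finite sequence of weighted positions over a fixed alphabet."""

    positions: Tuple[WeightedPosition, ...]
    alphabet: Tuple[str, ...]

    @classmethod
    def build(
        cls,
        positions: Iterable[Dict[str, float]],
        alphabet: Sequence[str] | None = None,
    ) -> "WeightedString":
        pos = tuple(WeightedPosition.from_dict(d) for d in positions)
        if alphabet is None:
            letters = sorted({s for wp in pos for s in wp.letters()})
            alphabet = tuple(letters)
        else:
            alphabet = tuple(alphabet)
            bad = {s for wp in pos for s in wp.letters()} - set(alphabet)
            if bad:
                raise ValueError(f"letters {sorted(bad)} outside declared alphabet")
        return cls(pos, alphabet)

    @classmethod
    def from_plain(cls, s: str, alphabet: Sequence[str] | None = None) -> "WeightedString":
        """Certain string: every position has a single probability-1 letter."""
        return cls.build(({c: 1.0} for c in s), alphabet)

    def __len__(self) -> int:
        return len(self.positions)

    def __getitem__(self, i: int) -> WeightedPosition:
        return self.positions[i]

    def __iter__(self) -> Iterator[WeightedPosition]:
        return iter(self.positions)

    def validate_raw(self) -> None:
        """Check per-position probability sums on raw (unfiltered) input."""
        for i, wp in enumerate(self.positions):
            if abs(wp.sum() - 1.0) > 1e-6:
                raise ValueError(
                    f"position {i}: probabilities sum to {wp.sum():.9f}, expected 1"
                )

    def word_probability(self, i: int, word: str) -> float:
        """Cumulative occurrence probability of ``word`` at position ``i``.

        Returns 0.0 if some letter of ``word`` does not occur.
        """
        if i < 0 or i + len(word) > len(self.positions):
            raise IndexError("word does not fit in the weighted string")
        prod = 1.0
        for k, a in enumerate(word):
            p = self.positions[i + k].prob(a)
            if p == 0.0:
                return 0.0
            prod *= p
        return prod


@dataclass(frozen=True)
class Threshold:
    """Cumulative weight threshold ``1/z`` with ``z >= 1``.

    ``ell`` is the bound ``log z / log(z/(z-1))`` on the number of BLACK
    positions any valid factor can contain: each black letter has
    probability at most ``1 - 1/z``, so ``(1 - 1/z)^ell >= 1/z`` pins
    down the maximum count.  It is 0 when ``z <= 1`` (no black positions
    can exist) and is only a useful bound for ``z >= 2``.
    """

    z: float

    def __post_init__(self) -> None:
        if not (self.z >= 1.0):
            raise ValueError(f"z must be >= 1, got {self.z!r}")

    @classmethod
    def from_value(cls, one_over_z: float) -> "Threshold":
        if not (0.0 < one_over_z <= 1.0):
            raise ValueError(f"threshold must lie in (0, 1], got {one_over_z!r}")
        return cls(1.0 / one_over_z)

    @property
    def value(self) -> float:
        """The threshold ``1/z`` itself."""
        return 1.0 / self.z

    @property
    def ell(self) -> float:
        if self.z <= 1.0:
            return 0.0
        return math.log(self.z) / math.log(self.z / (self.z - 1.0))

    def squared(self) -> "Threshold":
        """The relaxed threshold ``1/z**2`` used by the per-copy solver."""
        return Threshold(self.z * self.z)


@dataclass(frozen=True)
class Colouring:
    """Per-position BLACK/GREY/WHITE marks, stored as a compact string."""

    marks: str

    def __len__(self) -> int:
        return len(self.marks)

    def __getitem__(self, i: int) -> str:
        return self.marks[i]

    def black_positions(self) -> List[int]:
        return [i for i, m in enumerate(self.marks) if m == BLACK]


@dataclass(frozen=True, order=True)
class WeightedRepetition:
    """A tandem repeat ``v = u^e`` in a weighted string.

    ``i`` is the 0-based start, ``p = |u|`` the period, ``e >= 2`` the
    exponent, and ``b`` the set of ``(offset, letter)`` choices fixing
    ``u`` at the BLACK positions of its first copy.  Together with the
    weighted string (letters at non-black positions are forced) the
    quadruple reconstructs ``v`` uniquely; see :func:`reconstruct_v`.
    """

    i: int
    p: int
    e: int
    b: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.p < 1 or self.e < 2 or self.i < 0:
            raise ValueError(f"ill-formed repetition ({self.i},{self.p},{self.e})")

    def b_sorted(self) -> List[Tuple[int, str]]:
        return sorted(self.b)

    @property
    def span(self) -> Tuple[int, int]:
        return self.i, self.i + self.e * self.p


def filter_letters(ws: WeightedString, t: Threshold) -> WeightedString:
    """Drop every letter whose probability is below ``1/z``.

    Positions may become empty; the original position order (and count)
    is preserved so that coordinates still refer to the input string.
    Surviving probabilities are kept as-is, not renormalised, which
    makes the operation idempotent; raw-input sum validation happens on
    ingest and at the solver entry points instead.
    """
    thr = t.value
    new_positions = tuple(
        WeightedPosition(tuple((s, p) for s, p in wp.entries if prob_ge(p, thr)))
        for wp in ws.positions
    )
    return WeightedString(new_positions, ws.alphabet)


def split_unsupported(
    ws: WeightedString, t: Threshold
) -> List[Tuple[int, WeightedString]]:
    """Split a filtered string around positions that lost all letters.

    Returns ``(offset, segment)`` pairs; ``offset`` maps segment-local
    coordinates back to the original string.  No valid factor can cross
    an empty position, so segments are processed independently.
    """
    segments: List[Tuple[int, WeightedString]] = []
    start = None
    for i, wp in enumerate(ws.positions):
        if len(wp) == 0:
            if start is not None:
                segments.append((start, WeightedString(ws.positions[start:i], ws.alphabet)))
                start = None
        elif start is None:
            start = i
    if start is not None:
        segments.append((start, WeightedString(ws.positions[start:], ws.alphabet)))
    return segments


def colour(ws: WeightedString, t: Threshold) -> Colouring:
    """Assign B/G/W marks to a filtered, split weighted string.

    WHITE: a letter is certain (probability 1 within tolerance).
    GREY: exactly one letter has probability greater than ``1 - 1/z``
    (strictly; a probability of exactly ``1 - 1/z`` does not qualify).
    BLACK: no letter exceeds ``1 - 1/z`` -- the branching positions.
    For ``z < 2`` the bound ``1 - 1/z`` is below 1/2, so after filtering
    no position can be BLACK.
    """
    bound = 1.0 - t.value
    marks = []
    for i, wp in enumerate(ws.positions):
        if len(wp) == 0:
            raise ValueError(f"position {i} is empty; split the string first")
        if any(prob_ge(p, 1.0) for _, p in wp.entries):
            marks.append(WHITE)
        elif any(prob_gt(p, bound) for _, p in wp.entries):
            marks.append(GREY)
        else:
            marks.append(BLACK)
    return Colouring("".join(marks))


def next_black(c: Colouring) -> List[int]:
    """``NB[i]``: index of the leftmost BLACK position ``j > i``.

    The sentinel value ``len(c)`` means there is no black position to
    the right.  Computed in one right-to-left pass.
    """
    n = len(c)
    nb = [n] * n
    nxt = n
    for i in range(n - 1, -1, -1):
        nb[i] = nxt
        if c[i] == BLACK:
            nxt = i
    return nb


def reconstruct_v(
    rep: WeightedRepetition, ws: WeightedString, c: Colouring
) -> str:
    """Rebuild the concrete word ``v = u^e`` denoted by a quadruple.

    ``u[j]`` is taken from ``b`` when offset ``j`` is BLACK in the first
    copy; otherwise it is the unique letter stored at the first
    non-black occurrence of offset ``j`` in some copy of ``u``.
    """
    i, p, e = rep.i, rep.p, rep.e
    if i + e * p > len(ws):
        raise ValueError("repetition does not fit in the weighted string")
    bmap = dict(rep.b)
    u: List[str] = []
    for j in range(p):
        if j in bmap:
            u.append(bmap[j])
            continue
        letter = None
        for k in range(e):
            q = i + k * p + j
            if c[q] != BLACK:
                wp = ws[q]
                if len(wp) != 1:
                    raise ValueError(
                        f"non-black position {q} does not store a unique letter"
                    )
                letter = wp.letters()[0]
                break
        if letter is None:
            raise ValueError(
                f"offset {j} of the root is neither in b nor forced at any copy"
            )
        u.append(letter)
    return "".join(u) * e
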