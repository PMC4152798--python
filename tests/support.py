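"""Test-side helpers: oracle-equivalence checks shared by several suites."""

from __future__ import annotations

import random
from itertools import product as iter_product
from typing import List, Tuple

from wtrep import (
    Colouring,
    Threshold,
    WeightedString,
    brute_force_problem1,
    brute_force_valid_repetitions,
    filter_letters,
    is_primitive,
    reconstruct_v,
    solve_problem1,
    solve_problem2,
)
from wtrep.repetition_engine import _colour_with_gaps
from wtrep.weighted_core import prob_ge


def enumerate_valid_factors(
    ws: WeightedString, t: Threshold
) -> List[Tuple[int, str]]:
    """Every (start, concrete word) valid at ``1/z`` -- brute force.

    Enumerates letter choices position by position, pruning branches
    whose running product has already fallen below the threshold.
    """
    filtered = filter_letters(ws, t)
    thr = t.value
    n = len(filtered)
    out: List[Tuple[int, str]] = []
    for i in range(n):
        frontier = [("", 1.0)]
        for j in range(i, n):
            nxt = []
            for word, prob in frontier:
                for letter, p in filtered[j].entries:
                    np_ = prob * p
                    if prob_ge(np_, thr):
                        nxt.append((word + letter, np_))
            if not nxt:
                break
            out.extend((i, word) for word, _ in nxt)
            frontier = nxt
    return out


def check_problem2_equivalence(ws: WeightedString, t: Threshold) -> None:
    """Solver vs oracle, up to the break-up reporting convention.

    Every oracle repetition's span and root must be covered by an
    emitted quadruple of the same period and phase; every emitted
    quadruple must itself be valid (primitive root, whole span at or
    above the threshold).
    """
    solver = solve_problem2(ws, t)
    oracle = brute_force_valid_repetitions(ws, t)
    filtered = filter_letters(ws, t)
    c = Colouring(_colour_with_gaps(filtered, t))

    resolved = []
    for rep in solver:
        v = reconstruct_v(rep, filtered, c)
        assert is_primitive(v[: rep.p]), (rep, v)
        assert prob_ge(filtered.word_probability(rep.i, v), t.value), (rep, v)
        resolved.append((rep, v))

    for rep in oracle:
        v = reconstruct_v(rep, filtered, c)
        span_end = rep.i + rep.e * rep.p
        covered = any(
            s.p == rep.p
            and s.i <= rep.i
            and s.i + s.e * s.p >= span_end
            and (rep.i - s.i) % s.p == 0
            and sv[rep.i - s.i : rep.i - s.i + len(v)] == v
            for s, sv in resolved
        )
        assert covered, (rep, v, solver)


def check_problem1_equivalence(ws: WeightedString, t: Threshold) -> None:
    """Solver vs oracle: exact quadruple-set equality."""
    solver = solve_problem1(ws, t)
    oracle = brute_force_problem1(ws, t)
    assert solver == oracle, (solver, oracle)


def exhaustive_family(max_n: int):
    """The exhaustive small weighted family over a binary alphabet.

    Position kinds: each letter certain, the balanced 0.5/0.5 branch,
    and the skewed 0.75/0.25 position.
    """
    kinds = (
        {"a": 1.0},
        {"b": 1.0},
        {"a": 0.5, "b": 0.5},
        {"a": 0.75, "b": 0.25},
    )
    for n in range(2, max_n + 1):
        for combo in iter_product(range(len(kinds)), repeat=n):
            yield WeightedString.build([kinds[k] for k in combo], "ab")


# ---------------------------------------------------------------------------
# random weighted-string generation shared by equivalence sweeps

_POSITION_KINDS = (
    lambda rng, sigma: {rng.choice(sigma): 1.0},
    lambda rng, sigma: dict(zip(rng.sample(sigma, 2), (0.5, 0.5))),
    lambda rng, sigma: dict(zip(rng.sample(sigma, 2), (0.75, 0.25))),
    lambda rng, sigma: dict(zip(rng.sample(sigma, 2), (0.6, 0.4))),
    lambda rng, sigma: dict(zip(rng.sample(sigma, 3), (0.5, 0.3, 0.2))),
)


def random_weighted_string(rng: random.Random, max_n: int = 12) -> WeightedString:
    n = rng.randint(2, max_n)
    sigma = list("ab" if rng.random() < 0.7 else "abc")
    kinds = _POSITION_KINDS if len(sigma) >= 3 else _POSITION_KINDS[:-1]
    positions = [kinds[rng.randrange(len(kinds))](rng, sigma) for _ in range(n)]
    return WeightedString.build(positions, sigma)
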