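"""File formats and synthetic weighted-sequence generation.

Two input routes are supported:

* IUPAC-encoded DNA in FASTA.  Each ambiguity code expands to the
  uniform distribution over its base set (``M`` -> A/C at 0.5 each,
  ``N`` -> all four at 0.25); plain bases get probability 1.  This is a
  lossy convenience path -- real per-base probabilities cannot be
  expressed in FASTA.
* A native probability-matrix TSV: ``#``-prefixed header lines, the
  first being ``# alphabet: <letters>``, then one row per position with
  the 0-based index followed by one probability column per letter.
  Row sums must be 1 within 1e-6.

Results are written as a repetition-report TSV with fixed columns
(id, i, p, e, b, u, prob); it round-trips losslessly.

:func:`synthesize` builds test sequences with planted tandem repeats
and a controllable density of branching (two-letter, 0.5/0.5)
positions, returning the planted ground truth for recall checks.
"""

from __future__ import annotations

import contextlib
import math
import random
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

from .weighted_core import (
    Colouring,
    Threshold,
    WeightedRepetition,
    WeightedString,
    colour,
    filter_letters,
    next_black,
    reconstruct_v,
    split_unsupported,
)

__all__ = [
    "RepetitionRecord",
    "read_iupac_fasta",
    "read_probability_matrix",
    "write_probability_matrix",
    "write_repetitions",
    "read_repetitions",
    "records_for",
    "synthesize",
]

DNA_ALPHABET = ("A", "C", "G", "T")


def _expand_iupac(code: str, seq_id: str, pos: int) -> Dict[str, float]:
    bases = ambiguous_dna_values.get(code.upper())
    if bases is None or code.upper() == "X":
        raise ValueError(
            f"sequence {seq_id!r}: non-IUPAC character {code!r} at position {pos}"
        )
    p = 1.0 / len(bases)
    return {b: p for b in bases}


def read_iupac_fasta(path) -> List[Tuple[str, WeightedString]]:
    """Parse a FASTA file of IUPAC nucleotide sequences.

    Every ambiguity code becomes a uniform distribution over its base
    set; the alphabet is the four DNA bases.
    """
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        positions = [
            _expand_iupac(ch, record.id, i) for i, ch in enumerate(str(record.seq))
        ]
        out.append((record.id, WeightedString.build(positions, DNA_ALPHABET)))
    return out


def read_probability_matrix(path) -> WeightedString:
    """Parse the native probability-matrix TSV format."""
    alphabet: Tuple[str, ...] | None = None
    positions: List[Dict[str, float]] = []
    with _maybe_open(path, "r") as fh:
        expected = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("alphabet:"):
                    alphabet = tuple(body.split(":", 1)[1].split())
                continue
            if alphabet is None:
                raise ValueError(
                    f"line {lineno}: data row before '# alphabet:' header"
                )
            fields = line.split("\t")
            if len(fields) != 1 + len(alphabet):
                raise ValueError(
                    f"line {lineno}: expected {1 + len(alphabet)} columns, "
                    f"got {len(fields)}"
                )
            idx = int(fields[0])
            if idx != expected:
                raise ValueError(
                    f"line {lineno}: row index {idx}, expected {expected}"
                )
            expected += 1
            probs = {}
            for letter, field in zip(alphabet, fields[1:]):
                p = float(field)
                if not (0.0 <= p <= 1.0 + 1e-6):
                    raise ValueError(
                        f"row {idx}: probability {p!r} outside [0, 1]"
                    )
                if p > 0.0:
                    probs[letter] = p
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"row {idx}: probabilities sum to {total:.9f}, expected 1"
                )
            positions.append(probs)
    if alphabet is None:
        raise ValueError("missing '# alphabet:' header")
    return WeightedString.build(positions, alphabet)


@contextlib.contextmanager
def _maybe_open(path_or_handle, mode: str):
    if hasattr(path_or_handle, "write") or hasattr(path_or_handle, "read"):
        yield path_or_handle
    else:
        with open(path_or_handle, mode) as fh:
            yield fh


def write_probability_matrix(ws: WeightedString, path) -> None:
    """Serialise a weighted string in the native TSV dialect.

    ``path`` may be a filesystem path or an open text handle.
    """
    with _maybe_open(path, "w") as fh:
        fh.write(f"# alphabet: {' '.join(ws.alphabet)}\n")
        fh.write("# columns: pos\t" + "\t".join(f"p({a})" for a in ws.alphabet) + "\n")
        for i, wp in enumerate(ws.positions):
            row = "\t".join(f"{wp.prob(a):.10g}" for a in ws.alphabet)
            fh.write(f"{i}\t{row}\n")


@dataclass(frozen=True, order=True)
class RepetitionRecord:
    """One output row: a repetition of a named sequence, fully resolved."""

    seq_id: str
    i: int
    p: int
    e: int
    b: str  # semicolon-joined "offset:letter"
    u: str  # reconstructed root
    prob: float  # whole-span cumulative occurrence probability


def _serialise_b(b) -> str:
    return ";".join(f"{j}:{a}" for j, a in sorted(b))


def _parse_b(text: str):
    if not text:
        return frozenset()
    pairs = []
    for item in text.split(";"):
        j, a = item.split(":")
        pairs.append((int(j), a))
    return frozenset(pairs)


def records_for(
    seq_id: str,
    reps: Sequence[WeightedRepetition],
    ws: WeightedString,
    t: Threshold,
) -> List[RepetitionRecord]:
    """Resolve quadruples into report rows (root word and span probability).

    The root is reconstructed against the filtered string coloured at
    the threshold that defines branching positions for these outputs.
    """
    filtered = filter_letters(ws, t)
    marks = ["-"] * len(filtered)
    for offset, seg in split_unsupported(filtered, t):
        marks[offset:offset + len(seg)] = list(colour(seg, t).marks)
    c = Colouring("".join(marks))
    out = []
    for rep in reps:
        v = reconstruct_v(rep, filtered, c)
        prob = filtered.word_probability(rep.i, v)
        out.append(
            RepetitionRecord(
                seq_id, rep.i, rep.p, rep.e, _serialise_b(rep.b), v[: rep.p], prob
            )
        )
    return sorted(out)


_COLUMNS = ("id", "i", "p", "e", "b", "u", "prob")


def write_repetitions(records: Sequence[RepetitionRecord], path) -> None:
    """Write report rows as TSV with a fixed column order.

    ``path`` may be a filesystem path or an open text handle.
    """
    rows = sorted(records, key=lambda r: (r.seq_id, r.i, r.p, r.e, r.b))
    with _maybe_open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.seq_id}\t{r.i}\t{r.p}\t{r.e}\t{r.b}\t{r.u}\t{r.prob:.10g}\n"
            )


def read_repetitions(path) -> List[RepetitionRecord]:
    """Read back a repetition-report TSV."""
    out = []
    with _maybe_open(path, "r") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _COLUMNS:
            raise ValueError(f"unexpected header {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            seq_id, i, p, e, b, u, prob = line.split("\t")
            out.append(
                RepetitionRecord(seq_id, int(i), int(p), int(e), b, u, float(prob))
            )
    return out


def synthesize(
    n: int,
    alphabet: Sequence[str] = ("a", "b"),
    black_density: float = 0.05,
    planted: Sequence[Tuple[int, int]] = (),
    seed: int = 0,
    threshold: float = 0.5,
) -> Tuple[WeightedString, List[WeightedRepetition]]:
    """Random weighted string with planted tandem repeats.

    Plants each requested ``(period, exponent)`` at a random feasible
    start, separated by guard positions whose letters break the
    periodicity on both sides, so the planted start and exponent are
    exact.  Positions then become branching (two letters at 0.5 each)
    with probability ``black_density``, capped inside planted spans so
    that every copy stays valid at ``threshold`` (a copy with ``m``
    branching positions has probability ``0.5**m``); guard positions
    are never branched.  Deterministic under ``seed``.

    Returns the weighted string and the planted ground-truth
    quadruples (``b`` listing the branching offsets of the first copy).
    """
    if len(alphabet) < 2:
        raise ValueError("alphabet must contain at least two letters")
    rng = random.Random(seed)
    letters = [rng.choice(alphabet) for _ in range(n)]

    spans: List[Tuple[int, int, int]] = []  # (start, period, exponent)
    needed = sum(p * e + 2 for p, e in planted)
    if needed > n:
        raise ValueError(f"planted repeats need {needed} positions but n={n}")
    cursor = 0  # first position available for the next left guard
    slack = n - needed
    guard_positions: set = set()
    for p, e in planted:
        extra = rng.randint(0, slack) if slack > 0 else 0
        slack -= extra
        start = cursor + extra + 1  # left guard sits at start - 1
        root = _random_primitive(rng, alphabet, p)
        for k in range(p * e):
            letters[start + k] = root[k % p]
        # guards: break the periodicity immediately left and right
        left = start - 1
        letters[left] = rng.choice([a for a in alphabet if a != root[p - 1]])
        guard_positions.add(left)
        right = start + p * e
        if right < n:
            letters[right] = rng.choice([a for a in alphabet if a != root[0]])
            guard_positions.add(right)
        spans.append((start, p, e))
        cursor = right + 1

    # branching positions
    cap = int(math.floor(-math.log(threshold, 2) + 1e-9)) if threshold < 1 else 0
    copy_black_count: Dict[Tuple[int, int], int] = {}
    black_at: set = set()
    for q in range(n):
        if q in guard_positions or rng.random() >= black_density:
            continue
        owner = None
        for start, p, e in spans:
            if start <= q < start + p * e:
                owner = (start, p, e, (q - start) // p)
                break
        if owner is not None:
            key = (owner[0], owner[3])
            if copy_black_count.get(key, 0) >= cap:
                continue
            copy_black_count[key] = copy_black_count.get(key, 0) + 1
        black_at.add(q)

    positions: List[Dict[str, float]] = []
    for q in range(n):
        if q in black_at:
            other = rng.choice([a for a in alphabet if a != letters[q]])
            positions.append({letters[q]: 0.5, other: 0.5})
        else:
            positions.append({letters[q]: 1.0})
    ws = WeightedString.build(positions, alphabet)

    truth = []
    for start, p, e in spans:
        b = frozenset(
            (q - start, letters[q]) for q in range(start, start + p) if q in black_at
        )
        truth.append(WeightedRepetition(start, p, e, b))
    return ws, truth


def _random_primitive(rng: random.Random, alphabet: Sequence[str], p: int) -> str:
    from .partitioning import is_primitive

    while True:
        root = "".join(rng.choice(alphabet) for _ in range(p))
        if is_primitive(root):
            return root
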