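# wtrep — tandem repeats in weighted (probabilistic) sequences

`wtrep` finds **all tandem repeats in a weighted string**: a sequence in
which each position holds a probability distribution over the alphabet
rather than one certain letter. Weighted DNA sequences arise from
IUPAC-encoded genomes (the ambiguity code `M` means A or C, each with
probability 0.5), from SNP annotation, and from base-caller
uncertainty. Tandem repeats — two or more adjacent copies of the same
segment — are central to studies of replication slippage, unequal
crossing-over, and microsatellite variation, and the probabilistic
model is one way to admit the approximate copies biologists actually
observe.

## The model

A weighted string *x* of length *n* assigns each position *i* a set of
pairs (*s*, π<sub>i</sub>(*s*)) with Σ<sub>s</sub> π<sub>i</sub>(*s*) = 1.
A concrete word *u* **occurs** at *i* if every letter has positive
probability there, and is **valid** for a cumulative weight threshold
1/*z* ∈ (0, 1] when ∏<sub>j</sub> π<sub>i+j</sub>(*u*[j]) ≥ 1/*z*.

A repetition *v* = *u*<sup>e</sup> (*e* ≥ 2, *u* primitive) is reported
as a quadruple **(i, p, b, e)**: start, period, exponent, and the set
*b* of (offset, letter) choices fixing *u* at the *branching* (black)
positions of its first copy — everywhere else the letter is forced.
Two notions of presence are solved, in optimal O(*n* log *n*) time for
fixed 1/*z*:

* **every-copy validity** (the main problem, `solve_problem1`): each
  occurrence of *u* in *v* is valid at 1/*z*;
* **whole-span validity** (`solve_problem2`): the entire *u*<sup>e</sup>
  is valid at 1/*z*.

The pipeline filters letters below 1/*z*, splits around unsupported
positions, colours positions black/grey/white by branching behaviour,
generates *extended factors* around black positions (every valid factor
occurs in one), runs a maximal-repetition partitioner over each factor,
and either breaks the results at the longest-valid-factor (LF) boundary
(whole-span) or composes chains of overlapping valid squares generated
at the relaxed threshold 1/*z*² (every-copy). Brute-force oracles for
both problems and for the plain-string partitioner ship with the
package and back the test suite.

## Worked example

The 7-position weighted string *x* = `aab[(a,0.5)(b,0.5)][(a,0.5)(b,0.5)]ab`
at threshold 1/*z* = 1/4:

```python
from wtrep import Threshold, WeightedString, solve_problem1

x = WeightedString.build(
    [{"a": 1}, {"a": 1}, {"b": 1},
     {"a": 0.5, "b": 0.5}, {"a": 0.5, "b": 0.5},
     {"a": 1}, {"b": 1}],
    "ab",
)
for rep in solve_problem1(x, Threshold.from_value(0.25)):
    print(rep.i, rep.p, rep.e, sorted(rep.b))
```

prints

```
0 1 2 []
1 2 3 []
2 1 3 []
2 2 2 [(1, 'a')]
3 1 2 [(0, 'b')]
3 1 3 [(0, 'a')]
3 2 2 [(0, 'a'), (1, 'b')]
4 1 2 [(0, 'a')]
```

Reading a few rows: `1 2 3 []` is *v* = `ababab` — three copies of
`ab` from position 1; both branching positions are forced by other
copies, so *b* is empty and each copy has probability ≥ 1/4.
`3 2 2 [(0,'a'),(1,'b')]` is the same run's suffix square starting at
position 3, where both offsets of the first copy now sit on branching
positions and must be spelled out. `3 1 2 [(0,'b')]` and
`3 1 3 [(0,'a')]` show genuinely different letter choices at position 3
giving different repetitions (`bb` versus `aaa`).

The same computation from the shell, via the native probability-matrix
TSV (one row per position, one probability column per letter):

```
$ wtrep find --matrix ex.tsv --threshold 0.25 --problem all
id      i  p  e  b        u   prob
matrix  0  1  2           a   1
matrix  1  2  3           ab  0.25
matrix  2  1  3           b   0.25
matrix  2  2  2  1:a      ba  0.25
matrix  3  1  2  0:b      b   0.25
matrix  3  1  3  0:a      a   0.25
matrix  3  2  2  0:a;1:b  ab  0.25
matrix  4  1  2  0:a      a   0.5
```

(`prob` is the whole-span cumulative occurrence probability of the
reconstructed word.) `--problem valid` switches to whole-span validity,
`--report maximal` suppresses the per-copy suffix families, `--input`
accepts IUPAC FASTA, `wtrep synth` generates seeded test data with
planted repeats, and `wtrep oracle` runs the brute-force reference on
inputs up to length 16.

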