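# rnaloops

Pseudoknot-aware annotation of RNA secondary structures.

Most loop definitions used in RNA bioinformatics (the Nearest-Neighbor
Model's hairpins, bulges, internal loops and multibranch junctions) are
only well defined for pseudoknot-free structures. `rnaloops` implements a
generalized decomposition that works for arbitrary matchings — including
pseudoknots — and coincides with the classical one when no base pairs
cross. It is aimed at structural bioinformaticians who need uniform,
searchable motif annotations over collections of secondary structures.

## What it computes

Given a chain of `n` nucleotides and a secondary-structure matching
(pairs `(i, j)`, 1-based):

* **Stems** — maximal stacked runs `(i, j), (i+1, j−1), …, (i+k, j−k)`
  with `k ≥ 1`; the first pair is the *face*, the last the *internal
  pair*, the fragments `[i, i+k]` and `[j−k, j]` the *wings*. A
  *standard* stem contains only Watson–Crick or G·U wobble pairs. A pair
  `(m, n)` *crosses* a face `(i, j)` when `m < i < n < j` or
  `i < m < j < n` — the defining relation of pseudoknots.
* **Elementary closed regions (ECRs)** — intervals no pair of which
  connects inside to outside, not splittable into smaller closed
  regions, anchored on stem faces. *Classical* when the interval is
  itself a face, otherwise a *pseudoknot*. ECRs form a forest (nested
  children inside parents).
* **Loops** — one per stem `H` with internal pair `(r, s)`: the
  positions inside `(r, s)` not strictly inside any stem lying within
  `H`; equivalently `[r+1, s−1]` with `H`-related ECRs excised, their
  boundary *faces* kept. Faces split a loop into *sides* (possibly of
  zero length). Two label axes: hairpin / internal / bulge /
  multiple-junction, and classical / isolated / pseudoknotted (a loop
  containing a wing of a crossing stem is pseudoknotted).
* **Pseudoknot signatures** — each pseudoknotted ECR is summarized as a
  word pairing lower/upper-case letters at arc ends, at three levels:
  *full* (all member stems), *upper* (nested ECRs removed), *reduced*
  (parallel stem families — bands — collapsed). Reduced words name the
  classic topologies: `abAB` H-knot, `abAcBC` kissing hairpins,
  `abcABC` triple knot.
* **Tertiary-interaction taxonomy** — annotated tertiary pairs are
  labeled Helix–Helix / Helix–Loop / Loop–Loop, local vs long-range,
  and pseudoknot vs classical context, and tabulated as a contingency
  table with percentage blocks.

Input formats: extended dot-bracket (bracket families for pseudoknots),
CT, BPSEQ and a DSSR-like TSV pairs table (which may carry
Leontis–Westhof labels and canonical flags for tertiary pairs). Output:
versioned JSON reports plus flat TSV tables.

## Worked example

The built-in `figure3` fixture is a 31-nt pseudoknot with six stems:

```python
import rnaloops as rl
from rnaloops.ecr import ECRKind

s = rl.fixture_figure3()
print(rl.write_dotbracket(s))
ann = rl.annotate(s)
pk = next(e for e in ann.ecrs if e.kind is ECRKind.PSEUDOKNOTTED)
print("full   ", rl.full_signature(pk).word)
print("upper  ", rl.upper_signature(pk).word)
red = rl.reduced_signature(pk)
print("reduced", red.word, "->", rl.named_class(red).value)
```

prints

```
((.((((.((.)).))[[.[[)).))]].]]
full    abcdDCefBAFE
upper   abcdBADC
reduced abAB -> H_knot
```

The full word lists all six stems end by end; removing the two stems
inside the nested classical region gives the upper word; collapsing the
two parallel families leaves two mutually crossing arcs — an H-knot.

Loops are per-stem, even inside pseudoknots. For the `figure1` fixture
(five stems, one crossing another):

```python
ann = rl.annotate(rl.fixture_figure1())
loop = ann.loops[0]           # loop of stem with face (9, 48)
print([(sd.start, sd.end) for sd in loop.sides])
print([(f.i, f.j, f.tag.value) for f in loop.faces])
print(loop.wings_contained, loop.size_class.value, loop.pk_class.value)
```

```
[(11, 17), (32, 33), (44, 46)]
[(18, 31, 'pseudoknot_face'), (34, 43, 'stem_face')]
[(13, 15)] multiple_junction pseudoknotted
```

Three sides separated by two faces (one bounding a nested pseudoknot,
one a stem), with the wing 13–15 of the crossing stem lying inside the
first side: a pseudoknotted multiple junction.

## Command line

```sh
rnaloops fixtures --name hknot              # ((..[[....))..]]
rnaloops annotate input.ct --out reports/   # JSON + TSV reports
rnaloops stats *.dbn --json
rnaloops search *.ct --query "signature=abAB AND loop=bulge OR min_stems=6"
rnaloops generate --length 120 --stems 6 --pk-prob 0.4 --seed 7
```

Search queries are disjunctions of conjunctions (`AND` binds tighter
than `OR`) of elementary predicates: `signature=WORD[@level]`,
`loop=LABEL`, `min_stems=N`, `max_stems=N`, `seq=REGEX`,
`dotbracket=REGEX`.

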