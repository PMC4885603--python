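# Methods

This note documents the definitions the package implements, the
algorithms behind them, the synthetic data used to exercise them, and
the design decisions taken where the underlying notions left room.

## Model

The object of study is an RNA secondary structure: a chain of `n`
nucleotides (1-based positions, all intervals inclusive) with a set of
base pairs forming a matching. "Base pair" throughout means a
complementary pair — Watson–Crick (`A·U`, `C·G`) or wobble (`G·U`);
pair typing is symmetric and any pair involving `N` is *other*.
Tertiary contacts (non-canonical pairs, possibly carrying
Leontis–Westhof labels) ride on top of the matching as annotations and
never participate in the topological decomposition.

### Stems

A stem is a stacked run `(i, j), (i+1, j−1), …, (i+k, j−k)` with
`k ≥ 1`, i.e. at least two pairs. Detection scans the pair set for
maximal diagonal runs; maximality is required (a run extendable inward
or outward is not a stem) so that contiguous stacks are single stems.
Runs of length 1 are *isolated pairs*: they are excluded from every
downstream computation by default, because the closed-region conditions
are built from stems. An exploratory `keep_isolated` mode promotes them
to 1-pair arbitrary pseudo-stems and is marked nonstandard. *Standard*
stems admit only complementary pairs and are the default; a run may mix
Watson–Crick and wobble pairs (both are complementary). Without a
sequence, standard typing is impossible; detection falls back to
arbitrary with a warning rather than failing.

### Elementary closed regions

`[i, j]` is a closed region when no pair has exactly one endpoint
inside it; elementary when no `t` strictly inside yields a closed
`[i, t]` or `[t, j]`; and its ends must be anchored on faces — either
`(i, j)` is a stem face (classical ECR) or positions `x, y` inside
exist with `(i, x)` and `(y, j)` stem faces (pseudoknotted ECR). The
anchoring condition is what keeps stem interiors (e.g. `[2, 5]` in
`((..))`) from counting as regions of their own.

The fast decomposition expands, at each stem-face left end not yet
claimed, the minimal closed interval anchored there: start from the
partner of the left end, and grow the right bound while any enclosed
position is paired beyond it; a pair pointing left of the anchor rules
the anchor out. Minimality of this expansion implies elementarity, and
anchoring at face left ends implies the face condition; both
implications are nevertheless re-verified literally for every emitted
interval (the structures are small; the check is cheap insurance
against pathological inputs). Recursing into each found interval yields
the children, giving the ECR forest. Closure only ever depends on pairs
with exactly one endpoint in the candidate, so pairs fully enclosing a
candidate are transparent — this is why nested ECRs exist inside
pseudoknots at all.

An independent oracle enumerates all `O(n²)` intervals and applies the
four conditions verbatim; the two routes are compared on hundreds of
seeded random structures in the tests and the acceptance script.

Positions outside every top-level ECR (dangling ends, linkers) belong
to no ECR and are reported as exterior segments.

### Loops

For a stem `H` with internal pair `(r, s)`, the H-ECR conditions are
the ECR conditions relativized to the open interval `(r, s)`: a pair
reaching from inside a candidate to a position *outside* `(r, s)`
entirely does not break closure. That relativization is exactly what
lets a wing of a stem crossing `H` sit inside `H`'s loop (the wing
cannot anchor an H-ECR of its own, because its partner positions lie
outside `(r, s)` and so cannot supply the face condition). Only
outermost H-ECRs are returned; whether H-ECRs may nest is not settled
by the definitions, and the outermost reading is the one under which
the loop equivalence below holds (recorded as an interpretation).

The loop of `H` is computed directly from the membership rule — the
positions inside `(r, s)` not strictly inside the face of any stem
lying within `H` — and independently cross-checked (in tests, on
hundreds of structures) against the equivalent formulation
`[r+1, s−1]` minus H-ECR interiors. H-ECR boundary pairs are kept in
the loop as *faces*, tagged `stem_face` (classical region) or
`pseudoknot_face`. Sides are the runs between consecutive delimiters
(`r`, face ends, `s`); a zero-length side is represented explicitly as
an empty interval anchored between its delimiters, which is what makes
bulges (internal loops with an empty side) detectable. Hairpin loops
have exactly one side even when empty.

Size classes — hairpin (0 faces), internal (1 face; bulge if a side is
empty), multiple junction (≥ 2 faces) — and pseudoknot classes —
pseudoknotted (contains a wing of a crossing stem), isolated (no
wings), classical (no wings and no pseudoknot faces; every classical
loop is isolated) — are total and deterministic. Loops are in
bijection with stems. On pseudoknot-free structures the decomposition
is checked loop-for-loop against a classical Nearest-Neighbor-Model
oracle that knows nothing about H-ECRs (it reads loops off the stem
nesting tree).

A wing of a crossing stem is asserted to lie either wholly inside or
wholly outside a loop; a partial overlap raises rather than silently
producing an inconsistent annotation.

### Signatures

Each pseudoknotted ECR maps to arcs: one per member stem, with ends at
the leftmost coordinate of each wing. Since wings inside one ECR never
interleave coordinate-wise with another wing's interior, any consistent
end convention yields the same word; the leftmost-coordinate choice is
asserted collision-free rather than assumed. Letters are assigned in
alphabetical order of left ends; the word lists letters in end order,
lower case at left ends, capitals at right ends. Beyond 26 arcs,
indexed letters `a1/A1, …` are used and the word is serialized with
dot-separated tokens.

Levels: *full* uses all member stems (including those inside nested
ECRs of either kind); *upper* removes every stem inside a child ECR
and its subtree; *reduced* collapses parallel families. Two arcs are
parallel (in one band) when one properly nests inside the other and
both cross exactly the same set of other arcs; families are connected
components of this relation, verified to be cliques, and collapsed
simultaneously to their spanning arcs — crossing sets are family-level
invariants, so a single pass is idempotent (property-tested, and
cross-checked against an iterative pairwise-merging reducer). Reduced
words `abAB`, `abAcBC` and `abcABC` are recognized as H-knot, kissing
hairpins and triple knot; everything else is `other`.

### Tertiary-interaction taxonomy

Positions map to elements with helix priority: a stem-wing position is
helix even when the wing lies inside another stem's loop (a
`loop_priority` flag inverts this for sensitivity analysis); otherwise
the position's loop; otherwise its exterior segment. In pseudoknotted
structures loops of crossing stems genuinely overlap, so "the" loop of
a position is made deterministic by choosing the owner with the
smallest internal-pair span (ties: leftmost). Pair labels:

* structure type HH/HL/LL from the two elements (exterior counts as
  loop and is flagged);
* locality: local when both endpoints share an element, or when one is
  a stem and the other a loop adjacent to it — the stem's own loop, a
  loop carrying the stem's face among its faces, or a loop containing
  one of the stem's wings. The adjacency rule set is constructive;
  the notion itself is only exemplified in the literature ("between
  hairpin loop and its stem"), so the three cases are a recorded
  interpretation;
* context: pseudoknot when the innermost ECR enclosing either endpoint
  is pseudoknotted (one-endpoint rule, a recorded choice), else
  classical.

Tabulation produces counts over context × locality × structure type,
plus two percentage blocks: *fractions of structure types* (each
context × locality row renormalized across HH/HL/LL) and *fractions of
pair types* (each structure-type column renormalized across rows);
occupied rows/columns sum to 100%. Corpus-level percentages from 3D
databases are out of scope — the package computes tables only from
caller-supplied tertiary pairs.

## Synthetic data

The figure fixtures (`figure1`, `figure3`, and the three named motifs)
are minimal hand-built structures realizing every published statement
about the corresponding worked examples: wing coordinates, side and
face lists, H-ECR counts and the signature chain
`abcdDCefBAFE → abcdBADC → abAB`. Where a figure underdetermines a
detail (the exact arcs inside the nested pseudoknotted region of
`figure1`), the minimal two-crossing-stem realization is used; tests
re-check every caption-level assertion so the fixtures cannot drift.
Fixture sequences are simple complementary fills (cycled Watson–Crick
pairs, `A` elsewhere) — enough for standard-stem typing, with no
thermodynamic meaning.

The random generator plants `n_stems` stacked runs of 2–4 pairs in a
chain (defaults: length 100–150 in the test suites), rejecting
placements that touch or neighbor existing stems so at least one
unpaired spacer separates wings and detection provably recovers the
planting log. With probability `pk_prob` per stem (0.3–0.5 in the
suites) a placement is required to cross an existing stem, producing
pseudoknots of varied topology; `pk_prob = 0` yields pseudoknot-free
structures for the NNM comparison. Sequences are complementary with a
10% wobble rate. Identical seeds give identical structures; infeasible
configurations raise after bounded retries.

What the generator does *not* emulate: thermodynamic plausibility,
realistic loop-length or stem-length distributions, base-composition
bias, and DSSR-style noise (multiplets, modified residues). Passing
tests therefore demonstrate combinatorial correctness of the
annotation, not biological realism of the inputs.

## Numerical / procedural choices

* Problem sizes: oracle agreement is measured on 300 structures of
  length ≤ 120 and NNM equivalence on 200 pseudoknot-free structures of
  length ≤ 150 — large enough to exercise nested pseudoknots, small
  enough that the quadratic brute-force oracles stay comfortable.
* Multiplets (a position in two canonical pairs, possible in
  DSSR-derived tables) are a hard parse error by default;
  `resolve_multiplets="first"` keeps the first-listed pair and demotes
  the rest to tertiary annotations. The loop/ECR machinery requires a
  matching, so silent acceptance is not an option.
* Dot-bracket family precedence is fixed (`()`, `[]`, `{}`, `<>`,
  `Aa`…`Zz`) and families are assigned by greedy coloring of the
  pair-crossing conflict graph in ascending left-end order — output is
  deterministic and minimal for the nesting classes the greedy order
  produces, though not guaranteed globally minimal.
* `min_pairs < 2` is rejected in stem detection (`k ≥ 1` forbids
  1-pair stems); isolated pairs are handled by the explicit
  `keep_isolated` mode instead.
* Degenerate inputs: empty structures annotate to empty reports; a
  stem whose internal pair encloses nothing yields a hairpin with a
  single zero-length side.

## Known limitations

* No 3D ingestion: base pairs and Leontis–Westhof labels must be
  supplied (e.g. exported from DSSR); the package never computes them.
* One chain per structure; multi-model and multi-chain selection is
  the caller's job.
* Signature computation assumes the arc-end collision-freedom that
  holds for stems inside one ECR; exotic inputs violating the internal
  assertions fail loudly rather than approximately.
* Search predicates cover annotation only (no ions, ligands or entry
  metadata).
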