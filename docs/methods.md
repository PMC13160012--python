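# Methods

## Data model

A dataset is a set of tables (`TreeSequenceData`): nodes (age `time` in
generations before present, sample flag, optional population and label),
edges (`left`, `right`, `parent`, `child` with `time[parent] >
time[child]`), sites/mutations, and a sample-metadata frame. Coordinates
are 0-based, half-open `[start, end)`, floating point, matching the
succinct tree-sequence convention; the CSV genealogy dialect adopts the
same. Binary `.trees`/`.tsz` containers are decoded with tskit, but every
downstream computation operates on this package's tables, and the loader
re-validates all invariants, naming the first offending row. When the codec
itself refuses an invalid container, the loader falls back to raw table
decoding so validation errors still point at rows rather than at the codec.

Validation rejects: non-finite or negative node times, parent-not-older
edges, inverted or out-of-bounds spans, overlapping spans for one child,
non-increasing site positions, and dangling table cross-references.

## Local-tree decoding

The genealogy changes only at breakpoints `b_0 = 0 < … < b_K = L`, the
sorted distinct edge endpoints plus the sequence bounds. Decoding is an
incremental sweep over two edge orderings — insertion by `(left,
time[parent], parent, child)`, removal by `(right, time[parent], parent,
child)`. At each breakpoint **all removals are applied before all
insertions**, so a child switching parents never transiently has two; the
time component of the sort keys makes emission order (and therefore every
serialized payload) deterministic, while correctness does not depend on
within-breakpoint order. The sweep state is reversible: stepping backward
undoes insertions then re-applies removals in exact inverse order, which is
what the involution tests (`+1` then `−1` restores the parent array
element-wise) exercise.

Random access (`tree_at`) takes a deliberately different route: binary
search over breakpoints, then a direct filter of edges whose span contains
the query point. Keeping two independent routes to the same answer is the
package's main internal correctness check, and the test suite adds two
external ones: re-encoding random fixtures through tskit and comparing
parent arrays, and decoding an msprime ancestry simulation.

Multiple roots per interval are supported (a `roots` list); isolated
non-sample nodes are simply absent from it. Window extraction returns
boundary-straddling trees with **un-clipped** intervals so interval markers
can be drawn truthfully.

## Layout

Tips are placed on a unit grid in the configured order and normalized into
the tree's horizontal slot; internal nodes sit at the arithmetic mean of
their children's x (deterministic, and keeps the parent bracketed by its
children); branches are right-angle polylines (vertical riser, horizontal
run). Vertical scales: `linear` (y = t), `log` (y = log10(1+t), for
deep-time data), `rank` (y = rank of t among the window's distinct node
times; evens out bursts of recent coalescence). All three are strictly
increasing, so child-below-parent holds under each. Default tip order is
the fixed global sample order: it keeps every sample at the same relative
x across consecutive trees, which is what makes lineage tracing across
breakpoints legible; ladderized (clade size, ties by smallest tip id) and
metadata-sorted orders are options. Slots are uniform by default or
proportional to genomic interval length; `tree_gap_fraction` (default 0)
reserves a fraction of each slot as padding. A window shares one y domain
(the maximum transformed node time over its frames). Canvas coordinates
are abstract (`[0,1]` horizontally); pixel mapping belongs to renderers.

## Annotation

Palettes are deterministic: category labels sorted lexicographically,
colour index = position mod 12 over a fixed qualitative cycle embedded in
the code, so outputs are byte-stable. Numeric columns are rejected
(continuous ramps are out of scope). "Filter" is a render-state notion
(dim non-matching samples); "subset" is structural: `subset_simplify`
keeps the nodes on paths from the chosen samples to their MRCA, splices
out unary pass-throughs, and preserves original ids and times — hence
pairwise TMRCAs are provably unchanged, which the tests check on 1,000
random pairs. Mutation marks anchor on the branch above their node at
fraction `(i+1)/(k+1)` from the child (a lone mutation at the midpoint),
ordered by site position; a mutation above a root anchors at the root with
an `above_root` flag. BED features are clipped to `[0, L]`, intersected
with the breakpoint partition (covered tree indices are always a
consecutive run), and the chromosome column is ignored — the data model is
single-sequence.

## Topology comparison

Consecutive trees are compared by (a) the sweep's per-breakpoint edge
removals/insertions and the children whose parent changed, and (b) a
rooted Robinson–Foulds distance over sample-leaf clades (size ≥ 2, full
set excluded): `rf = |C_a Δ C_b|`. Rooted clades rather than unrooted
bipartitions because local genealogies are rooted; clades restricted to
sample leaves so trees with disjoint internal node ids are comparable.
The bedGraph export assigns each tree the RF value at its left breakpoint,
with 0 for the first tree.

## Payload and service

A window serializes to three Arrow IPC record batches in one framed byte
stream (magic tag, batch count, per-batch length prefix; schema version in
each batch's schema metadata, mismatch is a hard error). Node rows are in
postorder within each tree — a renderer can draw children before parents
in one pass — with `parent_slot` as a within-tree row offset (−1 for
roots). Canvas coordinates travel as float32 (GPU-buffer practice, 1e-6
relative round-trip tolerance); genomic positions and node times as
float64, bit-exact. The HTTP layer is a thin stateless wrapper: all request
state lives in the URL, so responses are repeatable byte-for-byte and
cacheable. A window covering more than `max_trees` local trees is answered
with 413 and an instruction to zoom in; the library-level pipeline instead
truncates to the first `max_trees` trees and sets a flag, so embedding
callers can choose either behaviour. The SVG exporter consumes only the
payload bytes — it is the proof that the payload contract suffices for a
client.

## Synthetic data

The generator is bespoke and seeded. *Independent* mode draws a Kingman
coalescent tree per interval: while k lineages remain, the next coalescence
waits Exp(k(k−1)/2), i.e. times are in coalescent units (one unit = 2N
generations for an effective size N); samples are contemporaneous at time
0. *Linked* mode starts from one such tree and applies one random
detach/reattach (SPR-like) move per breakpoint: a non-root node is detached,
its unary parent spliced out, and it is reattached under a fresh internal
node at a uniform time within a compatible branch's span (or above the
root, with an Exp(1) increment). This guarantees valid node times by
construction and produces the positive topological autocorrelation between
adjacent trees that recombination produces — the tests confirm mean
adjacent RF in linked mode is below the independent-pairs baseline.
Edges unchanged across consecutive intervals are written once with a merged
span, so generated tables are genuinely succinct. Interval boundaries are
uniform draws; mutations are placed at uniform positions on a uniformly
chosen branch of the local tree.

What the simulator does **not** emulate: demography, selection, mutation
models (states are fixed A→T), correlated breakpoint spacing, ancient
samples, or realistic ARG edge-sharing beyond single-move adjacency.
Passing tests therefore establish algorithmic correctness on valid inputs
of realistic shape, not statistical realism of the genealogies themselves;
the msprime cross-check covers one realistic input family end to end.

## Numerical and design choices

- CSV `depth` is interpreted as the max root-to-tip path length — the only
  scalar that converts branch lengths to absolute node times with
  ultrametric tips anchored at 0; an ancient sample simply gets a positive
  time. Computed times below −1e-9 (configurable) are an error; smaller
  negative round-off is clamped to 0.
- CSV intervals must tile `[0, L)` exactly; gaps and overlaps are errors,
  as is a tip-set mismatch between rows (both offending rows are named).
  Adjacent identical topologies are not merged. Tip times are fixed by the
  first row; a later row disagreeing by more than 1e-6 is an error.
- Exported floats use the shortest exact round-trip representation, so the
  CSV round-trip preserves node-time multisets to well below the 1e-9 test
  tolerance and golden files are byte-stable.
- Multi-root trees cannot be written to the single-Newick CSV dialect and
  are rejected at export with a clear message.
- Degenerate layouts: a single tip sits at slot centre (x = 0.5); an empty
  window is an error everywhere (extraction, layout, rendering).
- The acceptance script and the desk-scale test use 1,000 samples × 500
  intervals (≈2,500 nodes, ≈4,000 edges) with a 20-tree render window, and
  the oracle suites use ≤30 samples × ≤50 intervals × 100 fixtures — sizes
  chosen so the whole verification cycle stays interactive on one CPU
  while still covering every code path at non-trivial scale.

## Known limitations

- No crossing-minimization between adjacent trees (tanglegram
  optimization) and no force-directed full-ARG graph layout; the unit is
  the per-interval local tree.
- Unrooted/weighted RF, SPR and quartet distances are not provided.
- `.trees` writing, in-place table editing, polytomy resolution,
  multi-chromosome data, GFF tracks, and continuous colour ramps are out
  of scope.
- The HTTP service is single-dataset, read-only GET, unauthenticated — a
  streaming backend contract, not a hosted platform.
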