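# argview

Server-side decoding, layout, and streaming of **local genealogies** from
succinct tree sequences — the computational core of an ancestral
recombination graph (ARG) browser, usable headlessly from Python or a shell.

An ARG records the full history of coalescence and recombination behind a
sample of genomes. Its succinct *tree-sequence* encoding stores that history
as tables of **nodes** (genomes, each with an age in generations) and
**edges** (parent–child links, each active on a half-open genomic interval
`[left, right)`), so that structure shared by neighbouring genealogies is
stored once. The genealogy at any genomic position *p* is the forest of
edges whose interval contains *p*; it changes only at *breakpoints* — the
distinct edge endpoints. `argview` turns those tables into something a
renderer can draw, for datasets where materialising every tree up front is
not an option:

- **decode** the local tree for any genomic window on demand, by an
  incremental edge sweep (insertions ordered by `(left, time[parent],
  parent, child)`, removals by `(right, …)`, removals first at a shared
  breakpoint), with random access via binary search plus a direct
  point-query as an independent second route;
- **lay out** trees in genomic-position × coalescent-time space (linear,
  `log10(1+t)`, or time-rank vertical scales; per-tree slots of uniform or
  genomic width; stable, ladderized, or metadata-driven tip orders);
- **annotate** with sample metadata (deterministic 12-colour palettes,
  search, structural subsetting that preserves pairwise TMRCAs), mutation
  marks anchored on branches, and BED tracks;
- **compare** consecutive topologies: per-breakpoint edge edits, changed
  nodes, and rooted Robinson–Foulds distances (clades of sample leaves;
  `rf = |C_a Δ C_b|`, even, ≤ 2(n−2)), exportable as a bedGraph track;
- **stream** windows as compact Arrow IPC payloads (postorder node rows,
  within-tree parent slots, float32 canvas coordinates, float64 genomic
  positions and times) over a stateless HTTP API, and render them to SVG
  from the payload bytes alone.

Inputs: tskit `.trees` containers (and `.tsz` when `tszip` is installed), or
a CSV dialect with one rooted Newick genealogy per recombination interval
(`start,end,newick,depth`, where `depth` is the max root-to-tip path length
used to anchor branch lengths to absolute node times). A seeded simulator
(independent-coalescent or linked detach/reattach modes) generates valid
synthetic datasets, so nothing needs downloading.

## Worked example

Simulate nothing — use the built-in two-tree fixture (3 samples on a
sequence of length 10, breakpoint at 5, topologies `((0,1),2)` then
`((1,2),0)`):

```sh
$ python -c "import argview as av; av.write_csv_genealogies(av.make_fixture_f1(), 'demo.csv')"
$ argview info demo.csv
sequence_length: 10
samples: 3
nodes: 7
edges: 8
trees: 2
$ argview difftrack demo.csv -o rf.bedgraph && cat rf.bedgraph
seq	0	5	0
seq	5	10	2
$ argview render demo.csv --start 0 --end 10 -o demo.svg
```

The bedGraph says the genealogy is unchanged across `[0,5)` (first tree,
value 0 by convention) and that crossing the breakpoint at 5 replaces one
sample clade with another: rooted RF distance 2 (`{{0,1}}` vs `{{1,2}}`).
The SVG shows both trees side by side with breakpoint ticks at 0, 5, 10.

The same window through the payload route:

```python
>>> import argview as av
>>> ts = av.make_fixture_f1()
>>> data, _ = av.window_payload(ts, av.WindowRequest(0, 10, color_column="population"))
>>> av.deserialize_window(data).trees
 tree_index  start  end  depth  rf_left
          0    0.0  5.0    2.0        0
          1    5.0 10.0    2.0        2
>>> len(data)
3264
```

3264 bytes carry both trees' geometry, parent structure, node times,
population colour codes, and the one mutation mark — everything
`export_svg` (or a GPU client) needs, with no further access to the tables.

`argview serve demo.csv --port 8080` exposes the same pipeline over HTTP
(`/info`, `/window`, `/metadata/{column}`, `/search`, `/difftrack`);
windows covering more than `--max-trees` local trees return 413 and ask the
client to zoom in.

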