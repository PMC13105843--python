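# Methods

## The view model

phylostack treats a "view" of a compositional dataset as a pure value: a
rooted labeled tree `H` over taxa, an abundance matrix `X` (samples × taxa,
non-negative, rows *not* required to sum to one), and a `ViewState`
consisting of a set of collapsed nodes, an insertion-ordered log of paint
assignments (node → palette index), a palette with a cursor, and an
advisory `frozen` flag.  Everything downstream — the effective
composition, both panel layouts, the SVG — is a deterministic function of
these values, which is what makes interaction sessions replayable and
snapshot-testable.

### Trees

Hierarchies are rooted and need not be binary; an internal node may have
any number (≥1) of children.  Child order is data: it comes from the
Newick text or the first-appearance order in a taxonomy table and is never
re-sorted, because it induces `leaf_order`, the depth-first left-to-right
leaf sequence that fixes the vertical order of both panels.  Leaf labels
must be unique — they are the join key to the abundance columns — while
internal labels may repeat (taxonomic homonyms under different parents are
distinct nodes, disambiguated internally by their path).  Newick branch
lengths are parsed and stored but unused: the layout is a cladogram
(depth-based), matching how taxonomies, which have no meaningful branch
lengths, are usually drawn.

Taxonomy rank tables (columns ordered coarse → fine, one row per taxon)
convert to trees by making one internal node per distinct rank-path prefix.
Missing cells are simply skipped — a row's path is its non-missing cells in
rank order — rather than spawning "unclassified" placeholder nodes; this
keeps the tree minimal and leaves the interpretation of gaps to the user.
A synthetic root is added only when the table has more than one top-level
name.

### Collapse, aggregation, conservation

The *visible frontier* of a state is the depth-first traversal that does
not descend into collapsed nodes: uncollapsed leaves plus maximal collapsed
nodes.  Aggregation assigns each frontier node the sum of its descendant
leaves' columns, so per-sample totals are conserved exactly (integer
arithmetic is exact in double precision far beyond realistic count sizes).
Collapse states nest and are stored, not rewritten: expanding a node
restores the interior exactly, including collapsed descendants, because
activity is *derived* from the collapse set rather than mutated into the
paint log.

### Painting and color resolution

Paints live in an insertion-ordered log.  A paint whose node is hidden
inside a collapsed subtree is *suspended* — excluded from the legend and
from color resolution — and restored verbatim on expand.  A palette color
held only by suspended paints returns to a free pool; `next_color` offers
pooled colors first (FIFO by first appearance in the log) and otherwise
issues the cursor color, advancing the cursor modulo the palette length, so
without suspensions the issued sequence is 0, 1, …, L−1, 0, … for a
palette of length L.  A pooled color is offered until a paint actually
consumes it.  The default palette is a fixed six-color colorblind-safe set
(an Okabe–Ito subset), overridable in the style config.

Segment colors resolve by **nearest painted visible ancestor**: painting a
node colors its entire visible subtree, and a deeper paint overrides a
shallower one on the leaves it covers.  A collapsed node's single merged
rectangle follows the same rule — its own paint if any, else its nearest
painted ancestor, else the neutral gray (`#cccccc` by default).  When a
subtree that contained several paints is collapsed, the merged rectangle
therefore does *not* blend them; it takes the collapsed node's own
resolved color.  This was a genuinely open choice; consistency with the
resolution rule won.

The `frozen` flag mirrors the freeze-for-export toggle of an interactive
session.  It is carried through serialization for provenance but does not
gate operations: in a scripted setting there is no concurrent interaction
to lock out.

## Sample arrangement

Three orderings: verbatim input order (the user encodes time or design in
the file), dendrogram leaf order from agglomerative clustering, and the
grouped variant in which groups are laid out contiguously (first-appearance
or user-supplied order) and clustered independently within each group —
the standard way to compare two treatment arms side by side.

Clustering defaults to **complete linkage on Euclidean distance** between
community composition vectors, the common recipe for this display; both
the linkage and the metric (Euclidean or Bray–Curtis) are options.  The
agglomeration is scipy's (`scipy.cluster.hierarchy.linkage`), which is
deterministic for a fixed input; we do not impose a custom tie-break
inside the merge sequence, since re-implementing agglomeration to control
ties on measure-zero events would trade a well-tested code path for a
cosmetic guarantee.  Ties we do control — centroid and medoid
equidistance — break toward the smallest original sample index.  Values
are clustered on the scale given (no internal relative-abundance
normalization), since inputs are deliberately allowed to be
non-compositional.

Bray–Curtis, BC(x, y) = Σ|x_k − y_k| / Σ(x_k + y_k), is bounded in [0, 1]
for non-negative data with at least one positive entry per pair; it is
**not** a metric (the triangle inequality can fail), which is why it backs
medoid selection but no geometry.  A pair of all-zero samples has no
defined dissimilarity and raises an error naming the samples.

Representative selection cuts the complete-linkage dendrogram into `k`
clusters (`k` is user-supplied; no automatic selection) and reports one
member per cluster: the sample nearest the cluster mean (Euclidean) for
`"centroid"`, or the member minimizing summed Bray–Curtis dissimilarity to
its cluster for `"bc-medoid"`.  Clusters are reported in dendrogram
leaf-order of first appearance.

## Layout

The canvas (default 960 × 600 abstract units, origin top-left, y downward)
splits into a tree panel and a bar panel.  Tree layout uses the
even-leaf-spacing convention: the i-th of n frontier nodes sits at the
center of the i-th of n equal vertical bands, internal nodes at the mean y
of their children, x proportional to topological depth among visible
nodes.  Only visible nodes are laid out, so collapsing genuinely redraws
the tree into the freed space.  Bar segments stack top-to-bottom in
frontier order, so the i-th tree row and the i-th segment of every bar
correspond — the linkage invariant the tests assert.  Normalized mode
scales each bar to full panel height; raw mode shares one global scale set
by the largest arranged sample total, so bar heights encode totals.
Zero-valued segments are kept in the layout with zero height (stable
sample × leaf addressing for tests) and dropped only at render time.

Hover targeting is the nearest-site (Voronoi) partition over the laid-out
node positions; the Delaunay triangulation of the sites is kept on the map
(when ≥3 affinely independent sites exist) and the query itself is an
exact nearest-site computation, ties going to the smaller pre-order
index.  Delivering this as a pure query function rather than an event
stream is what makes hover behavior unit-testable.

## SVG export

A small SVG 1.1 subset (rect, line, circle, text, g), no CSS, no script.
Determinism is a contract: fixed attribute order, coordinates printed to
two decimals, fonts referenced by family name only, element ids derived
from node/sample ids.  Collapsed nodes get stroke width × a multiplier
(default 2.5).  Sample labels render beneath the bars and can be hidden
wholesale (the static analog of hide-until-hover).  The `"on-subtree"`
label mode places each legend label at its painted subtree root instead of
in the legend block.

## Synthetic data generator

`synth` emulates a two-arm 16S-style experiment: a random taxonomy
(single kingdom; the phylum level always splits into ≥2 blocks so a
planted clade has a non-trivial complement; 1–3-way splits below), then
zero-inflated rounded log-normal counts.  Defaults: 20 samples per group,
24 OTUs over Kingdom/Phylum/Class/OTU, leaf baselines `Normal(3.0, 0.9)`
on the log scale, within-sample log-noise 0.9, structural-zero probability
0.2, and a 4-fold enrichment of the largest phylum in the treatment group.
The noise scales were set by a one-time Monte-Carlo calibration so that the
empirical treatment/control fold on the target clade lands within ×[3, 5.3]
in ≥95% of seeds at the default size — dispersed enough to be non-trivial,
concentrated enough that the planted effect is recoverable.  Treatment
values on target leaves are control-law draws multiplied by the fold
*before* rounding, so the noise-free limit recovers the fold exactly.
Counts are rounded log-normals, not multinomial draws, precisely so that
per-sample totals differ and the raw-bar mode is exercised.

What the generator does **not** emulate: taxon–taxon correlation,
compositional closure (no fixed sequencing depth), overdispersion beyond
log-normality, longitudinal structure, and realistic taxon name
distributions.  Passing tests therefore demonstrate the machinery —
conservation, ordering, geometry, rendering — not robustness to the full
messiness of real sequencing data.

## Numerical and degenerate-input choices

* Conservation is exact for integer inputs; for reals the tests allow
  1e-9 relative slack (column-sum reordering).
* An all-zero sample yields zero-height segments in normalized mode rather
  than an error.
* Fewer than two samples: clustering returns input order with a warning.
* `k = n` representatives: every sample represents itself.
* Collapsing a leaf is a no-op; expanding a non-collapsed node is a logged
  no-op; collapse is idempotent.
* Search is case-insensitive substring over *all* labels, internal and
  leaf, in pre-order (the narrower alternatives — leaves only, exact
  match — are easy to express by filtering the result).
* Degenerate hover sites (collinear, <3 points) simply omit the stored
  triangulation; the query is exact regardless.

## Known limitations

* No branch-length-proportional tree layout (cladogram only).
* No ordination-based (PCoA/NMDS) sample ordering and no optimal-leaf-order
  dendrogram rearrangement.
* No label-collision avoidance in the SVG beyond hiding sample labels.
* Bray–Curtis clustering uses the dissimilarity matrix directly with
  complete linkage; no correction for its non-metricity is attempted.
* The CLI reads whole tables into memory; it targets study-scale inputs
  (thousands of samples × thousands of taxa), not streaming scale.
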