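# Methods

## Skeletonization model

`netvec` treats an elongated binary shape as a polygon (with holes) and
derives its skeleton from a constrained Delaunay triangulation (CDT) of
the polygon interior — the chordal-axis construction originally used for
character vectorization. Triangles are classified by how many of their
edges are shared with another triangle (internal edges): *isolated* (0),
*end* (1), *sleeve* (2), *junction* (3). The skeleton then follows from
three local rules:

* a junction triangle contributes a junction node at its centroid;
  junction triangles that share an internal edge are merged into a
  single node at their joint centroid, which avoids zero-length edges at
  wide crossings;
* an end triangle contributes a tip node at its boundary vertex opposite
  the internal edge, so branches extend to the visible end of the shape;
* a chain of sleeve triangles contributes an edge whose trajectory
  threads the midpoints of the successive shared edges.

Every trajectory waypoint is materialized as a degree-2 *redundant*
node, so the full graph retains the curvature of every branch; the
redundancy level `r ∈ {0, 1, 2}` (none / half / all redundant nodes)
only controls how much of that geometry is kept when the graph is
reduced or saved. Reduction merges chains exactly: lengths and triangle
counts are summed and radii recombined as length-weighted means, so the
total network length is invariant under `r` to floating-point accuracy.

Radii are local half-widths: the Euclidean distance transform of the
mask, sampled bilinearly at nodes and waypoints. An edge's radius is the
mean of its trajectory samples; after chain merging it is the
length-weighted mean, which makes the network-level mean radius R̄ a
length-weighted quantity (a long thin vein influences R̄ in proportion
to its extent).

Pure cycles (a ring with no junction or tip) keep one deterministic
anchor node — the node with the smallest (y, x) position — so the loop
survives reduction as a self-loop on the anchor.

## Pruning

Contour kinks produce short surplus branches. `prune(g, p)` removes
every dangling branch (tip-to-junction path) whose total triangle count
is strictly less than `p`; `p` is measured in triangles, not pixels, so
the threshold scales with the local triangulation density. Each sweep
decides all removals on the sweep-start graph and applies them at once
(this makes the result independent of tip enumeration order), then
collapses junctions whose degree dropped to 2 into through-edges, and
iterates to a fixed point. Two safeguards keep pruning conservative:
edges between two junctions are never candidates, and a junction that
would lose *all* incident branches spares its longest one — a bare tree
therefore reduces to its longest chain rather than vanishing, and pure
path components are never pruned at all. `p = 0` is the identity.

## Numerical and geometric choices

* **Coordinates**: 0-based pixel indices, origin top-left, x = column,
  y = row; node positions are sub-pixel.
* **Contours**: marching squares at level 0.5 on the padded mask
  (8-connected foreground), assembled into an outer ring plus hole
  rings. The contour is simplified by Douglas–Peucker with a default
  tolerance of **1.0 px**. This default matters: a rasterized boundary
  carries a ±0.5 px staircase, and tolerances below that leave wiggles
  that the CDT turns into cascades of spurious end/junction triangles —
  enough to corrupt branch topology. One pixel is the smallest tolerance
  that removes the staircase entirely; the cost is sub-pixel boundary
  detail that the skeleton does not use.
* **Densification**: after simplification, boundary segments longer
  than `max_segment` (default 10 px) are subdivided with vertices *on*
  the rings (never interior Steiner points), so sleeve chains sample the
  width of long straight branches instead of spanning them with a few
  skinny triangles.
* **Triangulation**: GEOS' constrained Delaunay triangulation via
  shapely; all ring edges are constrained, all vertices come from the
  rings.
* **Tie-breaks**: largest-component ties go to the component containing
  the first foreground pixel in raster order; equal-length graph
  components are kept by node count, then smallest node id; the r=1
  reduction drops every second interior node counting from the
  lower-id end of each chain.
* **Adaptive threshold**: foreground where intensity exceeds the
  arithmetic block mean by more than `offset` (reflective borders).
  The block mean is intentionally the simplest local statistic; its
  known weakness is that a bright neighbor structure raises the local
  mean and can sever a dim thin branch crossing a dark noise patch.

## Synthetic validation data

The round-trip harness generates known planar networks and rasterizes
them into noisy grayscale images:

* **Geometry**: `n_points` nodes sampled with a minimum-separation
  constraint in the image (default 100 nodes in 512 × 512 px), joined by
  their Euclidean minimum spanning tree; a fraction (default 0.1) of
  extra edges reticulates the tree. An extra edge is admitted only if it
  does not short-circuit a 2-hop path, meets its neighbors at ≥ 35°, and
  keeps clearance from unrelated nodes and edges — loops therefore
  enclose real mesh faces, as in leaf venation, instead of slivers.
* **Radii**: taper linearly with hop distance from a root near the
  center, from 6 px down to 2 px, emulating a vein hierarchy.
* **Rendering**: each edge is stroked at width 2 × radius with a
  per-edge intensity drawn from 0.5–1.0, composited over zero-mean
  Gaussian noise with correlation length 5 px and standard deviation
  0.1, and blurred by a 1-px Gaussian.

What this emulates: uneven staining/illumination (correlated noise),
branch-to-branch contrast variation (per-edge intensity), optical blur.
What it does **not** emulate: intensity gradients across the field,
broken or occluded branches, out-of-plane crossings of a 3-D structure
(the source of spurious junctions in projected tracheoles), or textured
backgrounds. Passing round-trip errors therefore bound the error of the
*extraction machinery* on well-segmentable images; they say nothing
about segmentation quality on pathological real data.

## Round-trip experiment and observed behavior

The reference experiment uses 30 networks (seeds 1–30), segmentation
with block size 51 px, offset 0.14, closing radius 1 and hole filling up
to 30 px² — the per-dataset tuning step any user of the pipeline
performs once per image family — followed by extraction with `p = 3`,
`r = 0`. Both graphs are reduced to `r = 0` before comparing node
counts, so the comparison is topological. With the default seeds the
mean errors are about 6 % for N, 6–7 % for L and 2–3 % for R̄ (run
`scripts/acceptance.py` to recompute them). The error distributions are
strongly skewed: most networks re-extract almost perfectly, while an
occasional network loses a sub-tree when the additive local-mean
threshold severs one dim branch (see above) and the largest-component
rule then discards everything behind the break.

Known biases: tips extend to the end of the rendered round cap, adding
roughly one radius of length per tip; junction regions can split into
two nearby junction nodes when a sleeve triangle separates their
junction triangles, slightly inflating N on shapes with shallow branch
angles; measured radii inherit any dilation/erosion bias of the
segmentation.

## Scope and limitations

Only 2-D images are handled. No gap-filling heuristics are applied —
a disconnected mask stays disconnected, by design, because invented
links are worse than visible breaks. Interactive graph editing is
exposed as a batch API (JSON edit scripts) rather than a GUI. The
legacy pickled-graph format is not emitted; GraphML and JSON carry the
same information portably.
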