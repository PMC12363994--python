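# Methods

This note records the model as implemented, the conventions the
implementation had to fix where the mathematics leaves a free choice, the
defaults and why, what the synthetic generators do and do not emulate, and
the numerical decisions a maintainer would need to know.

## Bracket state sum for linkoids

A linkoid diagram is produced by orthogonal projection of a polyline
collection along a unit vector ξ, with depth recorded per vertex.  Each
transverse crossing stores the over/under assignment (larger depth wins)
and a sign.  The bracket of a diagram with c crossings is computed by exact
enumeration of all 2^c states over a port graph: each crossing contributes
four ports (over-in/out, under-in/out), strand arcs connect consecutive
ports along each component, and a state's smoothing choice pairs the ports
crossing-by-crossing.  Tracing the union of the two pairings yields the
closed-loop count and, for open components, the endpoint pairing Ŝ.  The
segment cycles are the connected components of the multigraph on the
endpoint labels whose edges are the 2-cycles of L̂ and of Ŝ — equivalent to
the orbit construction Seg(a) = Orb(a) ⊔ Orb(L̂(a)) under L̂∘Ŝ, and always
of even size.  A state contributes A^σ d^(circ + cyc − 1); for a diagram
with no open component cyc = 0 and the sum reduces to the classical
Kauffman bracket (checked against a recursive skein-expansion oracle in the
test-suite).  The open-case normalization admits a free global d-factor;
the exponent circ + cyc − 1 is the unique choice that assigns 1 to a single
arc, 1 to a single circle, d to two disjoint arcs, and the classical
d^(|S|−1) to links.

### Conventions fixed by this implementation

* **Crossing sign**: +1 when the under-strand direction is counterclockwise
  from the over-strand direction in the projection plane.  Mirroring the
  collection negates every sign and replaces A by A⁻¹ in all polynomials;
  Jones values of chiral objects are defined up to t ↔ 1/t.
* **A-smoothing**: when the sign is +1 the A-smoothing joins over-in to
  under-out and over-out to under-in (the regions swept by rotating the
  over-strand counterclockwise merge).  This correlation between sign and
  smoothing is what makes the normalized bracket a projection invariant for
  closed curves; it is pinned down by the Reidemeister-I test (a kinked
  unknot normalizes to exactly 1) and the per-direction invariance test.
* **Endpoint labels**: the head of an open component is its first vertex;
  the j-th open component carries labels (2j−1, 2j), so L̂ is always
  (1,2)(3,4)…  Closed components carry no labels.  Any consistent choice
  gives the same segment-cycle counts.

## Sphere average

The integral over projection directions is evaluated by a fixed quadrature:
a spherical Fibonacci lattice by default (deterministic, well-spread;
n = 100 directions unless stated), or i.i.d. uniform directions from a
seed.  Irregular projections (tangencies, triple points, crossings at
vertices or endpoints, depth ties — a measure-zero set of directions) are
detected with tolerance 1e−9 and evaded by rotating ξ by at most 1e−4 rad
with a seeded jitter, retrying up to 10 times before raising.  Per-direction
normalized brackets are averaged coefficient-wise; evaluation at t uses
A = t^(−1/4) (real for t > 0; complex t is out of scope).  The default
evaluation point is t = 10.

Because the quadrature is finite and fixed, the sphere average is a
*piecewise-constant* function of the curve coordinates: each direction's
bracket depends only on the combinatorial diagram, which is locally stable.
Sufficiently small perturbations therefore often change nothing at all,
and stability tests assert bounded, non-increasing drift rather than
strictly positive continuous drift.

The state sum is exponential in the crossing count; diagrams with more than
`crossing_cap` = 20 crossings raise by default.  Callers may instead skip
such directions (`skip_overfull`), excluding them from the average and
reporting the skipped count — appropriate for feature pipelines where a
rare pathological direction should not abort a whole matrix.

## Segmentation, distances, retraction

Residue chains are segmented by cutting at midpoints between consecutive
representative points (Cα atoms): segment i runs midpoint(c_{i−1},c_i) → c_i
→ midpoint(c_i,c_{i+1}), terminal segments half-length; concatenation
reproduces the chain exactly.  Two segment metrics are provided: the
**representative** metric d(c_i, c_j) (the default, and the protein
convention), and a **sup** metric — the symmetrized supremum of
point-to-polyline distances sampled at 32 points per edge — for the generic
"upper bound" reading; the choice is an argument everywhere, and a distance
matrix is computed once and reused by all shells so every scale sees one
metric.  Adjacent midpoint segments share an endpoint; before any Jones
computation each segment in a sub-collection is retracted by 10⁻⁶ of its
length at both ends, making the components disjoint open curves without
measurably moving them.

## Multi-scale characteristic matrix

Entry (i, k) is the Jones value at t of the shell
P^i_{[r_k, R_k)} = {l_j : r_k ≤ d(l_i,l_j) < R_k} ∪ {l_i} — half-open, so a
segment at exactly r is in and at exactly R is out, and l_i is always
included (a lone segment gives the trivial value 1).  Identical shell index
sets share one Jones evaluation.  The B-factor scheme is r = 4 to 15 Å in
steps of 0.25 Å with R = r + 1 (45 shells sliding over 4–16 Å, chosen
around the ≈3.8 Å Cα spacing).  The normalized matrix is the column-wise
z-score with zero-variance columns mapped to zero; z-scoring is the
standard regression normalization and is idempotent.

## Facet persistence and weights

Critical values are the sorted distinct pairwise distances (ties grouped
within 1e−9 and represented by their mean).  The Vietoris–Rips complex at
parameter r is the clique complex of the graph with edges d ≤ r (closed
threshold, so births are attained); its facets are the maximal cliques,
enumerated per critical value with networkx and diffed between consecutive
values.  A vertex set's bar starts at the first critical value where it is
maximal (0 for vertices — every vertex is initially its own facet) and ends
at the first where it is absorbed; a set absorbed at the same value it
would appear is never a facet.  The final all-vertex facet never dies; its
bar is drawn open-ended (optionally capped at the largest critical value in
plots) and excluded from length statistics.

Each facet of up to `max_weight_size` segments (default 8) is weighted by
the Jones value at t of its segment sub-collection.  Two conventions:
**raw** is J(t) itself; **relative** (the default) subtracts the
crossing-free baseline d(t)^(|F|−1), so a facet whose segments never
project to a crossing weighs exactly 0 — this is the convention under which
single-segment facets report weight 0, matching how such barcodes are read
in the protein literature.  Larger facets are left uncomputed (their state
sums are exponential in the projected crossing count) unless forced.

Note an empirical subtlety: two *consecutive* helix segments span ≈200° of
twist, and a small fraction of projection directions does see them cross,
so adjacent-pair facets of an ideal helix have relative weights of order
−0.4 to 0 rather than exactly 0; on barcode color scales spanning tens of
units this is visually zero.

## Weighted diagrams and the bottleneck distance

Bars with equal (birth, death, weight) — within 1e−9 — collapse to one
diagram point with a multiplicity, per facet dimension; the multiplicities
agree with the alternating-sum-of-β definition (asserted in the tests).
The weighted bottleneck distance is the infimum over partial matchings of
the maximum of matched costs max(|Δbirth|, |Δdeath|, |Δweight|) and
unmatched half-persistences (death − birth)/2; points with infinite death
may only match each other.  It is computed exactly: binary search over the
finite candidate-cost set with a bipartite feasibility test
(diagonal-augmented maximum matching, scipy) at each candidate.  Because
unmatching is always available at half-persistence, the weight term can
dominate the distance only for bars whose persistence exceeds twice the
weight gap — a direct consequence of the definition worth remembering when
reading weighted distances between short-lived features.

## B-factor pipeline

A chain is reduced to Cα atoms (altlocs resolved by highest occupancy,
ties alphabetically; residues without Cα skipped with a warning), featurized
with the 45-shell normalized characteristic matrix at t = 10, and fit with
Lasso regression, ℓ1 penalty 0.16 on the z-scored features — an in-sample,
per-protein fit scored by the Pearson correlation between fitted and
experimental B-factors, the convention of the flexibility-prediction
literature.  A constant experimental vector is flagged degenerate; a fit
whose penalty zeroes every coefficient reports correlation 0.

With 45 features, an in-sample fit on a short chain can fit noise (p ≥ n),
so association claims about *shuffled* features are scored differently:
`crossval_bfactor` reports the out-of-fold (5-fold) prediction correlation,
which is ≈0 under row permutation while the planted-signal recovery keeps
the in-sample convention.  Benchmark-scale dataset correlations require
downloading external protein sets and heavy Jones computation; the pipeline
supports such runs (via the CLI `bfactor` subcommand) but the shipped
validation uses synthetic chains.

## Synthetic generators

The generators define the test conditions: an ideal α-helix (radius 2.3 Å,
rise 1.5 Å, twist 100°; consecutive Cα distance 3.83 Å, d(i,i+2) = 5.43 Å,
d(i,i+3) = 5.05 Å), two parallel straight strands (intra 3.8 Å, inter
4.8 Å), fixed-coordinate polygonal links (planar square unknot, 12-gon
trefoils of both chiralities sampled from the standard parametric trefoil,
two linked octagons), an open trefoil arc whose endpoint gap is a
controlled fraction of the diameter, and seeded uniform-in-ball vertex
perturbations.  They emulate the geometry that drives the method — regular
secondary-structure spacing, genuine entanglement, controlled noise — but
not side chains, hydrogen-bond irregularity, missing residues, or
crystallographic artifacts; tests passing on them validate the machinery,
not performance on real crystal structures.  Real structures enter through
the PDB reader and the CLI.

## Problem sizes and runtimes

The shipped tests and the acceptance script run at desk scale by choice:
16–120 quadrature directions depending on the accuracy a check needs
(counts and exact-zero weights need few; convergence comparisons share one
120-direction lattice), 19-residue helices for barcode counts and the
characteristic-matrix drift, an 8-residue helix for bottleneck stability so
that every facet weight is computable under the crossing cap, and weights
up to facet size 3 in the acceptance script (the 0/1/2-facet panels).
These sizes reproduce every targeted quantity; larger systems scale the
same pipelines at higher cost.

## Known limitations

* The state sum is exact but exponential; no polynomial-time Jones
  approximation is provided.
* Polylines only — no splines, no periodic boundary conditions.
* Real-coefficient evaluations at t > 0 only.
* Facet tracking recomputes maximal cliques per critical value; adequate to
  a few hundred segments, not for thousands.
* The sphere average at finite quadrature is piecewise constant in the
  coordinates; quantities change discretely as directions cross tangency
  configurations.
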