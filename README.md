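# knotjones

Multi-scale and persistent Jones polynomials for collections of open or
closed curves in 3-space — knot data analysis for structures that are not
actual knots.

## The problem

Polymers, protein backbones, and other filamentous structures are open
curves: classical knot invariants do not apply to them, and even for closed
curves those invariants are global, blind to *where* the entanglement sits.
`knotjones` implements two localizations of the Jones polynomial for
practitioners in structural bioinformatics and curve data analysis:

* the **multi-scale Jones polynomial**: a segments × distance-shells matrix
  of Jones values quantifying how entangled each curve segment is with its
  neighborhood at every length scale, and
* the **persistent Jones polynomial**: a Vietoris–Rips *facet* barcode over
  the segment distance matrix in which every facet (maximal simplex) is
  weighted by the Jones value of the curve segments it spans, compared
  across structures with a weighted bottleneck distance.

## The model

A projection of a collection of disjoint open/closed curves along a
direction ξ ∈ S² is a *linkoid diagram*: planar arcs with labeled endpoints
G = {1,…,2n}, endpoint pairing L̂ = (1,2)(3,4)…(2n−1,2n), and signed
crossings.  A state S chooses an A- or B-smoothing at every crossing; after
smoothing, closed loops are counted by |S|circ and the surviving open
strands induce a pairing Ŝ whose interaction with L̂ partitions G into
*segment cycles*, counted by |S|cyc.  The bracket is the state sum

    ⟨L⟩ = Σ_S A^σ(S) · d^(|S|circ + |S|cyc − 1),   d = −A² − A⁻²,

with σ(S) = #A − #B (and |S|cyc = 0 when no component is open, recovering
the classical link bracket).  The writhe-normalized bracket
f = (−A³)^(−Wr) ⟨L⟩, averaged over projection directions,

    f_L = (1/4π) ∫_{ξ∈S²} (−A³)^(−Wr((L)ξ)) ⟨(L)ξ⟩ dξ,

is the Jones polynomial of the 3-space collection; evaluations substitute
A = t^(−1/4) (real for t > 0; t = 10 throughout the applications).  For
closed curves this is the classical Jones polynomial; for open curves it is
a real-coefficient, continuous measure of entanglement that converges to
the classical one as the endpoints close up.

Localization: a segmentation P_n = l_1,…,l_n of the collection (for
proteins, one segment per residue, cut at Cα–Cα midpoints) with distances
d(l_i, l_j) yields (i) shell neighborhoods
P^i_{[r,R)} = {l_j : r ≤ d(l_i,l_j) < R} ∪ {l_i} whose Jones values at t
fill the n×m characteristic matrix, and (ii) a Vietoris–Rips facet
filtration whose bars (birth, death, Jones weight) form the persistent
Jones barcode.  Both are stable: an ε-perturbation of the curves moves
matrix entries and barcode points by only a small amount.

## Worked example

```python
from knotjones import (make_polygonal_knot, jones, make_ideal_helix,
                       segment_at_midpoints, distance_matrix, weighted_barcode)

# sphere-averaged Jones polynomial of a polygonal trefoil
jv = jones(make_polygonal_knot("trefoil"), n_directions=50)
print(jv.polynomial)   # +1*A^4 +1*A^12 -1*A^16
print(jv.at(10.0))     # 0.10089999999999999

# persistent Jones barcode of an ideal 19-residue alpha-helix
seg = segment_at_midpoints(make_ideal_helix(19))
B = weighted_barcode(seg, distance_matrix(seg), max_weight_size=3)
print(len(B.bars_of_dimension(0)))   # 19
print(len(B.bars_of_dimension(1)))   # 34
```

The trefoil's polynomial is A⁴ + A¹² − A¹⁶ = t⁻¹ + t⁻³ − t⁻⁴, the
classical Jones polynomial of the (left-handed) trefoil, identical in every
projection direction because the curve is closed; at t = 10 it evaluates to
0.1009.  The helix barcode shows 19 single-residue facets (each born at
r = 0, dying at the Cα spacing 3.83 Å, Jones weight exactly 0 — a lone
segment is unentangled), and 34 one-dimensional facets: 18 adjacent-residue
pairs persisting to 5.433 Å plus 16 short-lived i/i+3 pairs — the helix's
hydrogen-bond-register geometry read off from the filtration.

A command-line interface mirrors the library:

```sh
knotjones fixtures helix --out helix.txt --n-residues 19
knotjones persist helix.txt --out bars.csv --plot bars.png
knotjones bfactor structure.pdb --chain A
```

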