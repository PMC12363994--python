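"""Facet persistence of Vietoris–Rips filtrations, Jones weights, and the
weighted bottleneck distance.

Unlike persistent homology, which tracks homology classes, the persistent
Jones polynomial tracks *facets* — the maximal cliques of the Vietoris–Rips
threshold graph — through the filtration built from a segment distance
matrix.  Each facet is born at the first critical value where its vertex
set is maximal and dies when it is absorbed into a larger clique; the facet
is weighted by the Jones value (at fixed t) of the sub-collection of curve
segments it spans.  Barcodes of weighted facets, grouped by dimension,
are summarized as weighted diagrams and compared with a bottleneck distance
whose matching cost includes the weight difference:

    c(I, J) = max(|birth diff|, |death diff|, |weight diff|),
    c(unmatched I) = (death − birth) / 2.

Conventions: the VR edge rule is closed (d <= r), so births are attained;
0-facets are born at r = 0; the final all-vertex facet never dies (+inf).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .curves import DistanceMatrix, Segmentation, subcollection
from .jones import JonesSettings, TooManyCrossingsError, loop_value

__all__ = [
    "FacetBar",
    "WeightedBarcode",
    "WeightedDiagram",
    "Matching",
    "critical_values",
    "facet_filtration",
    "weighted_barcode",
    "diagram_from_barcode",
    "bottleneck_weighted",
]

_TIE_TOL = 1e-9


# --------------------------------------------------------------------------
# critical values and the facet filtration
# --------------------------------------------------------------------------

def critical_values(D: DistanceMatrix, tol: float = _TIE_TOL) -> np.ndarray:
    """Sorted distinct pairwise distances, ties grouped within ``tol``.

    These are the only parameters at which the Vietoris–Rips complex can
    change; each group of ties is represented by its mean.
    """
    n = D.n
    if n < 2:
        return np.array([])
    vals = np.sort(D.entries[np.triu_indices(n, k=1)])
    groups = []
    cur = [vals[0]]
    for v in vals[1:]:
        if v - cur[-1] <= tol:
            cur.append(v)
        else:
            groups.append(cur)
            cur = [v]
    groups.append(cur)
    return np.array([float(np.mean(g)) for g in groups])


def _maximal_cliques(D: DistanceMatrix, r: float, tol: float = _TIE_TOL) -> set:
    """Facets (maximal cliques) of the threshold graph with edges d <= r."""
    n = D.n
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.where(np.triu(D.entries <= r + 0.5 * tol, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return {frozenset(c) for c in nx.find_cliques(g)}


@dataclass
class FacetBar:
    """A facet's vertex set with its life-span and Jones weight.

    ``weight`` is None while uncomputed (facets larger than the weighting
    size cap).  ``dimension`` is |vertex_set| − 1.
    """

    vertex_set: frozenset
    birth: float
    death: float  # math.inf for the final all-vertex facet
    weight: float | None = None

    @property
    def dimension(self) -> int:
        return len(self.vertex_set) - 1

    @property
    def lifespan(self) -> float:
        return self.death - self.birth


def facet_filtration(D: DistanceMatrix, tol: float = _TIE_TOL) -> list:
    """All facets of the VR filtration with their birth and death values.

    The complex is evaluated only at r = 0 (every vertex maximal) and at
    each critical value; a facet's birth is the first critical value where
    its vertex set is maximal (0 for vertices) and its death the first
    where it stops being maximal.  A vertex set absorbed at the same value
    it would first appear is never a facet.  The final facet (the full
    vertex set) never dies.
    """
    n = D.n
    bars: list = []
    current: dict = {frozenset([i]): 0.0 for i in range(n)}
    for r in critical_values(D, tol=tol):
        cliques = _maximal_cliques(D, r, tol=tol)
        died = set(current) - cliques
        for f in died:
            bars.append(FacetBar(f, birth=current.pop(f), death=float(r)))
        for f in cliques - set(current):
            current[f] = float(r)
    for f, b in current.items():
        bars.append(FacetBar(f, birth=b, death=math.inf))
    bars.sort(key=lambda bar: (bar.dimension, bar.birth, sorted(bar.vertex_set)))
    return bars


# --------------------------------------------------------------------------
# Jones weights
# --------------------------------------------------------------------------

@dataclass
class WeightedBarcode:
    """Facet bars with Jones weights plus the filtration's critical values."""

    bars: list
    critical_values: np.ndarray
    weight_convention: str
    t: float

    def bars_of_dimension(self, k: int) -> list:
        return [b for b in self.bars if b.dimension == k]

    def max_dimension(self) -> int:
        return max(b.dimension for b in self.bars)

    def to_records(self) -> list:
        return [
            {
                "vertex_set": sorted(b.vertex_set),
                "dimension": b.dimension,
                "birth": b.birth,
                "death": None if math.isinf(b.death) else b.death,
                "weight": b.weight,
            }
            for b in self.bars
        ]

    def to_csv(self, path) -> None:
        import pandas as pd

        rec = self.to_records()
        for row in rec:
            row["vertex_set"] = " ".join(map(str, row["vertex_set"]))
        pd.DataFrame(rec).to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "t": self.t,
                "weight_convention": self.weight_convention,
                "critical_values": self.critical_values.tolist(),
                "bars": self.to_records(),
            },
            indent=1,
        )


def weighted_barcode(
    seg: Segmentation,
    D: DistanceMatrix,
    t: float = 10.0,
    jones_settings: JonesSettings | None = None,
    weight_convention: str = "relative",
    max_weight_size: int = 8,
    tol: float = _TIE_TOL,
) -> WeightedBarcode:
    """The persistent Jones polynomial of a segmentation as a weighted barcode.

    Each facet's weight is the Jones value at ``t`` of the sub-collection
    of its segments; under the default ``relative`` convention the
    crossing-free baseline d(t)^(|F|−1) is subtracted, so trivially
    arranged facets weigh exactly 0 (``raw`` keeps the plain Jones value).
    Facets with more than ``max_weight_size`` segments are left uncomputed
    (weight None): their state sums grow exponentially with the projected
    crossing count.
    """
    if weight_convention not in ("relative", "raw"):
        raise ValueError(f"unknown weight convention {weight_convention!r}")
    js = jones_settings or JonesSettings()
    bars = facet_filtration(D, tol=tol)
    cache: dict = {}
    for bar in bars:
        k = len(bar.vertex_set)
        if k > max_weight_size:
            continue
        key = bar.vertex_set
        if key not in cache:
            if k == 1:
                raw = 1.0
            else:
                sub = subcollection(seg, sorted(key), retract=js.retract)
                try:
                    raw = js.run(sub, t_values=(t,)).at(t)
                except TooManyCrossingsError as err:
                    raise TooManyCrossingsError(
                        f"facet {sorted(key)}: {err}"
                    ) from err
            cache[key] = raw
        raw = cache[key]
        bar.weight = raw - loop_value(t) ** (k - 1) if weight_convention == "relative" else raw
    return WeightedBarcode(
        bars=bars,
        critical_values=critical_values(D, tol=tol),
        weight_convention=weight_convention,
        t=t,
    )


# --------------------------------------------------------------------------
# weighted diagrams and the bottleneck distance
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagramPoint:
    birth: float
    death: float  # math.inf allowed
    weight: float | None
    multiplicity: int = 1


@dataclass
class WeightedDiagram:
    """Off-diagonal (birth, death, weight) points with multiplicities.

    The diagonal is implicit with infinite multiplicity; a bar of zero
    persistence would sit on it and is never recorded.
    """

    points: list = field(default_factory=list)
    dimension: int | None = None

    def expanded(self) -> list:
        """Points repeated by multiplicity."""
        return [p for p in self.points for _ in range(p.multiplicity)]

    @property
    def total_multiplicity(self) -> int:
        return sum(p.multiplicity for p in self.points)


def diagram_from_barcode(
    B: WeightedBarcode, dimension: int | None = None, tol: float = _TIE_TOL
) -> WeightedDiagram:
    """Collapse equal (birth, death, weight) bars into multiplicity counts.

    With ``dimension`` given, only bars of that facet dimension contribute
    (the per-dimension panels of the barcode plots).
    """
    bars = B.bars if dimension is None else B.bars_of_dimension(dimension)
    groups: list = []  # (birth, death, weight, count)
    for bar in bars:
        placed = False
        for g in groups:
            if (
                abs(bar.birth - g[0]) <= tol
                and (bar.death == g[1] or abs(bar.death - g[1]) <= tol)
                and _weights_equal(bar.weight, g[2], tol)
            ):
                g[3] += 1
                placed = True
                break
        if not placed:
            groups.append([bar.birth, bar.death, bar.weight, 1])
    return WeightedDiagram(
        points=[DiagramPoint(b, d, w, m) for b, d, w, m in groups],
        dimension=dimension,
    )


def _weights_equal(a, b, tol):
    if a is None or b is None:
        return a is None and b is None
    return abs(a - b) <= tol


@dataclass
class Matching:
    """A partial bijection between the off-diagonal points of two diagrams."""

    pairs: list  # (index into D1.expanded(), index into D2.expanded())
    unmatched_1: list
    unmatched_2: list


def _pair_cost(p, q) -> float:
    if math.isinf(p.death) != math.isinf(q.death):
        return math.inf
    dd = 0.0 if math.isinf(p.death) else abs(p.death - q.death)
    return max(abs(p.birth - q.birth), dd, abs(p.weight - q.weight))


def _unmatched_cost(p) -> float:
    return math.inf if math.isinf(p.death) else 0.5 * (p.death - p.birth)


def _feasible(C, Dd, lam: float, return_matching: bool = False):
    """Is there a matching of cost <= lam?  Diagonal-augmented bipartite test."""
    nc, nd = len(C), len(Dd)
    n = nc + nd
    rows, cols = [], []
    for i, p in enumerate(C):
        for j, q in enumerate(Dd):
            if _pair_cost(p, q) <= lam:
                rows.append(i)
                cols.append(j)
        if _unmatched_cost(p) <= lam:
            for j in range(nd, n):  # its own diagonal copies
                rows.append(i)
                cols.append(j)
    for i in range(nc, n):  # diagonal copies on the left
        q_idx = i - nc
        if _unmatched_cost(Dd[q_idx]) <= lam:
            rows.append(i)
            cols.append(q_idx)
        for j in range(nd, n):  # diagonal-to-diagonal, always free
            rows.append(i)
            cols.append(j)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    match = maximum_bipartite_matching(graph, perm_type="column")
    ok = bool(np.all(match >= 0))
    if not return_matching:
        return ok
    pairs, un1, un2 = [], [], []
    matched_right = set()
    for i in range(nc):
        j = int(match[i])
        if 0 <= j < nd:
            pairs.append((i, j))
            matched_right.add(j)
        else:
            un1.append(i)
    un2 = [j for j in range(nd) if j not in matched_right]
    return ok, Matching(pairs=pairs, unmatched_1=un1, unmatched_2=un2)


def bottleneck_weighted(
    D1: WeightedDiagram, D2: WeightedDiagram, return_matching: bool = False
):
    """Exact weighted bottleneck distance between two weighted diagrams.

    The infimum over matchings of the maximum of matched-pair costs
    max(|Δbirth|, |Δdeath|, |Δweight|) and unmatched half-persistences,
    computed by binary search over the finite set of candidate costs with a
    bipartite feasibility test at each.  Points with infinite death can
    only match each other; leaving one unmatched costs +inf.
    """
    C = D1.expanded()
    Dd = D2.expanded()
    for p in C + Dd:
        if p.weight is None:
            raise ValueError("diagram contains uncomputed weights")
    if not C and not Dd:
        return (0.0, Matching([], [], [])) if return_matching else 0.0
    n_inf1 = sum(math.isinf(p.death) for p in C)
    n_inf2 = sum(math.isinf(p.death) for p in Dd)
    if n_inf1 != n_inf2:
        return (math.inf, None) if return_matching else math.inf

    candidates = {0.0}
    for p in C:
        for q in Dd:
            c = _pair_cost(p, q)
            if math.isfinite(c):
                candidates.add(c)
    for p in C + Dd:
        c = _unmatched_cost(p)
        if math.isfinite(c):
            candidates.add(c)
    cand = sorted(candidates)
    lo, hi = 0, len(cand) - 1
    if not _feasible(C, Dd, cand[hi]):
        return (math.inf, None) if return_matching else math.inf
    while lo < hi:
        mid = (lo + hi) // 2
        if _feasible(C, Dd, cand[mid]):
            hi = mid
        else:
            lo = mid + 1
    if return_matching:
        _, matching = _feasible(C, Dd, cand[lo], return_matching=True)
        return cand[lo], matching
    return cand[lo]
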