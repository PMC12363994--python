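"""Polyline curve collections in 3-space.

Everything downstream — projections, bracket polynomials, shell matrices,
facet barcodes — acts on collections of open or closed polylines.  This
module provides the containers, midpoint segmentation of residue chains,
inter-segment distances, seeded perturbations, a plain-text exchange format
and the synthetic fixtures (ideal helices, parallel strands, polygonal
knots) used throughout the test-suite and the documentation examples.

Coordinates are in Ångström throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Polyline",
    "CurveCollection",
    "Segmentation",
    "DistanceMatrix",
    "segment_at_midpoints",
    "midpoint_segmentation",
    "segment_distance",
    "distance_matrix",
    "subcollection",
    "perturb",
    "make_ideal_helix",
    "make_parallel_strands",
    "make_polygonal_knot",
    "make_open_trefoil",
    "read_curves",
    "write_curves",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Polyline:
    """An ordered polygonal curve, open or closed.

    ``vertices`` is an (n, 3) float array; for a closed curve the final
    edge joins the last vertex back to the first (the first vertex is not
    repeated).
    """

    vertices: np.ndarray
    closed: bool = False

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
            raise ValueError("a polyline needs an (n>=2, 3) vertex array")
        if not np.all(np.isfinite(v)):
            raise ValueError("polyline vertices must be finite")
        d = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(d == 0.0):
            raise ValueError("consecutive polyline vertices must be distinct")
        if self.closed and np.linalg.norm(v[-1] - v[0]) == 0.0:
            raise ValueError("closed polyline must not repeat its first vertex")
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def edges(self) -> np.ndarray:
        """Edge array of shape (m, 2, 3); includes the wrap edge if closed."""
        v = self.vertices
        if self.closed:
            idx = np.arange(len(v))
            return np.stack([v, v[np.roll(idx, -1)]], axis=1)
        return np.stack([v[:-1], v[1:]], axis=1)

    def length(self) -> float:
        e = self.edges()
        return float(np.linalg.norm(e[:, 1] - e[:, 0], axis=1).sum())

    def retracted(self, factor: float = 1e-6) -> "Polyline":
        """Shrink an open polyline at both ends by ``factor`` of its length.

        Adjacent midpoint segments share endpoints; retraction makes the
        segments of a segmentation pairwise disjoint without measurably
        moving the curve.  Closed curves are returned unchanged.
        """
        if self.closed or factor == 0.0:
            return self
        v = self.vertices.copy()
        delta = factor * self.length()
        first = v[1] - v[0]
        last = v[-2] - v[-1]
        v[0] = v[0] + min(delta, 0.49 * np.linalg.norm(first)) * first / np.linalg.norm(first)
        v[-1] = v[-1] + min(delta, 0.49 * np.linalg.norm(last)) * last / np.linalg.norm(last)
        return Polyline(v, closed=False)


@dataclass(frozen=True)
class CurveCollection:
    """An ordered collection of disjoint open or closed polylines."""

    components: tuple

    def __init__(self, components: Iterable[Polyline]):
        comps = tuple(components)
        if not comps:
            raise ValueError("a curve collection needs at least one component")
        for i, a in enumerate(comps):
            for b in comps[i + 1:]:
                if (
                    a.closed == b.closed
                    and a.vertices.shape == b.vertices.shape
                    and np.array_equal(a.vertices, b.vertices)
                ):
                    raise ValueError("components must be pairwise non-identical")
        object.__setattr__(self, "components", comps)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def all_vertices(self) -> np.ndarray:
        return np.concatenate([c.vertices for c in self.components], axis=0)

    def diameter(self) -> float:
        from scipy.spatial.distance import pdist

        v = self.all_vertices()
        return float(pdist(v).max()) if len(v) > 1 else 0.0

    def retracted(self, factor: float = 1e-6) -> "CurveCollection":
        return CurveCollection([c.retracted(factor) for c in self.components])


@dataclass
class Segmentation:
    """A partition of a collection into consecutive curve segments.

    Concatenating the segments of one parent component (dropping each
    segment's repeated first vertex) reproduces the parent vertex path.
    ``component_index[i]`` / ``position[i]`` locate segment ``i`` on its
    parent component; representative points (the Cα atoms, for proteins)
    define the default inter-segment metric.
    """

    segments: list
    representative_points: np.ndarray
    parent: CurveCollection
    component_index: list = field(default_factory=list)
    position: list = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def is_sequence_adjacent(self, i: int, j: int) -> bool:
        """True when segments i and j are consecutive on the same component."""
        return (
            self.component_index[i] == self.component_index[j]
            and abs(self.position[i] - self.position[j]) == 1
        )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise segment distances with a metric label."""

    entries: np.ndarray
    metric_name: str = "representative"

    def __post_init__(self):
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(e, e.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(e) != 0.0) or np.any(e < 0.0):
            raise ValueError("distances must be non-negative with zero diagonal")
        object.__setattr__(self, "entries", e)

    @property
    def n(self) -> int:
        return self.entries.shape[0]


# --------------------------------------------------------------------------
# segmentation & distances
# --------------------------------------------------------------------------

def segment_at_midpoints(chain: Polyline) -> Segmentation:
    """Cut an open chain at the midpoints between consecutive vertices.

    Segment ``i`` runs from midpoint(c_{i-1}, c_i) through c_i to
    midpoint(c_i, c_{i+1}); the terminal segments are half-length.  The
    representative point of segment ``i`` is c_i itself.
    """
    if chain.closed:
        raise ValueError("midpoint segmentation is defined for open chains only")
    c = chain.vertices
    n = len(c)
    mids = 0.5 * (c[:-1] + c[1:])
    segments = []
    for i in range(n):
        verts = []
        if i > 0:
            verts.append(mids[i - 1])
        verts.append(c[i])
        if i < n - 1:
            verts.append(mids[i])
        segments.append(Polyline(np.array(verts), closed=False))
    return Segmentation(
        segments=segments,
        representative_points=c.copy(),
        parent=CurveCollection([chain]),
        component_index=[0] * n,
        position=list(range(n)),
    )


def midpoint_segmentation(L: CurveCollection) -> Segmentation:
    """Midpoint segmentation of every (open) component of a collection."""
    segs: list = []
    reps: list = []
    comp_idx: list = []
    pos: list = []
    for ci, comp in enumerate(L.components):
        s = segment_at_midpoints(comp)
        segs.extend(s.segments)
        reps.append(s.representative_points)
        comp_idx.extend([ci] * s.n_segments)
        pos.extend(range(s.n_segments))
    return Segmentation(
        segments=segs,
        representative_points=np.concatenate(reps, axis=0),
        parent=L,
        component_index=comp_idx,
        position=pos,
    )


def _point_to_segment_dist(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip((points - a) @ ab / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def _sample_polyline(p: Polyline, per_edge: int) -> np.ndarray:
    pts = []
    for a, b in p.edges():
        ts = np.linspace(0.0, 1.0, per_edge)
        pts.append(a + ts[:, None] * (b - a))
    return np.concatenate(pts, axis=0)


def segment_distance(
    a: Polyline,
    b: Polyline,
    metric: str = "representative",
    rep_a: np.ndarray | None = None,
    rep_b: np.ndarray | None = None,
    samples_per_edge: int = 32,
) -> float:
    """Distance between two curve segments.

    ``representative`` is the Euclidean distance between the segments'
    representative points (for proteins, d(c_i, c_j) between Cα atoms).
    ``sup`` is the symmetrized supremum bound: the larger of the two
    one-sided suprema of point-to-polyline distance, each evaluated on a
    dense sampling of the source segment's edges.
    """
    if metric == "representative":
        if rep_a is None or rep_b is None:
            raise ValueError("representative metric requires representative points")
        return float(np.linalg.norm(np.asarray(rep_a) - np.asarray(rep_b)))
    if metric == "sup":
        pa = _sample_polyline(a, samples_per_edge)
        pb = _sample_polyline(b, samples_per_edge)

        def one_sided(src: np.ndarray, dst: Polyline) -> float:
            d = np.full(len(src), np.inf)
            for e0, e1 in dst.edges():
                d = np.minimum(d, _point_to_segment_dist(src, e0, e1))
            return float(d.max())

        return max(one_sided(pa, b), one_sided(pb, a))
    raise ValueError(f"unknown segment metric {metric!r}")


def distance_matrix(
    seg: Segmentation, metric: str = "representative", samples_per_edge: int = 32
) -> DistanceMatrix:
    """Pairwise segment distances for a segmentation under one metric."""
    n = seg.n_segments
    if metric == "representative":
        from scipy.spatial.distance import squareform, pdist

        if n == 1:
            d = np.zeros((1, 1))
        else:
            d = squareform(pdist(seg.representative_points))
        return DistanceMatrix(d, metric_name="representative")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = segment_distance(
                seg.segments[i], seg.segments[j], metric="sup",
                samples_per_edge=samples_per_edge,
            )
    return DistanceMatrix(d, metric_name="sup")


def subcollection(
    seg: Segmentation, indices: Sequence[int], retract: float = 1e-6
) -> CurveCollection:
    """The sub-collection of segments ``indices``, retracted to be disjoint.

    Midpoint segments of one chain share endpoints; each segment is pulled
    in by ``retract`` of its own length at both ends so the result is a
    collection of disjoint open curves.
    """
    return CurveCollection(
        [seg.segments[i].retracted(retract) for i in indices]
    )


# --------------------------------------------------------------------------
# perturbation
# --------------------------------------------------------------------------

def perturb(L: CurveCollection, eps: float, seed: int) -> CurveCollection:
    """Displace every vertex by an independent random vector of norm < eps.

    Directions are uniform on the sphere and radii scale as u^(1/3) so the
    displacement is uniform in the open ball; the sup-norm displacement is
    strictly below ``eps``.  Deterministic in ``seed``.
    """
    if eps < 0:
        raise ValueError("eps must be non-negative")
    if eps == 0:
        return L
    rng = np.random.default_rng(seed)
    comps = []
    for comp in L.components:
        v = comp.vertices
        direc = rng.normal(size=v.shape)
        direc /= np.linalg.norm(direc, axis=1, keepdims=True)
        radii = eps * rng.random(len(v)) ** (1.0 / 3.0)
        comps.append(Polyline(v + radii[:, None] * direc, closed=comp.closed))
    return CurveCollection(comps)


# --------------------------------------------------------------------------
# synthetic fixtures
# --------------------------------------------------------------------------

def make_ideal_helix(
    n_residues: int,
    radius: float = 2.3,
    rise: float = 1.5,
    twist_deg: float = 100.0,
) -> Polyline:
    """Ideal α-helix Cα trace: vertex k at angle k·twist, height k·rise.

    The defaults give the canonical α-helix geometry with a consecutive
    Cα–Cα distance of ≈3.83 Å.
    """
    if n_residues < 2:
        raise ValueError("need at least two residues")
    k = np.arange(n_residues)
    theta = np.deg2rad(twist_deg) * k
    v = np.stack([radius * np.cos(theta), radius * np.sin(theta), rise * k], axis=1)
    return Polyline(v, closed=False)


def make_parallel_strands(
    n_per_strand: int, intra: float = 3.8, inter: float = 4.8
) -> CurveCollection:
    """Two straight parallel Cα strands (a parallel β-sheet stand-in)."""
    if n_per_strand < 2:
        raise ValueError("need at least two residues per strand")
    x = intra * np.arange(n_per_strand)
    a = np.stack([x, np.zeros_like(x), np.zeros_like(x)], axis=1)
    b = np.stack([x, np.full_like(x, inter), np.zeros_like(x)], axis=1)
    return CurveCollection([Polyline(a), Polyline(b)])


def _trefoil_vertices(n: int = 12) -> np.ndarray:
    t = 2.0 * np.pi * np.arange(n) / n
    return np.stack(
        [np.sin(t) + 2.0 * np.sin(2.0 * t),
         np.cos(t) - 2.0 * np.cos(2.0 * t),
         -np.sin(3.0 * t)],
        axis=1,
    )


def make_polygonal_knot(kind: str) -> CurveCollection:
    """Fixed-coordinate polygonal realizations of small links.

    kinds: ``unknot`` (planar square), ``trefoil`` / ``mirror_trefoil``
    (12-gon trefoils of opposite chirality), ``hopf`` (two linked octagons).
    """
    if kind == "unknot":
        v = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]], dtype=float)
        return CurveCollection([Polyline(v, closed=True)])
    if kind in ("trefoil", "mirror_trefoil"):
        v = _trefoil_vertices()
        if kind == "mirror_trefoil":
            v = v * np.array([1.0, 1.0, -1.0])
        return CurveCollection([Polyline(v, closed=True)])
    if kind == "hopf":
        th = 2.0 * np.pi * np.arange(8) / 8
        a = np.stack([np.cos(th), np.sin(th), np.zeros_like(th)], axis=1)
        s = np.sin(th) / math.sqrt(2.0)
        b = np.stack([1.0 + np.cos(th), s, s], axis=1)
        return CurveCollection([Polyline(a, closed=True), Polyline(b, closed=True)])
    raise ValueError(f"unknown knot kind {kind!r}")


def make_open_trefoil(gap_fraction: float) -> CurveCollection:
    """An open trefoil-shaped arc whose endpoint gap is a fraction of diameter.

    Starts from the closed 12-gon trefoil, cuts it at vertex 0 and slides the
    two cut ends along their incident edges until they are
    ``gap_fraction * diameter`` apart.  As the gap shrinks the sphere-averaged
    Jones value converges to the closed trefoil's.
    """
    closed = make_polygonal_knot("trefoil").components[0]
    v = closed.vertices
    diam = CurveCollection([closed]).diameter()
    gap = gap_fraction * diam
    # walk the loop v0 -> v1 -> ... -> v_{n-1} -> v0 and truncate its tail at
    # the first point (searching backward from the closing vertex) whose
    # straight-line distance to v0 equals the requested gap
    path = np.concatenate([v, v[:1]], axis=0)
    start = path[0]
    for k in range(len(path) - 1, 0, -1):
        a, b = path[k - 1], path[k]  # search the edge a->b, b nearer the end
        da, db = np.linalg.norm(a - start), np.linalg.norm(b - start)
        lo_s, hi_s = (db, da) if db < da else (da, db)
        if lo_s <= gap <= hi_s:
            # bisect the edge for |p - start| = gap (monotone along one edge
            # whenever the bracket above holds)
            lo, hi = 0.0, 1.0
            f = lambda s: np.linalg.norm(a + s * (b - a) - start) - gap
            if f(0.0) * f(1.0) > 0:
                continue
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if f(lo) * f(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            cut = a + 0.5 * (lo + hi) * (b - a)
            w = np.concatenate([path[:k], cut[None, :]], axis=0)
            return CurveCollection([Polyline(w, closed=False)])
    # gap unattainable on the tail: return the most-open truncation
    dists = np.linalg.norm(path - start, axis=1)
    k = int(np.argmax(dists))
    return CurveCollection([Polyline(path[: k + 1], closed=False)])


# --------------------------------------------------------------------------
# plain-text exchange format
# --------------------------------------------------------------------------

def write_curves(L: CurveCollection, path) -> None:
    """One block per component: header ``open``/``closed``, then x y z lines."""
    with open(path, "w") as fh:
        for i, comp in enumerate(L.components):
            if i:
                fh.write("\n")
            fh.write("closed\n" if comp.closed else "open\n")
            for x, y, z in comp.vertices:
                fh.write(f"{x:.10g} {y:.10g} {z:.10g}\n")


def read_curves(path) -> CurveCollection:
    with open(path) as fh:
        text = fh.read()
    comps = []
    for block in text.strip().split("\n\n"):
        lines = [ln.strip() for ln in block.strip().splitlines() if ln.strip()]
        if not lines:
            continue
        flag = lines[0].lower()
        if flag not in ("open", "closed"):
            raise ValueError(f"component header must be 'open' or 'closed', got {flag!r}")
        verts = np.array([[float(x) for x in ln.split()] for ln in lines[1:]])
        comps.append(Polyline(verts, closed=(flag == "closed")))
    return CurveCollection(comps)
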