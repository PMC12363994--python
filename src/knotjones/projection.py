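"""Planar projection of curve collections into linkoid diagrams.

A linkoid diagram is what a collection of open/closed curves looks like
after orthogonal projection along a direction on the sphere: planar
polylines with a recorded depth per vertex, labeled endpoints for the open
components, and a list of signed transverse crossings with over/under
resolved by depth.  Irregular projections (tangencies, triple points,
crossings at vertices or endpoints, depth ties) form a measure-zero set of
directions; they are detected and evaded by a small seeded jitter of the
projection direction.

Conventions, fixed once:

* crossing sign is +1 when the under-strand direction is counterclockwise
  from the over-strand direction in the projection plane (both taken along
  the traversal orientation); mirroring the collection flips every sign;
* the head of an open component is its leading vertex, the leg its trailing
  vertex; the j-th open component (in collection order, 1-based) carries the
  endpoint labels (2j-1, 2j), so the diagram pairing is always
  L̂ = (1,2)(3,4)…(2n-1,2n).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .curves import CurveCollection

__all__ = [
    "Direction",
    "DirectionSample",
    "sample_directions",
    "ArcRef",
    "Crossing",
    "LinkoidDiagram",
    "IrregularProjectionError",
    "project",
    "writhe",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: parameters / depth gaps closer than this to a degeneracy are irregular
IRREGULARITY_TOL = 1e-9
#: maximum jitter rotation applied to evade an irregular projection (rad)
JITTER_ANGLE = 1e-4
DEFAULT_MAX_RETRIES = 10


class IrregularProjectionError(RuntimeError):
    """Raised when a projection stays irregular after all jitter retries."""


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector is not a direction")
    return v / n


@dataclass(frozen=True)
class Direction:
    """A unit vector on the sphere of projection directions."""

    vector: np.ndarray

    def __post_init__(self):
        v = _unit(self.vector)
        if abs(np.linalg.norm(v) - 1.0) > 1e-12:
            raise ValueError("direction must be a unit vector")
        object.__setattr__(self, "vector", v)


@dataclass(frozen=True)
class DirectionSample:
    directions: tuple
    scheme: str
    seed: int | None = None


def sample_directions(n: int, scheme: str = "fibonacci", seed: int | None = None) -> DirectionSample:
    """Directions for the Monte-Carlo sphere average.

    ``fibonacci`` is the deterministic spherical Fibonacci lattice (well
    spread, no seed needed); ``uniform_random`` draws i.i.d. uniform points
    on the sphere from ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    if scheme == "fibonacci":
        i = np.arange(n)
        z = 1.0 - (2.0 * i + 1.0) / n
        rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
        phi = i * _GOLDEN_ANGLE
        vecs = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    elif scheme == "uniform_random":
        rng = np.random.default_rng(seed)
        vecs = rng.normal(size=(n, 3))
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown direction scheme {scheme!r}")
    return DirectionSample(tuple(Direction(v) for v in vecs), scheme=scheme, seed=seed)


class ArcRef(NamedTuple):
    """A point on the diagram: component, edge index, parameter in (0, 1)."""

    component: int
    edge: int
    t: float


@dataclass(frozen=True)
class Crossing:
    id: int
    over: ArcRef
    under: ArcRef
    sign: int  # +1 iff under-direction is CCW from over-direction


@dataclass
class LinkoidDiagram:
    """A projected collection: planar polylines with depth and crossings.

    ``passes[c]`` lists, in traversal order, the crossing passes of
    component ``c`` as tuples ``(edge, t, crossing_id, role)`` with role
    "over"/"under" — the combinatorial data the bracket state sum consumes.
    """

    points2d: list
    depths: list
    closed_flags: list
    crossings: list
    passes: list
    open_labels: list  # (head, leg) per open component, in component order

    @property
    def n_open(self) -> int:
        return len(self.open_labels)

    @property
    def G(self) -> list:
        return list(range(1, 2 * self.n_open + 1))

    @property
    def L_hat(self) -> list:
        return [(2 * j + 1, 2 * j + 2) for j in range(self.n_open)]

    def mirror(self) -> "LinkoidDiagram":
        """The depth-negated diagram: over/under swap, every sign flips."""
        crossings = [
            Crossing(c.id, over=c.under, under=c.over, sign=-c.sign)
            for c in self.crossings
        ]
        passes = [
            [(e, t, cid, "under" if role == "over" else "over") for (e, t, cid, role) in plist]
            for plist in self.passes
        ]
        return LinkoidDiagram(
            points2d=self.points2d,
            depths=[-d for d in self.depths],
            closed_flags=list(self.closed_flags),
            crossings=crossings,
            passes=passes,
            open_labels=list(self.open_labels),
        )

    def dump(self) -> str:
        """JSON text dump of the combinatorial diagram data."""
        return json.dumps(
            {
                "components": [
                    {
                        "closed": bool(cl),
                        "points": np.asarray(p).tolist(),
                        "depths": np.asarray(d).tolist(),
                    }
                    for p, d, cl in zip(self.points2d, self.depths, self.closed_flags)
                ],
                "open_labels": [list(hl) for hl in self.open_labels],
                "crossings": [
                    {
                        "id": c.id,
                        "over": list(c.over),
                        "under": list(c.under),
                        "sign": c.sign,
                    }
                    for c in self.crossings
                ],
            },
            indent=1,
        )


def _plane_basis(xi: np.ndarray):
    a = np.array([1.0, 0.0, 0.0])
    if abs(xi @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = a - (a @ xi) * xi
    u /= np.linalg.norm(u)
    v = np.cross(xi, u)
    return u, v


def _edge_arrays(L: CurveCollection, u, v, xi):
    """Per-component 2D points/depths plus a flat edge table."""
    pts2d, depths = [], []
    comp_id, edge_id = [], []
    p0, p1, z0, z1 = [], [], [], []
    for ci, comp in enumerate(L.components):
        V = comp.vertices
        xy = np.stack([V @ u, V @ v], axis=1)
        z = V @ xi
        pts2d.append(xy)
        depths.append(z)
        n = len(V)
        if comp.closed:
            nxt = np.roll(np.arange(n), -1)
            a, b = np.arange(n), nxt
        else:
            a, b = np.arange(n - 1), np.arange(1, n)
        comp_id.extend([ci] * len(a))
        edge_id.extend(range(len(a)))
        p0.append(xy[a]); p1.append(xy[b])
        z0.append(z[a]); z1.append(z[b])
    return (
        pts2d,
        depths,
        np.array(comp_id),
        np.array(edge_id),
        np.concatenate(p0),
        np.concatenate(p1),
        np.concatenate(z0),
        np.concatenate(z1),
    )


def _detect_crossings(L, comp_id, edge_id, p0, p1, z0, z1):
    """All transverse crossings, or a reason string if irregular."""
    E = len(comp_id)
    r = p1 - p0
    scale = max(1.0, float(np.abs(np.concatenate([p0, p1])).max()))
    tol = IRREGULARITY_TOL

    # candidate pairs: i < j, not the same edge, not sharing a vertex
    ii, jj = np.triu_indices(E, k=1)
    same_comp = comp_id[ii] == comp_id[jj]
    n_edges_per_comp = np.bincount(comp_id)
    closed_arr = np.array([c.closed for c in L.components])
    de = np.abs(edge_id[ii] - edge_id[jj])
    adjacent = same_comp & (de == 1)
    # wrap adjacency (first and last edge share a vertex) on closed components
    wrap = same_comp & closed_arr[comp_id[ii]] & (de == n_edges_per_comp[comp_id[ii]] - 1)
    keep = ~(adjacent | wrap)
    ii, jj = ii[keep], jj[keep]
    if len(ii) == 0:
        return [], None

    ri, sj = r[ii], r[jj]
    denom = ri[:, 0] * sj[:, 1] - ri[:, 1] * sj[:, 0]
    qp = p0[jj] - p0[ii]
    parallel = np.abs(denom) < tol * scale * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        tpar = (qp[:, 0] * sj[:, 1] - qp[:, 1] * sj[:, 0]) / denom
        upar = (qp[:, 0] * ri[:, 1] - qp[:, 1] * ri[:, 0]) / denom

    near = (~parallel) & (tpar > -tol) & (tpar < 1 + tol) & (upar > -tol) & (upar < 1 + tol)
    on_boundary = near & (
        (np.abs(tpar) < tol) | (np.abs(tpar - 1) < tol)
        | (np.abs(upar) < tol) | (np.abs(upar - 1) < tol)
    )
    if np.any(on_boundary):
        return None, "crossing at an edge endpoint or component endpoint"
    # parallel edges that come too close: tangential / collinear overlap
    par_idx = np.where(parallel)[0]
    if len(par_idx):
        for k in par_idx:
            a0, a1 = p0[ii[k]], p1[ii[k]]
            b0, b1 = p0[jj[k]], p1[jj[k]]
            if _segments_close(a0, a1, b0, b1, tol * scale):
                return None, "tangential or collinear edge overlap"

    hit = np.where(near & ~on_boundary)[0]
    crossings = []
    locs = []
    for k in hit:
        t, s = float(tpar[k]), float(upar[k])
        zi = z0[ii[k]] + t * (z1[ii[k]] - z0[ii[k]])
        zjv = z0[jj[k]] + s * (z1[jj[k]] - z0[jj[k]])
        if abs(zi - zjv) < tol * scale:
            return None, "depth tie at a crossing"
        ref_i = ArcRef(int(comp_id[ii[k]]), int(edge_id[ii[k]]), t)
        ref_j = ArcRef(int(comp_id[jj[k]]), int(edge_id[jj[k]]), s)
        if zi > zjv:
            over, under, odir, udir = ref_i, ref_j, ri[k], sj[k]
        else:
            over, under, odir, udir = ref_j, ref_i, sj[k], ri[k]
        cr = float(odir[0] * udir[1] - odir[1] * udir[0])
        crossings.append((over, under, 1 if cr > 0 else -1))
        locs.append(p0[ii[k]] + t * (p1[ii[k]] - p0[ii[k]]))

    # triple points: two crossings at (nearly) the same planar location
    if len(locs) > 1:
        locs = np.asarray(locs)
        d2 = np.sum((locs[:, None, :] - locs[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if d2.min() < (tol * scale) ** 2:
            return None, "triple point"
    return crossings, None


def _segments_close(a0, a1, b0, b1, tol) -> bool:
    def seg_point(p, q0, q1):
        d = q1 - q0
        t = np.clip((p - q0) @ d / (d @ d), 0.0, 1.0)
        return np.linalg.norm(p - (q0 + t * d))

    return min(
        seg_point(a0, b0, b1), seg_point(a1, b0, b1),
        seg_point(b0, a0, a1), seg_point(b1, a0, a1),
    ) < tol


def project(
    L: CurveCollection,
    xi: Direction | np.ndarray,
    jitter_seed: int = 0,
    max_retries: int = DEFAULT_MAX_RETRIES,
) -> LinkoidDiagram:
    """Orthogonal projection of ``L`` along ``xi`` into a linkoid diagram.

    Irregular projections are evaded by rotating ``xi`` by a small random
    angle (at most :data:`JITTER_ANGLE` rad, seeded by ``jitter_seed``) and
    retrying; after ``max_retries`` failures an
    :class:`IrregularProjectionError` names the offending feature.
    """
    vec = xi.vector if isinstance(xi, Direction) else _unit(xi)
    rng = np.random.default_rng(jitter_seed)
    reason = "unknown"
    for _ in range(max_retries + 1):
        u, v = _plane_basis(vec)
        pts2d, depths, comp_id, edge_id, p0, p1, z0, z1 = _edge_arrays(L, u, v, vec)
        raw, reason = _detect_crossings(L, comp_id, edge_id, p0, p1, z0, z1)
        if raw is not None:
            crossings = []
            passes = [[] for _ in L.components]
            for cid, (over, under, sign) in enumerate(raw):
                crossings.append(Crossing(cid, over=over, under=under, sign=sign))
                passes[over.component].append((over.edge, over.t, cid, "over"))
                passes[under.component].append((under.edge, under.t, cid, "under"))
            for plist in passes:
                plist.sort(key=lambda p: (p[0], p[1]))
            open_labels = []
            j = 0
            for comp in L.components:
                if not comp.closed:
                    open_labels.append((2 * j + 1, 2 * j + 2))
                    j += 1
            return LinkoidDiagram(
                points2d=pts2d,
                depths=depths,
                closed_flags=[c.closed for c in L.components],
                crossings=crossings,
                passes=passes,
                open_labels=open_labels,
            )
        # jitter: small random rotation of the direction
        axis = rng.normal(size=3)
        axis -= (axis @ vec) * vec
        axis /= np.linalg.norm(axis)
        ang = JITTER_ANGLE * (0.5 + 0.5 * rng.random())
        vec = _unit(np.cos(ang) * vec + np.sin(ang) * np.cross(axis, vec))
    raise IrregularProjectionError(
        f"projection stayed irregular after {max_retries} jittered retries: {reason}"
    )


def writhe(D: LinkoidDiagram) -> int:
    """Sum of crossing signs of the diagram."""
    return int(sum(c.sign for c in D.crossings))
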