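"""The bracket state sum for linkoids and the sphere-averaged Jones polynomial.

A state of a linkoid diagram chooses an A- or B-smoothing at every crossing.
Smoothing and tracing a state yields closed loops (counted by ``circ``) and
open strands whose endpoint pairing Ŝ, combined with the diagram pairing
L̂ = (1,2)(3,4)…, decomposes the endpoint set into *segment cycles* (counted
by ``cyc``).  The bracket is the state sum

    ⟨L⟩ = Σ_S  A^σ(S) · d^(circ(S) + cyc(S) − 1),      d = −A² − A⁻²,

with σ(S) = #A − #B, and ``cyc = 0`` for a diagram with no open components
(the classical link bracket).  The writhe-normalized bracket
f = (−A³)^(−Wr) ⟨L⟩ of a projection, averaged over directions on the
sphere, is the Jones polynomial of the 3-space collection; evaluations use
the substitution A = t^(−1/4), which is real for t > 0.

Sign/smoothing conventions follow :mod:`knotjones.projection`: they fix the
chirality labelling (mirror images swap t ↔ 1/t) but nothing else.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .curves import CurveCollection
from .projection import (
    Direction,
    LinkoidDiagram,
    project,
    sample_directions,
    writhe,
)

__all__ = [
    "LaurentPolynomial",
    "JonesValue",
    "JonesSettings",
    "TooManyCrossingsError",
    "smooth_and_trace",
    "segment_cycle_count",
    "bracket",
    "normalized_bracket",
    "jones",
    "trivial_value",
    "loop_value",
    "DEFAULT_CROSSING_CAP",
]

DEFAULT_CROSSING_CAP = 20
DEFAULT_N_DIRECTIONS = 100


class TooManyCrossingsError(RuntimeError):
    """The 2^c state sum would exceed the configured crossing cap."""


@dataclass(frozen=True)
class JonesSettings:
    """Quadrature and state-sum settings shared across a computation.

    ``retract`` is the fraction of each segment's length pulled in at both
    ends before projection, so that midpoint segments sharing an endpoint
    become disjoint open curves.
    """

    n_directions: int = 100
    scheme: str = "fibonacci"
    seed: int | None = 0
    crossing_cap: int = 20
    skip_overfull: bool = False
    retract: float = 1e-6

    def run(self, L: CurveCollection, t_values=(10.0,)) -> "JonesValue":
        return jones(
            L,
            n_directions=self.n_directions,
            scheme=self.scheme,
            seed=self.seed,
            t_values=t_values,
            crossing_cap=self.crossing_cap,
            skip_overfull=self.skip_overfull,
        )


# --------------------------------------------------------------------------
# Laurent polynomials in A
# --------------------------------------------------------------------------

class LaurentPolynomial:
    """A real-coefficient Laurent polynomial in the bracket variable A."""

    __slots__ = ("coeffs",)

    def __init__(self, coeffs: dict | None = None):
        self.coeffs = {}
        if coeffs:
            for e, c in coeffs.items():
                if c != 0.0:
                    self.coeffs[int(e)] = float(c)

    @classmethod
    def one(cls) -> "LaurentPolynomial":
        return cls({0: 1.0})

    @classmethod
    def monomial(cls, exponent: int, coeff: float = 1.0) -> "LaurentPolynomial":
        return cls({exponent: coeff})

    def __add__(self, other: "LaurentPolynomial") -> "LaurentPolynomial":
        out = dict(self.coeffs)
        for e, c in other.coeffs.items():
            out[e] = out.get(e, 0.0) + c
        return LaurentPolynomial(out)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return LaurentPolynomial({e: c * other for e, c in self.coeffs.items()})
        out: dict = {}
        for e1, c1 in self.coeffs.items():
            for e2, c2 in other.coeffs.items():
                out[e1 + e2] = out.get(e1 + e2, 0.0) + c1 * c2
        return LaurentPolynomial(out)

    __rmul__ = __mul__

    def __sub__(self, other: "LaurentPolynomial") -> "LaurentPolynomial":
        return self + (other * -1.0)

    def __pow__(self, k: int) -> "LaurentPolynomial":
        if k < 0:
            raise ValueError("negative powers of polynomials are not defined")
        out = LaurentPolynomial.one()
        base = self
        while k:
            if k & 1:
                out = out * base
            base = base * base
            k >>= 1
        return out

    def shift(self, k: int) -> "LaurentPolynomial":
        """Multiply by A^k."""
        return LaurentPolynomial({e + k: c for e, c in self.coeffs.items()})

    def mirror(self) -> "LaurentPolynomial":
        """Substitute A -> A^(-1) (the mirror-image bracket)."""
        return LaurentPolynomial({-e: c for e, c in self.coeffs.items()})

    def eval(self, a: float) -> float:
        return float(sum(c * a ** e for e, c in self.coeffs.items()))

    def eval_t(self, t: float) -> float:
        """Evaluate under the Jones substitution A = t^(-1/4)."""
        return self.eval(t ** -0.25)

    def almost_equal(self, other: "LaurentPolynomial", tol: float = 1e-9) -> bool:
        exps = set(self.coeffs) | set(other.coeffs)
        return all(
            abs(self.coeffs.get(e, 0.0) - other.coeffs.get(e, 0.0)) <= tol for e in exps
        )

    def __eq__(self, other):
        return isinstance(other, LaurentPolynomial) and self.almost_equal(other, 0.0)

    def __hash__(self):
        return hash(frozenset(self.coeffs.items()))

    def __repr__(self):
        if not self.coeffs:
            return "0"
        terms = [f"{c:+g}*A^{e}" for e, c in sorted(self.coeffs.items())]
        return " ".join(terms)


#: the loop value d = -A^2 - A^(-2)
LOOP = LaurentPolynomial({2: -1.0, -2: -1.0})


def loop_value(t: float) -> float:
    """d evaluated at A = t^(-1/4): −(√t + 1/√t)."""
    return -(t ** 0.5 + t ** -0.5)


def trivial_value(n_components: int, t: float) -> float:
    """Jones value of n crossing-free disjoint arcs/loops: d(t)^(n−1)."""
    if n_components < 1:
        raise ValueError("need at least one component")
    return loop_value(t) ** (n_components - 1)


# --------------------------------------------------------------------------
# smoothing, tracing, segment cycles
# --------------------------------------------------------------------------

def _ports(cid: int):
    # port node ids: 4*cid + {0: over-in, 1: over-out, 2: under-in, 3: under-out}
    return 4 * cid, 4 * cid + 1, 4 * cid + 2, 4 * cid + 3


def _build_strand_graph(D: LinkoidDiagram):
    """State-independent connections along the diagram's strands.

    Node ids: crossing ports 0..4c-1, then endpoint labels mapped to
    4c + (label-1).  Returns (strand partner map, per-crossing smoothing
    options, number of standalone circles).
    """
    c = len(D.crossings)
    n_open = D.n_open
    label_node = lambda lab: 4 * c + (lab - 1)
    strand: dict = {}
    standalone = 0

    def connect(a, b):
        strand[a] = b
        strand[b] = a

    open_j = 0
    for comp_idx, plist in enumerate(D.passes):
        closed = D.closed_flags[comp_idx]
        entries = []
        exits = []
        for (edge, t, cid, role) in plist:
            o_in, o_out, u_in, u_out = _ports(cid)
            if role == "over":
                entries.append(o_in)
                exits.append(o_out)
            else:
                entries.append(u_in)
                exits.append(u_out)
        if closed:
            if not plist:
                standalone += 1
                continue
            for k in range(len(plist)):
                connect(exits[k], entries[(k + 1) % len(plist)])
        else:
            head, leg = D.open_labels[open_j]
            open_j += 1
            if not plist:
                connect(label_node(head), label_node(leg))
                continue
            connect(label_node(head), entries[0])
            for k in range(len(plist) - 1):
                connect(exits[k], entries[k + 1])
            connect(exits[-1], label_node(leg))

    smooth_options = []
    for cr in D.crossings:
        o_in, o_out, u_in, u_out = _ports(cr.id)
        if cr.sign > 0:
            # under-direction CCW from over-direction: the A-smoothing joins
            # over-in with under-out and over-out with under-in
            a_pairs = ((o_in, u_out), (o_out, u_in))
            b_pairs = ((o_in, u_in), (o_out, u_out))
        else:
            a_pairs = ((o_in, u_in), (o_out, u_out))
            b_pairs = ((o_in, u_out), (o_out, u_in))
        smooth_options.append((a_pairs, b_pairs))
    return strand, smooth_options, standalone


def _trace(D: LinkoidDiagram, strand, smooth_options, standalone, labels):
    """Trace one state: (number of closed loops, endpoint pairing Ŝ)."""
    c = len(D.crossings)
    smooth = {}
    for cid, lab in enumerate(labels):
        pairs = smooth_options[cid][0 if lab == "A" else 1]
        for a, b in pairs:
            smooth[a] = b
            smooth[b] = a
    n_open = D.n_open
    endpoint_nodes = [4 * c + k for k in range(2 * n_open)]
    visited = set()
    S_hat = []
    # open strands: walk endpoint -> ... -> endpoint, alternating connections
    for start in endpoint_nodes:
        if start in visited:
            continue
        visited.add(start)
        node = strand[start]
        via_strand = True
        while True:
            if node >= 4 * c:  # reached an endpoint
                visited.add(node)
                S_hat.append((start - 4 * c + 1, node - 4 * c + 1))
                break
            visited.add(node)
            node = smooth[node] if via_strand else strand[node]
            via_strand = not via_strand
    # closed loops among remaining ports
    circ = standalone
    for start in range(4 * c):
        if start in visited:
            continue
        circ += 1
        node = start
        via_strand = True  # leave via smoothing first (arbitrary for a cycle)
        while True:
            visited.add(node)
            node = smooth[node] if via_strand else strand[node]
            via_strand = not via_strand
            if node == start:
                break
    return circ, S_hat


def smooth_and_trace(D: LinkoidDiagram, labels) -> tuple:
    """Apply the smoothing ``labels`` (one 'A'/'B' per crossing) and trace.

    Returns ``(circ_count, S_hat)`` where ``S_hat`` is the endpoint pairing
    of the state as a list of 2-cycles on the label set G.
    """
    labels = list(labels)
    if len(labels) != len(D.crossings) or any(l not in ("A", "B") for l in labels):
        raise ValueError("need one 'A'/'B' label per crossing")
    strand, smooth_options, standalone = _build_strand_graph(D)
    return _trace(D, strand, smooth_options, standalone, labels)


def _as_involution(pairs, G) -> dict:
    m: dict = {}
    for a, b in pairs:
        if a == b or a in m or b in m:
            raise ValueError("pairing must be a fixed-point-free involution")
        m[a] = b
        m[b] = a
    if set(m) != set(G):
        raise ValueError("pairing must cover the endpoint set G")
    return m


def segment_cycle_count(L_hat, S_hat, G) -> int:
    """Number of segment cycles of the state pairing Ŝ against L̂.

    A segment cycle is Seg(a) = Orb(a) ⊔ Orb(L̂(a)) where orbits are taken
    under the composition L̂∘Ŝ; equivalently, the connected components of
    the multigraph on G whose edges are the 2-cycles of L̂ and of Ŝ.  Every
    segment cycle has an even number of elements.
    """
    G = list(G)
    if not G:
        return 0
    L = _as_involution(L_hat, G)
    S = _as_involution(S_hat, G)
    seen: set = set()
    count = 0
    for a in G:
        if a in seen:
            continue
        count += 1
        # orbit of a under L∘S, plus the orbit of L(a)
        for start in (a, L[a]):
            x = start
            while x not in seen:
                seen.add(x)
                x = L[S[x]]
    return count


# --------------------------------------------------------------------------
# bracket state sum and normalization
# --------------------------------------------------------------------------

def bracket(D: LinkoidDiagram, crossing_cap: int = DEFAULT_CROSSING_CAP) -> LaurentPolynomial:
    """The linkoid bracket by exact enumeration of all 2^c states."""
    c = len(D.crossings)
    if c > crossing_cap:
        raise TooManyCrossingsError(
            f"{c} crossings exceeds the state-sum cap of {crossing_cap}"
        )
    strand, smooth_options, standalone = _build_strand_graph(D)
    L = D.L_hat
    G = D.G
    counts: dict = {}
    for labels in itertools.product("AB", repeat=c):
        circ, S_hat = _trace(D, strand, smooth_options, standalone, labels)
        cyc = segment_cycle_count(L, S_hat, G) if G else 0
        sigma = sum(1 if l == "A" else -1 for l in labels)
        key = (sigma, circ + cyc - 1)
        counts[key] = counts.get(key, 0) + 1
    out = LaurentPolynomial()
    d_pows: dict = {0: LaurentPolynomial.one()}
    for (sigma, e), k in counts.items():
        if e not in d_pows:
            d_pows[e] = LOOP ** e
        out = out + d_pows[e].shift(sigma) * float(k)
    return out


def normalized_bracket(
    D: LinkoidDiagram, crossing_cap: int = DEFAULT_CROSSING_CAP
) -> LaurentPolynomial:
    """Writhe-normalized bracket f = (−A³)^(−Wr) ⟨L⟩."""
    w = writhe(D)
    b = bracket(D, crossing_cap=crossing_cap)
    sign = -1.0 if (w % 2) else 1.0
    return b.shift(-3 * w) * sign


# --------------------------------------------------------------------------
# sphere-averaged Jones polynomial
# --------------------------------------------------------------------------

@dataclass
class JonesValue:
    """A sphere-averaged Jones polynomial and its evaluations at t."""

    polynomial: LaurentPolynomial
    t_evaluations: dict
    n_directions: int
    scheme: str
    seed: int | None
    skipped: int = 0
    per_direction: list | None = None

    def at(self, t: float) -> float:
        if t in self.t_evaluations:
            return self.t_evaluations[t]
        return self.polynomial.eval_t(t)

    def to_json(self) -> dict:
        return {
            "coefficients": {str(e): c for e, c in sorted(self.polynomial.coeffs.items())},
            "t_evaluations": {str(t): v for t, v in self.t_evaluations.items()},
            "n_directions": self.n_directions,
            "scheme": self.scheme,
            "seed": self.seed,
            "skipped_directions": self.skipped,
        }


def _jitter_seed(seed: int | None, i: int) -> int:
    base = 0 if seed is None else int(seed)
    return (base * 1000003 + 7919 * i + 1) % (2 ** 31)


def jones(
    L: CurveCollection,
    n_directions: int = DEFAULT_N_DIRECTIONS,
    scheme: str = "fibonacci",
    seed: int | None = 0,
    t_values=(10.0,),
    crossing_cap: int = DEFAULT_CROSSING_CAP,
    skip_overfull: bool = False,
    keep_per_direction: bool = False,
    directions: "DirectionSample | None" = None,
) -> JonesValue:
    """Monte-Carlo sphere average of writhe-normalized brackets of ``L``.

    Each direction's projection is computed (with seeded jitter past
    irregular configurations), its bracket normalized by the writhe, and
    the polynomials averaged coefficient-wise.  Directions whose diagrams
    exceed the crossing cap raise by default; with ``skip_overfull`` they
    are excluded from the average and counted in ``skipped``.

    A pre-sampled ``directions`` argument overrides ``n_directions``/
    ``scheme`` — used to share one quadrature between runs being compared.
    """
    if directions is None:
        directions = sample_directions(n_directions, scheme=scheme, seed=seed)
    dirs = directions.directions
    total = LaurentPolynomial()
    used = 0
    skipped = 0
    per_dir = [] if keep_per_direction else None
    for i, xi in enumerate(dirs):
        D = project(L, xi, jitter_seed=_jitter_seed(seed, i))
        try:
            f = normalized_bracket(D, crossing_cap=crossing_cap)
        except TooManyCrossingsError:
            if skip_overfull:
                skipped += 1
                continue
            raise
        total = total + f
        used += 1
        if per_dir is not None:
            per_dir.append(f)
    if used == 0:
        raise TooManyCrossingsError("every projection direction exceeded the crossing cap")
    avg = total * (1.0 / used)
    return JonesValue(
        polynomial=avg,
        t_evaluations={float(t): avg.eval_t(float(t)) for t in t_values},
        n_directions=len(dirs),
        scheme=directions.scheme,
        seed=seed,
        skipped=skipped,
        per_direction=per_dir,
    )
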