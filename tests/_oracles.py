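"""Independent oracle implementations used only by the test-suite.

These deliberately avoid the production code paths: the bracket oracle is a
recursive skein expansion that rewrites an abstract strand representation of
the diagram (the production bracket enumerates all states over a port
graph), and the facet oracle enumerates all vertex subsets (the production
filtration diffs maximal-clique sets).
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from knotjones.jones import LOOP, LaurentPolynomial, segment_cycle_count


# --------------------------------------------------------------------------
# recursive skein-expansion bracket
# --------------------------------------------------------------------------

def _initial_state(D):
    strands = []
    open_j = 0
    for ci, plist in enumerate(D.passes):
        passes = [(cid, role) for (_e, _t, cid, role) in plist]
        if D.closed_flags[ci]:
            strands.append({"open": False, "passes": passes})
        else:
            strands.append({
                "open": True,
                "ends": tuple(D.open_labels[open_j]),
                "passes": passes,
            })
            open_j += 1
    signs = {c.id: c.sign for c in D.crossings}
    return strands, signs


def _locate(strands, cid):
    out = []
    for si, s in enumerate(strands):
        for pi, (c, _role) in enumerate(s["passes"]):
            if c == cid:
                out.append((si, pi))
    return out


def _flip_signs(signs, reversed_passes):
    counts = {}
    for (c, _r) in reversed_passes:
        counts[c] = counts.get(c, 0) + 1
    out = dict(signs)
    for c, k in counts.items():
        if c in out and k == 1:
            out[c] = -out[c]
    return out


def _smooth(strands, signs, loops, cid, preserve):
    """Remove crossing ``cid`` with the orientation-preserving or the
    orientation-reversing reconnection; returns (strands, signs, loops)."""
    strands = [dict(s, passes=list(s["passes"])) for s in strands]
    signs = {c: s for c, s in signs.items() if c != cid}
    locs = _locate(strands, cid)
    assert len(locs) == 2
    (si, pi), (ti, qi) = locs
    if si == ti:
        s = strands.pop(si)
        p, q = sorted((pi, qi))
        if s["open"]:
            a, b, c = s["passes"][:p], s["passes"][p + 1:q], s["passes"][q + 1:]
            if preserve:
                new = [{"open": True, "ends": s["ends"], "passes": a + c}]
                if b:
                    new.append({"open": False, "passes": b})
                else:
                    loops += 1
                strands.extend(new)
            else:
                signs = _flip_signs(signs, b)
                strands.append(
                    {"open": True, "ends": s["ends"], "passes": a + b[::-1] + c}
                )
        else:
            # rotate the cyclic pass list so position p comes first
            cyc = s["passes"][p:] + s["passes"][:p]
            qq = (q - p) % len(s["passes"])
            m1, m2 = cyc[1:qq], cyc[qq + 1:]
            if preserve:
                for part in (m1, m2):
                    if part:
                        strands.append({"open": False, "passes": part})
                    else:
                        loops += 1
            else:
                signs = _flip_signs(signs, m2)
                merged = m1 + m2[::-1]
                if merged:
                    strands.append({"open": False, "passes": merged})
                else:
                    loops += 1
        return strands, signs, loops

    S, T = strands[si], strands[ti]
    if not S["open"] and T["open"]:  # the pairing is symmetric in the two passes
        S, T = T, S
        si, ti = ti, si
        pi, qi = qi, pi
    for idx in sorted((si, ti), reverse=True):
        strands.pop(idx)
    if S["open"] and T["open"]:
        s_pre, s_post = S["passes"][:pi], S["passes"][pi + 1:]
        t_pre, t_post = T["passes"][:qi], T["passes"][qi + 1:]
        if preserve:
            strands.append({"open": True, "ends": (S["ends"][0], T["ends"][1]),
                            "passes": s_pre + t_post})
            strands.append({"open": True, "ends": (T["ends"][0], S["ends"][1]),
                            "passes": t_pre + s_post})
        else:
            signs = _flip_signs(signs, t_pre + t_post)
            strands.append({"open": True, "ends": (S["ends"][0], T["ends"][0]),
                            "passes": s_pre + t_pre[::-1]})
            strands.append({"open": True, "ends": (T["ends"][1], S["ends"][1]),
                            "passes": t_post[::-1] + s_post})
    elif S["open"] and not T["open"]:
        s_pre, s_post = S["passes"][:pi], S["passes"][pi + 1:]
        u = T["passes"][qi + 1:] + T["passes"][:qi]  # cyclic rest after the pass
        if preserve:
            strands.append({"open": True, "ends": S["ends"],
                            "passes": s_pre + u + s_post})
        else:
            signs = _flip_signs(signs, u)
            strands.append({"open": True, "ends": S["ends"],
                            "passes": s_pre + u[::-1] + s_post})
    else:  # both closed
        v = S["passes"][pi + 1:] + S["passes"][:pi]
        u = T["passes"][qi + 1:] + T["passes"][:qi]
        if preserve:
            merged = v + u
        else:
            signs = _flip_signs(signs, u)
            merged = v + u[::-1]
        if merged:
            strands.append({"open": False, "passes": merged})
        else:
            loops += 1
    return strands, signs, loops


def skein_bracket(D) -> LaurentPolynomial:
    """Bracket polynomial by recursive skein expansion (oracle)."""
    L_hat = D.L_hat
    G = D.G

    def recurse(strands, signs, loops):
        live = [c for s in strands for (c, _r) in s["passes"]]
        if not live:
            n_loops = loops + sum(1 for s in strands if not s["open"])
            S_hat = [s["ends"] for s in strands if s["open"]]
            cyc = segment_cycle_count(L_hat, S_hat, G) if G else 0
            return LOOP ** (n_loops + cyc - 1)
        cid = live[0]
        sign = signs[cid]
        # A-smoothing preserves orientation iff the under-direction is CCW
        # from the over-direction (sign > 0); B is the other reconnection
        out = LaurentPolynomial()
        for choice, coeff_exp in (("A", 1), ("B", -1)):
            preserve = (choice == "A") == (sign > 0)
            s2, g2, l2 = _smooth(strands, signs, loops, cid, preserve)
            out = out + recurse(s2, g2, l2).shift(coeff_exp)
        return out

    strands, signs = _initial_state(D)
    return recurse(strands, signs, 0)


# --------------------------------------------------------------------------
# brute-force facet filtration
# --------------------------------------------------------------------------

def brute_force_facets(entries: np.ndarray, criticals, tol: float = 1e-9):
    """All facets with (birth, death) by subset enumeration (n <= ~10)."""
    n = entries.shape[0]
    verts = list(range(n))

    def is_clique(sub, r):
        return all(entries[i, j] <= r + 0.5 * tol for i, j in itertools.combinations(sub, 2))

    def maximal_sets(r):
        cliques = [
            frozenset(sub)
            for k in range(1, n + 1)
            for sub in itertools.combinations(verts, k)
            if is_clique(sub, r)
        ]
        return {
            c for c in cliques
            if not any(c < other for other in cliques)
        }

    params = [0.0] + [float(r) for r in criticals]
    snapshots = [maximal_sets(r) for r in params]
    bars = {}
    for f in set().union(*snapshots):
        present = [k for k, snap in enumerate(snapshots) if f in snap]
        birth = params[present[0]]
        after = present[-1] + 1
        death = math.inf if after == len(params) else params[after]
        bars[f] = (birth, death)
    return bars
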