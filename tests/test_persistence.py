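"""Facet filtration, weighted barcodes/diagrams, bottleneck distance."""

import itertools
import math

import numpy as np
import pytest

from knotjones import (
    CurveCollection,
    DistanceMatrix,
    Polyline,
    bottleneck_weighted,
    critical_values,
    diagram_from_barcode,
    distance_matrix,
    facet_filtration,
    loop_value,
    make_ideal_helix,
    midpoint_segmentation,
    perturb,
    segment_at_midpoints,
    weighted_barcode,
)
from knotjones.jones import JonesSettings
from knotjones.persistence import DiagramPoint, WeightedDiagram, _maximal_cliques

from _oracles import brute_force_facets


def collinear_seg(spacing=1.0, n=3):
    pts = np.array([[spacing * k, 0.0, 0.0] for k in range(n)])
    return segment_at_midpoints(Polyline(pts))


def random_metric(rng, n):
    pts = rng.normal(scale=2.0, size=(n, 3))
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return DistanceMatrix(d)


class TestCriticalValues:
    def test_collinear(self):
        D = distance_matrix(collinear_seg())
        assert critical_values(D) == pytest.approx([1.0, 2.0])

    def test_single_point(self):
        D = DistanceMatrix(np.zeros((1, 1)))
        assert len(critical_values(D)) == 0

    def test_helix_first_three(self, helix19_seg):
        _, D = helix19_seg
        cv = critical_values(D)
        assert cv[:3] == pytest.approx([3.830, 5.054, 5.433], abs=1e-3)

    def test_tie_grouping(self):
        e = np.array([[0.0, 1.0, 1.0 + 1e-12], [1.0, 0.0, 2.0], [1.0 + 1e-12, 2.0, 0.0]])
        e = 0.5 * (e + e.T)
        assert len(critical_values(DistanceMatrix(e))) == 2


class TestFacetFiltration:
    def test_collinear_toy(self):
        bars = facet_filtration(distance_matrix(collinear_seg()))
        assert len(bars) == 6
        by_dim = {k: [(b.vertex_set, b.birth, b.death) for b in bars if b.dimension == k]
                  for k in (0, 1, 2)}
        assert all(b == 0.0 and d == 1.0 for _, b, d in by_dim[0])
        assert {frozenset(v) for v, _, _ in by_dim[1]} == {frozenset({0, 1}), frozenset({1, 2})}
        assert all(b == 1.0 and d == 2.0 for _, b, d in by_dim[1])
        assert by_dim[2] == [(frozenset({0, 1, 2}), 2.0, math.inf)]

    def test_helix_panel_counts(self, helix19_seg):
        seg, D = helix19_seg
        bars = facet_filtration(D)
        d0 = [b for b in bars if b.dimension == 0]
        d1 = [b for b in bars if b.dimension == 1]
        adj = [b for b in d1 if seg.is_sequence_adjacent(*sorted(b.vertex_set))]
        non = [b for b in d1 if not seg.is_sequence_adjacent(*sorted(b.vertex_set))]
        assert len(d0) == 19
        assert len(adj) == 18
        assert len(non) == 16
        assert all(b.death == pytest.approx(3.830, abs=0.01) for b in d0)
        assert all(b.death == pytest.approx(5.433, abs=0.01) for b in adj)
        assert all(b.lifespan < 0.5 for b in non)  # short-lived

    def test_strands_panel_counts(self, strands8_seg):
        seg, D = strands8_seg
        bars = facet_filtration(D)
        d0 = [b for b in bars if b.dimension == 0]
        d1 = [b for b in bars if b.dimension == 1]
        adj = [b for b in d1 if seg.is_sequence_adjacent(*sorted(b.vertex_set))]
        assert (len(d0), len(adj), len(d1) - len(adj)) == (16, 14, 8)

    def test_matches_brute_force_on_random_configurations(self):
        rng = np.random.default_rng(31)
        for k in range(30):
            D = random_metric(rng, int(rng.integers(2, 9)))
            bars = facet_filtration(D)
            oracle = brute_force_facets(D.entries, critical_values(D))
            got = {b.vertex_set: (b.birth, b.death) for b in bars}
            assert got.keys() == oracle.keys()
            for f, (birth, death) in oracle.items():
                assert got[f][0] == pytest.approx(birth)
                assert got[f][1] == pytest.approx(death) or (
                    math.isinf(got[f][1]) and math.isinf(death)
                )

    def test_facets_are_maximal_cliques_at_every_critical_value(self):
        rng = np.random.default_rng(5)
        D = random_metric(rng, 7)
        bars = facet_filtration(D)
        for r in critical_values(D):
            live = {b.vertex_set for b in bars if b.birth <= r < b.death}
            assert live == _maximal_cliques(D, float(r))

    def test_vr_nesting(self):
        """Every clique of the complex at x is contained in a clique at y>x."""
        rng = np.random.default_rng(6)
        D = random_metric(rng, 6)
        cv = critical_values(D)
        for x, y in zip(cv[:-1], cv[1:]):
            for c in _maximal_cliques(D, float(x)):
                assert any(c <= big for big in _maximal_cliques(D, float(y)))

    def test_lifespans_nonempty(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            for b in facet_filtration(random_metric(rng, 6)):
                assert b.birth < b.death


class TestWeightedBarcode:
    settings = JonesSettings(n_directions=20)

    def test_single_segment(self):
        seg = collinear_seg(n=2)
        sub = type(seg)(segments=seg.segments[:1],
                        representative_points=seg.representative_points[:1],
                        parent=seg.parent, component_index=[0], position=[0])
        D = distance_matrix(sub)
        B = weighted_barcode(sub, D, jones_settings=self.settings)
        assert len(B.bars) == 1
        assert B.bars[0].weight == 0.0  # relative convention
        raw = weighted_barcode(sub, D, jones_settings=self.settings,
                               weight_convention="raw")
        assert raw.bars[0].weight == 1.0

    def test_two_distant_segments(self):
        L = CurveCollection([
            Polyline(np.array([[0.0, 0, 0], [1, 0, 0]])),
            Polyline(np.array([[0.0, 50, 0], [1, 50, 0]])),
        ])
        seg = midpoint_segmentation(L)
        D = distance_matrix(seg)
        raw = weighted_barcode(seg, D, jones_settings=self.settings,
                               weight_convention="raw")
        pair = [b for b in raw.bars if b.dimension == 1][0]
        assert pair.weight == pytest.approx(loop_value(10.0), abs=1e-6)
        rel = weighted_barcode(seg, D, jones_settings=self.settings)
        assert [b for b in rel.bars if b.dimension == 1][0].weight == pytest.approx(0.0)

    def test_collinear_bar_count(self):
        seg = collinear_seg(spacing=3.8)
        B = weighted_barcode(seg, distance_matrix(seg), jones_settings=self.settings)
        assert len(B.bars) == 6

    def test_helix_zero_facet_weights_are_zero(self, helix19_seg):
        seg, D = helix19_seg
        B = weighted_barcode(seg, D, jones_settings=self.settings, max_weight_size=2)
        w0 = {b.weight for b in B.bars_of_dimension(0)}
        assert w0 == {0.0}

    def test_oversize_facets_uncomputed(self, helix19_seg):
        seg, D = helix19_seg
        B = weighted_barcode(seg, D, jones_settings=self.settings, max_weight_size=2)
        assert all(b.weight is None for b in B.bars if len(b.vertex_set) > 2)

    def test_unknown_convention(self, helix19_seg):
        seg, D = helix19_seg
        with pytest.raises(ValueError):
            weighted_barcode(seg, D, weight_convention="absolute")

    def test_export_roundtrip(self, tmp_path, helix19_seg):
        import json

        seg, D = helix19_seg
        B = weighted_barcode(seg, D, jones_settings=self.settings, max_weight_size=1)
        data = json.loads(B.to_json())
        assert len(data["bars"]) == len(B.bars)
        p = tmp_path / "bars.csv"
        B.to_csv(p)
        assert len(p.read_text().splitlines()) == len(B.bars) + 1


class TestWeightedDiagram:
    def test_helix_one_facet_multiplicities(self, helix19_seg):
        seg, D = helix19_seg
        B = weighted_barcode(seg, D, max_weight_size=0)  # geometry only
        dg = diagram_from_barcode(B, dimension=1)
        by_interval = {}
        for p in dg.points:
            key = (round(p.birth, 2), round(p.death, 2))
            by_interval[key] = by_interval.get(key, 0) + p.multiplicity
        assert by_interval == {(3.83, 5.43): 18, (5.05, 5.43): 16}

    def test_multiplicities_match_beta_alternating_sum(self, helix19_seg):
        """μ_ij must equal the alternating sum of the facet-counting function
        β at the corners of the (b_{i-1},b_i]×(b_{j-1},b_j] box."""
        seg, D = helix19_seg
        B = weighted_barcode(seg, D, max_weight_size=0)
        k = 1
        bars = [(b.birth, b.death) for b in B.bars_of_dimension(k)]
        cv = list(critical_values(D))
        # interleaved values b_{-1} < r_0 < b_0 < r_1 < ... (r_0 = 0 here)
        params = [0.0] + cv
        inter = [-1.0] + [0.5 * (a + b) for a, b in zip(params[:-1], params[1:])] \
            + [params[-1] + 1.0]

        def beta(x, y):
            return sum(1 for (b, d) in bars if b <= x and y < d)

        dg = diagram_from_barcode(B, dimension=k)
        for i, ri in enumerate(params):
            for j, rj in enumerate(params):
                if not i < j:
                    continue
                mu = (beta(inter[i], inter[j + 1]) - beta(inter[i + 1], inter[j + 1])
                      + beta(inter[i + 1], inter[j]) - beta(inter[i], inter[j]))
                assert mu >= 0
                got = sum(p.multiplicity for p in dg.points
                          if abs(p.birth - ri) < 1e-9 and abs(p.death - rj) < 1e-9)
                assert got == mu

    def test_empty_barcode_gives_empty_diagram(self):
        from knotjones.persistence import WeightedBarcode

        B = WeightedBarcode(bars=[], critical_values=np.array([]),
                            weight_convention="relative", t=10.0)
        assert diagram_from_barcode(B).points == []


def point(b, d, w, m=1):
    return DiagramPoint(b, d, w, m)


def diag(*pts):
    return WeightedDiagram(points=list(pts))


class TestBottleneck:
    def test_identity_is_zero(self):
        d = diag(point(0.0, 2.0, 0.5), point(1.0, 3.0, -1.0, 2))
        assert bottleneck_weighted(d, d) == 0.0

    def test_single_bar_vs_empty(self):
        assert bottleneck_weighted(diag(point(0.0, 2.0, 0.0)), diag()) == pytest.approx(1.0)

    def test_unmatching_caps_weight_difference(self):
        """Leaving both copies of a short bar unmatched costs its
        half-persistence, which undercuts a large weight difference."""
        a, b = diag(point(0.0, 2.0, 0.0)), diag(point(0.0, 2.0, 5.0))
        assert bottleneck_weighted(a, b) == pytest.approx(1.0)

    def test_weight_term_dominates_for_persistent_bars(self):
        a, b = diag(point(0.0, 20.0, 0.0)), diag(point(0.0, 20.0, 5.0))
        assert bottleneck_weighted(a, b) == pytest.approx(5.0)

    def test_birth_death_terms(self):
        a = diag(point(0.0, 10.0, 0.0))
        b = diag(point(0.3, 9.0, 0.0))
        assert bottleneck_weighted(a, b) == pytest.approx(1.0)

    def test_infinite_bars_must_match_each_other(self):
        a = diag(point(1.0, math.inf, 0.0))
        b = diag(point(1.5, math.inf, 0.2))
        assert bottleneck_weighted(a, b) == pytest.approx(0.5)
        assert bottleneck_weighted(a, diag()) == math.inf

    def test_uncomputed_weights_rejected(self):
        with pytest.raises(ValueError):
            bottleneck_weighted(diag(point(0, 1, None)), diag())

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(17)
        diags = []
        for _ in range(6):
            pts = [point(float(b), float(b + rng.random() * 3 + 0.1),
                         float(rng.normal()), int(rng.integers(1, 3)))
                   for b in rng.random(int(rng.integers(1, 4))) * 2]
            diags.append(diag(*pts))
        for a, b in itertools.combinations(diags, 2):
            assert bottleneck_weighted(a, b) == pytest.approx(bottleneck_weighted(b, a))
        for a, b, c in itertools.combinations(diags, 3):
            ab, bc, ac = (bottleneck_weighted(a, b), bottleneck_weighted(b, c),
                          bottleneck_weighted(a, c))
            assert ac <= ab + bc + 1e-9

    def test_matching_returned(self):
        a = diag(point(0.0, 5.0, 0.0), point(0.0, 0.5, 0.0))
        b = diag(point(0.1, 5.0, 0.1))
        dist, m = bottleneck_weighted(a, b, return_matching=True)
        assert dist == pytest.approx(0.25)
        assert len(m.pairs) == 1


class TestBarcodeStability:
    def test_bottleneck_shrinks_with_perturbation(self):
        """ε-perturbing an 8-residue helix moves the weighted diagram by at
        most ~max(2ε, weight drift), decreasing with ε."""
        L = CurveCollection([make_ideal_helix(8)])
        js = JonesSettings(n_directions=16)

        def diagram_of(coll):
            seg = midpoint_segmentation(coll)
            D = distance_matrix(seg)
            B = weighted_barcode(seg, D, jones_settings=js, max_weight_size=8)
            return diagram_from_barcode(B)

        base = diagram_of(L)
        dists = []
        for eps in (1e-2, 1e-3):
            dists.append(bottleneck_weighted(base, diagram_of(perturb(L, eps, seed=42))))
        assert dists[1] < dists[0]
        assert dists[0] < max(2e-2, 0.1)
        assert dists[1] < max(2e-3, 0.05)
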