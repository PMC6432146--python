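"""Alexander-polynomial classification against closed-form oracles."""

import numpy as np
import pytest

from knotswap.init_config import make_knot_template
from knotswap.model import BeadChain, WallSlab
from knotswap.topology import (
    ClosedPolygon,
    alexander_at,
    classify,
    close_radial,
    close_semicircle,
    delta_p,
    delta_p_reference,
    project_and_cross,
    radial_anchors,
    simplify,
)

#: closed-form Delta(-1.1)*Delta(-1/1.1) values
REF = {"unknot": 1.0, "3_1": 9.054628, "4_1": 25.090992,
       "composite_31_41": 9.054628 * 25.090992}


@pytest.fixture(scope="module", params=["unknot", "3_1", "4_1"])
def template_poly(request):
    return request.param, ClosedPolygon(make_knot_template(request.param).curve)


class TestAlexanderOracles:
    def test_reference_values_match_closed_forms(self):
        for label, ref in REF.items():
            assert delta_p_reference(label) == pytest.approx(ref, rel=1e-5)

    def test_template_delta_p(self, template_poly):
        label, poly = template_poly
        kc = classify(poly, seed=3)
        assert kc.label == label
        assert kc.delta_p == pytest.approx(delta_p_reference(label), rel=1e-6)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5, 6])
    def test_projection_direction_invariance(self, template_poly, seed):
        label, poly = template_poly
        assert classify(poly, seed=seed).label == label

    def test_knot_determinant_at_minus_one(self):
        # |Delta(-1)| is the knot determinant: 3 for 3_1, 5 for 4_1
        for label, det in (("3_1", 3.0), ("4_1", 5.0)):
            poly = simplify(ClosedPolygon(make_knot_template(label).curve))
            diagram = project_and_cross(poly, [0.3, 0.2, 0.93], seed=5)
            assert alexander_at(diagram, -1.0) == pytest.approx(det, rel=1e-8)

    def test_trefoil_symmetry_axis_projection_has_three_crossings(self):
        poly = ClosedPolygon(make_knot_template("3_1").curve)
        diagram = project_and_cross(poly, [0.0, 0.0, 1.0], seed=5)
        assert diagram.n_crossings == 3

    def test_figure_eight_diagrams_have_at_least_four_crossings(self):
        poly = simplify(ClosedPolygon(make_knot_template("4_1").curve))
        for seed in range(4):
            rng = np.random.default_rng(seed)
            diagram = project_and_cross(poly, rng.standard_normal(3), seed=seed)
            assert diagram.n_crossings >= 4

    def test_planar_circle_projects_without_crossings(self):
        poly = ClosedPolygon(make_knot_template("unknot").curve)
        diagram = project_and_cross(poly, [0.2, 0.3, 0.93], seed=5)
        assert diagram.n_crossings == 0
        assert alexander_at(diagram, -1.1) == pytest.approx(1.0)

    def test_reciprocal_product_invariance_raw_vs_simplified(self,
                                                             template_poly):
        label, poly = template_poly
        raw = project_and_cross(poly, [0.3, -0.5, 0.81], seed=7)
        red = project_and_cross(simplify(poly), [0.11, 0.47, -0.87], seed=7)
        assert delta_p(raw) == pytest.approx(delta_p(red), rel=1e-6)


class TestSimplify:
    def test_preserves_delta_p_and_reduces(self, template_poly):
        label, poly = template_poly
        red = simplify(poly)
        assert red.n_vertices <= poly.n_vertices
        if label != "unknot":
            assert red.n_vertices < poly.n_vertices // 4
        assert classify(red, seed=3).delta_p == pytest.approx(
            delta_p_reference(label), rel=1e-6)

    def test_idempotent_at_fixpoint(self, template_poly):
        _, poly = template_poly
        once = simplify(poly)
        twice = simplify(once)
        assert np.array_equal(once.vertices, twice.vertices)

    def test_triangle_is_a_fixpoint(self):
        tri = ClosedPolygon(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.1]],
                                     dtype=float))
        assert simplify(tri).n_vertices == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_preserves_delta_p_on_randomized_knots(self, seed):
        """Randomly rotated/jittered templates keep their invariant."""
        rng = np.random.default_rng(seed)
        label = ("3_1", "4_1")[seed % 2]
        pts = make_knot_template(label).curve.copy()
        # random rotation
        q = rng.standard_normal((3, 3))
        qr, _ = np.linalg.qr(q)
        pts = pts @ qr
        pts += 0.01 * rng.standard_normal(pts.shape)
        kc = classify(ClosedPolygon(pts), seed=seed)
        assert kc.delta_p == pytest.approx(delta_p_reference(label), rel=1e-3)


class TestClosures:
    def _grafted(self, n=40, l=10.0):
        pts = np.zeros((n, 3))
        pts[:, 2] = np.linspace(0, l, n)
        pts[:, 0] = 0.3 * np.sin(np.linspace(0, 3, n))
        return BeadChain(pts, grafted_ends=np.vstack([pts[0], pts[-1]])), \
            WallSlab(l)

    def test_straight_grafted_chain_closes_to_unknot(self):
        chain, slab = self._grafted()
        assert classify(close_semicircle(chain, slab), seed=3).label == "unknot"

    def test_semicircle_radius_independence(self, composite_chain):
        from knotswap.init_config import graft_to_walls
        g = graft_to_walls(composite_chain, 100.0, seed=3)
        slab = WallSlab(100.0)
        p1 = close_semicircle(g, slab)
        bigger = ClosedPolygon(p1.vertices)  # reference
        p2 = close_semicircle(g, slab, n_arc=40)
        d1 = classify(p1, seed=3).delta_p
        d2 = classify(p2, seed=4).delta_p
        assert d1 == pytest.approx(d2, rel=1e-6)
        assert classify(bigger, seed=5).label == "composite_31_41"

    def test_radial_closure_extent_independence(self, composite_chain):
        lab3 = classify(close_radial(composite_chain, extent_factor=3.0),
                        seed=3).label
        lab5 = classify(close_radial(composite_chain, extent_factor=5.0),
                        seed=3).label
        assert lab3 == lab5 == "composite_31_41"

    def test_radial_anchors_reusable(self, composite_chain):
        anchors = radial_anchors(composite_chain)
        poly = close_radial(composite_chain, anchors=anchors)
        assert np.array_equal(poly.provenance["anchors"], anchors)
        assert classify(poly, seed=3).label == "composite_31_41"

    def test_open_arc_closes_to_unknot(self):
        t = np.linspace(0, 1.5 * np.pi, 60)
        pts = np.column_stack([np.cos(t), np.sin(t), 0.01 * t])
        assert classify(close_radial(BeadChain(pts)), seed=3).label == "unknot"


class TestMultiplicativity:
    def test_composite_chain_delta_p_is_product(self, composite_chain):
        kc = classify(close_radial(composite_chain), seed=3)
        ref = delta_p_reference("3_1") * delta_p_reference("4_1")
        assert kc.delta_p == pytest.approx(ref, rel=1e-6)
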