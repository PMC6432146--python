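"""Knot identification on closed curves.

Open chains are first closed — wall-grafted chains by a large lateral
semicircular arc, free chains by radial extension of both ends away from the
center of mass and connection at large distance. The closed polygon is reduced
by topology-preserving vertex elision, projected onto a generic plane, and its
crossing diagram is converted to the Alexander matrix. Knot types are told
apart by the scalar

    Delta_p = |Delta(-1.1)| * |Delta(-1/1.1)|,

the product of the Alexander polynomial at reciprocal points, which cancels
the +-t^k normalization ambiguity of the determinant and separates the knot
types handled here (unknot, 3_1, 4_1 and their connected sum) by two orders
of magnitude in band position.

Caveat: the Alexander polynomial cannot distinguish the composite 3_1 # 4_1
from certain prime knots with the same Delta_p (e.g. 8_21). Configurations of
that kind are rare in the regimes studied here and are accepted as composite;
a HOMFLY-based second filter would be needed to exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from knotswap._kernels import closure_min_dist, find_crossings, kmt_reduce
from knotswap.exceptions import ClosureError, ProjectionError
from knotswap.model import BeadChain, WallSlab

#: Evaluation point of the Alexander polynomial (with its reciprocal).
T_EVAL = -1.1

LABELS = ("unknot", "3_1", "4_1", "composite_31_41")

#: Relative half-width of the Delta_p acceptance band around each reference.
BAND_REL_TOL = 0.10


def _alexander_poly_closed_form(label: str, t: float) -> float:
    """Closed-form Alexander polynomials of the knot types handled here."""
    if label == "unknot":
        return 1.0
    if label == "3_1":
        return t - 1.0 + 1.0 / t
    if label == "4_1":
        return -t + 3.0 - 1.0 / t
    if label == "composite_31_41":
        return _alexander_poly_closed_form("3_1", t) * \
            _alexander_poly_closed_form("4_1", t)
    raise ValueError(f"unknown knot label {label!r}")


def delta_p_reference(label: str) -> float:
    """Reference Delta_p = Delta(-1.1) * Delta(-1/1.1) from the closed forms."""
    return abs(_alexander_poly_closed_form(label, T_EVAL)
               * _alexander_poly_closed_form(label, 1.0 / T_EVAL))


@dataclass
class ClosedPolygon:
    """A closed 3D polygon (no implicit repeat of the first vertex)."""

    vertices: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must have shape (n, 3)")
        if self.vertices.shape[0] < 3:
            raise ValueError("a closed polygon needs at least 3 vertices")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]


@dataclass
class CrossingDiagram:
    """Planar crossing data of a projected closed polygon.

    ``under_pos`` / ``over_pos`` give the position of each crossing along the
    polygon as segment index plus fractional parameter; ``sign`` is the
    right-handed crossing sign.
    """

    under_pos: np.ndarray
    over_pos: np.ndarray
    sign: np.ndarray
    direction: np.ndarray

    @property
    def n_crossings(self) -> int:
        return self.under_pos.shape[0]


@dataclass(frozen=True)
class KnotClass:
    """Classification result: the invariant Delta_p and the matched label."""

    delta_p: float
    label: str


# --------------------------------------------------------------------------
# closures
# --------------------------------------------------------------------------

def close_semicircle(
    chain: BeadChain,
    slab: WallSlab,
    n_arc: int = 24,
    min_clearance: float = 0.2,
    max_attempts: int = 8,
) -> ClosedPolygon:
    """Close a wall-grafted chain by a large lateral semicircular arc.

    The arc lies in the plane spanned by the end-to-end vector and a lateral
    direction pointing away from the chain, with a radius exceeding the
    chain's lateral extent so the closure cannot thread the chain. The radius
    is grown geometrically until the arc keeps ``min_clearance`` from the
    chain; failure after ``max_attempts`` raises :class:`ClosureError`.
    """
    pos = chain.positions
    a = pos[0]
    b = pos[-1]
    mid = 0.5 * (a + b)
    lat = np.array([mid[0] - pos[:, 0].mean(), mid[1] - pos[:, 1].mean(), 0.0])
    norm = np.linalg.norm(lat)
    u = lat / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    proj = (pos - mid) @ u
    radius = float(proj.max()) + 3.0
    half = 0.5 * (b - a)
    for _ in range(max_attempts):
        s = np.linspace(0.0, 1.0, n_arc + 2)
        arc = (mid[None, :] - np.cos(np.pi * s)[:, None] * half[None, :]
               + np.sin(np.pi * s)[:, None] * (radius * u)[None, :])
        # polyline from bead N-1 back to bead 0
        arc_back = arc[::-1].copy()
        arc_back[0] = b
        arc_back[-1] = a
        if closure_min_dist(pos, arc_back) > min_clearance:
            verts = np.vstack([pos, arc_back[1:-1]])
            return ClosedPolygon(
                verts,
                provenance={"scheme": "semicircle", "radius": radius,
                            "direction": u.copy(), "n_arc": n_arc},
            )
        radius *= 1.6
    raise ClosureError(
        "semicircular closure intersects the chain at every tried radius")


def radial_anchors(chain: BeadChain, extent_factor: float = 3.0) -> np.ndarray:
    """Fixed closure anchors for a free chain: each end extrapolated away from
    the center of mass, plus one distant waypoint joining them.

    Returned array has shape (3, 3): (anchor for bead N-1, waypoint, anchor
    for bead 0). Holding these fixed while beads are removed keeps the
    closure — and hence the detected knot type — stable during boundary
    scans.
    """
    pos = chain.positions
    com = pos.mean(axis=0)
    extent = float(np.linalg.norm(pos - com, axis=1).max())
    d = extent_factor * extent
    dirs = []
    for end in (pos[-1], pos[0]):
        v = end - com
        nv = np.linalg.norm(v)
        if nv < 1e-9:  # end sitting on the COM: deterministic perturbation
            v = np.array([1.0, 0.0, 0.0])
            nv = 1.0
        dirs.append(v / nv)
    a1 = pos[-1] + d * dirs[0]
    a0 = pos[0] + d * dirs[1]
    m = dirs[0] + dirs[1]
    nm = np.linalg.norm(m)
    if nm < 1e-6:
        # antipodal ends: pick any perpendicular for the waypoint
        m = np.cross(dirs[0], [0.0, 0.0, 1.0])
        if np.linalg.norm(m) < 1e-6:
            m = np.cross(dirs[0], [0.0, 1.0, 0.0])
        nm = np.linalg.norm(m)
    waypoint = com + 2.0 * d * (m / nm)
    return np.vstack([a1, waypoint, a0])


def close_radial(
    chain: BeadChain,
    anchors: Optional[np.ndarray] = None,
    extent_factor: float = 3.0,
) -> ClosedPolygon:
    """Close a free chain through fixed outward anchors.

    Each end is extended along its direction away from the center of mass to
    a distance large against the chain extent; the two extended points are
    joined through a still more distant waypoint so the connecting segments
    stay outside the region occupied by the chain. Pass ``anchors`` (from
    :func:`radial_anchors`) to reuse one closing arc across repeated analyses
    of reduced chains.
    """
    if anchors is None:
        anchors = radial_anchors(chain, extent_factor)
    anchors = np.asarray(anchors, dtype=np.float64)
    if anchors.shape != (3, 3):
        raise ValueError("anchors must have shape (3, 3)")
    verts = np.vstack([chain.positions, anchors])
    return ClosedPolygon(
        verts,
        provenance={"scheme": "radial", "anchors": anchors.copy(),
                    "extent_factor": extent_factor},
    )


# --------------------------------------------------------------------------
# projection, Alexander evaluation, classification
# --------------------------------------------------------------------------

def _basis_for(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 \
        else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def project_and_cross(
    poly: ClosedPolygon,
    direction: Sequence[float],
    max_attempts: int = 12,
    seed: int = 0,
) -> CrossingDiagram:
    """Project the polygon along ``direction`` and list all crossings.

    Non-generic projections (tangencies, matched depths, grazing contacts)
    are retried with a slightly perturbed direction, deterministically seeded;
    :class:`ProjectionError` after ``max_attempts``.
    """
    rng = np.random.default_rng(seed)
    d = np.asarray(direction, dtype=np.float64)
    if np.linalg.norm(d) < 1e-12:
        raise ProjectionError("projection direction must be nonzero")
    for _ in range(max_attempts):
        dn = d / np.linalg.norm(d)
        e1, e2 = _basis_for(dn)
        v = poly.vertices
        xy = np.column_stack([v @ e1, v @ e2])
        depth = v @ dn
        data, m, degen = find_crossings(xy, depth)
        if not degen:
            return CrossingDiagram(
                under_pos=data[:m, 0].copy(),
                over_pos=data[:m, 1].copy(),
                sign=data[:m, 2].copy(),
                direction=dn,
            )
        d = dn + 0.05 * rng.standard_normal(3)
    raise ProjectionError(
        f"no generic projection found after {max_attempts} attempts")


def _alexander_matrix(diagram: CrossingDiagram, t: float) -> Optional[np.ndarray]:
    """Alexander matrix of the diagram at parameter t.

    Underpasses are numbered along the curve; generator arc j runs from
    underpass j to underpass j+1. Row j encodes the crossing relation at
    underpass j between the incoming arc (j-1), the outgoing arc (j), and the
    overpassing arc. Returns None for diagrams with fewer than two
    underpasses (unknot presentation, Delta = 1).
    """
    n = diagram.n_crossings
    if n <= 1:
        return None
    order = np.argsort(diagram.under_pos)
    u_sorted = diagram.under_pos[order]
    over = diagram.over_pos[order]
    sign = diagram.sign[order]
    A = np.zeros((n, n), dtype=np.float64)
    for j in range(n):
        o = int(np.searchsorted(u_sorted, over[j])) - 1
        if o < 0:
            o = n - 1
        jin = (j - 1) % n
        jout = j
        if o == jin or o == jout:
            A[j, jin] += 1.0
            A[j, jout] += -1.0
        elif sign[j] > 0:
            A[j, jin] += 1.0
            A[j, jout] += -t
            A[j, o] += t - 1.0
        else:
            A[j, jin] += -t
            A[j, jout] += 1.0
            A[j, o] += t - 1.0
    return A


def alexander_at(diagram: CrossingDiagram, t: float) -> float:
    """|Delta(t)| of the diagram, up to the usual +-t^k factor.

    Computed as the absolute determinant of the (n-1)x(n-1) minor of the
    Alexander matrix. The t^k ambiguity cancels in the reciprocal product
    used for classification; at t = -1 the value is the knot determinant.
    """
    A = _alexander_matrix(diagram, t)
    if A is None:
        return 1.0
    M = A[:-1, :-1]
    sign, logdet = np.linalg.slogdet(M)
    if sign == 0.0:
        return 0.0
    return float(np.exp(logdet))


def delta_p(diagram: CrossingDiagram, t: float = T_EVAL) -> float:
    """The reciprocal-point product |Delta(t) Delta(1/t)| for the diagram."""
    return alexander_at(diagram, t) * alexander_at(diagram, 1.0 / t)


def _label_from_delta_p(dp: float) -> str:
    best = "other"
    for label in LABELS:
        ref = delta_p_reference(label)
        if abs(dp - ref) <= BAND_REL_TOL * ref:
            best = label
            break
    return best


def simplify(poly: ClosedPolygon) -> ClosedPolygon:
    """Topology-preserving vertex elision (KMT-style reduction).

    A vertex is removed only when the triangle it spans with its neighbors is
    crossed by no other segment, so the knot type — and Delta_p — of the
    polygon is preserved while the vertex count typically drops by an order
    of magnitude. Idempotent at its fixed point.
    """
    reduced = kmt_reduce(poly.vertices)
    prov = dict(poly.provenance)
    prov["simplified_from"] = poly.n_vertices
    return ClosedPolygon(reduced, provenance=prov)


def classify(
    poly: ClosedPolygon,
    seed: int = 0,
    direction: Optional[Sequence[float]] = None,
    pre_simplify: bool = True,
    jitter: float = 1e-6,
) -> KnotClass:
    """Classify a closed polygon as unknot, 3_1, 4_1, composite or other.

    The polygon is reduced, its vertices jittered by ``jitter`` (seeded; this
    resolves exactly-degenerate projections of constructed configurations),
    projected along a seeded random direction (or ``direction``), and
    Delta_p is matched against the closed-form references within a 10%
    relative band. Anything outside every band is labeled ``"other"``.
    """
    work = simplify(poly) if pre_simplify else poly
    rng = np.random.default_rng(seed)
    verts = work.vertices
    if jitter > 0:
        verts = verts + jitter * rng.standard_normal(verts.shape)
        work = ClosedPolygon(verts, provenance=work.provenance)
    if direction is None:
        d = rng.standard_normal(3)
    else:
        d = np.asarray(direction, dtype=np.float64)
    diagram = project_and_cross(work, d, seed=seed + 1)
    dp = delta_p(diagram)
    return KnotClass(delta_p=dp, label=_label_from_delta_p(dp))


def classify_chain(
    chain: BeadChain,
    slab: Optional[WallSlab] = None,
    anchors: Optional[np.ndarray] = None,
    seed: int = 0,
) -> KnotClass:
    """Close an open chain with the scheme fitting its boundary conditions
    (semicircle for grafted chains in a slab, radial otherwise) and classify."""
    if slab is not None and chain.is_grafted:
        poly = close_semicircle(chain, slab)
    else:
        poly = close_radial(chain, anchors=anchors)
    return classify(poly, seed=seed)
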