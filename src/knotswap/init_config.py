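"""Synthetic starting configurations with prescribed knot content.

Chains are built by splicing open knot templates (trefoil from the (2,3)
torus-knot parametrization, figure-eight from its standard trigonometric
parametrization) into a straight backbone and resampling at the target bond
length. Every construction is self-verifying: the finished chain is closed
and classified, and a mismatch with the requested knot content is an error,
never a silent pass. Wall-grafted starts are the same tied chain rotated so
its termini land on the two walls, followed by capped Metropolis relaxation
that removes overlaps without ever changing the topology (checked).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from knotswap import topology
from knotswap._kernels import min_nonadjacent_dist, relax_drive, total_energy_kernel
from knotswap.exceptions import (
    ConstructionError,
    InfeasibleConfinementError,
    RelaxationFailureError,
)
from knotswap.model import BeadChain, ForceField, WallSlab

logger = logging.getLogger(__name__)

#: Default number of beads a freshly tied knot spans (loose-knot regime).
DEFAULT_SPAN = 60


@dataclass(frozen=True)
class KnotTemplate:
    """A smooth closed curve of known knot type."""

    label: str
    curve: np.ndarray  # (M, 3), closed (no repeated endpoint)
    handedness: int = +1


def make_knot_template(label: str, n_points: int = 160) -> KnotTemplate:
    """Parametric closed curve for ``unknot``, ``3_1`` or ``4_1``.

    The returned curve classifies to its own label (verified on
    construction).
    """
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    if label == "unknot":
        curve = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
    elif label == "3_1":
        curve = np.column_stack([
            np.sin(t) + 2.0 * np.sin(2.0 * t),
            np.cos(t) - 2.0 * np.cos(2.0 * t),
            -np.sin(3.0 * t),
        ])
    elif label == "4_1":
        # braid-closure-style parametrization; unlike the torus-style form
        # it does not wind around an axis, so open sub-arcs of it stay
        # figure-eight-knotted under straight-line extension of the ends
        curve = np.column_stack([
            10.0 * (np.cos(t) + np.cos(3.0 * t))
            + np.cos(2.0 * t) + np.cos(4.0 * t),
            6.0 * np.sin(t) + 10.0 * np.sin(3.0 * t),
            4.0 * np.sin(3.0 * t) * np.sin(2.5 * t)
            + 4.0 * np.sin(4.0 * t) - 2.0 * np.sin(6.0 * t),
        ])
    else:
        raise ValueError(f"unknown knot label {label!r}")
    got = topology.classify(topology.ClosedPolygon(curve), seed=1).label
    if got != label:
        raise ConstructionError(
            f"template for {label} classified as {got}")
    return KnotTemplate(label=label, curve=curve)


# --------------------------------------------------------------------------
# path machinery
# --------------------------------------------------------------------------

def _polyline_arclength(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at(pts: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    i = int(np.searchsorted(cum, s, side="right")) - 1
    i = min(max(i, 0), pts.shape[0] - 2)
    ds = cum[i + 1] - cum[i]
    f = 0.0 if ds <= 0 else (s - cum[i]) / ds
    return pts[i] + f * (pts[i + 1] - pts[i])


_ARC_CACHE: dict = {}


def _candidate_arcs(label: str) -> list[np.ndarray]:
    """Open template arcs that stay knotted under straight-chord closure.

    Sub-arcs of the closed template are screened exhaustively over window
    sizes and positions; a candidate survives only if the arc *with its
    endpoints joined directly* — which is exactly what a ClosedPolygon does —
    still classifies to the template's own knot type. Survivors are ranked by
    how smoothly the chord continues the end tangents, so splicing onto a
    straight backbone creates no hairpin corner.
    """
    if label in _ARC_CACHE:
        return _ARC_CACHE[label]
    template = make_knot_template(label)
    curve = template.curve
    big_m = curve.shape[0]
    scored = []
    for m in (big_m // 12, big_m // 8, big_m // 6, big_m // 5, big_m // 4,
              big_m // 3):
        for s0 in range(0, big_m, 4):
            arc = np.roll(curve, -((s0 + m) % big_m), axis=0)[: big_m - m]
            try:
                got = topology.classify(
                    topology.ClosedPolygon(arc), seed=1).label
            except Exception:
                continue
            if got != label:
                continue
            ch = arc[-1] - arc[0]
            ch = ch / np.linalg.norm(ch)
            # second screen: the arc must stay knotted when its ends are
            # extended along the chord line and closed far away, which is
            # the situation after splicing onto a straight backbone
            ext = 4.0 * float(np.linalg.norm(
                arc - arc.mean(axis=0), axis=1).max())
            spliced = np.vstack([arc[0] - ext * ch, arc, arc[-1] + ext * ch])
            got2 = topology.classify_chain(BeadChain(spliced), seed=1).label
            if got2 != label:
                continue
            t0 = arc[1] - arc[0]
            t0 = t0 / np.linalg.norm(t0)
            t1 = arc[-1] - arc[-2]
            t1 = t1 / np.linalg.norm(t1)
            score = min(float(np.dot(t0, ch)), float(np.dot(t1, ch)))
            scored.append((score, arc))
    if not scored:
        raise ConstructionError(
            f"no chord-closable open arc found for template {label}")
    scored.sort(key=lambda x: -x[0])
    _ARC_CACHE[label] = [arc for _, arc in scored]
    return _ARC_CACHE[label]


def _open_template_arc(template: KnotTemplate, cut_rank: int,
                       roll: float) -> np.ndarray:
    """Open arc of the template, rank ``cut_rank`` in junction quality;
    ``roll`` rotates it about the z axis to vary the geometry between
    retries."""
    arcs = _candidate_arcs(template.label) if template.label != "unknot" \
        else [template.curve[1:]]
    arc = arcs[cut_rank % len(arcs)]
    if roll != 0.0:
        c, s = math.cos(roll), math.sin(roll)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        arc = arc @ rot.T
    return arc


def _orient_arc_along(arc: np.ndarray, origin: np.ndarray,
                      direction: np.ndarray, chord_target: float) -> np.ndarray:
    """Rigid-transform an open arc so its chord runs from ``origin`` along
    ``direction`` with length ``chord_target`` (isotropic rescale)."""
    chord = arc[-1] - arc[0]
    clen = np.linalg.norm(chord)
    if clen < 1e-12:
        raise ConstructionError("degenerate template chord")
    scale = chord_target / clen
    pts = (arc - arc[0]) * scale
    # rotate chord onto direction
    a = chord / clen
    b = direction / np.linalg.norm(direction)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else -np.eye(3) + 2.0 * np.outer(b, b)
    else:
        vx = np.array([[0.0, -v[2], v[1]],
                       [v[2], 0.0, -v[0]],
                       [-v[1], v[0], 0.0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return origin + pts @ rot.T


def _splice_arc(path: np.ndarray, s_center: float, arc_len: float,
                chord_frac: float, arc_raw: np.ndarray
                ) -> tuple[np.ndarray, float]:
    """Replace the path window of length arc_len*chord_frac centered at
    arclength s_center by the template arc oriented along the window chord.

    Returns the new path and the arclength where the inserted arc starts
    (the arc then occupies [s0, s0 + arc_len] of the new path)."""
    cum = _polyline_arclength(path)
    chord_len = arc_len * chord_frac
    s0 = s_center - 0.5 * chord_len
    s1 = s_center + 0.5 * chord_len
    if s0 <= 0.0 or s1 >= cum[-1]:
        raise ConstructionError("knot window falls off the chain")
    p0 = _point_at(path, cum, s0)
    p1 = _point_at(path, cum, s1)
    chord_vec = p1 - p0
    if np.linalg.norm(chord_vec) < 0.5 * chord_len:
        raise ConstructionError("path too curved inside the knot window")
    arc = _orient_arc_along(arc_raw, p0, chord_vec,
                            float(np.linalg.norm(chord_vec)))
    before = path[cum[: path.shape[0]] < s0]
    after = path[cum[: path.shape[0]] > s1]
    return np.vstack([before, arc, after]), s0


def _resample(path: np.ndarray, n_beads: int) -> np.ndarray:
    """Place n_beads points along the path with uniform euclidean spacing.

    The spacing is tuned by bisection so the last bead lands on the path end
    (all bonds then share one length; corner-cutting shortens none below 90%
    of the nominal spacing for the gentle paths built here).
    """
    total = _polyline_arclength(path)[-1]
    lo = 0.80 * total / (n_beads - 1)
    hi = 1.02 * total / (n_beads - 1)

    def walk(spacing: float) -> tuple[int, np.ndarray, float]:
        """Place beads at exact euclidean distance `spacing` from the
        previous bead (sphere/polyline intersection). Returns (#placed,
        points, leftover distance to the path end)."""
        out = np.empty((n_beads, 3))
        out[0] = path[0]
        prev = path[0]
        cur = path[0].copy()
        vi = 0
        for b in range(1, n_beads):
            placed = False
            while vi < path.shape[0] - 1:
                q1 = path[vi + 1]
                d = q1 - cur
                seg_len = float(np.linalg.norm(d))
                if seg_len < 1e-15:
                    vi += 1
                    cur = q1.copy()
                    continue
                u = d / seg_len
                w = cur - prev
                bq = float(np.dot(w, u))
                cq = float(np.dot(w, w)) - spacing * spacing
                disc = bq * bq - cq
                if disc >= 0.0:
                    tstep = -bq + math.sqrt(disc)
                    if 0.0 <= tstep <= seg_len:
                        cur = cur + tstep * u
                        placed = True
                        break
                vi += 1
                cur = q1.copy()
            if not placed:
                return b, out, -1.0
            out[b] = cur
            prev = out[b]
        return n_beads, out, float(np.linalg.norm(path[-1] - cur))

    best = None
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        n_placed, pts, leftover = walk(mid)
        if n_placed < n_beads:
            hi = mid  # spacing too large: ran out of path
            continue
        best = pts
        if leftover < 1e-7:
            break
        lo = mid  # spacing too small: stopped short of the end
    if best is None:
        raise ConstructionError("resampling failed to place all beads")
    return best


def _expected_label(labels: Sequence[str]) -> str:
    if not labels:
        return "unknot"
    if len(labels) == 1:
        return labels[0]
    if sorted(labels) == ["3_1", "4_1"]:
        return "composite_31_41"
    raise ValueError("only 3_1, 4_1 and their composite are supported")


def tie_knots_on_chain(
    n_beads: int,
    knots: Sequence[tuple],
    bond_target: float = 0.97,
    seed: int = 0,
    max_attempts: int = 12,
) -> BeadChain:
    """Build an open chain of ``n_beads`` containing the requested knots.

    ``knots`` is a list of ``(label, center_fraction)`` or
    ``(label, center_fraction, span_beads)`` entries; span defaults to 60
    beads (the loose-knot regime). Overlapping windows are allowed and
    produce an intertwined start in which the later (smaller-span) knot is
    tied inside the earlier one. The result is self-verified by closing and
    classifying the chain; construction retries with re-rolled templates
    before giving up.
    """
    knots = [(k[0], float(k[1]), int(k[2]) if len(k) > 2 else DEFAULT_SPAN)
             for k in knots]
    expected = _expected_label([k[0] for k in knots])
    contour = (n_beads - 1) * bond_target
    rng = np.random.default_rng(seed)
    last_err: Optional[Exception] = None
    for attempt in range(max_attempts):
        try:
            # prepare template arcs; each knot consumes arc_len of contour but
            # advances the backbone by only its chord
            arcs = []
            for label, frac, span in knots:
                template = make_knot_template(label)
                arc_raw = _open_template_arc(
                    template, cut_rank=attempt,
                    roll=float(rng.uniform(0.0, 2.0 * np.pi)) if attempt else 0.0)
                arc_len_rel = _polyline_arclength(arc_raw)[-1]
                chord_rel = float(np.linalg.norm(arc_raw[-1] - arc_raw[0]))
                chord_frac = chord_rel / arc_len_rel
                arc_len = span * bond_target
                arcs.append((frac, arc_len, chord_frac, arc_raw))
            backbone = contour - sum(a[1] * (1.0 - a[2]) for a in arcs)
            if backbone <= sum(a[1] * a[2] for a in arcs):
                raise ConstructionError("knots do not fit on the backbone")
            path = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, backbone]])
            # disjoint windows: splice left to right, centering each knot at
            # final-chain arclength frac*contour; overlapping windows: big
            # knot first, the smaller one is then tied into the middle of
            # the bigger arc (intertwined start)
            windows = [(f * contour - 0.5 * al, f * contour + 0.5 * al)
                       for f, al, _, _ in arcs]
            disjoint = all(windows[i][1] < windows[j][0]
                           for i in range(len(arcs))
                           for j in range(len(arcs))
                           if windows[i][0] < windows[j][0] and i != j)
            if disjoint:
                order = sorted(range(len(arcs)), key=lambda i: arcs[i][0])
            else:
                order = sorted(range(len(arcs)), key=lambda i: -arcs[i][1])
            regions: dict[int, list[float]] = {}
            for rank, idx in enumerate(order):
                frac, arc_len, chord_frac, arc_raw = arcs[idx]
                extra = arc_len * (1.0 - chord_frac)
                if disjoint or rank == 0:
                    # window center so the *inserted arc* is centered at
                    # frac*contour of the finished chain
                    s_center = frac * contour - 0.5 * extra
                else:
                    host = regions[order[0]]
                    s_center = 0.5 * (host[0] + host[1]) - 0.5 * extra
                path, s0 = _splice_arc(path, s_center, arc_len, chord_frac,
                                       arc_raw)
                for r in regions.values():
                    if r[0] >= s0:  # splice happened left of this region
                        r[0] += extra
                        r[1] += extra
                    elif r[0] < s0 < r[1]:  # nested inside this region
                        r[1] += extra
                regions[idx] = [s0, s0 + arc_len]
            pts = _resample(path, n_beads)
            bonds = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            if bonds.min() < 0.9 * 0.97 or bonds.max() > 1.05:
                raise ConstructionError(
                    f"bead spacing out of range [{bonds.min():.3f}, "
                    f"{bonds.max():.3f}]")
            bead_regions = [
                [knots[i][0],
                 int(round(regions[i][0] / bond_target)),
                 int(round(regions[i][1] / bond_target))]
                for i in range(len(knots))
            ]
            chain = BeadChain(pts, knot_spec={
                "n_beads": n_beads,
                "knots": [list(k) for k in knots],
                "regions": bead_regions,
                "bond_target": bond_target,
                "seed": seed,
            })
            got = topology.classify_chain(chain, seed=2).label
            if got != expected:
                raise ConstructionError(
                    f"built chain classifies as {got}, wanted {expected}")
            # 0.55 sigma keeps the WCA energy finite; `relax` opens the
            # remaining tight contacts without touching the topology
            if knots and min_nonadjacent_dist(pts) < 0.55:
                raise ConstructionError("knot strands too close; increase span")
            return chain
        except ConstructionError as err:
            last_err = err
            continue
    raise ConstructionError(
        f"could not tie {knots} on {n_beads} beads: {last_err}")


def graft_to_walls(
    chain: BeadChain,
    l: float,
    ff: Optional[ForceField] = None,
    relax_sweeps: int = 200,
    seed: int = 0,
) -> BeadChain:
    """Anchor the chain's termini to two walls at separation ``l``.

    The chain is rebuilt from its knot specification (tilted so the
    end-to-end vector spans exactly the slab) and relaxed against the walls
    with topology verification. Knot spans shrink automatically if the
    requested separation leaves too little slack.
    """
    ff = ff or ForceField()
    n = chain.n_beads
    if l >= (n - 1) * ff.fene_R0:
        raise InfeasibleConfinementError(
            f"l={l} exceeds the maximum contour (N-1)*R0={(n - 1) * ff.fene_R0}")
    if chain.knot_spec is None:
        raise ConstructionError(
            "graft_to_walls needs the generator's knot_spec metadata")
    spec = dict(chain.knot_spec)
    knots = [tuple(k) for k in spec["knots"]]
    bond_target = spec["bond_target"]
    spans = [k[2] for k in knots]
    for shrink in range(6):
        trial = [(k[0], k[1], max(30, int(s * 0.8 ** shrink)))
                 for k, s in zip(knots, spans)]
        straight = tie_knots_on_chain(n, trial, bond_target=bond_target,
                                      seed=spec.get("seed", 0))
        e0 = straight.end_to_end()
        if e0 > l * 1.001 or abs(e0 - l) < 1e-9:
            break
    else:
        # tight confinement: stretch bonds uniformly (FENE allows up to R0;
        # we cap well below at 8%) before giving up
        if l / e0 <= 1.08:
            straight = BeadChain(straight.positions * (l / e0),
                                 knot_spec=straight.knot_spec)
            e0 = straight.end_to_end()
        else:
            raise InfeasibleConfinementError(
                f"end-to-end {e0:.1f} cannot reach wall distance {l}")
    # tilt: map the end-to-end axis (z) to a diagonal with z-extent exactly l
    cosb = min(l / e0, 1.0)
    sinb = math.sqrt(max(1.0 - cosb * cosb, 0.0))
    rot = np.array([[cosb, 0.0, sinb], [0.0, 1.0, 0.0], [-sinb, 0.0, cosb]])
    pts = (straight.positions - straight.positions[0]) @ rot.T
    # the build axis is z; after rotation the ends sit at z=0 and z=l
    pts[:, 2] -= pts[0, 2]
    zf = pts[-1, 2]
    if abs(zf - l) > 1e-6 * max(l, 1.0):
        pts[:, 2] *= l / zf
    if pts[1:-1, 2].min() <= 0.0 or pts[1:-1, 2].max() >= l:
        raise ConstructionError(
            "knot region pokes through a wall; move center fractions inward")
    grafted = BeadChain(pts, grafted_ends=np.vstack([pts[0], pts[-1]]),
                        knot_spec={**spec, "knots": [list(t) for t in trial],
                                   "wall_l": l})
    slab = WallSlab(l)
    before = topology.classify_chain(grafted, slab=slab, seed=2).label
    grafted = relax(grafted, ff, slab=slab, n_sweeps=relax_sweeps, seed=seed)
    after = topology.classify_chain(grafted, slab=slab, seed=2).label
    if before != after:
        raise RelaxationFailureError(
            f"grafting relaxation changed topology {before} -> {after}")
    return grafted


def relax(
    chain: BeadChain,
    ff: Optional[ForceField] = None,
    slab: Optional[WallSlab] = None,
    n_sweeps: int = 200,
    max_disp: float = 0.1,
    seed: int = 0,
    check_topology: bool = True,
) -> BeadChain:
    """Capped-displacement Metropolis relaxation.

    Removes overlaps and overstretched bonds left by geometric construction.
    With ``max_disp`` at its 0.1 sigma default a single move cannot carry a
    bead through another strand, and the knot type is re-verified afterwards
    anyway: a change aborts with :class:`RelaxationFailureError` rather than
    returning a corrupted configuration.
    """
    ff = ff or ForceField()
    out = chain.copy()
    mobile = np.ones(out.n_beads, dtype=np.bool_)
    wall_feel = np.ones(out.n_beads, dtype=np.bool_)
    if out.is_grafted:
        mobile[0] = mobile[-1] = False
        wall_feel[0] = wall_feel[-1] = False
    wall_l = -1.0 if slab is None else slab.separation
    if check_topology:
        before = topology.classify_chain(out, slab=slab, seed=2).label
    relax_drive(out.positions, mobile, n_sweeps, max_disp,
                ff.sigma, ff.epsilon, ff.fene_k, ff.fene_R0, ff.kappa,
                ff.temperature, ff.excluded_volume, wall_l, wall_feel,
                seed & 0x7FFFFFFF)
    energy = total_energy_kernel(out.positions, ff.sigma, ff.epsilon,
                                 ff.fene_k, ff.fene_R0, ff.kappa,
                                 ff.excluded_volume, wall_l, out.is_grafted)
    if not np.isfinite(energy):
        raise RelaxationFailureError("relaxation left infinite energy")
    if check_topology:
        after = topology.classify_chain(out, slab=slab, seed=2).label
        if after != before:
            raise RelaxationFailureError(
                f"relaxation changed topology {before} -> {after}")
    return out
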