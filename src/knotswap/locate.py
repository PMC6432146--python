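"""Knot localization by the monomer-removal scan.

The boundary of a knot on an open chain is found by deleting beads one at a
time from one end (keeping the terminal bead, which anchors the closure),
bridging the gap with a straight segment, and re-classifying after every
deletion. The first deletion after which the chain no longer carries the
knot under study (nor the composite) marks that side's boundary; the scan is
repeated from the other end, and for both knots, giving four scans per
configuration. Size is the monomeric distance end - start, position the
arithmetic mean of the two boundary monomers, and the relative position

    d = position(3_1) - position(4_1)

is negative when the trefoil sits nearer the chain start. For wall-grafted
chains every re-classification uses the semicircular closure; for free
chains the radial closing arc is computed once per configuration and its
endpoints held fixed for the whole scan, and any Delta_p outside all
reference bands is treated as "still composite" (the tolerant criterion
appropriate for the larger closure fluctuations of free chains).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from knotswap import topology
from knotswap.exceptions import BoundaryNotFoundError, LocalizationError
from knotswap.model import BeadChain, WallSlab


@dataclass(frozen=True)
class KnotSpan:
    """One localized knot: boundary monomers, size and position."""

    label: str
    start_monomer: int
    end_monomer: int

    @property
    def size(self) -> int:
        return self.end_monomer - self.start_monomer

    @property
    def position(self) -> float:
        return 0.5 * (self.start_monomer + self.end_monomer)

    def overlaps(self, other: "KnotSpan") -> bool:
        return (self.start_monomer <= other.end_monomer
                and other.start_monomer <= self.end_monomer)


@dataclass(frozen=True)
class RelativePosition:
    """Signed monomer distance between the two knots (3_1 minus 4_1)."""

    d: float


def _reduced_chain(pos: np.ndarray, j: int, from_start: bool) -> np.ndarray:
    """Chain with beads 1..j (or the mirror set) removed; the terminal bead
    stays and the gap closes by the direct segment to bead j+1."""
    if from_start:
        return np.vstack([pos[:1], pos[j + 1:]])
    n = pos.shape[0]
    return np.vstack([pos[: n - 1 - j], pos[-1:]])


def _classify_reduced(pos, slab, anchors, seed) -> str:
    chain = BeadChain(pos)
    if slab is not None:
        chain = BeadChain(pos, grafted_ends=np.vstack([pos[0], pos[-1]]))
        poly = topology.close_semicircle(chain, slab)
    else:
        poly = topology.close_radial(chain, anchors=anchors)
    return topology.classify(poly, seed=seed).label


def scan_boundary(
    chain: BeadChain,
    target_label: str,
    from_end: str = "start",
    closure_mode: str = "free",
    slab: Optional[WallSlab] = None,
    anchors: Optional[np.ndarray] = None,
    seed: int = 17,
) -> int:
    """Boundary monomer of ``target_label`` scanning from one chain end.

    Beads are removed one at a time starting with the second monomer from
    the chosen end; after each removal the reduced chain is closed and
    classified. The scan stops at the first classification that is neither
    the target knot nor the composite; the index (original numbering) of the
    bead removed last is the boundary. ``closure_mode="walls"`` uses the
    strict criterion with semicircular closure; ``"free"`` uses fixed radial
    anchors and tolerates unrecognized Delta_p values as still-composite.
    """
    if target_label not in ("3_1", "4_1"):
        raise ValueError("target_label must be '3_1' or '4_1'")
    if closure_mode not in ("walls", "free"):
        raise ValueError("closure_mode must be 'walls' or 'free'")
    if closure_mode == "walls" and slab is None:
        raise ValueError("closure_mode='walls' needs a WallSlab")
    tolerant = closure_mode == "free"
    use_slab = slab if closure_mode == "walls" else None
    if closure_mode == "free" and anchors is None:
        anchors = topology.radial_anchors(chain)
    pos = chain.positions
    n = pos.shape[0]
    initial = _classify_reduced(pos, use_slab, anchors, seed)
    keep = {target_label, "composite_31_41"}
    if tolerant:
        keep.add("other")
    if initial not in keep:
        raise BoundaryNotFoundError(
            f"chain classifies {initial}; no {target_label} to scan")
    from_start = from_end == "start"
    for j in range(1, n - 2):
        red = _reduced_chain(pos, j, from_start)
        label = _classify_reduced(red, use_slab, anchors, seed)
        if label not in keep:
            return j if from_start else n - 1 - j
    raise BoundaryNotFoundError(
        f"scan from {from_end} exhausted the chain without leaving "
        f"{target_label}/composite")


def locate_both(
    chain: BeadChain,
    closure_mode: str = "free",
    slab: Optional[WallSlab] = None,
    seed: int = 17,
) -> tuple[KnotSpan, KnotSpan, RelativePosition]:
    """Localize the 3_1 and the 4_1 knot with four boundary scans.

    In the intertwined state one span may contain the other; the sizes then
    overlap and |d| is small. Inconsistent boundaries (end before start)
    raise :class:`LocalizationError` so the frame can be flagged upstream.
    """
    anchors = None
    if closure_mode == "free":
        anchors = topology.radial_anchors(chain)
    spans = {}
    for label in ("3_1", "4_1"):
        start = scan_boundary(chain, label, "start", closure_mode,
                              slab=slab, anchors=anchors, seed=seed)
        end = scan_boundary(chain, label, "end", closure_mode,
                            slab=slab, anchors=anchors, seed=seed)
        if end < start:
            raise LocalizationError(
                f"{label}: end boundary {end} before start {start}")
        spans[label] = KnotSpan(label, start, end)
    d = spans["3_1"].position - spans["4_1"].position
    return spans["3_1"], spans["4_1"], RelativePosition(d)


def locate_trajectory(
    frames: Union[Sequence[BeadChain], "np.ndarray"],
    closure_mode: str = "free",
    slab: Optional[WallSlab] = None,
    seed: int = 17,
) -> pd.DataFrame:
    """Per-frame knot spans and relative position.

    ``frames`` may be a Trajectory-frames array or a sequence of chains (for
    MC ensembles the rows are independent configurations, not a time
    series). Frames whose localization fails are kept in the table with a
    ``flag`` reason and NaN observables; a quality warning is emitted when
    more than 10% of frames are flagged.
    """
    rows = []
    chains: Sequence[BeadChain]
    if isinstance(frames, np.ndarray):
        chains = [BeadChain(f) for f in frames]
    else:
        chains = list(frames)
    for i, c in enumerate(chains):
        try:
            s31, s41, rel = locate_both(c, closure_mode, slab=slab, seed=seed)
            rows.append({"frame": i, "size_31": s31.size, "size_41": s41.size,
                         "pos_31": s31.position, "pos_41": s41.position,
                         "d": rel.d, "flag": ""})
        except (BoundaryNotFoundError, LocalizationError) as err:
            rows.append({"frame": i, "size_31": np.nan, "size_41": np.nan,
                         "pos_31": np.nan, "pos_41": np.nan, "d": np.nan,
                         "flag": type(err).__name__})
    df = pd.DataFrame(rows)
    n_flagged = int((df["flag"] != "").sum())
    if len(df) and n_flagged / len(df) > 0.10:
        warnings.warn(
            f"{n_flagged}/{len(df)} frames failed knot localization",
            stacklevel=2)
    return df
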