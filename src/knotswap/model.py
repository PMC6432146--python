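"""Coarse-grained bead-spring polymer model and its dsDNA parameterization.

The chain is a Kremer–Grest-type bead-spring polymer: purely repulsive
Weeks–Chandler–Andersen (WCA) excluded volume between all bead pairs, FENE
bonds between consecutive beads, and a harmonic bending potential on the angle
between adjacent bonds, centered at the straight configuration. Confining
walls, when present, act on each bead through the same WCA form in the
wall-normal distance.

Reduced units are used throughout the engine: the bead diameter sigma is the
unit of length, epsilon = kBT = 1 the unit of energy. The mapping onto dsDNA
at physiological salt (bead diameter 5 nm, rise 0.33 nm/bp, persistence length
50 nm) lives in :class:`DnaMapping` and is applied only when reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from knotswap.exceptions import EscapedSlabError, InvalidGeometryError

#: WCA cutoff in units of sigma: the potential minimum of the parent LJ.
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ForceField:
    """Interaction parameters in reduced units (sigma = epsilon = kBT = 1).

    Parameters
    ----------
    sigma : bead diameter, the length unit.
    epsilon : WCA energy scale, in kBT.
    fene_k : FENE spring constant, epsilon/sigma^2.
    fene_R0 : maximum FENE bond extension; bonds diverge there, which together
        with the WCA core prevents strand crossing (k=30, R0=1.5 are the
        standard non-crossing choice).
    kappa : bending stiffness, kBT/rad^2. kappa=10 reproduces the 50 nm
        persistence length of dsDNA for 5 nm beads.
    temperature : kBT.
    excluded_volume : disable to obtain the ideal (phantom) chain used by
        closed-form sampler checks.
    """

    sigma: float = 1.0
    epsilon: float = 1.0
    fene_k: float = 30.0
    fene_R0: float = 1.5
    kappa: float = 10.0
    temperature: float = 1.0
    excluded_volume: bool = True

    def __post_init__(self) -> None:
        for name in ("sigma", "epsilon", "fene_k", "fene_R0", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ForceField.{name} must be strictly positive")
        if self.kappa < 0:
            raise ValueError("ForceField.kappa must be non-negative")
        if self.fene_R0 <= WCA_CUTOFF * self.sigma:
            raise ValueError("fene_R0 must exceed the WCA cutoff 2^(1/6) sigma")

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "epsilon": self.epsilon,
            "fene_k": self.fene_k,
            "fene_R0": self.fene_R0,
            "kappa": self.kappa,
            "temperature": self.temperature,
            "excluded_volume": self.excluded_volume,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForceField":
        return cls(**d)


@dataclass(frozen=True)
class DnaMapping:
    """Unit conversion between reduced model units and dsDNA.

    One bead of diameter sigma = 5 nm covers round(5/0.33) = 15 base pairs;
    the 50 nm persistence length then fixes kappa ~= 10 kBT via the discrete
    worm-like-chain relation kappa ~= lp kBT / sigma.
    """

    nm_per_sigma: float = 5.0
    bp_per_nm: float = 1.0 / 0.33
    persistence_length_nm: float = 50.0

    @property
    def bp_per_bead(self) -> int:
        return round(self.nm_per_sigma * self.bp_per_nm)

    def beads_to_bp(self, n_beads: int) -> int:
        return n_beads * self.bp_per_bead

    def sigma_to_nm(self, x_sigma: float) -> float:
        return x_sigma * self.nm_per_sigma

    def nm_to_sigma(self, x_nm: float) -> float:
        return x_nm / self.nm_per_sigma


@dataclass(frozen=True)
class WallSlab:
    """Two parallel repulsive walls normal to z, at z = 0 and z = separation."""

    separation: float
    axis: int = 2

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise ValueError("wall separation must be positive")
        if self.axis != 2:
            raise ValueError("only z-normal walls are supported")


@dataclass
class BeadChain:
    """An open chain of N beads: ordered 3D coordinates plus grafting state.

    ``grafted_ends`` holds the fixed anchor coordinates of bead 0 and bead
    N-1 when the chain is grafted to walls, else None. ``knot_spec`` is
    generator metadata (requested knots, seed) carried along for provenance
    and for rebuilding the chain under different confinement.
    """

    positions: np.ndarray
    grafted_ends: Optional[np.ndarray] = None
    knot_spec: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if self.positions.shape[0] < 2:
            raise ValueError("a chain needs at least 2 beads")
        if self.grafted_ends is not None:
            self.grafted_ends = np.asarray(self.grafted_ends, dtype=np.float64)
            if self.grafted_ends.shape != (2, 3):
                raise ValueError("grafted_ends must have shape (2, 3)")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def is_grafted(self) -> bool:
        return self.grafted_ends is not None

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))

    def copy(self) -> "BeadChain":
        return BeadChain(
            self.positions.copy(),
            None if self.grafted_ends is None else self.grafted_ends.copy(),
            None if self.knot_spec is None else dict(self.knot_spec),
        )

    def validate_bonds(self, ff: ForceField) -> bool:
        """True iff all bond lengths are strictly below fene_R0."""
        return bool(np.all(self.bond_lengths() < ff.fene_R0))


# --------------------------------------------------------------------------
# scalar potentials
# --------------------------------------------------------------------------

def wca_energy(r: float, ff: ForceField) -> float:
    """WCA pair energy 4 eps [(s/r)^12 - (s/r)^6 + 1/4], zero beyond 2^(1/6) s."""
    r = float(r)
    if r <= 0:
        raise InvalidGeometryError(f"pair distance must be positive, got {r}")
    if r > WCA_CUTOFF * ff.sigma:
        return 0.0
    sr6 = (ff.sigma / r) ** 6
    return 4.0 * ff.epsilon * (sr6 * sr6 - sr6 + 0.25)


def fene_energy(r: float, ff: ForceField) -> float:
    """FENE bond energy -(k R0^2 / 2) ln(1 - (r/R0)^2); +inf at or beyond R0."""
    r = float(r)
    if r < 0:
        raise InvalidGeometryError(f"bond length must be non-negative, got {r}")
    if r >= ff.fene_R0:
        return np.inf
    x = r / ff.fene_R0
    return -0.5 * ff.fene_k * ff.fene_R0**2 * np.log1p(-x * x)


def angle_energy(theta: float, ff: ForceField) -> float:
    """Harmonic bending energy (kappa/2)(theta - pi)^2 for a bond angle."""
    theta = float(theta)
    if not (0.0 <= theta <= np.pi + 1e-12):
        raise InvalidGeometryError(f"bond angle must lie in [0, pi], got {theta}")
    return 0.5 * ff.kappa * (theta - np.pi) ** 2


def wall_energy(z: float, ff: ForceField) -> float:
    """WCA repulsion from a single wall at normal distance z (escape: z < 0)."""
    z = float(z)
    if z < 0:
        raise EscapedSlabError(f"bead behind the wall: distance {z}")
    if z == 0.0:
        raise InvalidGeometryError("bead exactly on the wall has divergent energy")
    if z > WCA_CUTOFF * ff.sigma:
        return 0.0
    sz6 = (ff.sigma / z) ** 6
    return 4.0 * ff.epsilon * (sz6 * sz6 - sz6 + 0.25)


def total_energy(
    chain: BeadChain, ff: ForceField, slab: Optional[WallSlab] = None
) -> float:
    """Total potential energy of a chain configuration.

    Sums WCA over all bead pairs (bonded neighbors included, the standard
    Kremer–Grest convention), FENE over bonds, bending over the N-2 interior
    angles, and, if ``slab`` is given, WCA wall terms for both walls. Grafted
    terminal beads sit in the wall planes and are excluded from the wall sum.
    Returns +inf if any bond has reached fene_R0.
    """
    from knotswap._kernels import total_energy_kernel

    pos = chain.positions
    if slab is not None:
        z = pos[:, slab.axis]
        lo, hi = (1, pos.shape[0] - 1) if chain.is_grafted else (0, pos.shape[0])
        inner = z[lo:hi]
        if np.any(inner < 0) or np.any(inner > slab.separation):
            raise EscapedSlabError("bead outside the slab")
    wall_l = -1.0 if slab is None else slab.separation
    return float(
        total_energy_kernel(
            pos,
            ff.sigma,
            ff.epsilon,
            ff.fene_k,
            ff.fene_R0,
            ff.kappa,
            ff.excluded_volume,
            wall_l,
            chain.is_grafted,
        )
    )


def kappa_from_persistence(lp_nm: float, mapping: DnaMapping | None = None) -> float:
    """Bending stiffness (kBT) matching a persistence length, kappa = lp / sigma.

    Discrete worm-like-chain relation: lp kBT / sigma with kBT = 1. For
    lp = 50 nm and sigma = 5 nm this gives the dsDNA value kappa = 10.
    """
    if lp_nm <= 0:
        raise ValueError("persistence length must be positive")
    mapping = mapping or DnaMapping()
    return lp_nm / mapping.nm_per_sigma
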