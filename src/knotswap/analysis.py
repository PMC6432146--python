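"""Statistical post-processing: distributions, free-energy profiles, barriers.

The central object is the distribution P(d) of the relative knot position
d = position(3_1) - position(4_1), accumulated over runs with equal run
weights, Boltzmann-inverted to the topological free energy

    F(d) = -kBT ln P(d),       F(d = 0) := 0,

and summarized by the barrier Delta_1->3 between the intertwined minimum (1,
near d = 0) and the flanking maxima (3), and the level difference Delta_1->2
involving the separated-state minima (2). The module also provides knot-size
statistics, end-to-end distances and persistence-length fits used to anchor
the model's dsDNA parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from knotswap.exceptions import KnotswapError
from knotswap.model import BeadChain, DnaMapping


@dataclass
class FreeEnergyProfile:
    """Binned P(d) with optional Boltzmann-inverted F(d)."""

    bin_centers: np.ndarray
    p: np.ndarray
    counts: np.ndarray
    bin_width: float
    f: Optional[np.ndarray] = None  # NaN-masked where P = 0
    f_err: Optional[np.ndarray] = None
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        data = {"d": self.bin_centers, "count": self.counts, "P": self.p}
        if self.f is not None:
            data["F"] = self.f
        if self.f_err is not None:
            data["F_err"] = self.f_err
        return pd.DataFrame(data)


@dataclass(frozen=True)
class BarrierSummary:
    """Free-energy differences between the intertwined minimum (1), the
    barrier maxima (3) and the separated minima (2), in kBT."""

    delta_1_to_3: float
    delta_1_to_2: float
    d_min_intertwined: float
    d_max_barrier: tuple
    d_min_separated: tuple
    per_side_1_to_3: tuple = ()
    per_side_1_to_2: tuple = ()
    flags: tuple = ()


@dataclass(frozen=True)
class ChainStats:
    """Chain-level observables in sigma units."""

    mean_ree: float = np.nan
    rms_ree: float = np.nan
    se_ree: float = np.nan
    lp: float = np.nan
    lp_fit_residual: float = np.nan
    n_samples: int = 0
    flags: tuple = ()


def moving_average(series: Sequence[float], window: int) -> np.ndarray:
    """Centered moving mean; edges use the shrinking window (pandas
    convention, even windows weighted toward the trailing side). Output
    length equals input length."""
    x = np.asarray(series, dtype=np.float64)
    if window < 1:
        raise ValueError("window must be >= 1")
    if x.size < window:
        raise ValueError(f"series of length {x.size} shorter than window {window}")
    return (pd.Series(x)
            .rolling(window, center=True, min_periods=1)
            .mean()
            .to_numpy())


def distance_distribution(
    series_list: Iterable[Sequence[float]],
    bin_width: float = 5.0,
    d_max: Optional[float] = None,
    symmetrize: bool = False,
) -> FreeEnergyProfile:
    """Run-averaged, symmetric-binned distribution of the relative position.

    Each run (time series, or one ensemble sample set for MC data) is
    histogrammed and normalized on its own, then runs are averaged with
    equal weights; bins are centered so d = 0 is a bin center. NaN entries
    (flagged frames) are dropped per run.

    ``symmetrize`` averages P(d) with P(-d). Neither knot has a preferred
    side, so the equilibrium distribution is even in d; enforcing the exact
    symmetry removes the start-side bias of short runs that production-scale
    run averaging removes statistically.
    """
    runs = [np.asarray(s, dtype=np.float64) for s in series_list]
    runs = [r[np.isfinite(r)] for r in runs]
    runs = [r for r in runs if r.size]
    if not runs:
        raise ValueError("no finite data in any run")
    if d_max is None:
        d_max = max(np.abs(r).max() for r in runs)
    k = int(np.ceil(d_max / bin_width)) + 1
    edges = (np.arange(-k, k + 1) + 0.5) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    p_runs = []
    counts = np.zeros(centers.size)
    for r in runs:
        h, _ = np.histogram(r, bins=edges)
        counts += h
        tot = h.sum()
        p_runs.append(h / tot if tot else h.astype(float))
    p = np.mean(p_runs, axis=0)
    flags = []
    if symmetrize:
        p = 0.5 * (p + p[::-1])
        flags.append("symmetrized")
    norm = p.sum() * bin_width
    if norm > 0:
        p = p / norm
    return FreeEnergyProfile(bin_centers=centers, p=p, counts=counts,
                             bin_width=bin_width, flags=flags)


def boltzmann_invert(profile: FreeEnergyProfile,
                     kbt: float = 1.0) -> FreeEnergyProfile:
    """F(d) = -kBT ln P(d), shifted so F = 0 at the d = 0 bin.

    Empty bins get NaN (never +-inf). If the d = 0 bin itself is empty the
    shift falls back to the global minimum and the profile is flagged."""
    p = profile.p
    f = np.full_like(p, np.nan)
    mask = p > 0
    f[mask] = -kbt * np.log(p[mask])
    i0 = int(np.argmin(np.abs(profile.bin_centers)))
    flags = list(profile.flags)
    if mask[i0]:
        f -= f[i0]
    else:
        flags.append("shift_reference_fallback_global_min")
        f -= np.nanmin(f)
    return FreeEnergyProfile(
        bin_centers=profile.bin_centers, p=p, counts=profile.counts,
        bin_width=profile.bin_width, f=f, f_err=profile.f_err, flags=flags)


def _local_extrema(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local minima and maxima of a 1D array.

    Boundary bins count when strictly below/above their single inner
    neighbor: the intertwined minimum of a sparsely sampled profile can sit
    in the outermost populated bin."""
    mins, maxs = [], []
    n = y.size
    if n >= 2:
        if y[0] < y[1]:
            mins.append(0)
        elif y[0] > y[1]:
            maxs.append(0)
    for i in range(1, n - 1):
        left = y[i - 1]
        right = y[i + 1]
        if y[i] < left and y[i] <= right:
            mins.append(i)
        elif y[i] > left and y[i] >= right:
            maxs.append(i)
    if n >= 2:
        if y[n - 1] < y[n - 2]:
            mins.append(n - 1)
        elif y[n - 1] > y[n - 2]:
            maxs.append(n - 1)
    return np.asarray(mins, dtype=int), np.asarray(maxs, dtype=int)


def extract_barriers(profile: FreeEnergyProfile,
                     median_bins: int = 3,
                     fill_empty: bool = False) -> BarrierSummary:
    """Barrier heights from a free-energy profile.

    On the NaN-free central range of F (median-filtered over
    ``median_bins``), the intertwined minimum is the local minimum nearest
    d = 0; on each side the first local maximum beyond it and the lowest
    minimum beyond that maximum define the per-side Delta_1->3 = F(max) -
    F(min1) and Delta_1->2 = F(max) - F(min2); both are reported per side
    and side-averaged. A monotone profile yields zeros with a ``no_barrier``
    flag.

    ``fill_empty`` enables a regularization for sparsely sampled profiles:
    empty bins lying between populated ones are assigned the free energy of
    half the smallest observed bin probability (a never-visited transition
    region is at least that unlikely). This turns an undefined barrier into
    a finite lower-confidence estimate and preserves monotone trends across
    sampling conditions; it biases barriers downward, never upward.
    """
    if profile.f is None:
        raise ValueError("profile has no F; run boltzmann_invert first")
    d = profile.bin_centers
    f = profile.f
    if fill_empty and np.any(profile.p > 0):
        f = f.copy()
        valid_idx = np.where(np.isfinite(f))[0]
        if valid_idx.size:
            # recover the shift constant C of F = -ln P - C from a valid bin
            i = valid_idx[0]
            shift = -(f[i] + np.log(profile.p[i]))
            f_fill = -np.log(0.5 * profile.p[profile.p > 0].min()) - shift
            inner = f[valid_idx[0]:valid_idx[-1] + 1]
            inner[~np.isfinite(inner)] = f_fill
    valid = np.isfinite(f)
    if valid.sum() < 3:
        return BarrierSummary(0.0, 0.0, np.nan, (), (), flags=("no_data",))
    # largest connected valid block containing the bin nearest d=0
    i0 = int(np.argmin(np.abs(d)))
    lo = i0
    while lo - 1 >= 0 and valid[lo - 1]:
        lo -= 1
    hi = i0
    while hi + 1 < f.size and valid[hi + 1]:
        hi += 1
    dd = d[lo:hi + 1]
    ff = f[lo:hi + 1]
    if median_bins > 1 and ff.size >= median_bins:
        ff = medfilt(ff, kernel_size=median_bins | 1)
    mins, maxs = _local_extrema(ff)
    if mins.size == 0 or maxs.size == 0:
        return BarrierSummary(0.0, 0.0, np.nan, (), (), flags=("no_barrier",))
    imin1 = int(mins[np.argmin(np.abs(dd[mins]))])
    side13, side12, dmaxs, dmins2 = [], [], [], []
    for side in (-1, +1):
        cand = maxs[maxs > imin1] if side > 0 else maxs[maxs < imin1]
        if cand.size == 0:
            continue
        imax = int(cand.min()) if side > 0 else int(cand.max())
        beyond = mins[mins > imax] if side > 0 else mins[mins < imax]
        side13.append(float(ff[imax] - ff[imin1]))
        dmaxs.append(float(dd[imax]))
        if beyond.size:
            imin2 = int(beyond[np.argmin(ff[beyond])])
            side12.append(float(ff[imax] - ff[imin2]))
            dmins2.append(float(dd[imin2]))
    if not side13:
        return BarrierSummary(0.0, 0.0, float(dd[imin1]), (), (),
                              flags=("no_barrier",))
    return BarrierSummary(
        delta_1_to_3=float(np.mean(side13)),
        delta_1_to_2=float(np.mean(side12)) if side12 else np.nan,
        d_min_intertwined=float(dd[imin1]),
        d_max_barrier=tuple(dmaxs),
        d_min_separated=tuple(dmins2),
        per_side_1_to_3=tuple(side13),
        per_side_1_to_2=tuple(side12),
    )


@dataclass(frozen=True)
class SizeSummary:
    """Two-state summary of one knot's size distribution (monomer units)."""

    label: str
    mean: float
    std: float
    state_means: tuple
    threshold: float
    n: int
    flags: tuple = ()

    def in_bp(self, mapping: Optional[DnaMapping] = None) -> "SizeSummary":
        m = mapping or DnaMapping()
        k = m.bp_per_bead
        return SizeSummary(self.label, self.mean * k, self.std * k,
                           tuple(s * k for s in self.state_means),
                           self.threshold * k, self.n, self.flags)


def _otsu_threshold(x: np.ndarray) -> float:
    """Two-class threshold minimizing within-class variance."""
    xs = np.sort(x)
    best, best_t = -1.0, xs[xs.size // 2]
    for i in range(1, xs.size):
        w0 = i / xs.size
        w1 = 1.0 - w0
        m0 = xs[:i].mean()
        m1 = xs[i:].mean()
        between = w0 * w1 * (m0 - m1) ** 2
        if between > best:
            best = between
            best_t = 0.5 * (xs[i - 1] + xs[i])
    return float(best_t)


def size_statistics(
    sizes_31: Sequence[float],
    sizes_41: Sequence[float],
    mapping: Optional[DnaMapping] = None,
) -> dict[str, SizeSummary]:
    """Per-knot size distributions with a small/grown two-state split.

    The split threshold is Otsu's between-class criterion; if the two state
    means are not separated by at least the pooled spread the distribution
    is summarized as single-state and flagged. Pass ``mapping`` to convert
    the summaries to base pairs.
    """
    out = {}
    for label, raw in (("3_1", sizes_31), ("4_1", sizes_41)):
        x = np.asarray(raw, dtype=np.float64)
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise ValueError(f"no finite sizes for {label}")
        flags: tuple = ()
        if x.std() < 1e-12 or x.size < 4:
            summary = SizeSummary(label, float(x.mean()), float(x.std()),
                                  (float(x.mean()),), float(x.mean()),
                                  x.size, ("single_state",))
        else:
            t = _otsu_threshold(x)
            lo, hi = x[x <= t], x[x > t]
            if lo.size < 2 or hi.size < 2 or \
                    (hi.mean() - lo.mean()) < (lo.std() + hi.std()):
                summary = SizeSummary(label, float(x.mean()), float(x.std()),
                                      (float(x.mean()),), t, x.size,
                                      ("single_state",))
            else:
                summary = SizeSummary(label, float(x.mean()), float(x.std()),
                                      (float(lo.mean()), float(hi.mean())),
                                      t, x.size, flags)
        out[label] = summary.in_bp(mapping) if mapping else summary
    return out


def _block_se(x: np.ndarray, n_blocks: int = 10) -> float:
    if x.size < 2 * n_blocks:
        return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    blocks = np.array_split(x, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


def end_to_end(chains) -> ChainStats:
    """Mean and RMS end-to-end distance with block-averaged standard error.

    ``chains`` may be a sequence of :class:`BeadChain`, a frames array of
    shape (F, N, 3), or a 1D array of precomputed Ree values."""
    if isinstance(chains, np.ndarray) and chains.ndim == 3:
        ree = np.linalg.norm(chains[:, -1, :] - chains[:, 0, :], axis=-1)
    elif isinstance(chains, np.ndarray) and chains.ndim == 1:
        ree = chains.astype(np.float64)
    else:
        ree = np.array([c.end_to_end() for c in chains])
    if ree.size == 0:
        raise ValueError("no configurations")
    flags: tuple = ("single_configuration",) if ree.size == 1 else ()
    return ChainStats(
        mean_ree=float(ree.mean()),
        rms_ree=float(np.sqrt((ree ** 2).mean())),
        se_ree=_block_se(ree),
        n_samples=ree.size,
        flags=flags,
    )


def bond_autocorrelation(frames: np.ndarray, s_max: int) -> np.ndarray:
    """<u_i . u_{i+s}> averaged over bonds i and frames, s = 0..s_max."""
    bonds = np.diff(frames, axis=1)
    bonds /= np.linalg.norm(bonds, axis=-1, keepdims=True)
    nb = bonds.shape[1]
    out = np.empty(s_max + 1)
    for s in range(s_max + 1):
        out[s] = float(np.mean(np.sum(
            bonds[:, : nb - s, :] * bonds[:, s:, :], axis=-1)))
    return out


def persistence_length(
    chains,
    fit_range: tuple[int, int] = (1, 20),
    mapping: Optional[DnaMapping] = None,
) -> ChainStats:
    """Persistence length from the bond-angle autocorrelation decay.

    Fits <cos theta(s)> = exp(-s b / lp) over contour separations
    ``fit_range`` (in bonds, inclusive) by linear regression of the log;
    ``b`` is the measured mean bond length. Returns lp in sigma units (use
    ``mapping`` for nanometres via ChainStats consumers). Raises if the
    correlation does not decay.
    """
    if isinstance(chains, np.ndarray) and chains.ndim == 3:
        frames = chains
    else:
        frames = np.stack([c.positions for c in chains])
    s0, s1 = fit_range
    corr = bond_autocorrelation(frames, s1)
    b = float(np.mean(np.linalg.norm(np.diff(frames, axis=1), axis=-1)))
    s = np.arange(s0, s1 + 1)
    c = corr[s0:s1 + 1]
    if np.any(c <= 0):
        pos_mask = c > 0
        if pos_mask.sum() < 3:
            raise KnotswapError("bond correlation non-positive in fit window")
        s, c = s[pos_mask], c[pos_mask]
    slope, intercept = np.polyfit(s, np.log(c), 1)
    if slope >= 0:
        raise KnotswapError("bond correlation does not decay in fit window")
    lp = -b / slope
    resid = float(np.sqrt(np.mean((np.log(c) - (slope * s + intercept)) ** 2)))
    return ChainStats(lp=float(lp), lp_fit_residual=resid,
                      n_samples=frames.shape[0])
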