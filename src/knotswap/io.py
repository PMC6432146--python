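"""Formats, configuration and the study pipeline.

Interchange is deliberately plain-text: multi-frame XYZ for coordinates
(with step and energy on the comment line), CSV for per-frame observables,
JSON for configuration and manifests. ``run_study`` chains the stages —
generate, simulate, locate, profile — into the two study regimes (grafted
chains between walls via Langevin MD; free chains via MC) and writes a QC
report plus a manifest from which every output is regenerable.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from knotswap import analysis, locate
from knotswap.init_config import graft_to_walls, relax, tie_knots_on_chain
from knotswap.model import BeadChain, ForceField, WallSlab
from knotswap.samplers import SimProtocol, Trajectory, langevin_md_run, mc_run

XYZ_PRECISION = 8


def write_xyz(path, frames: Sequence[np.ndarray],
              comments: Optional[Sequence[str]] = None) -> None:
    """Write multi-frame XYZ; one comment line per frame."""
    path = Path(path)
    with path.open("w") as fh:
        for i, fr in enumerate(frames):
            fr = np.asarray(fr)
            comment = comments[i] if comments is not None else f"frame={i}"
            fh.write(f"{fr.shape[0]}\n{comment}\n")
            for x, y, z in fr:
                fh.write(f"B {x:.{XYZ_PRECISION}f} {y:.{XYZ_PRECISION}f} "
                         f"{z:.{XYZ_PRECISION}f}\n")


def read_xyz(path) -> tuple[list[np.ndarray], list[str]]:
    """Read multi-frame XYZ written by :func:`write_xyz`.

    Returns (frames, comments). An empty file yields zero frames; malformed
    content raises ValueError naming the offending line."""
    path = Path(path)
    frames: list[np.ndarray] = []
    comments: list[str] = []
    with path.open() as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as err:
            raise ValueError(f"line {i + 1}: expected atom count") from err
        if i + 1 + n >= len(lines) + 1:
            raise ValueError(f"line {i + 1}: truncated frame of {n} atoms")
        comments.append(lines[i + 1])
        fr = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise ValueError(f"line {i + 3 + k}: malformed atom record")
            fr[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(fr)
        i += 2 + n
    return frames, comments


def write_trajectory(path, traj: Trajectory) -> None:
    comments = [f"step={s} energy={e:.6f}"
                for s, e in zip(traj.steps, traj.energies)]
    write_xyz(path, traj.frames, comments)


@dataclass
class StudyConfig:
    """Everything needed to reproduce one study run."""

    regime: str  # "walls" | "free"
    n_beads: int = 300
    wall_distance: Optional[float] = 60.0
    knots: Sequence = (("3_1", 0.32), ("4_1", 0.68))
    force_field: dict = field(default_factory=dict)
    n_steps: int = 200_000
    snapshot_every: int = 2_000
    n_runs: int = 4
    seed: int = 0
    bin_width: float = 5.0
    smoothing_window: int = 100
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.regime not in ("walls", "free"):
            raise ValueError("regime must be 'walls' or 'free'")
        if self.regime == "walls" and not self.wall_distance:
            raise ValueError("walls regime needs wall_distance")
        if self.n_steps % self.snapshot_every != 0:
            raise ValueError("snapshot_every must divide n_steps")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        d = json.loads(Path(path).read_text())
        d["knots"] = tuple(tuple(k) for k in d.get("knots", []))
        return cls(**d)

    def ff(self) -> ForceField:
        return ForceField(**self.force_field)


def run_study(config: StudyConfig, outdir) -> Path:
    """Generate -> simulate -> locate -> profile, writing all artifacts.

    Deterministic for a fixed config: per-run seeds derive from
    ``config.seed``. Returns the artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    ff = config.ff()
    t_start = time.time()
    qc: dict = {"runs": []}
    d_series = []
    size_rows = []
    slab = WallSlab(config.wall_distance) if config.regime == "walls" else None
    for run in range(config.n_runs):
        run_seed = config.seed * 10_000 + run
        chain = tie_knots_on_chain(config.n_beads, list(config.knots),
                                   seed=run_seed)
        if config.regime == "walls":
            chain = graft_to_walls(chain, config.wall_distance, ff,
                                   seed=run_seed)
        else:
            chain = relax(chain, ff, n_sweeps=100, seed=run_seed)
        proto = SimProtocol(n_steps=config.n_steps,
                            snapshot_every=config.snapshot_every,
                            seed=run_seed, dt=config.dt)
        if config.regime == "walls":
            traj = langevin_md_run(chain, ff, slab, proto)
        else:
            traj = mc_run(chain, ff, proto, topology_restricted=True)
        write_trajectory(outdir / f"run{run}.xyz", traj)
        pd.DataFrame({"step": traj.steps, "energy": traj.energies}).to_csv(
            outdir / f"run{run}_energy.csv", index=False)
        mode = "walls" if config.regime == "walls" else "free"
        table = locate.locate_trajectory(
            [BeadChain(f, grafted_ends=chain.grafted_ends)
             for f in traj.frames],
            closure_mode=mode, slab=slab)
        table.to_csv(outdir / f"run{run}_locate.csv", index=False)
        d = table["d"].to_numpy()
        if config.regime == "walls" and np.isfinite(d).sum() >= \
                config.smoothing_window:
            d = analysis.moving_average(
                pd.Series(d).ffill().bfill().to_numpy(),
                config.smoothing_window)
        d_series.append(d)
        size_rows.append(table[["size_31", "size_41"]])
        run_qc = {
            "run": run,
            "seed": run_seed,
            "flagged_frames": int((table["flag"] != "").sum()),
            "n_frames": int(len(table)),
        }
        if traj.temperatures is not None:
            run_qc["mean_temperature"] = float(np.mean(traj.temperatures))
        if traj.acceptance:
            run_qc["acceptance"] = {
                k: (v if isinstance(v, int) else v.get("rate"))
                for k, v in traj.acceptance.items()}
        qc["runs"].append(run_qc)
    profile = analysis.distance_distribution(d_series,
                                             bin_width=config.bin_width)
    profile = analysis.boltzmann_invert(profile, kbt=ff.temperature)
    profile.to_frame().to_csv(outdir / "profile.csv", index=False)
    barriers = analysis.extract_barriers(profile)
    sizes = pd.concat(size_rows, ignore_index=True)
    stats = analysis.size_statistics(sizes["size_31"], sizes["size_41"])
    (outdir / "barriers.json").write_text(json.dumps({
        "delta_1_to_3": barriers.delta_1_to_3,
        "delta_1_to_2": barriers.delta_1_to_2,
        "d_min_intertwined": barriers.d_min_intertwined,
        "flags": list(barriers.flags),
        "mean_size_31": stats["3_1"].mean,
        "mean_size_41": stats["4_1"].mean,
    }, indent=2))
    qc["wall_time_s"] = time.time() - t_start
    (outdir / "qc.json").write_text(json.dumps(qc, indent=2))
    manifest = {
        "package": "knotswap",
        "config": asdict(config),
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=list))
    return outdir
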