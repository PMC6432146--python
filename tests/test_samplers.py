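"""Sampling engines against closed-form and quadrature oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from knotswap.exceptions import KnotswapError
from knotswap.model import BeadChain
from knotswap.samplers import SimProtocol, langevin_md_run, mc_run
from knotswap._kernels import rotate_segment


def mean_cos_bend(frames):
    """<u_i . u_{i+1}> per frame and its standard error over frames."""
    vals = []
    for f in frames:
        b = np.diff(f, axis=0)
        b /= np.linalg.norm(b, axis=1, keepdims=True)
        vals.append(float(np.sum(b[:-1] * b[1:], axis=1).mean()))
    vals = np.asarray(vals)
    return vals.mean(), vals.std(ddof=1) / np.sqrt(vals.size)


class TestProtocol:
    def test_snapshot_must_divide_steps(self):
        with pytest.raises(ValueError):
            SimProtocol(n_steps=1000, snapshot_every=300)

    def test_move_mix_must_normalize(self):
        with pytest.raises(ValueError):
            SimProtocol(n_steps=100, snapshot_every=10, move_mix=(1, 1, 1))


class TestMonteCarlo:
    def test_deterministic_for_fixed_seed(self, ff_ideal, straight_chain):
        proto = SimProtocol(n_steps=20_000, snapshot_every=2_000, seed=5)
        t1 = mc_run(straight_chain(30), ff_ideal, proto)
        t2 = mc_run(straight_chain(30), ff_ideal, proto)
        assert np.array_equal(t1.frames, t2.frames)
        assert np.array_equal(t1.energies, t2.energies)

    def test_ideal_chain_bend_statistics_match_quadrature(
            self, ff_ideal, straight_chain):
        """<cos theta> of the phantom semiflexible chain vs the 1D integral
        of the Boltzmann weight with the sin(theta) measure."""
        proto = SimProtocol(n_steps=400_000, snapshot_every=4_000, seed=1)
        traj = mc_run(straight_chain(50), ff_ideal, proto)
        got, se = mean_cos_bend(traj.frames[25:])
        k = ff_ideal.kappa
        num = quad(lambda th: np.cos(np.pi - th)
                   * np.exp(-0.5 * k * (th - np.pi) ** 2) * np.sin(th),
                   0, np.pi)[0]
        den = quad(lambda th: np.exp(-0.5 * k * (th - np.pi) ** 2)
                   * np.sin(th), 0, np.pi)[0]
        assert got == pytest.approx(num / den, abs=max(3 * se, 1e-3))

    def test_dimer_bond_length_matches_boltzmann_quadrature(self, ff):
        """N=2 chain: mean FENE+WCA bond length vs radial quadrature."""
        from knotswap.model import fene_energy, wca_energy
        proto = SimProtocol(n_steps=400_000, snapshot_every=2_000, seed=2,
                            move_mix=(1.0, 0.0, 0.0))
        chain = BeadChain(np.array([[0, 0, 0], [0, 0, 0.97]], dtype=float))
        traj = mc_run(chain, ff, proto)
        r = np.linalg.norm(traj.frames[:, 1] - traj.frames[:, 0], axis=1)
        r = r[50:]
        se = r.std(ddof=1) / np.sqrt(r.size / 20)  # generous correlation

        def u(x):
            return fene_energy(x, ff) + wca_energy(x, ff)
        num = quad(lambda x: x * x * x * np.exp(-u(x)), 0.5, 1.499)[0]
        den = quad(lambda x: x * x * np.exp(-u(x)), 0.5, 1.499)[0]
        assert r.mean() == pytest.approx(num / den, abs=max(3 * se, 5e-3))

    def test_zero_rotation_is_identity(self):
        pos = np.random.default_rng(3).normal(size=(20, 3))
        seg = rotate_segment(pos, 5, 15, *pos[5], 0.0, 0.0, 1.0, 0.0)
        assert np.allclose(seg, pos[5:15], atol=1e-14)

    def test_grafted_chain_rejected(self, ff):
        pts = np.zeros((10, 3))
        pts[:, 2] = np.arange(10.0)
        chain = BeadChain(pts, grafted_ends=np.vstack([pts[0], pts[-1]]))
        with pytest.raises(KnotswapError):
            mc_run(chain, ff, SimProtocol(n_steps=100, snapshot_every=10))


class TestLangevin:
    def test_temperature_and_determinism(self, ff, straight_chain):
        proto = SimProtocol(n_steps=60_000, snapshot_every=2_000, seed=3)
        t1 = langevin_md_run(straight_chain(40), ff, None, proto)
        t2 = langevin_md_run(straight_chain(40), ff, None, proto)
        assert np.array_equal(t1.frames, t2.frames)
        temps = t1.temperatures[5:]
        se = temps.std(ddof=1) / np.sqrt(temps.size)
        assert temps.mean() == pytest.approx(1.0, abs=max(3 * se, 5e-3))

    def test_com_diffusion_matches_einstein_relation(self, ff_ideal):
        """Free dimer center of mass: D = kBT/(2 m gamma) exactly (internal
        forces cancel), so MSD(t) = 6 D t."""
        proto = SimProtocol(n_steps=200_000, snapshot_every=200, seed=4)
        chain = BeadChain(np.array([[0, 0, 0], [0, 0, 0.97]], dtype=float))
        traj = langevin_md_run(chain, ff_ideal, None, proto)
        com = traj.frames.mean(axis=1)
        t = traj.steps * proto.dt
        msd = np.sum((com - com[0]) ** 2, axis=1)
        d_est = np.polyfit(t, msd, 1)[0] / 6.0
        assert d_est == pytest.approx(0.5, rel=0.25)

    def test_bonds_never_exceed_r0_in_frames(self, ff, straight_chain):
        proto = SimProtocol(n_steps=20_000, snapshot_every=1_000, seed=5)
        traj = langevin_md_run(straight_chain(30), ff, None, proto)
        bonds = np.linalg.norm(np.diff(traj.frames, axis=1), axis=-1)
        assert bonds.max() < ff.fene_R0


class TestCrossEngineConsistency:
    def test_mc_and_md_agree_on_ree_squared(self, ff):
        """Same free N=16 chain in both engines: <Ree^2> within 3 combined
        standard errors."""
        pts = np.zeros((16, 3))
        pts[:, 2] = np.arange(16) * 0.97
        mc = mc_run(BeadChain(pts.copy()), ff,
                    SimProtocol(n_steps=600_000, snapshot_every=3_000,
                                seed=6, move_mix=(0.6, 0.3, 0.1)))
        md = langevin_md_run(BeadChain(pts.copy()), ff, None,
                             SimProtocol(n_steps=400_000,
                                         snapshot_every=2_000, seed=7))

        def stat(traj, burn):
            r2 = traj.end_to_end_series()[burn:] ** 2
            blocks = np.array_split(r2, 10)
            means = np.array([b.mean() for b in blocks])
            return r2.mean(), means.std(ddof=1) / np.sqrt(len(blocks))
        m1, s1 = stat(mc, 40)
        m2, s2 = stat(md, 40)
        assert abs(m1 - m2) < 3 * np.hypot(s1, s2) + 1e-9
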