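"""Potentials, total energy against a brute-force oracle, DNA mapping."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from knotswap.exceptions import EscapedSlabError, InvalidGeometryError
from knotswap.model import (
    WCA_CUTOFF,
    BeadChain,
    DnaMapping,
    ForceField,
    WallSlab,
    angle_energy,
    fene_energy,
    kappa_from_persistence,
    total_energy,
    wall_energy,
    wca_energy,
)


class TestScalarPotentials:
    @pytest.mark.parametrize("r, expected", [
        (WCA_CUTOFF, 0.0),          # vanishes at the cutoff by construction
        (1.0, 1.0),                  # 4*eps*(1 - 1 + 1/4) at r = sigma
        (1.2, 0.0),                  # beyond cutoff
        (2.0, 0.0),
    ])
    def test_wca_values(self, ff, r, expected):
        assert wca_energy(r, ff) == pytest.approx(expected, abs=1e-12)

    def test_wca_continuous_at_cutoff(self, ff):
        eps = 1e-9
        assert wca_energy(WCA_CUTOFF - eps, ff) == pytest.approx(0.0, abs=1e-7)

    def test_wca_rejects_nonpositive_distance(self, ff):
        with pytest.raises(InvalidGeometryError):
            wca_energy(0.0, ff)
        with pytest.raises(InvalidGeometryError):
            wca_energy(-1.0, ff)

    def test_fene_zero_at_origin_and_infinite_at_r0(self, ff):
        assert fene_energy(0.0, ff) == 0.0
        assert fene_energy(ff.fene_R0, ff) == np.inf
        assert fene_energy(2.0, ff) == np.inf

    def test_fene_closed_form(self, ff):
        # independent evaluation of -(k R0^2/2) ln(1 - (r/R0)^2)
        r, k, r0 = 0.96, 30.0, 1.5
        expected = -0.5 * k * r0**2 * math.log(1.0 - (r / r0) ** 2)
        assert expected == pytest.approx(17.79, abs=0.01)
        assert fene_energy(r, ff) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("theta, expected", [
        (math.pi, 0.0),
        (math.pi - 0.1, 0.05),               # kappa/2 * 0.01 with kappa=10
        (math.pi / 2, 5.0 * (math.pi / 2) ** 2),
    ])
    def test_angle_values(self, ff, theta, expected):
        assert angle_energy(theta, ff) == pytest.approx(expected, rel=1e-12)

    def test_angle_domain(self, ff):
        with pytest.raises(InvalidGeometryError):
            angle_energy(-0.1, ff)
        with pytest.raises(InvalidGeometryError):
            angle_energy(math.pi + 0.1, ff)

    @pytest.mark.parametrize("z, expected", [
        (2.0, 0.0), (1.0, 1.0), (WCA_CUTOFF, 0.0),
    ])
    def test_wall_same_form_as_wca(self, ff, z, expected):
        assert wall_energy(z, ff) == pytest.approx(expected, abs=1e-12)

    def test_wall_escape(self, ff):
        with pytest.raises(EscapedSlabError):
            wall_energy(-0.5, ff)

    def test_bond_minimum_is_kremer_grest(self, ff):
        # FENE + WCA minimizer must sit strictly inside (0.9, 1.0) sigma
        res = minimize_scalar(
            lambda r: fene_energy(r, ff) + wca_energy(r, ff),
            bounds=(0.5, 1.4), method="bounded")
        assert 0.9 < res.x < 1.0
        assert res.x == pytest.approx(0.96, abs=0.02)


class TestTotalEnergy:
    def _brute(self, pos, ff, wall_l=None, grafted=False):
        """Independent O(N^2) oracle in plain numpy."""
        n = len(pos)
        e = 0.0
        for i in range(n - 1):
            e += fene_energy(np.linalg.norm(pos[i + 1] - pos[i]), ff)
        for i in range(1, n - 1):
            u = pos[i] - pos[i - 1]
            v = pos[i + 1] - pos[i]
            c = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)),
                        -1, 1)
            e += 0.5 * ff.kappa * math.acos(c) ** 2
        if ff.excluded_volume:
            for i in range(n - 1):
                for j in range(i + 1, n):
                    e += wca_energy(np.linalg.norm(pos[j] - pos[i]), ff)
        if wall_l is not None:
            lo, hi = (1, n - 1) if grafted else (0, n)
            for i in range(lo, hi):
                e += wall_energy(pos[i][2], ff)
                e += wall_energy(wall_l - pos[i][2], ff)
        return e

    def test_straight_chain_decomposition(self, ff, straight_chain):
        r0 = 1.05
        chain = straight_chain(20, bond=r0)
        expected = 19 * (wca_energy(r0, ff) + fene_energy(r0, ff))
        # non-bonded pairs at 2*r0 > cutoff contribute nothing
        assert total_energy(chain, ff) == pytest.approx(expected, rel=1e-10)

    def test_overstretched_bond_is_infinite(self, ff):
        chain = BeadChain(np.array([[0, 0, 0], [0, 0, 1.5]], dtype=float))
        assert total_energy(chain, ff) == np.inf

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, ff, seed):
        rng = np.random.default_rng(seed)
        pos = np.cumsum(rng.normal(scale=0.5, size=(10, 3)), axis=0)
        # rescale bonds into the FENE range
        bonds = np.diff(pos, axis=0)
        bonds /= np.linalg.norm(bonds, axis=1, keepdims=True)
        pos = np.vstack([[0, 0, 0], np.cumsum(bonds * 0.97, axis=0)])
        chain = BeadChain(pos)
        assert total_energy(chain, ff) == pytest.approx(
            self._brute(pos, ff), rel=1e-10)

    def test_wall_terms_and_graft_exclusion(self, ff):
        pos = np.zeros((5, 3))
        pos[:, 2] = [0.0, 1.0, 2.0, 3.0, 4.0]
        pos[:, 0] = np.arange(5) * 0.97
        slab = WallSlab(4.0)
        grafted = BeadChain(pos, grafted_ends=np.vstack([pos[0], pos[-1]]))
        expected = self._brute(pos, ff, wall_l=4.0, grafted=True)
        assert total_energy(grafted, ff, slab) == pytest.approx(
            expected, rel=1e-10)
        # ungrafted bead on the wall plane would diverge
        with pytest.raises(EscapedSlabError):
            total_energy(BeadChain(pos - [0, 0, 0.5]), ff, slab)


class TestDnaMapping:
    def test_kappa_from_persistence_reference_values(self):
        m = DnaMapping()
        assert kappa_from_persistence(50.0, m) == pytest.approx(10.0)
        assert kappa_from_persistence(5.0, m) == pytest.approx(1.0)
        assert kappa_from_persistence(100.0, m) == pytest.approx(20.0)

    def test_kappa_linearity(self):
        m = DnaMapping()
        for lp in (1.0, 7.3, 42.0):
            assert kappa_from_persistence(2 * lp, m) == pytest.approx(
                2 * kappa_from_persistence(lp, m))

    def test_kappa_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            kappa_from_persistence(0.0)

    def test_bead_base_pair_conversion(self):
        m = DnaMapping()
        assert m.bp_per_bead == 15
        assert m.beads_to_bp(1000) == 15_000
        assert m.sigma_to_nm(10.0) == pytest.approx(50.0)


class TestValidation:
    def test_force_field_invariants(self):
        with pytest.raises(ValueError):
            ForceField(fene_R0=1.0)   # below the WCA cutoff
        with pytest.raises(ValueError):
            ForceField(sigma=-1.0)

    def test_chain_shape_validation(self):
        with pytest.raises(ValueError):
            BeadChain(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            BeadChain(np.zeros((1, 3)))

    def test_wall_slab_validation(self):
        with pytest.raises(ValueError):
            WallSlab(-1.0)
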