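"""Distribution, Boltzmann inversion and barrier extraction exactness."""

import numpy as np
import pytest

from knotswap.analysis import (
    FreeEnergyProfile,
    boltzmann_invert,
    distance_distribution,
    end_to_end,
    extract_barriers,
    moving_average,
    persistence_length,
    size_statistics,
)
from knotswap.exceptions import KnotswapError


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        assert np.allclose(moving_average(np.full(50, 3.2), 100 // 10), 3.2)

    def test_window_one_is_identity(self):
        x = np.arange(20.0)
        assert np.array_equal(moving_average(x, 1), x)

    def test_alternating_pm_one_window_two_vanishes_inside(self):
        x = np.tile([1.0, -1.0], 10)
        out = moving_average(x, 2)
        assert np.allclose(out[1:], 0.0)

    def test_series_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average([1.0, 2.0], 5)


class TestDistanceDistribution:
    def test_single_delta_series_occupies_one_bin(self):
        prof = distance_distribution([[7.0] * 20], bin_width=5.0)
        assert np.isclose(prof.p.sum() * prof.bin_width, 1.0)
        assert (prof.p > 0).sum() == 1

    def test_symmetric_input_gives_symmetric_histogram(self):
        prof = distance_distribution([[-40.0] * 10 + [40.0] * 10],
                                     bin_width=5.0)
        i_neg = np.argmin(np.abs(prof.bin_centers + 40))
        i_pos = np.argmin(np.abs(prof.bin_centers - 40))
        assert prof.p[i_neg] == pytest.approx(prof.p[i_pos])

    def test_runs_enter_with_equal_weights(self):
        # second run has 10x the frames but must contribute equal mass
        prof = distance_distribution([[-30.0] * 5, [30.0] * 50],
                                     bin_width=5.0)
        i_neg = np.argmin(np.abs(prof.bin_centers + 30))
        i_pos = np.argmin(np.abs(prof.bin_centers - 30))
        assert prof.p[i_neg] == pytest.approx(prof.p[i_pos])

    def test_zero_is_a_bin_center(self):
        prof = distance_distribution([[0.0, 1.0, -1.0]], bin_width=5.0)
        assert 0.0 in prof.bin_centers


class TestBoltzmannInversion:
    def test_uniform_probability_gives_flat_zero_f(self):
        # integers -22..22 fill each 5-wide bin with exactly five samples
        prof = distance_distribution([np.arange(-22, 23, dtype=float)],
                                     bin_width=5.0)
        prof = boltzmann_invert(prof)
        valid = np.isfinite(prof.f)
        assert np.allclose(prof.f[valid], 0.0, atol=1e-12)

    def test_gaussian_profile_inverts_to_parabola(self):
        centers = np.arange(-10, 11, dtype=float)
        p = np.exp(-centers**2 / 20)
        p /= p.sum() * 1.0
        prof = FreeEnergyProfile(bin_centers=centers, p=p,
                                 counts=np.ones_like(p), bin_width=1.0)
        prof = boltzmann_invert(prof)
        assert np.allclose(prof.f, centers**2 / 20, atol=1e-10)

    def test_kbt_scales_f_linearly(self):
        centers = np.arange(-5, 6, dtype=float)
        p = np.exp(-np.abs(centers))
        p /= p.sum()
        prof = FreeEnergyProfile(centers, p, np.ones_like(p), 1.0)
        f1 = boltzmann_invert(prof, kbt=1.0).f
        f2 = boltzmann_invert(prof, kbt=2.0).f
        assert np.allclose(f2, 2 * f1, atol=1e-12)

    def test_empty_center_bin_falls_back_to_global_min(self):
        centers = np.arange(-5, 6, dtype=float)
        p = np.where(np.abs(centers) > 2, 0.1, 0.0)
        p /= p.sum()
        prof = boltzmann_invert(FreeEnergyProfile(centers, p,
                                                  (p > 0).astype(float), 1.0))
        assert "shift_reference_fallback_global_min" in prof.flags
        assert np.nanmin(prof.f) == pytest.approx(0.0)
        assert not np.any(np.isinf(prof.f[np.isfinite(prof.f)]))


def triple_well(depth13=2.5, depth23=1.0):
    """Synthetic F with intertwined minimum at 0, maxima at +-30, separated
    minima at +-60: Delta_1->3 = depth13, Delta_2->3 = depth23."""
    centers = np.arange(-100, 101, 5, dtype=float)
    f = np.full_like(centers, depth13)
    f -= (depth13) * np.exp(-centers**2 / 200)
    f -= depth23 * np.exp(-(np.abs(centers) - 60) ** 2 / 200)
    p = np.exp(-f)
    p /= p.sum() * 5.0
    prof = FreeEnergyProfile(centers, p, np.ones_like(p), 5.0)
    return boltzmann_invert(prof)


class TestBarriers:
    def test_programmed_triple_well_recovered(self):
        prof = triple_well()
        bar = extract_barriers(prof, median_bins=1)
        f = prof.f
        c = prof.bin_centers
        exp13 = f[np.abs(c) == 30].mean() - f[c == 0][0]
        exp12 = (f[np.abs(c) == 30].mean()
                 - f[np.abs(c) == 60].mean())
        assert bar.delta_1_to_3 == pytest.approx(exp13, abs=1e-9)
        assert bar.delta_1_to_2 == pytest.approx(exp12, abs=1e-9)
        assert bar.d_min_intertwined == 0.0

    def test_flat_profile_flags_no_barrier(self):
        centers = np.arange(-20, 21, 5, dtype=float)
        p = np.full_like(centers, 1.0 / (len(centers) * 5.0))
        prof = boltzmann_invert(
            FreeEnergyProfile(centers, p, np.ones_like(p), 5.0))
        bar = extract_barriers(prof, median_bins=1)
        assert "no_barrier" in bar.flags
        assert bar.delta_1_to_3 == 0.0

    def test_asymmetric_wells_report_both_sides(self):
        centers = np.arange(-100, 101, 5, dtype=float)
        f = 2.0 * np.exp(-(centers - 30) ** 2 / 100) \
            + 3.0 * np.exp(-(centers + 30) ** 2 / 100)
        p = np.exp(-f)
        p /= p.sum() * 5.0
        prof = boltzmann_invert(FreeEnergyProfile(centers, p,
                                                  np.ones_like(p), 5.0))
        bar = extract_barriers(prof, median_bins=1)
        assert len(bar.per_side_1_to_3) == 2
        assert bar.per_side_1_to_3[0] != pytest.approx(
            bar.per_side_1_to_3[1], abs=0.1)
        assert bar.delta_1_to_3 == pytest.approx(
            np.mean(bar.per_side_1_to_3))

    def test_fill_empty_bridges_unsampled_transition_region(self):
        centers = np.arange(-50, 51, 5, dtype=float)
        p = np.zeros_like(centers)
        p[np.abs(centers) <= 5] = 0.2    # intertwined basin
        p[np.abs(centers) >= 40] = 0.05  # separated basins, gap in between
        p /= p.sum() * 5.0
        prof = boltzmann_invert(FreeEnergyProfile(
            centers, p, (p > 0) * 10.0, 5.0))
        assert "no_barrier" in extract_barriers(prof, median_bins=1).flags
        bar = extract_barriers(prof, median_bins=1, fill_empty=True)
        assert "no_barrier" not in bar.flags
        assert bar.delta_1_to_3 > 0


class TestSizesAndChains:
    def test_bimodal_sizes_recover_two_state_means(self):
        rng = np.random.default_rng(1)
        small = rng.normal(40, 3, 300)
        grown = rng.normal(100, 5, 200)
        x31 = np.concatenate([small, grown])
        stats = size_statistics(x31, x31 + 12)
        m31 = stats["3_1"].state_means
        assert len(m31) == 2
        assert m31[0] == pytest.approx(40, abs=3)
        assert m31[1] == pytest.approx(100, abs=3)
        assert stats["4_1"].mean > stats["3_1"].mean

    def test_constant_sizes_are_single_state(self):
        stats = size_statistics([50.0] * 20, [60.0] * 20)
        assert "single_state" in stats["3_1"].flags
        assert stats["3_1"].std == 0.0

    def test_base_pair_conversion(self):
        stats = size_statistics([40.0] * 10, [60.0] * 10)
        from knotswap.model import DnaMapping
        bp = stats["3_1"].in_bp(DnaMapping())
        assert bp.mean == pytest.approx(600.0)

    def test_straight_rod_end_to_end_exact(self):
        from tests.conftest import make_straight
        st = end_to_end([make_straight(25, bond=1.0)])
        assert st.mean_ree == pytest.approx(24.0)
        assert "single_configuration" in st.flags
        assert st.se_ree == 0.0

    def test_persistence_length_increases_with_stiffness(self, straight_chain):
        from knotswap.model import ForceField
        from knotswap.samplers import SimProtocol, mc_run
        lps = []
        for kappa in (2.0, 10.0):
            ffk = ForceField(kappa=kappa, excluded_volume=False)
            proto = SimProtocol(n_steps=150_000, snapshot_every=3_000,
                                seed=int(kappa))
            traj = mc_run(straight_chain(80), ffk, proto)
            lps.append(persistence_length(traj.frames[20:],
                                          fit_range=(1, 8)).lp)
        assert lps[1] > lps[0] > 0.3

    def test_nondecaying_correlation_raises(self):
        from tests.conftest import make_straight
        frames = np.stack([make_straight(30).positions] * 4)
        with pytest.raises(KnotswapError):
            persistence_length(frames)
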