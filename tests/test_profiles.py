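import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recharge import constants as const
from recharge.errors import ValidationError
from recharge.profiles import (
    DensityProfile,
    PMFCurve,
    boltzmann_invert,
    compute_midplane,
    flip_flop_barrier,
    lateral_density_profile,
    replica_aggregate,
    replica_barrier_stats,
    surface_access_cost,
)
from recharge.toys import synth_bilayer_frames

from conftest import make_frame_table


def flat_profile(value=2.0, n=20):
    centers = -0.665 + np.arange(n) * 0.07
    return DensityProfile(centers, np.full(n, value), 0.07)


def two_bin_profile(ratio):
    return DensityProfile(
        np.array([-0.035, 0.035]), np.array([ratio, 1.0]), 0.07
    )


class TestDensityProfile:
    def test_all_atoms_one_bin(self):
        rows = [(0, "OIL", "C2", 0.0, 0.0, 0.5, 12.011) for _ in range(30)]
        ft = make_frame_table(rows, box=(5.0, 5.0, 12.0))
        prof = lateral_density_profile(
            ft, {"atomname": "C2"}, bin_width=0.07, z_range=(0.0, 1.4)
        )
        nz = np.flatnonzero(prof.density)
        assert len(nz) == 1
        # mass / (bin volume): 30 * 12.011 / (0.07 * 25)
        assert prof.density[nz[0]] == pytest.approx(30 * 12.011 / (0.07 * 25.0))

    def test_uniform_atoms_flat_profile(self):
        rng = np.random.default_rng(5)
        rows = [(0, "OIL", "C2", 0.0, 0.0, z, 12.011)
                for z in rng.uniform(0.0, 7.0, 40000)]
        ft = make_frame_table(rows, box=(5.0, 5.0, 7.0))
        prof = lateral_density_profile(
            ft, {"atomname": "C2"}, bin_width=0.07, z_range=(0.0, 7.0)
        )
        rel = prof.density / prof.density.mean()
        assert np.all(np.abs(rel - 1.0) < 0.25)  # Poisson noise at ~400/bin

    def test_mass_conservation(self):
        rng = np.random.default_rng(6)
        rows = [(0, "OIL", "C2", 0.0, 0.0, z, 12.011)
                for z in rng.uniform(0.0, 6.93, 500)]
        ft = make_frame_table(rows, box=(4.0, 4.0, 6.93))
        prof = lateral_density_profile(
            ft, {"atomname": "C2"}, bin_width=0.07, z_range=(0.0, 6.93)
        )
        integral = prof.density.sum() * prof.bin_width * prof.area
        assert integral == pytest.approx(500 * 12.011, rel=1e-6)

    def test_empty_selection_rejected(self, slab_frames):
        with pytest.raises(ValidationError):
            lateral_density_profile(slab_frames, {"atomname": "XX"})

    def test_midplane_centering(self):
        rows = []
        for z in (2.0, 2.1, 5.9, 6.0):  # phosphate layers around z = 4
            rows.append((0, "POPC", "P", 0.0, 0.0, z, 30.974))
        rows.append((0, "OIL", "C2", 0.0, 0.0, 4.0, 12.011))
        ft = make_frame_table(rows, box=(5.0, 5.0, 8.0))
        prof = lateral_density_profile(
            ft, {"atomname": "C2"}, bin_width=0.07, z_range=(-2.1, 2.1),
            center="midplane", center_selection={"atomname": "P"},
        )
        nz = np.flatnonzero(prof.density)
        assert abs(prof.bin_centers[nz[0]]) < 0.07

    def test_compute_midplane(self):
        z = np.array([1.0, 1.2, 6.8, 7.0])
        assert compute_midplane(z) == pytest.approx(4.0)


class TestBoltzmannInvert:
    def test_flat_profile_zero_pmf(self):
        pmf = boltzmann_invert(flat_profile())
        np.testing.assert_allclose(pmf.pmf, 0.0, atol=1e-12)

    def test_two_bin_kt_ln10(self):
        pmf = boltzmann_invert(two_bin_profile(10.0), temperature=298.15)
        d = pmf.pmf[1] - pmf.pmf[0]
        assert d == pytest.approx(const.kt_kcal(298.15) * np.log(10.0), rel=1e-12)
        assert d == pytest.approx(1.364, abs=1e-3)

    def test_min_anchored_to_zero(self):
        pmf = boltzmann_invert(two_bin_profile(3.0))
        assert np.nanmin(pmf.pmf) == pytest.approx(0.0, abs=1e-14)

    def test_zero_bins_masked_not_zero(self):
        prof = DensityProfile(
            np.array([0.0, 0.07, 0.14]), np.array([1.0, 0.0, 2.0]), 0.07
        )
        pmf = boltzmann_invert(prof)
        assert np.isnan(pmf.pmf[1])
        assert np.isfinite(pmf.pmf[[0, 2]]).all()

    def test_all_zero_rejected(self):
        prof = DensityProfile(np.array([0.0]), np.array([0.0]), 0.07)
        with pytest.raises(ValidationError):
            boltzmann_invert(prof)

    def test_reexponentiation_round_trip(self):
        rng = np.random.default_rng(8)
        dens = rng.uniform(0.1, 5.0, 40)
        prof = DensityProfile(np.arange(40) * 0.07, dens, 0.07)
        pmf = boltzmann_invert(prof, temperature=310.0)
        back = np.exp(-pmf.pmf / const.kt_kcal(310.0))
        ratio = dens / back
        assert np.max(np.abs(ratio / ratio[0] - 1.0)) < 1e-10


class TestFlipFlopBarrier:
    def make_double_well(self, depth=3.5, z0=1.47, span=2.975, nbins=85):
        # z0 = 1.47 puts the minima exactly on bin centers
        z = -span + 0.035 + np.arange(nbins) * 0.07
        v = depth * (1.0 - (z / z0) ** 2) ** 2
        v = np.where(np.abs(z) > z0, np.minimum(v, 6 * depth), v)
        kt = const.kt_kcal(298.15)
        dens = np.exp(-v / kt)
        return PMFCurve(z, v - v.min(), 0.07), DensityProfile(z, dens, 0.07)

    def test_flat_pmf_zero_barrier(self):
        pmf = boltzmann_invert(flat_profile())
        assert flip_flop_barrier(pmf, (-0.5, 0.5)) == pytest.approx(0.0)

    def test_constructed_double_well(self):
        pmf, _ = self.make_double_well(depth=3.5, z0=1.5)
        # minima slightly off-grid: barrier correct to the grid resolution
        assert flip_flop_barrier(pmf, (-2.975, 2.975)) == pytest.approx(3.5, abs=0.01)

    def test_offset_invariance(self):
        pmf, _ = self.make_double_well()
        shifted = PMFCurve(pmf.z, pmf.pmf + 11.7, pmf.bin_width)
        assert flip_flop_barrier(shifted, (-2.975, 2.975)) == pytest.approx(
            flip_flop_barrier(pmf, (-2.975, 2.975))
        )

    def test_max_convention_matches_for_midplane_peak(self):
        pmf, _ = self.make_double_well()
        a = flip_flop_barrier(pmf, (-2.0, 2.0), convention="midplane")
        b = flip_flop_barrier(pmf, (-2.0, 2.0), convention="max")
        assert a == pytest.approx(b)

    def test_masked_midplane_rejected(self):
        z = np.array([-0.07, 0.0, 0.07])
        pmf = PMFCurve(z, np.array([0.0, np.nan, 0.5]), 0.07)
        with pytest.raises(ValidationError):
            flip_flop_barrier(pmf, (-0.1, 0.1))

    def test_surface_access_cost(self):
        pmf, _ = self.make_double_well(depth=3.5)
        # at the phosphate level (z ~ 2.1): V(2.1) - 0
        v_at = pmf.pmf[np.argmin(np.abs(pmf.z - 2.1))]
        assert surface_access_cost(pmf, 2.1) == pytest.approx(v_at)

    def test_constructed_double_well_exact_grid(self):
        pmf, _ = self.make_double_well(depth=3.5)
        assert flip_flop_barrier(pmf, (-2.975, 2.975)) == pytest.approx(3.5)


class TestReplicaAggregate:
    def test_identical_replicas_zero_sd(self):
        pmf = boltzmann_invert(two_bin_profile(4.0))
        agg = replica_aggregate([pmf, pmf, pmf, pmf])
        np.testing.assert_allclose(agg.replica_sd, 0.0, atol=1e-14)
        np.testing.assert_allclose(agg.pmf, pmf.pmf, atol=1e-12)

    def test_two_replica_barrier_stats(self):
        z = np.array([-1.5, 0.0, 1.5])
        # hand-built curves with barriers 3.0 and 4.0
        c1 = PMFCurve(z, np.array([0.0, 3.0, 0.0]), 1.5)
        c2 = PMFCurve(z, np.array([0.0, 4.0, 0.0]), 1.5)
        mean, sd = replica_barrier_stats([c1, c2], (-1.5, 1.5))
        assert mean == pytest.approx(3.5)
        assert sd == pytest.approx(np.sqrt(0.5), rel=1e-9)  # 0.7071

    def test_binning_mismatch_rejected(self):
        c1 = boltzmann_invert(two_bin_profile(4.0))
        c2 = PMFCurve(c1.z + 0.01, c1.pmf.copy(), 0.07)
        with pytest.raises(ValidationError):
            replica_aggregate([c1, c2])

    def test_mean_closer_to_truth_than_replicas(self):
        kt = const.kt_kcal(298.15)
        z = -2.975 + 0.035 + np.arange(85) * 0.07
        truth = 3.5 * (1.0 - (z / 1.5) ** 2) ** 2
        truth -= truth.min()
        wins = 0
        n_trials = 20
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            reps = [
                PMFCurve(z, truth + rng.normal(0, 0.25, z.size), 0.07)
                for _ in range(4)
            ]
            agg = replica_aggregate(reps)

            def rmsd(c):
                p = c.pmf - np.nanmin(c.pmf)
                return np.sqrt(np.nanmean((p - truth) ** 2))

            if all(rmsd(agg) < rmsd(r.anchored()) for r in reps):
                wins += 1
        assert wins >= 0.9 * n_trials - 2


class TestInverseSamplingRecovery:
    def test_planted_double_well_recovery(self):
        barrier = 3.5

        def v(z):
            return barrier * (1.0 - (z / 1.5) ** 2) ** 2

        ft = synth_bilayer_frames(v, (-2.975, 2.975), 300_000, seed=21)
        prof = lateral_density_profile(
            ft, {"atomname": "C2"}, bin_width=0.07, z_range=(-2.975, 2.975)
        )
        pmf = boltzmann_invert(prof, 298.15)
        est = flip_flop_barrier(pmf, (-2.975, 2.975))
        assert est == pytest.approx(barrier, abs=0.2)

    def test_symmetric_fixture_symmetric_pmf(self):
        def v(z):
            return 2.0 * (1.0 - (z / 1.2) ** 2) ** 2

        ft = synth_bilayer_frames(v, (-2.1, 2.1), 200_000, seed=3)
        prof = lateral_density_profile(
            ft, {"atomname": "C2"}, bin_width=0.07, z_range=(-2.1, 2.1)
        )
        pmf = boltzmann_invert(prof)
        asym = pmf.pmf - pmf.pmf[::-1]
        # compare over the well-sampled central region; tail bins carry
        # few counts and a noisy log
        central = np.abs(pmf.z) <= 1.5
        assert np.nanmax(np.abs(asym[central])) < 0.2


@given(st.floats(0.5, 50.0), st.floats(270.0, 340.0))
@settings(max_examples=30, deadline=None)
def test_two_bin_ratio_property(ratio, temperature):
    pmf = boltzmann_invert(two_bin_profile(ratio), temperature)
    expected = const.kt_kcal(temperature) * np.log(ratio)
    assert pmf.pmf[1] - pmf.pmf[0] == pytest.approx(expected, rel=1e-10)
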