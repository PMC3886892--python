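"""Lipid-shell analysis: frame alignment, density accumulation, radial
projection, peak detection and the overlay separation predictions."""

import numpy as np
import pytest
from scipy import stats

from dimerpmf.geometry import ellipse_ring, rotation_matrix
from dimerpmf.lipidmap import (
    DensityMap2D,
    PeakSet,
    RadialProfile,
    SeparationPrediction,
    accumulate_density,
    align_frames,
    detect_peaks,
    mean_profile,
    predict_separations,
    radial_projection,
)
from dimerpmf.toygen import ToyConfig, Trajectory


def make_trajectory(lipid_frames, angles=None, com=None, n_lipids=None, box=16.0):
    """Hand-built single-protein trajectory from explicit lipid coordinates."""
    lipid_frames = np.asarray(lipid_frames, dtype=float)
    frames = lipid_frames.shape[0]
    nl = lipid_frames.shape[1]
    angles = np.zeros(frames) if angles is None else np.asarray(angles, dtype=float)
    com = np.full((frames, 2), box / 2.0) if com is None else np.asarray(com, dtype=float)
    return Trajectory(
        times=np.arange(frames, dtype=float),
        lipid_xy=lipid_frames,
        leaflet=np.arange(nl) % 2,
        protein_com=com[:, None, :],
        protein_angle=angles[:, None],
        body_ref=ellipse_ring((2.0, 1.2), 16)[None],
        box_side=box,
        seed=0,
        config=ToyConfig(n_lipids=nl),
    )


class TestAlignFrames:
    def test_already_aligned_is_identity(self):
        rng = np.random.default_rng(0)
        lip = np.tile(rng.uniform(2, 14, size=(5, 2)), (3, 1, 1))
        traj = make_trajectory(lip)
        out = align_frames(traj)
        assert np.allclose(out.lipid_xy, traj.lipid_xy, atol=1e-10)
        assert np.allclose(out.protein_angle, traj.protein_angle, atol=1e-12)

    def test_known_rotations_inverted_exactly(self):
        # lipids co-rotate rigidly with the protein; alignment must freeze them
        rng = np.random.default_rng(1)
        base = rng.uniform(-3, 3, size=(6, 2))
        com = np.array([8.0, 8.0])
        angles = np.radians([0.0, 10.0, -25.0, 140.0])
        frames = np.stack([base @ rotation_matrix(a).T + com for a in angles])
        traj = make_trajectory(frames, angles=angles, com=np.tile(com, (4, 1)))
        out = align_frames(traj, reference_frame=0)
        for f in range(4):
            assert np.allclose(out.lipid_xy[f], frames[0], atol=1e-8)

    def test_alignment_never_increases_protein_rmsd(self):
        cfg = ToyConfig(n_lipids=20, n_steps=400, n_equil=50, stride=10)
        from dimerpmf.toygen import simulate_toy_membrane

        traj = simulate_toy_membrane(cfg, None, seed=3, n_proteins=1)
        out = align_frames(traj)
        ref = traj.ring_positions(0)[0]
        for f in range(traj.n_frames):
            before = np.sqrt(np.mean((traj.ring_positions(f)[0] - ref) ** 2))
            after = np.sqrt(np.mean((out.ring_positions(f)[0] - ref) ** 2))
            assert after <= before + 1e-9


class TestAccumulateDensity:
    def test_static_lipid_fills_single_cell(self):
        pos = np.tile(np.array([[9.1, 8.3]]), (7, 1, 1))
        traj = make_trajectory(pos)
        dmap = accumulate_density(traj, region_side=6.0, bin_size=0.5)
        total = dmap.total()
        assert total.sum() == 7
        assert (total > 0).sum() == 1
        assert total.max() == 7

    def test_channel_additivity(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(6, 10, size=(4, 10, 2))
        traj = make_trajectory(pos)
        dmap = accumulate_density(traj, region_side=6.0, bin_size=0.5,
                                  channels=("upper", "lower", "both"))
        assert np.array_equal(
            dmap.channels["upper"] + dmap.channels["lower"], dmap.channels["both"]
        )

    def test_uniform_lipids_are_poisson_homogeneous(self):
        # synthetic uniform occupancy (no protein exclusion): per-cell counts
        # must pass a chi-square homogeneity/dispersion test
        rng = np.random.default_rng(3)
        pos = rng.uniform(5.0, 11.0, size=(200, 30, 2))  # exactly the region
        traj = make_trajectory(pos)
        dmap = accumulate_density(traj, region_side=6.0, bin_size=1.0)
        counts = dmap.total().ravel()
        res = stats.chisquare(counts)
        assert res.pvalue > 0.01

    def test_bin_size_must_divide_region(self):
        traj = make_trajectory(np.full((2, 3, 2), 8.0))
        with pytest.raises(ValueError, match="divide"):
            accumulate_density(traj, region_side=6.0, bin_size=0.7)

    def test_empty_trajectory_rejected(self):
        traj = make_trajectory(np.empty((3, 0, 2)), n_lipids=0)
        with pytest.raises(ValueError, match="empty"):
            accumulate_density(traj, region_side=6.0, bin_size=0.5)


def gaussian_ring_map(radius=1.62, side=6.0, nb=120, sigma=0.08):
    edges = np.linspace(-side / 2, side / 2, nb + 1)
    c = 0.5 * (edges[:-1] + edges[1:])
    gx, gy = np.meshgrid(c, c, indexing="ij")
    r = np.hypot(gx, gy)
    dens = np.exp(-((r - radius) ** 2) / (2 * sigma**2))
    return DensityMap2D(side=side, bin_size=side / nb, channels={"both": dens}, n_frames=1)


class TestRadialProjection:
    @pytest.mark.parametrize("direction", [0.0, 37.0, 90.0, 211.0])
    def test_symmetric_ring_peaks_at_radius_for_any_direction(self, direction):
        dmap = gaussian_ring_map(radius=1.62)
        prof = radial_projection(dmap, direction, half_window=15.0, line_spacing=1.0,
                                 line_length=3.0)
        assert prof.r[np.argmax(prof.density)] == pytest.approx(1.62, abs=0.05)

    def test_zero_map_gives_zero_profile(self):
        dmap = gaussian_ring_map()
        zero = DensityMap2D(side=dmap.side, bin_size=dmap.bin_size,
                            channels={"both": np.zeros_like(dmap.channels["both"])},
                            n_frames=1)
        prof = radial_projection(zero, 45.0, 15.0, 1.0, 3.0)
        assert np.all(prof.density == 0.0)

    def test_full_window_equals_radial_average(self):
        dmap = gaussian_ring_map()
        p1 = radial_projection(dmap, 0.0, half_window=180.0, line_spacing=1.0,
                               line_length=3.0)
        p2 = radial_projection(dmap, 133.0, half_window=180.0, line_spacing=1.0,
                               line_length=3.0)
        # equality holds up to bilinear-interpolation anisotropy on the grid
        assert np.allclose(p1.density, p2.density, atol=5e-3 * p1.density.max())

    def test_rotational_equivariance(self):
        rng = np.random.default_rng(4)
        dens = rng.random((120, 120))
        dmap = DensityMap2D(side=6.0, bin_size=0.05, channels={"both": dens}, n_frames=1)
        rot = DensityMap2D(side=6.0, bin_size=0.05,
                           channels={"both": np.rot90(dens, k=-1).copy()}, n_frames=1)
        # rotating the map by -90 deg (k=-1 about the grid) and the direction
        # by -90 deg leaves the profile unchanged
        p1 = radial_projection(dmap, 30.0, 10.0, 1.0, 2.5)
        p2 = radial_projection(rot, 30.0 - 90.0, 10.0, 1.0, 2.5)
        assert np.allclose(p1.density, p2.density, atol=1e-8)

    def test_line_longer_than_region_rejected(self):
        with pytest.raises(ValueError, match="length"):
            radial_projection(gaussian_ring_map(), 0.0, 15.0, 1.0, line_length=4.0)


class TestMeanProfile:
    def r(self):
        return np.linspace(0.05, 3.0, 40)

    def test_identical_profiles_unchanged(self):
        p = RadialProfile(r=self.r(), density=np.sin(self.r()))
        m = mean_profile([p, p])
        assert np.allclose(m.density, p.density)

    def test_constant_profiles_average(self):
        p1 = RadialProfile(r=self.r(), density=np.full(40, 1.0))
        p2 = RadialProfile(r=self.r(), density=np.full(40, 3.0))
        assert np.allclose(mean_profile([p1, p2]).density, 2.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        ps = [RadialProfile(r=self.r(), density=rng.random(40)) for _ in range(3)]
        assert np.allclose(
            mean_profile(ps).density, mean_profile(ps[::-1]).density
        )

    def test_mismatched_bins_rejected(self):
        p1 = RadialProfile(r=self.r(), density=np.zeros(40))
        p2 = RadialProfile(r=self.r() + 0.1, density=np.zeros(40))
        with pytest.raises(ValueError, match="mismatch"):
            mean_profile([p1, p2])


class TestDetectPeaks:
    def test_single_gaussian_bump_located(self):
        r = np.arange(0.025, 3.5, 0.05)
        prof = RadialProfile(r=r, density=np.exp(-((r - 1.62) ** 2) / 0.02))
        peaks = detect_peaks(prof, min_prominence=0.1, min_separation=0.2)
        assert peaks.positions.size == 1
        assert abs(peaks.positions[0] - 1.62) <= 0.025  # within half a bin

    def test_three_shells_at_lipid_spacing(self):
        r = np.arange(0.025, 3.5, 0.05)
        dens = sum(
            h * np.exp(-((r - m) ** 2) / 0.005)
            for h, m in ((1.0, 1.62), (0.6, 2.01), (0.4, 2.40))
        )
        peaks = detect_peaks(RadialProfile(r=r, density=dens),
                             min_prominence=0.05, min_separation=0.2)
        assert peaks.positions.size == 3
        assert np.allclose(peaks.positions, [1.62, 2.01, 2.40], atol=0.03)

    def test_flat_profile_yields_no_peaks(self):
        r = np.arange(0.025, 3.5, 0.05)
        peaks = detect_peaks(RadialProfile(r=r, density=np.ones_like(r)))
        assert peaks.positions.size == 0


def overlay_misalignment(s, peaks, pairs):
    """Oracle: squared misalignment of the prescribed (peak, reversed-peak)
    pairs when the reversed profile's origin sits at separation s."""
    return sum((s - peaks[j - 1] - peaks[i - 1]) ** 2 for i, j in pairs)


def exhaustive_best_shift(peaks, pairs, lo=0.0, hi=10.0, n=200_001):
    grid = np.linspace(lo, hi, n)
    costs = [overlay_misalignment(s, peaks, pairs) for s in grid]
    return grid[int(np.argmin(costs))]


class TestPredictSeparations:
    def test_closed_forms_on_integer_peaks(self):
        peaks = PeakSet(positions=[1.0, 2.0, 3.0], heights=[1, 1, 1])
        assert predict_separations(peaks, 1).separation == pytest.approx(2.0)
        assert predict_separations(peaks, 2).separation == pytest.approx(3.0)
        assert predict_separations(peaks, 3).separation == pytest.approx(4.0)

    def test_shell_spaced_peaks_reproduce_reference_predictions(self):
        peaks = PeakSet(positions=[1.62, 2.01, 2.40], heights=[1, 1, 1])
        got = [predict_separations(peaks, n).separation for n in (1, 2, 3)]
        assert got == pytest.approx([3.24, 3.63, 4.02])
        # cross-check every case against the exhaustive overlay-shift oracle
        for n, pairs in ((1, ((1, 1),)), (2, ((1, 2),)), (3, ((1, 3), (2, 2)))):
            oracle = exhaustive_best_shift(np.array([1.62, 2.01, 2.40]), pairs)
            assert predict_separations(peaks, n).separation == pytest.approx(
                oracle, abs=1e-4
            )

    def test_unequal_spacing_least_squares_between_pairwise_solutions(self):
        r = np.array([1.0, 2.2, 3.0])  # r1 + r3 != 2 r2
        peaks = PeakSet(positions=r, heights=[1, 1, 1])
        s = predict_separations(peaks, 3).separation
        s13, s22 = r[0] + r[2], 2 * r[1]
        assert min(s13, s22) < s < max(s13, s22)
        oracle = exhaustive_best_shift(r, ((1, 3), (2, 2)))
        assert s == pytest.approx(oracle, abs=1e-4)

    def test_insufficient_peaks_rejected(self):
        peaks = PeakSet(positions=[1.5], heights=[1.0])
        with pytest.raises(ValueError, match="at least 2"):
            predict_separations(peaks, 2)

    def test_more_than_three_lipids_undefined(self):
        peaks = PeakSet(positions=[1, 2, 3, 4], heights=[1, 1, 1, 1])
        with pytest.raises(ValueError, match="up to 3"):
            predict_separations(peaks, 4)

    def test_prediction_record_fields(self):
        peaks = PeakSet(positions=[1.6, 2.0], heights=[1.0, 0.5])
        pred = predict_separations(peaks, 2)
        assert isinstance(pred, SeparationPrediction)
        assert pred.matched_pairs == ((1, 2),)
        assert pred.n_intervening_lipids == 2
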