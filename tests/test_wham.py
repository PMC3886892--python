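"""WHAM estimator: histogram construction, overlap diagnostics, the
self-consistent solve against analytic oracles, zero-referencing and the
split-half convergence assessment."""

import numpy as np
import pytest
from scipy import stats

from dimerpmf.restraints import HarmonicBias
from dimerpmf.toygen import (
    PotentialSpec1D,
    exact_free_energy_1d,
    generate_umbrella_dataset,
    sample_boltzmann_1d,
)
from dimerpmf.wham import (
    HistogramSet,
    PMFProfile,
    UmbrellaPMF,
    UmbrellaWindow,
    WhamError,
    build_histograms,
    overlap_diagnostics,
    solve_wham,
    split_half_convergence,
    zero_reference,
)


def window(samples, center=0.0, k=0.0, temperature=1.0):
    return UmbrellaWindow(
        bias=HarmonicBias(center=center, force_constant=k),
        samples=np.asarray(samples, dtype=float),
        temperature=temperature,
    )


def aligned_rms(profile: PMFProfile, exact: PMFProfile, mask) -> float:
    diff = profile.free_energy[mask] - exact.free_energy[mask]
    diff = diff - diff.mean()  # both profiles carry an arbitrary constant
    return float(np.sqrt(np.mean(diff**2)))


class TestHistograms:
    def test_small_hand_counted_histogram(self):
        hs = build_histograms([window([3.0, 3.0, 3.1])], bin_width=0.1)
        occupied = hs.counts[0][hs.counts[0] > 0]
        assert list(occupied) == [2.0, 1.0]

    def test_identical_samples_occupy_single_bin(self):
        hs = build_histograms([window([2.5] * 7)], bin_width=0.1)
        assert (hs.counts[0] > 0).sum() == 1
        assert hs.counts[0].max() == 7

    def test_counts_conserve_sample_totals(self):
        rng = np.random.default_rng(0)
        wins = [window(rng.normal(c, 0.3, size=500), center=c) for c in (1.0, 2.0)]
        hs = build_histograms(wins, bin_width=0.05)
        assert np.all(hs.counts.sum(axis=1) == hs.totals)
        assert np.all(hs.totals + hs.out_of_range == 500)

    def test_out_of_range_reported_not_dropped(self):
        hs = build_histograms([window([1.0, 2.0, 9.0])], 0.5, bin_range=(0.0, 3.0))
        assert hs.out_of_range[0] == 1
        assert hs.totals[0] == 2

    def test_empty_window_named(self):
        with pytest.raises(ValueError):
            window([])


class TestOverlap:
    def test_identical_histograms_overlap_fully(self):
        s = [1.0, 1.1, 1.2, 1.2]
        hs = build_histograms([window(s, 1.0), window(s, 1.1)], 0.1)
        frac, flagged = overlap_diagnostics(hs)
        assert frac[0] == pytest.approx(1.0)
        assert flagged == []

    def test_disjoint_supports_do_not_overlap(self):
        hs = build_histograms([window([1.0, 1.05], 1.0), window([5.0, 5.05], 5.0)], 0.1)
        frac, flagged = overlap_diagnostics(hs, threshold=0.05)
        assert frac[0] == 0.0
        assert flagged == [(0, 1)]

    def test_half_shared_mass_gives_half(self):
        # window A: bins {0, 1}; window B: bins {1, 2}; each half its mass
        a = window([0.05, 0.15], 0.0)
        b = window([0.15, 0.25], 0.1)
        hs = build_histograms([a, b], 0.1)
        frac, _ = overlap_diagnostics(hs)
        assert frac[0] == pytest.approx(0.5)


class TestSolve:
    def test_single_unbiased_window_flat_potential_is_constant(self):
        spec = PotentialSpec1D("flat", {}, (0.0, 1.0))
        samples = sample_boltzmann_1d(spec, None, 20_000, seed=1)
        hs = build_histograms([window(samples)], 0.05, bin_range=(0.0, 1.0))
        prof = solve_wham(hs, [HarmonicBias(0.0, 0.0)], temperature=1.0)
        # counts should be uniform within Poisson noise (chi^2 GOF)
        counts = hs.counts[0]
        res = stats.chisquare(counts)
        assert res.pvalue > 0.01
        assert np.ptp(prof.free_energy) < 0.2  # flat to within sampling noise

    def test_recovers_harmonic_oracle(self, harmonic_spec, harmonic_windows):
        res = UmbrellaPMF(harmonic_windows, bin_width=0.02).fit()
        exact = exact_free_energy_1d(harmonic_spec, res.profile.edges)
        mask = res.profile.support & (res.histograms.counts.sum(axis=0) >= 100)
        assert aligned_rms(res.profile, exact, mask) < 0.1

    def test_deterministic_and_permutation_invariant(self, harmonic_windows):
        res1 = UmbrellaPMF(harmonic_windows, bin_width=0.02).fit()
        res2 = UmbrellaPMF(harmonic_windows[::-1], bin_width=0.02).fit()
        res3 = UmbrellaPMF(harmonic_windows, bin_width=0.02).fit()
        assert np.array_equal(res1.profile.free_energy, res3.profile.free_energy)
        assert np.allclose(
            res1.profile.free_energy, res2.profile.free_energy, atol=1e-8, equal_nan=True
        )

    def test_bias_strength_independence(self, harmonic_spec):
        centers = np.linspace(0.1, 0.9, 11)
        p = []
        for k, seed in ((40.0, 11), (80.0, 12)):
            wins = generate_umbrella_dataset(harmonic_spec, centers, k, 20_000, seed)
            res = UmbrellaPMF(wins, bin_width=0.02).fit()
            p.append(res)
        common = p[0].profile.support & p[1].profile.support
        common &= (p[0].histograms.counts.sum(axis=0) >= 100) & (
            p[1].histograms.counts.sum(axis=0) >= 100
        )
        assert aligned_rms(p[0].profile, p[1].profile, common) < 0.1

    def test_temperature_scaling_linear(self):
        # same sampled densities, biases scaled with T: free energies scale by T
        rng = np.random.default_rng(3)
        samples = [rng.normal(c, 0.25, 4000) for c in (1.0, 1.5, 2.0)]
        wins_t1 = [window(s, c, 20.0, temperature=1.0) for s, c in zip(samples, (1.0, 1.5, 2.0))]
        wins_t2 = [window(s, c, 40.0, temperature=2.0) for s, c in zip(samples, (1.0, 1.5, 2.0))]
        h1 = build_histograms(wins_t1, 0.05)
        h2 = build_histograms(wins_t2, 0.05)
        p1 = solve_wham(h1, [w.bias for w in wins_t1], 1.0, tolerance=1e-10)
        p2 = solve_wham(h2, [w.bias for w in wins_t2], 2.0, tolerance=1e-10)
        d1 = p1.free_energy - np.nanmean(p1.free_energy)
        d2 = p2.free_energy - np.nanmean(p2.free_energy)
        assert np.allclose(d2, 2.0 * d1, atol=1e-5, equal_nan=True)

    def test_disconnected_support_raises_with_gap(self):
        rng = np.random.default_rng(9)
        wins = [
            window(rng.normal(1.0, 0.05, 500), 1.0, 10.0),
            window(rng.normal(3.0, 0.05, 500), 3.0, 10.0),
        ]
        hs = build_histograms(wins, 0.05)
        with pytest.raises(WhamError, match="disconnected"):
            solve_wham(hs, [w.bias for w in wins], 1.0)

    def test_stray_tail_bins_become_gaps_not_errors(self):
        rng = np.random.default_rng(10)
        samples = np.concatenate([rng.normal(1.0, 0.1, 2000), [2.5]])
        hs = build_histograms([window(samples, 1.0, 5.0)], 0.05)
        prof = solve_wham(hs, [HarmonicBias(1.0, 5.0)], 1.0)
        idx = np.searchsorted(prof.edges, 2.5) - 1
        assert np.isnan(prof.free_energy[idx])  # reported as gap, not invented

    def test_non_convergence_raises_with_residual(self, harmonic_windows):
        with pytest.raises(WhamError, match="converge"):
            UmbrellaPMF(harmonic_windows, bin_width=0.02).fit(
                tolerance=1e-14, max_iter=3
            )

    def test_oracle_error_shrinks_with_sample_size(self, double_well_spec):
        centers = np.linspace(0.05, 0.95, 13)
        errs = []
        for n in (1_000, 100_000):
            wins = generate_umbrella_dataset(double_well_spec, centers, 40.0, n, 42)
            res = UmbrellaPMF(wins, bin_width=0.02).fit()
            exact = exact_free_energy_1d(double_well_spec, res.profile.edges)
            mask = res.profile.support & (res.histograms.counts.sum(axis=0) >= 100)
            errs.append(aligned_rms(res.profile, exact, mask))
        assert errs[1] < errs[0]


class TestReferencing:
    def make_profile(self):
        edges = np.linspace(0.0, 1.0, 11)
        f = np.linspace(5.0, 2.0, 10)
        return PMFProfile(edges=edges, free_energy=f)

    def test_reference_bin_pinned_to_exact_zero(self):
        prof = zero_reference(self.make_profile(), 0.55)
        idx = np.searchsorted(prof.edges, 0.55) - 1
        assert prof.free_energy[idx] == 0.0
        assert prof.reference_separation == 0.55

    def test_idempotent(self):
        p1 = zero_reference(self.make_profile(), 0.55)
        p2 = zero_reference(p1, 0.55)
        assert np.array_equal(p1.free_energy, p2.free_energy)

    def test_constant_profile_becomes_zero(self):
        prof = PMFProfile(edges=np.linspace(0, 1, 6), free_energy=np.full(5, 3.3))
        assert np.all(zero_reference(prof, 0.5).free_energy == 0.0)

    def test_reference_outside_support_rejected(self):
        with pytest.raises(ValueError):
            zero_reference(self.make_profile(), 2.0)

    def test_reference_in_gap_bin_rejected(self):
        f = np.linspace(5.0, 2.0, 10)
        f[4] = np.nan
        prof = PMFProfile(edges=np.linspace(0.0, 1.0, 11), free_energy=f)
        with pytest.raises(ValueError, match="gap"):
            zero_reference(prof, 0.45)


class TestSplitHalf:
    def test_duplicated_samples_give_zero_discrepancy(self):
        rng = np.random.default_rng(4)
        wins = []
        for c in (1.0, 1.4, 1.8):
            s = rng.normal(c, 0.25, 300)
            wins.append(window(np.concatenate([s, s]), c, 16.0))
        _, _, disc = split_half_convergence(wins, 0.05)
        assert disc == pytest.approx(0.0, abs=1e-9)

    def test_harmonic_oracle_halves_agree(self, harmonic_spec):
        centers = np.linspace(0.1, 0.9, 11)
        wins = generate_umbrella_dataset(harmonic_spec, centers, 40.0, 40_000, 17)
        p1, p2, disc = split_half_convergence(wins, 0.02)
        assert disc < 0.2
        assert p1.reference_separation == p2.reference_separation

    def test_split_is_contiguous_in_time(self):
        # the split is defined on contiguous time blocks: a series whose mean
        # drifts mid-run shows a large half-to-half discrepancy, which a
        # shuffled (interleaved) series would hide
        rng = np.random.default_rng(5)
        drifting = np.concatenate(
            [rng.normal(1.0, 0.12, 500), rng.normal(1.25, 0.12, 500)]
        )
        w_drift = window(drifting, 1.1, 2.0)
        _, _, disc_contiguous = split_half_convergence([w_drift], 0.05)
        w_shuffled = window(rng.permutation(drifting), 1.1, 2.0)
        _, _, disc_shuffled = split_half_convergence([w_shuffled], 0.05)
        assert disc_contiguous > disc_shuffled
        assert disc_contiguous > 0.3

    def test_window_too_short_to_split_named(self):
        with pytest.raises(WhamError, match="window 0"):
            split_half_convergence([window([1.0])], 0.1)


def test_summary_reports_fit_diagnostics(harmonic_windows):
    res = UmbrellaPMF(harmonic_windows, bin_width=0.02).fit(reference_separation=0.5)
    text = res.summary()
    assert "windows" in text and "11" in text
    assert "iterations" in text
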