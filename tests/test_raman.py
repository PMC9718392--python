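"""Raman ν₁ fitting, polymorph identification and group statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import voigt_profile

from aragsim import (
    Spectrum,
    compare_groups,
    fit_v1_peak,
    identify_polymorph,
    in_vitro_fraction,
)
from aragsim.raman import CoverageError
from aragsim.synthdata import _voigt_peak, _voigt_widths_for_fwhm

GRID = np.arange(650.0, 1200.0, 0.5)


def _baseline(x, intercept=50.0, slope=0.0):
    return intercept + slope * (x - x[0])


def aragonite_spectrum(rng=None, fwhm=2.0, center=1084.0, noise=0.0):
    y = (
        _voigt_peak(GRID, center, fwhm, 1000.0)
        + _voigt_peak(GRID, 701.1, 2.0, 140.0)
        + _voigt_peak(GRID, 705.5, 2.0, 160.0)
        + _baseline(GRID)
    )
    if noise > 0.0:
        y = y + rng.normal(0.0, noise, GRID.size)
    return Spectrum(GRID, y)


class TestPolymorphID:
    def test_aragonite_doublet_detected(self):
        rng = np.random.default_rng(1)
        assert identify_polymorph(aragonite_spectrum(rng, noise=5.0)) == "aragonite"

    def test_single_nu4_is_calcite(self):
        rng = np.random.default_rng(2)
        y = (
            _voigt_peak(GRID, 1086.0, 2.0, 1000.0)
            + _voigt_peak(GRID, 711.0, 2.0, 120.0)
            + _baseline(GRID)
            + rng.normal(0.0, 5.0, GRID.size)
        )
        assert identify_polymorph(Spectrum(GRID, y)) == "calcite"

    def test_flat_noise_is_unknown(self):
        rng = np.random.default_rng(3)
        y = _baseline(GRID) + rng.normal(0.0, 5.0, GRID.size)
        assert identify_polymorph(Spectrum(GRID, y)) == "unknown"

    def test_insufficient_coverage_rejected(self):
        x = np.arange(900.0, 1200.0, 1.0)
        with pytest.raises(CoverageError):
            identify_polymorph(Spectrum(x, np.ones_like(x)))


class TestVoigtFit:
    def test_pure_gaussian_degenerate_case(self):
        """Voigt with zero Lorentzian width is Gaussian: centre 1084.0,
        FWHM 3.00 recovered to ±0.01."""
        sigma = 3.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        y = 800.0 * np.exp(-0.5 * ((GRID - 1084.0) / sigma) ** 2) + _baseline(GRID)
        fit = fit_v1_peak(Spectrum(GRID, y))
        assert fit.center == pytest.approx(1084.0, abs=0.01)
        assert fit.fwhm == pytest.approx(3.00, abs=0.01)
        assert fit.r2_fit > 0.9999

    def test_fwhm_against_dense_grid_oracle(self):
        """Numeric FWHM agrees with a brute-force half-max scan of the
        generating Voigt and with the Olivero–Longbothum estimate."""
        fg, fl = 2.0, 1.0
        sigma = fg / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        gamma = fl / 2.0
        y = 900.0 * voigt_profile(GRID - 1084.0, sigma, gamma) / voigt_profile(
            np.zeros(1), sigma, gamma
        )[0] + _baseline(GRID)
        fit = fit_v1_peak(Spectrum(GRID, y))

        dense = np.arange(1074.0, 1094.0, 1e-4)
        prof = voigt_profile(dense - 1084.0, sigma, gamma)
        above = dense[prof >= prof.max() / 2.0]
        oracle_fwhm = above[-1] - above[0]
        ol_fwhm = 0.5346 * fl + math.sqrt(0.2166 * fl ** 2 + fg ** 2)
        assert oracle_fwhm == pytest.approx(ol_fwhm, rel=5e-4)
        assert fit.fwhm == pytest.approx(oracle_fwhm, rel=2e-3)

    def test_repeatability_under_noise(self):
        rng = np.random.default_rng(11)
        widths = [
            fit_v1_peak(aragonite_spectrum(rng, fwhm=2.0, noise=10.0)).fwhm
            for _ in range(10)
        ]
        assert np.std(widths) < 0.1
        assert np.mean(widths) == pytest.approx(2.0, abs=0.1)

    def test_baseline_shift_invariance(self):
        base = aragonite_spectrum(fwhm=2.2)
        ramp = Spectrum(GRID, base.intensities + 200.0 + 0.5 * (GRID - GRID[0]))
        f0, f1 = fit_v1_peak(base).fwhm, fit_v1_peak(ramp).fwhm
        assert abs(f1 - f0) / f0 < 5e-3

    def test_wavenumber_shift_equivariance(self):
        base = aragonite_spectrum(fwhm=2.2)
        delta = 4.0
        shifted = Spectrum(GRID + delta, base.intensities)
        fit0 = fit_v1_peak(base)
        fit1 = fit_v1_peak(shifted, window=(1060.0 + delta, 1110.0 + delta))
        assert fit1.center - fit0.center == pytest.approx(delta, abs=0.02)
        assert fit1.fwhm == pytest.approx(fit0.fwhm, rel=2e-3)

    def test_mixture_width_monotone_in_precipitate_fraction(self):
        """Seed-like (FWHM 1.5) + precipitate-like (FWHM 2.5) mixtures:
        fitted width increases with the precipitate fraction."""
        widths = []
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            y = (
                (1.0 - frac) * _voigt_peak(GRID, 1084.0, 1.5, 1000.0)
                + frac * _voigt_peak(GRID, 1084.0, 2.5, 1000.0)
                + _baseline(GRID)
            )
            widths.append(fit_v1_peak(Spectrum(GRID, y)).fwhm)
        assert all(b > a for a, b in zip(widths, widths[1:]))


def permutation_pairwise_p(a, b, rng, n_perm=3000):
    """Permutation test on the difference of means (two-sided)."""
    a, b = np.asarray(a), np.asarray(b)
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        diff = abs(pooled[: a.size].mean() - pooled[a.size:].mean())
        if diff >= obs - 1e-15:
            count += 1
    return (count + 1) / (n_perm + 1)


class TestGroupComparison:
    def test_identical_groups_have_no_significant_pairs(self):
        groups = {"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]}
        comp = compare_groups(groups)
        assert comp.significant_pairs == []
        assert math.isnan(comp.anova_F)

    def test_two_group_separation_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(21)
        a = rng.normal(1.5, 0.2, 10)
        b = rng.normal(2.5, 0.2, 10)
        comp = compare_groups({"seed": list(a), "precip": list(b)})
        assert comp.anova_p < 0.05
        assert (("precip", "seed") in comp.significant_pairs
                or ("seed", "precip") in comp.significant_pairs)
        assert permutation_pairwise_p(a, b, rng) < 0.05

    def test_tukey_flags_only_shifted_group_pairs(self):
        rng = np.random.default_rng(22)
        groups = {
            "g1": list(rng.normal(2.0, 0.15, 10)),
            "g2": list(rng.normal(2.0, 0.15, 10)),
            "g3": list(rng.normal(3.0, 0.15, 10)),
        }
        comp = compare_groups(groups)
        sig = {frozenset(p) for p in comp.significant_pairs}
        assert sig == {frozenset({"g1", "g3"}), frozenset({"g2", "g3"})}
        # permutation oracle agrees pair by pair at alpha=0.05
        for x, y in itertools.combinations(groups, 2):
            p_perm = permutation_pairwise_p(
                groups[x], groups[y], np.random.default_rng(99)
            )
            assert (p_perm < 0.05) == (frozenset({x, y}) in sig)

    def test_single_member_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})


class TestInVitroFraction:
    @pytest.mark.parametrize(
        "seed,precip,pct,resolvable",
        [
            (200.0, 300.0, 60.0, True),
            (0.0, 123.0, 100.0, True),
            (200.0, 100.0, 100.0 / 3.0, False),
        ],
    )
    def test_fraction_arithmetic(self, seed, precip, pct, resolvable):
        frac = in_vitro_fraction(seed, precip)
        assert frac.percent == pytest.approx(pct, abs=0.05)
        assert frac.resolvable is resolvable

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            in_vitro_fraction(0.0, 0.0)
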