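"""Umbrella windows, WHAM self-consistency, binding ΔG and landmark detection."""

import math

import numpy as np
import pytest
from scipy import stats

from lj1264.constants import kt
from lj1264.errors import ContractError, ConvergenceError, DomainError
from lj1264.sampling import RestraintSpec, SamplerConfig, TimeSeries
from lj1264.systems import DoubleWell1D
from lj1264.wham import (
    PMFProfile,
    WHAMConfig,
    Window,
    binding_dg_from_pmf,
    check_overlap,
    find_landmarks,
    plan_windows,
    run_umbrella,
    wham_solve,
)

KT300 = kt(300.0)


def _gaussian_window(rng, r0, k, n=20_000, offset=0.0):
    sigma = math.sqrt(KT300 / k)
    values = rng.normal(r0, sigma, n)
    return Window(
        RestraintSpec(k_rest=k, r0=r0, offset=offset), TimeSeries(values, {})
    )


@pytest.fixture(scope="module")
def doublewell_windows():
    system = DoubleWell1D()
    restraints = plan_windows(2.0, 9.0, 0.5, 10.0)
    cfg = SamplerConfig(n_steps=22_000, burn_in=2_000, thin=1, seed=42)
    return system, run_umbrella(system, restraints, cfg, seed=42)


class TestPlanWindows:
    def test_even_coverage_count(self):
        specs = plan_windows(2.0, 11.0, 0.5, 10.0)
        assert len(specs) == 19
        assert specs[0].r0 == 2.0
        assert specs[-1].r0 == 11.0

    def test_centres_strictly_increasing(self):
        centres = [w.r0 for w in plan_windows(1.0, 7.0, 0.3, 5.0)]
        assert all(b > a for a, b in zip(centres, centres[1:]))

    def test_degenerate_range_gives_single_midpoint_window(self):
        specs = plan_windows(2.0, 4.0, 10.0, 5.0)
        assert len(specs) == 1
        assert specs[0].r0 == pytest.approx(3.0)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(DomainError):
            plan_windows(5.0, 5.0, 0.5, 1.0)
        with pytest.raises(DomainError):
            plan_windows(2.0, 5.0, -0.5, 1.0)


class TestOverlap:
    def test_identical_windows_overlap_fully(self, rng):
        w = _gaussian_window(np.random.default_rng(1), 5.0, 10.0)
        w2 = Window(w.restraint, TimeSeries(w.series.values.copy(), {}))
        report = check_overlap([w, w2])
        assert report.fractions[0] == pytest.approx(1.0)

    def test_far_separated_stiff_windows_do_not_overlap(self):
        g = np.random.default_rng(2)
        a = _gaussian_window(g, 2.0, 200.0)
        b = _gaussian_window(g, 8.0, 200.0)
        report = check_overlap([a, b])
        assert report.fractions[0] < 1e-6
        assert report.low_pairs == ((0, 1),)

    def test_one_sigma_apart_matches_normal_overlap_integral(self):
        # closed form for equal-width normals d = σ apart: 2·Φ(−1/2)
        g = np.random.default_rng(3)
        k = 10.0
        sigma = math.sqrt(KT300 / k)
        a = _gaussian_window(g, 5.0, k, n=200_000)
        b = _gaussian_window(g, 5.0 + sigma, k, n=200_000)
        expected = 2.0 * stats.norm.cdf(-0.5)
        report = check_overlap([a, b], bin_width=sigma / 20)
        assert report.fractions[0] == pytest.approx(expected, abs=0.02)

    def test_contract_errors(self):
        w = _gaussian_window(np.random.default_rng(4), 3.0, 5.0)
        with pytest.raises(ContractError):
            check_overlap([w])


class TestWham:
    def test_single_unbiased_window_gives_flat_pmf(self):
        g = np.random.default_rng(5)
        values = g.uniform(2.0, 6.0, 200_000)
        w = Window(RestraintSpec(k_rest=1e-9, r0=4.0), TimeSeries(values, {}))
        pmf = wham_solve([w], WHAMConfig())
        ok = pmf.well_sampled
        assert np.nanmax(pmf.free_energy[ok]) < 0.15

    def test_single_window_reduces_to_log_histogram(self):
        g = np.random.default_rng(6)
        values = g.normal(4.0, 0.5, 100_000)
        w = Window(RestraintSpec(k_rest=1e-12, r0=4.0), TimeSeries(values, {}))
        cfg = WHAMConfig()
        pmf = wham_solve([w], cfg)
        edges = np.concatenate(
            [pmf.bin_centers - cfg.bin_width / 2, [pmf.bin_centers[-1] + cfg.bin_width / 2]]
        )
        hist, _ = np.histogram(values, bins=edges)
        ok = pmf.well_sampled & (hist > 0)
        ref = -KT300 * np.log(hist[ok])
        diff = pmf.free_energy[ok] - ref
        assert np.ptp(diff) < 1e-8  # equal up to an additive constant

    def test_double_well_pmf_matches_analytic_potential(self, doublewell_windows):
        system, windows = doublewell_windows
        pmf = wham_solve(windows, WHAMConfig())
        ok = pmf.well_sampled
        u = np.array([system.energy(r) for r in pmf.bin_centers])
        u -= u[ok].min()
        rms = math.sqrt(np.mean((pmf.free_energy[ok] - u[ok]) ** 2))
        assert rms < 0.15

    def test_splitting_a_window_leaves_pmf_unchanged(self, doublewell_windows):
        _, windows = doublewell_windows
        pmf_ref = wham_solve(windows, WHAMConfig())
        mid = len(windows) // 2
        w = windows[mid]
        half = len(w.series) // 2
        split = (
            list(windows[:mid])
            + [
                Window(w.restraint, TimeSeries(w.series.values[:half], {})),
                Window(w.restraint, TimeSeries(w.series.values[half:], {})),
            ]
            + list(windows[mid + 1:])
        )
        pmf_split = wham_solve(split, WHAMConfig())
        both = pmf_ref.well_sampled & pmf_split.well_sampled
        assert np.allclose(
            pmf_ref.free_energy[both], pmf_split.free_energy[both], atol=1e-8
        )

    def test_translation_invariance_of_biases(self, doublewell_windows):
        _, windows = doublewell_windows
        pmf_ref = wham_solve(windows, WHAMConfig())
        shifted = [
            Window(
                RestraintSpec(
                    k_rest=w.restraint.k_rest, r0=w.restraint.r0, offset=7.3
                ),
                w.series,
            )
            for w in windows
        ]
        pmf_shift = wham_solve(shifted, WHAMConfig())
        both = pmf_ref.well_sampled & pmf_shift.well_sampled
        assert np.allclose(
            pmf_ref.free_energy[both], pmf_shift.free_energy[both], atol=1e-8
        )

    def test_deterministic_given_inputs(self, doublewell_windows):
        _, windows = doublewell_windows
        a = wham_solve(windows, WHAMConfig())
        b = wham_solve(windows, WHAMConfig())
        assert np.array_equal(
            a.free_energy[a.well_sampled], b.free_energy[b.well_sampled]
        )

    def test_nonconvergence_raises_with_residual(self, doublewell_windows):
        _, windows = doublewell_windows
        with pytest.raises(ConvergenceError) as exc:
            wham_solve(windows, WHAMConfig(max_iterations=2, tolerance=1e-14))
        assert exc.value.residual is not None


def _flat_pmf(depth=0.0):
    centers = 2.0 + 0.05 * np.arange(160)
    g = np.zeros(160)
    if depth:
        g[:40] = depth
    return PMFProfile(centers, g - g.min(), np.full(160, 100.0))


class TestBindingDg:
    def test_zero_pmf_gives_zero(self):
        res = binding_dg_from_pmf(_flat_pmf(), bound_max_r=4.0)
        assert res.delta_g == pytest.approx(0.0, abs=1e-12)

    def test_deepening_bound_minimum_is_additive(self):
        centers = 2.0 + 0.05 * np.arange(160)
        g = np.abs(centers - 3.0) * 2.0
        g = np.minimum(g, 4.0)
        base = PMFProfile(centers, g - g.min(), np.full(160, 100.0))
        res0 = binding_dg_from_pmf(base, bound_max_r=4.5)
        delta = 1.7
        g2 = g.copy()
        bound = centers <= 4.5
        g2[bound] -= delta  # deepen the basin rigidly
        deeper = PMFProfile(centers, g2 - 0.0, np.full(160, 100.0))
        res1 = binding_dg_from_pmf(deeper, bound_max_r=4.5)
        assert res1.delta_g == pytest.approx(res0.delta_g - delta, abs=1e-9)

    def test_square_well_depth_recovered(self):
        centers = 2.0 + 0.05 * np.arange(160)
        g = np.full(160, 3.0)
        g[20:40] = 0.0
        pmf = PMFProfile(centers, g, np.full(160, 100.0))
        res = binding_dg_from_pmf(pmf, bound_max_r=4.5)
        assert res.delta_g == pytest.approx(-3.0, abs=1e-12)
        assert not res.warnings

    def test_invariant_to_additive_referencing(self):
        centers = 2.0 + 0.05 * np.arange(160)
        g = np.cos(centers) + 1.5
        a = PMFProfile(centers, g, np.full(160, 100.0))
        b = PMFProfile(centers, g + 11.0, np.full(160, 100.0))
        ra = binding_dg_from_pmf(a, bound_max_r=4.5)
        rb = binding_dg_from_pmf(b, bound_max_r=4.5)
        assert ra.delta_g == pytest.approx(rb.delta_g, abs=1e-12)

    def test_unsampled_plateau_is_an_error(self):
        centers = 2.0 + 0.05 * np.arange(160)
        n_eff = np.full(160, 100.0)
        n_eff[-40:] = 0.0  # outer region unsampled
        pmf = PMFProfile(centers, np.zeros(160), n_eff)
        with pytest.raises(ContractError):
            binding_dg_from_pmf(pmf, bound_max_r=4.0, plateau_range=(9.0, 10.0))

    def test_sloped_plateau_warns(self):
        centers = 2.0 + 0.05 * np.arange(160)
        g = 0.5 * (centers - 2.0)  # 0.5 kcal/mol/Å everywhere
        pmf = PMFProfile(centers, g, np.full(160, 100.0))
        res = binding_dg_from_pmf(pmf, bound_max_r=4.0)
        assert any("not flat" in w for w in res.warnings)


class TestLandmarks:
    def test_monotone_pmf_has_no_interior_landmarks(self):
        centers = 2.0 + 0.05 * np.arange(100)
        pmf = PMFProfile(centers, 1.5 * (centers - 2.0), np.full(100, 100.0))
        marks = find_landmarks(pmf)
        assert marks.labels == ()

    def test_double_well_landmarks_at_analytic_positions(self, doublewell_windows):
        system, windows = doublewell_windows
        pmf = wham_solve(windows, WHAMConfig())
        marks = find_landmarks(pmf)
        assert len(marks.minima) == 2
        assert len(marks.barriers) == 1
        lo, hi = system.minima
        tol = pmf.bin_width + 1e-9
        assert abs(marks.minima[0][0] - lo) <= tol
        assert abs(marks.minima[1][0] - hi) <= tol
        assert abs(marks.barriers[0][0] - system.center) <= tol

    def test_landmark_values_read_from_profile(self, doublewell_windows):
        _, windows = doublewell_windows
        pmf = wham_solve(windows, WHAMConfig())
        marks = find_landmarks(pmf)
        for _, _, r, g in marks.labels:
            i = int(np.argmin(np.abs(pmf.bin_centers - r)))
            assert g == pytest.approx(pmf.free_energy[i])

    def test_labels_alternate_and_order_by_position(self, doublewell_windows):
        _, windows = doublewell_windows
        marks = find_landmarks(wham_solve(windows, WHAMConfig()))
        kinds = [k for _, k, _, _ in marks.labels]
        rs = [r for _, _, r, _ in marks.labels]
        assert rs == sorted(rs)
        for a, b in zip(kinds, kinds[1:]):
            assert a != b
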