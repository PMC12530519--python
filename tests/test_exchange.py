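"""Residual-chromatogram and fraction-sum-residual (theta_res) analysis."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimerswap import exchange, synthetic
from dimerswap.exchange import Chromatogram, ExchangeConfig
from dimerswap.reference import exchange_panel_records

from conftest import theta_from_scenario


def gaussian_peak(grid: np.ndarray, center: float, width: float, area: float) -> np.ndarray:
    return area / (width * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((grid - center) / width) ** 2
    )


class TestResample:
    def test_identical_grids_pass_through(self):
        grid = np.linspace(13, 19, 101)
        chroms = [Chromatogram(grid, np.sin(grid) + 2.0) for _ in range(3)]
        out = exchange.resample_to_common_grid(*chroms)
        for before, after in zip(chroms, out):
            np.testing.assert_allclose(after.time, before.time)
            np.testing.assert_allclose(after.signal, before.signal)

    def test_constant_signal_resamples_to_constant(self):
        a = Chromatogram(np.linspace(13, 19, 61), np.full(61, 1.0))
        b = Chromatogram(np.linspace(12, 20, 47), np.full(47, 1.0))
        c = Chromatogram(np.linspace(13.5, 18.5, 31), np.full(31, 1.0))
        for ch in exchange.resample_to_common_grid(a, b, c):
            np.testing.assert_allclose(ch.signal, 1.0)

    def test_linear_ramp_interpolates_exactly_at_midpoints(self):
        # linear interpolation is exact on affine signals
        coarse = np.linspace(14, 18, 9)
        mid = Chromatogram((coarse[:-1] + coarse[1:]) / 2, np.zeros(8))
        ramp_b = Chromatogram(coarse, 3.0 * coarse - 5.0)
        ramp_c = Chromatogram(coarse, -2.0 * coarse + 40.0)
        _, b, c = exchange.resample_to_common_grid(mid, ramp_b, ramp_c)
        np.testing.assert_allclose(b.signal, 3.0 * mid.time - 5.0, rtol=1e-12)
        np.testing.assert_allclose(c.signal, -2.0 * mid.time + 40.0, rtol=1e-12)

    def test_disjoint_ranges_error(self):
        a = Chromatogram(np.linspace(10, 12, 20), np.zeros(20))
        b = Chromatogram(np.linspace(15, 18, 20), np.zeros(20))
        with pytest.raises(ValueError, match="overlap"):
            exchange.resample_to_common_grid(a, b, b)


class TestResidual:
    def test_additive_mixture_gives_zero_residual(self, time_grid):
        a = Chromatogram(time_grid, gaussian_peak(time_grid, 15.4, 0.2, 2.0))
        b = Chromatogram(time_grid, gaussian_peak(time_grid, 16.0, 0.2, 1.0))
        mix = Chromatogram(time_grid, a.signal + b.signal)
        res = exchange.residual_chromatogram(mix, a, b)
        np.testing.assert_allclose(res.signal, 0.0, atol=1e-14)

    def test_empty_mixture_gives_negated_sum(self, time_grid):
        a = Chromatogram(time_grid, gaussian_peak(time_grid, 15.4, 0.2, 2.0))
        b = Chromatogram(time_grid, gaussian_peak(time_grid, 16.0, 0.2, 1.0))
        mix = Chromatogram(time_grid, np.zeros_like(time_grid))
        res = exchange.residual_chromatogram(mix, a, b)
        np.testing.assert_allclose(res.signal, -(a.signal + b.signal), rtol=1e-12)

    def test_complete_exchange_lobes_match_arithmetic_oracle(self, time_grid):
        """f=0.5 resolved peaks: one positive heterodimer lobe flanked by two
        negative homodimer-depletion lobes, built by hand and compared
        pointwise against the library residual."""
        mass_a, mass_b, conc = 23000.0, 42000.0, 50.0
        t_a, t_b, t_h, w = 15.97, 15.37, 15.62, 0.03
        comp_a = Chromatogram(time_grid, gaussian_peak(time_grid, t_a, w, conc * mass_a))
        comp_b = Chromatogram(time_grid, gaussian_peak(time_grid, t_b, w, conc * mass_b))
        # statistical mixture at f=0.5: half of each homodimer remains
        mix = Chromatogram(
            time_grid,
            gaussian_peak(time_grid, t_a, w, 0.5 * conc * mass_a)
            + gaussian_peak(time_grid, t_b, w, 0.5 * conc * mass_b)
            + gaussian_peak(time_grid, t_h, w, conc * (mass_a + mass_b) / 2.0),
        )
        res = exchange.residual_chromatogram(mix, comp_a, comp_b)
        expected = (
            gaussian_peak(time_grid, t_h, w, conc * (mass_a + mass_b) / 2.0)
            - gaussian_peak(time_grid, t_a, w, 0.5 * conc * mass_a)
            - gaussian_peak(time_grid, t_b, w, 0.5 * conc * mass_b)
        )
        np.testing.assert_allclose(res.signal, expected, rtol=1e-10, atol=1e-8)
        # positive lobe area equals the sum of the two negative lobe areas
        dt = time_grid[1] - time_grid[0]
        pos = res.signal[res.signal > 0].sum() * dt
        neg = -res.signal[res.signal < 0].sum() * dt
        assert neg == pytest.approx(pos, rel=1e-10)  # mass conservation
        # lobe area matches the heterodimer area up to tiny tail overlap
        assert pos == pytest.approx(conc * (mass_a + mass_b) / 2.0, rel=1e-4)


class TestThetaRes:
    def test_zero_residual_gives_zero(self, time_grid):
        total = Chromatogram(time_grid, gaussian_peak(time_grid, 16.0, 0.2, 1.0))
        res = Chromatogram(time_grid, np.zeros_like(time_grid))
        assert exchange.theta_res(res, total) == 0.0

    def test_complete_statistical_exchange_is_50_percent(self):
        assert theta_from_scenario(
            synthetic.resolved_exchange_scenario(0.5)
        ) == pytest.approx(50.0, abs=0.1)

    @pytest.mark.parametrize("f", [0.1, 0.2, 0.3])
    def test_resolved_peaks_theta_equals_heterodimer_fraction(self, f):
        assert theta_from_scenario(
            synthetic.resolved_exchange_scenario(f)
        ) == pytest.approx(100.0 * f, abs=0.5)

    def test_agrees_with_oversampled_quadrature_oracle(self):
        """Trapezoid on the working grid vs 10x-oversampled quadrature."""
        scenario = synthetic.resolved_exchange_scenario(0.3)
        coarse = synthetic.default_time_grid(1.0 / 240.0)
        fine = synthetic.default_time_grid(1.0 / 2400.0)
        assert theta_from_scenario(scenario, coarse) == pytest.approx(
            theta_from_scenario(scenario, fine), abs=0.5
        )

    def test_empty_signals_raise(self, time_grid):
        zero = Chromatogram(time_grid, np.zeros_like(time_grid))
        with pytest.raises(ValueError, match="zero"):
            exchange.theta_res(zero, zero)

    @settings(deadline=None, max_examples=25)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        """theta_res is unchanged when all chromatograms share a rescaling."""
        grid = synthetic.default_time_grid(1.0 / 120.0)
        mix, a, b = synthetic.simulate_exchange_pair(
            synthetic.resolved_exchange_scenario(0.25), grid
        )
        def theta(factor):
            res = exchange.residual_chromatogram(
                Chromatogram(grid, factor * mix.signal),
                Chromatogram(grid, factor * a.signal),
                Chromatogram(grid, factor * b.signal),
            )
            tot = Chromatogram(grid, factor * (a.signal + b.signal))
            return exchange.theta_res(res, tot)
        assert theta(scale) == pytest.approx(theta(1.0), rel=1e-9)

    def test_monotonic_in_heterodimer_fraction(self):
        fracs = np.arange(0.0, 0.51, 0.1)
        thetas = [
            theta_from_scenario(synthetic.resolved_exchange_scenario(f))
            for f in fracs
        ]
        assert np.all(np.diff(thetas) >= 0)

    def test_peak_overlap_only_reduces_theta(self):
        """Shrinking the homodimer retention gap never increases theta_res."""
        thetas = []
        for mass_b in (42000.0, 33000.0, 27000.0, 24000.0):
            a = synthetic.SpeciesSpec("a", 23000.0, 50.0, peak_width=0.1)
            b = synthetic.SpeciesSpec("b", mass_b, 50.0, peak_width=0.1)
            scenario = synthetic.ExchangeScenario(a, b, 0.3, 0.0, 0)
            thetas.append(theta_from_scenario(scenario))
        assert np.all(np.diff(thetas) <= 1e-9)


class TestBackgroundAndScore:
    def test_mismatched_pair_background_mean_and_sd(self):
        # the four Dimer-1-mismatched panel values
        mean, sd = exchange.background_estimate([2.7, 2.0, 2.0, 2.3])
        assert round(mean, 1) == 2.2
        assert round(sd, 1) == 0.3

    def test_degenerate_and_hand_computed_backgrounds(self):
        assert exchange.background_estimate([5, 5, 5]) == (5.0, 0.0)
        mean, sd = exchange.background_estimate([1.0, 3.0])
        assert (mean, sd) == (2.0, pytest.approx(np.sqrt(2.0)))

    def test_single_value_raises(self):
        with pytest.raises(ValueError):
            exchange.background_estimate([2.2])

    @pytest.mark.parametrize(
        "theta,expected",
        [(25.4, 3), (17.6, 3), (6.2, 2), (3.2, 1), (2.7, 0), (2.0, 0), (2.3, 0)],
    )
    def test_panel_theta_values_score_as_published(self, theta, expected):
        assert exchange.classify_exchange(theta, 2.25) == expected

    def test_exact_threshold_falls_to_lower_score(self):
        bg = 2.0
        assert exchange.classify_exchange(1.3 * bg, bg) == 0
        assert exchange.classify_exchange(2.0 * bg, bg) == 1
        assert exchange.classify_exchange(5.0 * bg, bg) == 2

    def test_nonpositive_background_raises(self):
        with pytest.raises(ValueError):
            exchange.classify_exchange(5.0, 0.0)


class TestExchangeMatrix:
    def test_published_panel_reproduces_score_rows(self):
        results, bg_mean, _ = exchange.score_records(exchange_panel_records())
        scores = {(r.pair[1], r.pair[0]): r.score for r in results}
        assert bg_mean == pytest.approx(2.25)
        row_ca = [
            scores[("Ty1c CA(F323S)", rf)]
            for rf in ["p18m(F323S)", "Drt2m(SSS)", "p18m-VTF(F323S)", "Drt2m-AVL(SSS)"]
        ]
        row_vtf = [
            scores[("Ty1c CA-VTF(F323S)", rf)]
            for rf in ["p18m(F323S)", "Drt2m(SSS)", "p18m-VTF(F323S)", "Drt2m-AVL(SSS)"]
        ]
        assert row_ca == [3, 0, 0, 2]
        assert row_vtf == [0, 1, 3, 0]

    def test_all_background_pairs_score_zero(self):
        records = [("ca", f"rf{i}", 2.2, True) for i in range(4)]
        results, _, _ = exchange.score_records(records)
        assert all(r.score == 0 for r in results)

    def test_no_background_flagged_raises(self):
        with pytest.raises(ValueError, match="background"):
            exchange.score_records([("ca", "rf", 10.0, False)])

    def test_simulated_panel_matched_pairs_score_matched_mismatched_zero(self):
        """Closed loop: matched Dimer-1 pairs simulated at f=0.25, mismatched
        at f=0, with 1 % noise, classify correctly against each other."""
        grid = synthetic.default_time_grid(1.0 / 120.0)
        pairs = []
        for k, (f, is_bg) in enumerate(
            [(0.25, False), (0.25, False), (0.0, True), (0.0, True), (0.0, True)]
        ):
            # ~1% of the homodimer peak height 50*23000/(0.03*sqrt(2*pi))
            scenario = synthetic.resolved_exchange_scenario(
                f, noise_sd=1.5e5, seed=100 + k
            )
            mix, a, b = synthetic.simulate_exchange_pair(scenario, grid)
            pairs.append(
                exchange.PairRecord(
                    mix, a, b, ca_label=f"ca{k}", rf_label=f"rf{k}",
                    is_background=is_bg,
                )
            )
        per_pair, _, _, _ = exchange.exchange_matrix(pairs)
        matched = per_pair[~per_pair.is_background]["score"]
        mismatched = per_pair[per_pair.is_background]["score"]
        assert (matched >= 2).all()
        assert (mismatched == 0).all()


def test_linear_baseline_subtraction_recovers_flat_baseline(time_grid):
    peak = gaussian_peak(time_grid, 16.0, 0.2, 1000.0)
    drift = 3.0 + 0.5 * time_grid
    chrom = Chromatogram(time_grid, peak + drift)
    corrected = exchange.fit_linear_baseline(chrom, (12.0, 14.0), (18.0, 20.0))
    np.testing.assert_allclose(corrected.signal, peak, atol=1e-8)
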