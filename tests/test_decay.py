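"""Half-life and two-phase decay estimation against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riftkin import (
    ChaseDesign, DecayModel, PipelineConfig, estimate_all,
    fit_exponential_segment, summarize_decay, twofold_half_life, two_phase_fit,
)
from riftkin.datasets import NCRNA_REPORT_CAP, ncrna_decay_rates
from riftkin.synthetic import TrueKinetics, simulate_gene

from conftest import GRID


def ols_slope_oracle(t, y):
    """Closed-form least-squares slope of log2 y on t."""
    t = np.asarray(t, float)
    ly = np.log2(np.asarray(y, float))
    return (np.mean(t * ly) - t.mean() * ly.mean()) / (np.mean(t * t) - t.mean() ** 2)


def brute_force_two_phase(t, y):
    """Enumerate every admissible breakpoint with independent segment fits.

    Returns (breakpoint, rate1, rate2, mse) minimizing the pooled MSE,
    ties to the earliest breakpoint.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    i_on = np.flatnonzero(y == y.max())[-1]
    ts, ys = t[i_on:], y[i_on:]
    best = None
    for i in range(1, len(ts) - 1):
        results = []
        for lo, hi in ((0, i + 1), (i, len(ts))):
            tt, yy = ts[lo:hi], np.log2(ys[lo:hi])
            A = np.vstack([tt, np.ones_like(tt)]).T
            coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
            ssr = float(((A @ coef - yy) ** 2).sum())
            results.append((coef[0], ssr, hi - lo))
        mse = (results[0][1] + results[1][1]) / (results[0][2] + results[1][2])
        if best is None or mse < best[3] - 1e-15:
            best = (ts[i], -1 / results[0][0] if results[0][0] else np.inf,
                    -1 / results[1][0] if results[1][0] else np.inf, mse)
    return best


class TestFitExponentialSegment:
    def test_two_point_fit_is_exact(self):
        seg = fit_exponential_segment([(0, 100), (5, 50)])
        assert seg.k == pytest.approx(0.2)
        assert seg.time_per_twofold == pytest.approx(5.0)
        assert seg.mse == pytest.approx(0.0, abs=1e-15)

    def test_flat_segment_flags_infinite_twofold_time(self):
        seg = fit_exponential_segment([(0, 100), (5, 100), (10, 100)])
        assert seg.k == 0
        assert np.isinf(seg.time_per_twofold)

    def test_noisy_slope_matches_closed_form_oracle(self):
        rng = np.random.default_rng(12)
        y = 100 * 2 ** (-GRID / 3.0) * np.exp(rng.normal(0, 0.05, GRID.size))
        seg = fit_exponential_segment(np.column_stack([GRID, y]))
        assert -seg.k == pytest.approx(ols_slope_oracle(GRID, y), rel=1e-12)
        assert seg.k == pytest.approx(1 / 3.0, rel=0.05)

    @pytest.mark.parametrize("pts", [[(0, 100)], [(0, 100), (5, -1)],
                                     [(0, 100), (5, 0)]])
    def test_invalid_windows_rejected(self, pts):
        with pytest.raises(ValueError):
            fit_exponential_segment(pts)


class TestTwofoldHalfLife:
    def test_pure_exponential_exact(self):
        y = 100 * 2 ** (-GRID / 5.0)
        hl, fell = twofold_half_life(GRID, y)
        assert fell
        assert hl == pytest.approx(5.0, rel=1e-12)

    def test_crossing_point_formula(self):
        # t1/2 = 3: ratio at 2.5 min is 1.78 (<2), at 5 min 3.17 (>=2)
        y = 100 * 2 ** (-GRID / 3.0)
        hl, fell = twofold_half_life(GRID, y)
        assert fell
        assert hl == pytest.approx((5.0 - 0.0) / np.log2(y[0] / y[2]), rel=1e-12)
        assert hl == pytest.approx(3.0, rel=1e-12)

    def test_rising_series_negative_half_life_flagged_stable(self):
        y = 100 * 2 ** (GRID / 30.0)
        hl, fell = twofold_half_life(GRID, y)
        assert not fell
        assert hl < 0

    def test_never_halving_slow_decay_falls_back_to_all_points(self):
        y = 100 * 2 ** (-GRID / 200.0)
        hl, fell = twofold_half_life(GRID, y)
        assert not fell
        assert hl == pytest.approx(200.0, rel=1e-9)

    @given(h=st.floats(0.6, 25.0))
    @settings(max_examples=60, deadline=None)
    def test_property_exact_recovery_for_pure_exponentials(self, h):
        y = 640.0 * 2 ** (-GRID / h)
        hl, fell = twofold_half_life(GRID, y)
        assert fell
        assert hl == pytest.approx(h, rel=1e-9)


class TestTwoPhaseFit:
    def test_pure_exponential_ties_break_to_earliest_breakpoint(self):
        y = 100 * 2 ** (-GRID / 5.0)
        fit = two_phase_fit(GRID, y)
        assert fit.t_on == 0.0
        assert fit.breakpoint == 2.5
        assert fit.decay_rate == pytest.approx(5.0, rel=1e-12)
        assert fit.phase2.time_per_twofold == pytest.approx(5.0, rel=1e-12)

    def test_piecewise_truth_recovered_and_confirmed_by_enumeration(self):
        y = np.where(GRID < 10, 100 * 2 ** (-GRID / 2.5),
                     100 * 2 ** (-10 / 2.5) * 2 ** (-(GRID - 10) / 20.0))
        fit = two_phase_fit(GRID, y)
        assert fit.breakpoint == 10.0
        assert fit.decay_rate == pytest.approx(2.5, rel=1e-12)
        assert fit.phase2.time_per_twofold == pytest.approx(20.0, rel=1e-12)
        bx, r1, r2, _ = brute_force_two_phase(GRID, y)
        assert (bx, r1, r2) == pytest.approx((10.0, 2.5, 20.0), rel=1e-9)

    def test_onset_rule_uses_last_maximal_timepoint(self):
        y = np.array([100.0, 100, 120, 120, 60, 30, 15])
        fit = two_phase_fit(GRID, y)
        assert fit.t_on == 10.0
        assert fit.decay_rate == pytest.approx(10.0, rel=1e-12)

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(77)
        checked = 0
        for _ in range(400):
            y = np.exp(rng.normal(5, 1, GRID.size))
            if np.argmax(y) > GRID.size - 4:  # onset too late to fit
                continue
            checked += 1
            fit = two_phase_fit(GRID, y)
            bx, r1, r2, mse = brute_force_two_phase(GRID, y)
            assert fit.breakpoint == bx
            assert fit.decay_rate == pytest.approx(r1, rel=1e-9, abs=1e-9)
            assert fit.mse == pytest.approx(mse, rel=1e-9, abs=1e-12)
        assert checked > 200

    def test_too_few_points_after_onset_rejected(self):
        y = np.array([10.0, 20, 40, 80, 100, 50, 25])
        with pytest.raises(ValueError, match="onset"):
            two_phase_fit(GRID, y)


class TestInvarianceProperties:
    @given(scale=st.floats(0.01, 1e4))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance_of_both_estimators(self, scale):
        rng = np.random.default_rng(3)
        y = np.exp(rng.normal(5, 0.8, GRID.size))
        hl_a, _ = twofold_half_life(GRID, y)
        hl_b, _ = twofold_half_life(GRID, y * scale)
        fit_a = two_phase_fit(GRID, y)
        fit_b = two_phase_fit(GRID, y * scale)
        assert hl_b == pytest.approx(hl_a, rel=1e-9)
        assert fit_b.breakpoint == fit_a.breakpoint
        assert fit_b.decay_rate == pytest.approx(fit_a.decay_rate, rel=1e-9)

    def test_delayed_onset_raises_half_life_but_not_decay_rate(self):
        h = 4.0
        no_delay = 100 * 2 ** (-GRID / h)
        delayed = np.where(GRID < 10, 100.0,
                           100 * 2 ** (-(GRID - 10) / h))
        hl0, _ = twofold_half_life(GRID, no_delay)
        hl1, _ = twofold_half_life(GRID, delayed)
        assert hl1 > hl0
        fit0 = two_phase_fit(GRID, no_delay)
        fit1 = two_phase_fit(GRID, delayed)
        assert fit1.decay_rate == pytest.approx(fit0.decay_rate, rel=1e-9)
        assert fit1.t_on == 10.0


class TestDecayModelResults:
    def test_summary_and_row_report_both_estimates(self, design_noisy):
        k = TrueKinetics("gX", E0=500, fast_half_life=3, slow_half_life=3,
                         phase_break=30)
        ser = simulate_gene(k, design_noisy)
        res = DecayModel(design_noisy.times, ser.to_numpy(), gene_id="gX").fit()
        text = res.summary()
        assert "half-life" in text and "decay rate" in text and "gX" in text
        row = res.to_row()
        assert row["half_life_min"] == pytest.approx(3.0, rel=0.3)
        assert np.isfinite(row["half_life_se"])
        assert not row["stable"]

    def test_delayed_gene_shows_half_life_above_decay_rate(self, design_clean):
        # delayed onset inflates the twofold half-life but the two-phase
        # decay rate stays at the post-onset speed
        k = TrueKinetics("delayed", E0=500, onset_delay=10, fast_half_life=5,
                         slow_half_life=5, phase_break=30)
        ser = simulate_gene(k, design_clean)
        res = DecayModel(design_clean.times, ser.to_numpy(),
                         gene_id="delayed").fit()
        assert res.decay_rate == pytest.approx(5.0, rel=1e-9)
        assert res.half_life > res.decay_rate

    def test_stable_flag_for_long_and_negative_half_lives(self, design_clean):
        rising = TrueKinetics("r", E0=100, onset_delay=59, fast_half_life=1,
                              slow_half_life=1, phase_break=60,
                              rise_amplitude=1.0)
        ser = simulate_gene(rising, design_clean)
        res = DecayModel(design_clean.times, ser.to_numpy(), gene_id="r").fit()
        assert res.stable
        assert res.half_life < 0


class TestEstimateAll:
    def test_zero_noise_recovery_of_pure_exponentials(self, design_clean):
        rng = np.random.default_rng(9)
        frames = {}
        truth = {}
        for i in range(40):
            h = float(rng.uniform(0.8, 5.0))
            k = TrueKinetics(f"g{i:02d}", E0=300, fast_half_life=h,
                             slow_half_life=h, phase_break=30)
            truth[k.gene_id] = h
            frames[k.gene_id] = simulate_gene(k, design_clean)
        coll = pd.concat(frames, names=["gene_id", "replicate"])
        table = estimate_all(coll)
        for _, row in table.iterrows():
            assert row["half_life_min"] == pytest.approx(
                truth[row["gene_id"]], rel=1e-9)

    def test_unfittable_gene_flagged_not_fatal(self, design_clean):
        k = TrueKinetics("ok", E0=300, fast_half_life=3, slow_half_life=3,
                         phase_break=30)
        good = simulate_gene(k, design_clean)
        bad = good.copy() * np.nan
        coll = pd.concat({"ok": good, "bad": bad},
                         names=["gene_id", "replicate"])
        table = estimate_all(coll)
        flags = table.set_index("gene_id")["flags"]
        assert flags["bad"] == "unfittable"
        assert flags["ok"] == ""


class TestSummarizeDecay:
    def test_printed_ncrna_rates_median(self):
        tab = ncrna_decay_rates().rename(columns={"decay_rate_min": "x"})
        table = pd.DataFrame({
            "gene_id": tab["gene_id"],
            "half_life_min": 1.0,
            "decay_rate_min": tab["x"],
            "stable": False,
        })
        summ = summarize_decay(
            table, PipelineConfig(decay_rate_report_cap=NCRNA_REPORT_CAP),
            subsets={"ncrna": list(tab["gene_id"])})
        assert summ["median_decay_rate_ncrna_min"] == pytest.approx(3.3)

    def test_single_gene_percentiles_collapse(self):
        table = pd.DataFrame({"gene_id": ["g"], "half_life_min": [4.2],
                              "decay_rate_min": [4.0], "stable": [False]})
        s = summarize_decay(table)
        assert s["median_half_life_min"] == 4.2
        assert s["half_life_p10_min"] == s["half_life_p90_min"] == 4.2

    def test_percentiles_match_sorted_oracle(self):
        rng = np.random.default_rng(21)
        vals = rng.lognormal(1, 0.7, 1000)
        table = pd.DataFrame({"gene_id": [f"g{i}" for i in range(1000)],
                              "half_life_min": vals,
                              "decay_rate_min": vals, "stable": False})
        s = summarize_decay(table)
        assert s["half_life_p10_min"] == pytest.approx(
            np.percentile(vals, 10), rel=1e-12)
        assert s["half_life_p90_min"] == pytest.approx(
            np.percentile(vals, 90), rel=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_decay(pd.DataFrame(columns=["half_life_min"]))
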