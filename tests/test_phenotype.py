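import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from mutcloud.phenotype import (
    GrowthCurve,
    biolog_score,
    call_tolerance,
    curve_auc,
    fit_logistic,
    logistic,
    noise_threshold,
    relative_fitness,
    select_concentration_well,
    stress_fold_change,
)
from mutcloud.simulate import simulate_growth_curve, simulate_plate

TIMES = np.arange(0.0, 18.0, 1.0 / 6.0)  # 18 h at 10-minute cadence


class TestFitLogistic:
    def test_noiseless_recovery(self):
        curve = simulate_growth_curve(0.5, 1.0, 0.02, TIMES)
        fit = fit_logistic(curve)
        assert fit.converged
        assert fit.r == pytest.approx(0.5, abs=1e-6)
        assert fit.K == pytest.approx(1.0, abs=1e-6)
        assert fit.n0 == pytest.approx(0.02, abs=1e-6)

    def test_noisy_recovery(self):
        curve = simulate_growth_curve(0.5, 1.0, 0.02, TIMES, noise_sd=0.005, seed=1)
        fit = fit_logistic(curve)
        assert fit.converged
        assert fit.r == pytest.approx(0.5, abs=0.02)

    def test_constant_readings_flagged_non_growth(self):
        curve = GrowthCurve(TIMES, np.full_like(TIMES, 0.05))
        fit = fit_logistic(curve)
        assert fit.non_growth
        assert math.isnan(fit.r)

    def test_scale_equivariance(self):
        curve = simulate_growth_curve(0.7, 0.9, 0.03, TIMES)
        scaled = GrowthCurve(TIMES, curve.readings * 3.0)
        a, b = fit_logistic(curve), fit_logistic(scaled)
        assert b.r == pytest.approx(a.r, rel=1e-5)
        assert b.K == pytest.approx(3 * a.K, rel=1e-5)
        assert b.n0 == pytest.approx(3 * a.n0, rel=1e-5)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_logistic(GrowthCurve(np.arange(5.0), np.arange(5.0) + 1))

    def test_blank_subtraction(self):
        curve = simulate_growth_curve(0.5, 1.0, 0.02, TIMES)
        shifted = GrowthCurve(TIMES, curve.readings + 0.08)
        fit = fit_logistic(shifted, blank=0.08)
        assert fit.r == pytest.approx(0.5, abs=1e-6)


class TestRelativeFitness:
    def test_identical(self):
        assert relative_fitness(0.9, 0.9) == 0.0

    def test_arithmetic(self):
        assert relative_fitness(1.2, 0.9) == pytest.approx(0.3)

    def test_ancestor_vs_reference_convention(self):
        # the same op serves r_anc - r_K12
        assert relative_fitness(0.34, 0.0) == pytest.approx(0.34)

    def test_antisymmetry(self):
        assert relative_fitness(1.2, 0.9) == -relative_fitness(0.9, 1.2)


class TestCurveAuc:
    def test_constant_readings_zero(self):
        curve = GrowthCurve(TIMES, np.full_like(TIMES, 0.3))
        assert curve_auc(curve) == 0.0

    def test_rectangle_exact(self):
        h, T = 0.7, 10.0
        times = np.linspace(0.0, T, 41)
        curve = GrowthCurve(times, np.full_like(times, h))
        assert curve_auc(curve, baseline=0.0) == pytest.approx(h * T)

    def test_converges_to_analytic_integral(self):
        r, K, n0, T = 0.5, 1.0, 0.02, 18.0
        exact, _ = integrate.quad(lambda t: logistic(t, r, K, n0) - n0, 0.0, T)
        errors = []
        for n_points in (20, 80, 320):
            times = np.linspace(0.0, T, n_points)
            curve = GrowthCurve(times, logistic(times, r, K, n0))
            errors.append(abs(curve_auc(curve) - exact))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 1e-3


def make_plate(records):
    return pd.DataFrame(records, columns=["sample_id", "compound", "well", "time_label", "od600"])


class TestBiologScore:
    def test_zero_difference(self):
        plate = make_plate([("s", "c", 1, "10m", 0.2), ("s", "c", 1, "24h", 0.2)])
        assert biolog_score(plate)["B"].iloc[0] == 0.0

    def test_arithmetic(self):
        plate = make_plate([("s", "c", 1, "10m", 0.1), ("s", "c", 1, "24h", 0.5)])
        assert biolog_score(plate)["B"].iloc[0] == pytest.approx(0.4)

    def test_vectorized_equals_loop(self):
        rng = np.random.default_rng(3)
        rows = []
        for s in ("a", "b"):
            for c in ("c1", "c2", "c3"):
                for w in (1, 2, 3, 4):
                    rows.append((s, c, w, "10m", rng.uniform(0.05, 0.15)))
                    rows.append((s, c, w, "24h", rng.uniform(0.1, 0.9)))
        plate = make_plate(rows)
        scores = biolog_score(plate).set_index(["sample_id", "compound", "well"])["B"]
        t10 = plate[plate.time_label == "10m"].set_index(["sample_id", "compound", "well"])["od600"]
        t24 = plate[plate.time_label == "24h"].set_index(["sample_id", "compound", "well"])["od600"]
        for key in scores.index:
            assert scores.loc[key] == pytest.approx(t24.loc[key] - t10.loc[key])

    def test_missing_time_label(self):
        plate = make_plate([("s", "c", 1, "10m", 0.1)])
        with pytest.raises(ValueError):
            biolog_score(plate)


class TestNoiseThreshold:
    def test_identical_readings(self):
        plate = make_plate(
            [(s, "c", 1, "10m", 0.1) for s in ("a", "b", "c")]
        )
        assert noise_threshold(plate) == 0.0

    def test_single_pair(self):
        plate = make_plate([("a", "c", 1, "10m", 0.10), ("b", "c", 1, "10m", 0.15)])
        assert noise_threshold(plate) == pytest.approx(0.05)

    def test_halfnormal_quantile_oracle(self):
        # pair differences of iid N(0, sigma) readings are half-normal(sqrt(2) sigma)
        sigma = 0.02
        rng = np.random.default_rng(7)
        rows = []
        for g in range(40):  # independent (compound, well) groups
            for i in range(20):
                rows.append((f"s{i}", f"c{g}", 1, "10m", 0.1 + rng.normal(0, sigma)))
        plate = make_plate(rows)
        from scipy import stats

        expected = stats.halfnorm.ppf(0.99, scale=math.sqrt(2) * sigma)
        assert noise_threshold(plate) == pytest.approx(expected, rel=0.12)


class TestWellSelection:
    def _scores(self, variances_by_well):
        rng = np.random.default_rng(0)
        rows = []
        for pair in range(6):
            for well, sd in enumerate(variances_by_well, start=1):
                delta = rng.normal(0, sd)
                rows.append({"sample_id": f"e{pair}", "compound": "c", "well": well, "B": 0.5 + delta})
                rows.append({"sample_id": f"a{pair}", "compound": "c", "well": well, "B": 0.5})
        return pd.DataFrame(rows)

    def test_monotone_variance_picks_last_well(self):
        scores = self._scores([0.001, 0.01, 0.1, 1.0])
        pairs = [(f"e{i}", f"a{i}") for i in range(6)]
        assert select_concentration_well(scores, pairs).loc["c"] == 4

    def test_explicit_variances(self):
        rows = []
        deltas = {1: [0.1, 0.11], 2: [0.0, 0.4], 3: [0.2, 0.25], 4: [0.3, 0.32]}
        for well, (d1, d2) in deltas.items():
            rows += [
                {"sample_id": "e1", "compound": "c", "well": well, "B": d1},
                {"sample_id": "a1", "compound": "c", "well": well, "B": 0.0},
                {"sample_id": "e2", "compound": "c", "well": well, "B": d2},
                {"sample_id": "a2", "compound": "c", "well": well, "B": 0.0},
            ]
        scores = pd.DataFrame(rows)
        assert select_concentration_well(scores, [("e1", "a1"), ("e2", "a2")]).loc["c"] == 2

    def test_sample_order_invariance(self):
        scores = self._scores([0.01, 0.3, 0.05, 0.02])
        pairs = [(f"e{i}", f"a{i}") for i in range(6)]
        a = select_concentration_well(scores, pairs)
        b = select_concentration_well(
            scores.sample(frac=1.0, random_state=5).reset_index(drop=True), pairs[::-1]
        )
        pd.testing.assert_series_equal(a, b)


class TestCallTolerance:
    def test_boundary_none(self):
        # exactly-representable values so the boundary is hit exactly
        assert call_tolerance(0.5, 0.375, 0.125) == "none"
        assert call_tolerance(0.375, 0.5, 0.125) == "none"

    def test_gained(self):
        assert call_tolerance(0.5, 0.3, 0.097) == "gained"

    def test_lost(self):
        assert call_tolerance(0.1, 0.3, 0.097) == "lost"

    def test_mutually_exclusive(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            b_e, b_a = rng.uniform(-0.5, 0.5, 2)
            calls = {call_tolerance(b_e, b_a, 0.097), call_tolerance(b_a, b_e, 0.097)}
            assert calls != {"gained"} and calls != {"lost"}

    def test_thresh_guard(self):
        with pytest.raises(ValueError):
            call_tolerance(0.5, 0.3, 0.0)


class TestStressFoldChange:
    def test_all_equal(self):
        assert stress_fold_change(0.3, 0.3, 0.3, 0.3) == pytest.approx(1.0)

    def test_doubling(self):
        assert stress_fold_change(0.4, 0.2, 0.3, 0.3) == pytest.approx(2.0)

    def test_control_cancellation(self):
        g = stress_fold_change(0.4, 0.2, 0.6, 0.3)
        for c in (0.5, 2.0, 7.3):
            assert stress_fold_change(0.4 * c, 0.2, 0.6 * c, 0.3) == pytest.approx(g)

    def test_nonpositive_raises_with_identifier(self):
        with pytest.raises(ValueError, match="A_ctrl_ancestor"):
            stress_fold_change(0.4, 0.2, 0.3, 0.0)


class TestSimulatedPlateCalls:
    def test_zero_noise_planted_calls_perfect(self):
        effects = []
        truth = {}
        rng = np.random.default_rng(9)
        for i, compound in enumerate(f"c{j}" for j in range(20)):
            direction = ["gained", "lost", "none"][i % 3]
            delta = {"gained": 0.3, "lost": -0.3, "none": 0.0}[direction]
            truth[compound] = direction
            for well in (1, 2, 3, 4):
                effects.append({"sample_id": "evo", "compound": compound, "well": well, "effect": 0.4 + delta})
                effects.append({"sample_id": "anc", "compound": compound, "well": well, "effect": 0.4})
        plate = simulate_plate(pd.DataFrame(effects), noise_sd=0.0, seed=0)
        scores = biolog_score(plate).set_index(["sample_id", "compound", "well"])["B"]
        for compound, expected in truth.items():
            call = call_tolerance(
                scores.loc[("evo", compound, 1)], scores.loc[("anc", compound, 1)], 0.097
            )
            assert call == expected
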