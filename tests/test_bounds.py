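"""Bound-suite tests on synthetic catalogues with known envelopes."""

import numpy as np
import pandas as pd
import pytest

from simbias.bounds import (
    BoundFit,
    UnderdeterminedFitError,
    cumulative_curve,
    deviation,
    evaluate_bounds,
    fit_upper_bound,
    fit_summary_json,
    lower_bound,
    normalized_predictor,
)
from simbias.catalog import EnumeratedMap


def _synthetic_map(k_out, probability, delta_max=None, input_bits=20.0):
    probability = np.asarray(probability, dtype=float)
    k_out = np.asarray(k_out, dtype=float)
    if delta_max is None:
        delta_max = np.zeros_like(k_out)
    n_inputs = 2 ** 20
    counts = np.maximum((probability * n_inputs).round().astype(int), 1)
    table = pd.DataFrame({
        "output": [f"x{i}" for i in range(len(k_out))],
        "neutral_set_size": counts,
        "probability": probability,
        "k_out": k_out,
        "k_max_input": input_bits - np.asarray(delta_max, dtype=float),
        "delta_max": np.asarray(delta_max, dtype=float),
    })
    return EnumeratedMap("synthetic", n_inputs, input_bits, table, complete=False)


class TestUpperBoundFit:
    def test_collinear_envelope_recovers_slope_one(self):
        k = np.arange(1.0, 11.0)
        emap = _synthetic_map(k, np.exp2(-k))
        fit = fit_upper_bound(emap)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_planted_bin_maxima_recovered(self):
        """Bin maxima planted on a known line are refit exactly; clutter below is ignored."""
        a0, b0 = 0.7, 2.0
        rng = np.random.default_rng(0)
        ks, ps = [], []
        for kb in range(1, 12):
            k = kb + 0.25
            ks.append(k)
            ps.append(2.0 ** (-a0 * k - b0))            # the planted envelope point
            for _ in range(5):                          # strictly-below clutter
                ks.append(k + rng.uniform(0, 0.4))
                ps.append(2.0 ** (-a0 * k - b0 - rng.uniform(1, 6)))
        fit = fit_upper_bound(_synthetic_map(ks, ps))
        assert fit.slope == pytest.approx(a0, rel=1e-3)
        assert fit.intercept == pytest.approx(b0, rel=1e-2)

    def test_envelope_postcondition_no_output_above_line(self):
        rng = np.random.default_rng(1)
        k = rng.uniform(0, 20, 200)
        p = np.exp2(-0.5 * k - rng.uniform(0, 8, 200))
        p /= p.sum()
        emap = _synthetic_map(k, p)
        fit = fit_upper_bound(emap)
        viol = np.log2(p) + fit.slope * k + fit.intercept
        assert viol.max() <= 1e-9

    def test_underdetermined_fit_rejected(self):
        emap = _synthetic_map([1.0, 2.0], [0.5, 0.5])
        with pytest.raises(UnderdeterminedFitError):
            fit_upper_bound(emap)

    def test_quantile_method_also_covers_envelope(self):
        rng = np.random.default_rng(2)
        k = rng.uniform(0, 15, 300)
        p = np.exp2(-0.8 * k - rng.exponential(2, 300))
        emap = _synthetic_map(k, p / p.sum())
        fit = fit_upper_bound(emap, method="quantile")
        assert fit.slope > 0
        assert (np.log2(p / p.sum()) + fit.slope * k + fit.intercept).max() <= 1e-9


class TestDeviation:
    def test_identity(self):
        assert deviation(0.25, 0.25) == 0.0

    def test_powers_of_two(self):
        assert deviation(0.5, 0.125) == pytest.approx(2.0)

    def test_zero_probability_flagged_infinite(self):
        assert np.isinf(deviation(0.5, np.array([0.0]))[0])


class TestLowerBound:
    def test_zero_deficit_coincides_with_p0(self):
        fit = BoundFit(1.0, 0.0, "test", 5)
        assert lower_bound(3.0, 0.0, fit) == pytest.approx(fit.p0(3.0))

    def test_monotone_decreasing_in_delta_max(self):
        fit = BoundFit(0.5, 1.0, "test", 5)
        vals = lower_bound(4.0, np.array([0.0, 1.0, 5.0]), fit)
        assert (np.diff(vals) < 0).all()

    def test_negative_delta_max_rejected(self):
        with pytest.raises(ValueError):
            lower_bound(1.0, -1.0, BoundFit(1.0, 0.0, "t", 3))


class TestEvaluation:
    def test_deviation_nonnegative_with_touching_envelope(self):
        rng = np.random.default_rng(3)
        k = rng.uniform(0, 12, 100)
        p = np.exp2(-k - rng.exponential(1.5, 100))
        ev = evaluate_bounds(_synthetic_map(k, p / p.sum()))
        assert (ev.table["deviation_bits"] >= -1e-9).all()

    def test_constants_reported(self):
        rng = np.random.default_rng(4)
        k = rng.uniform(0, 12, 100)
        p = np.exp2(-k - rng.exponential(1.5, 100))
        ev = evaluate_bounds(_synthetic_map(k, p / p.sum(), delta_max=rng.uniform(0, 5, 100)))
        summary = fit_summary_json(ev)
        for key in ("slope_a", "intercept_b", "c0_lower_bound_intercept", "c1_deviation_p95"):
            assert key in summary

    def test_lower_bound_quantile_construction(self):
        """The fitted c0 leaves at most ~5% of outputs below the lower bound."""
        rng = np.random.default_rng(5)
        k = rng.uniform(0, 12, 400)
        p = np.exp2(-k - rng.exponential(1.5, 400))
        ev = evaluate_bounds(_synthetic_map(k, p / p.sum(), delta_max=rng.uniform(0, 5, 400)))
        frac_below = (ev.table["probability"] < ev.table["lower_bound"] * (1 - 1e-12)).mean()
        assert frac_below <= 0.06


class TestCumulative:
    def _ev(self):
        rng = np.random.default_rng(6)
        k = rng.uniform(0, 12, 150)
        p = np.exp2(-k - rng.exponential(2, 150))
        emap = _synthetic_map(k, p / p.sum())
        return emap, evaluate_bounds(emap)

    def test_full_mass_at_smallest_deviation(self):
        emap, ev = self._ev()
        curve = cumulative_curve(emap, ev)
        assert curve.cumulative_prob[0] == pytest.approx(1.0)

    def test_non_increasing(self):
        emap, ev = self._ev()
        curve = cumulative_curve(emap, ev)
        assert (np.diff(curve.cumulative_prob) <= 1e-12).all()
        assert ((curve.cumulative_prob >= 0) & (curve.cumulative_prob <= 1)).all()

    def test_reference_curve(self):
        emap, ev = self._ev()
        curve = cumulative_curve(emap, ev, grid=[0.0, 1.0, 2.0])
        assert curve.bound_curve == pytest.approx([2.0, 1.0, 0.5])


class TestNormalizedPredictor:
    def test_sums_to_one(self):
        rng = np.random.default_rng(7)
        k = rng.uniform(0, 12, 80)
        p = np.exp2(-k - rng.exponential(1, 80))
        q = normalized_predictor(_synthetic_map(k, p / p.sum()))
        assert q.sum() == pytest.approx(1.0)

    def test_uniform_inputs_give_uniform_predictor(self):
        emap = _synthetic_map([3.0, 3.0 + 1e-12, 3.0 - 1e-12, 3.0],
                              [0.25, 0.25, 0.25, 0.25],
                              delta_max=[2.0, 2.0, 2.0, 2.0])
        fit = BoundFit(1.0, 0.0, "manual", 4)
        q = normalized_predictor(emap, fit)
        assert q == pytest.approx([0.25] * 4)
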