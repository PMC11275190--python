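"""Binary temporal coding, weight initialisation, charge, current stats."""
import numpy as np
import pytest

from protospike import (
    Trace,
    binarize_current,
    cumulative_charge,
    current_distribution_stats,
    init_weights,
    subsample_active,
)
from protospike.errors import UnitMismatchError
from protospike.neuro import BinaryTemporalCode


def current(values, dt=1.0):
    return Trace(np.asarray(values, dtype=float), dt=dt, unit="uA")


class TestBinarizeCurrent:
    def test_threshold_rule(self):
        code = binarize_current(current([5e-5, 2e-4, 9e-5, 3e-4]),
                                threshold=1e-4)
        np.testing.assert_array_equal(code.bits, [0, 1, 0, 1])

    def test_all_zero_trace(self):
        code = binarize_current(current(np.zeros(10)))
        assert code.n_active == 0

    def test_boundary_is_strict(self):
        code = binarize_current(current([1e-4, 1e-4 + 1e-12]),
                                threshold=1e-4)
        np.testing.assert_array_equal(code.bits, [0, 1])

    def test_unit_mismatch_rejected(self):
        with pytest.raises(UnitMismatchError):
            binarize_current(Trace(np.ones(5), unit="mV"))

    def test_idempotent_under_rethresholding(self):
        code = binarize_current(current([5e-5, 2e-4, 9e-5, 3e-4]))
        again = binarize_current(current(code.bits.astype(float)),
                                 threshold=0.5)
        np.testing.assert_array_equal(again.bits, code.bits)

    def test_one_bit_per_sample(self):
        trace = current(np.linspace(0, 1e-3, 137))
        assert binarize_current(trace).bits.size == 137


class TestSubsampleActive:
    def make_code(self, n_active, n_total=500):
        bits = np.zeros(n_total, dtype=np.uint8)
        bits[:n_active] = 1
        return BinaryTemporalCode(bits=bits, threshold=1e-4)

    def test_size_inverse_in_neuron_count(self):
        subset = subsample_active(self.make_code(100), n_neurons=30, seed=0)
        assert subset.size == 3  # floor(100/30)

    def test_single_neuron_takes_all(self):
        subset = subsample_active(self.make_code(50), n_neurons=1, seed=0)
        assert subset.size == 50

    def test_deterministic_under_seed(self):
        a = subsample_active(self.make_code(200), n_neurons=30, seed=5)
        b = subsample_active(self.make_code(200), n_neurons=30, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_no_activity_gives_empty_set(self):
        assert subsample_active(self.make_code(0), n_neurons=30).size == 0

    def test_minimum_one_when_active(self):
        assert subsample_active(self.make_code(5), n_neurons=30,
                                seed=1).size == 1

    def test_invalid_neuron_count(self):
        with pytest.raises(ValueError):
            subsample_active(self.make_code(10), n_neurons=0)


class TestInitWeights:
    def test_entries_in_half_open_interval(self):
        W = init_weights(30, seed=0).W
        assert W.shape == (30, 30)
        assert W.min() >= -1.0 and W.max() < 1.0

    def test_mean_near_zero(self):
        W = init_weights(1000, seed=1).W  # 1e6 entries
        assert abs(W.mean()) < 0.01

    def test_variance_approaches_one_third(self):
        W = init_weights(1000, seed=2).W
        assert W.var() == pytest.approx(1.0 / 3.0, rel=0.01)

    def test_deterministic(self):
        np.testing.assert_array_equal(init_weights(30, seed=3).W,
                                      init_weights(30, seed=3).W)

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            init_weights(0, seed=0)


class TestCumulativeCharge:
    def test_constant_current_rectangle(self):
        q = cumulative_charge(current(np.ones(11), dt=1.0))
        assert q[0] == 0.0
        assert q[-1] == pytest.approx(10.0)

    def test_zero_current_zero_charge(self):
        q = cumulative_charge(current(np.zeros(50)))
        assert np.all(q == 0.0)

    def test_finite_difference_recovers_current(self):
        rng = np.random.default_rng(4)
        values = np.abs(rng.normal(1.0, 0.2, 200))
        trace = current(values, dt=0.5)
        q = cumulative_charge(trace)
        # centred difference of the trapezoid integral gives the midpoint
        # average of the current
        recovered = np.diff(q) / trace.dt
        expected = 0.5 * (values[1:] + values[:-1])
        np.testing.assert_allclose(recovered, expected, rtol=1e-10)

    def test_unit_checked(self):
        with pytest.raises(UnitMismatchError):
            cumulative_charge(Trace(np.ones(5), unit="mV"))


class TestCurrentDistributionStats:
    def test_small_set_quartiles(self):
        s = current_distribution_stats(current([1, 2, 3, 4, 5]))
        assert s["median"] == 3.0
        assert s["q1"] == 2.0
        assert s["q3"] == 4.0

    def test_constant_trace_no_outliers(self):
        s = current_distribution_stats(current(np.full(20, 7.0)))
        assert s["iqr"] == 0.0
        assert s["outliers"].size == 0
        assert s["whisker_low"] == s["whisker_high"] == 7.0

    def test_against_sort_based_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            v = rng.normal(10.0, 3.0, rng.integers(20, 200))
            v[rng.integers(0, v.size)] += 50.0  # force an outlier
            s = current_distribution_stats(current(v))
            srt = np.sort(v)
            q1, med, q3 = (np.percentile(srt, p) for p in (25, 50, 75))
            assert s["q1"] == pytest.approx(q1)
            assert s["median"] == pytest.approx(med)
            assert s["q3"] == pytest.approx(q3)
            lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
            inside = srt[(srt >= lo) & (srt <= hi)]
            assert s["whisker_low"] == inside[0]
            assert s["whisker_high"] == inside[-1]
            assert s["outliers"].size == np.sum((srt < lo) | (srt > hi))
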