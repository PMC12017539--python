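"""Spike/voltage statistics and perturbation-matrix bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_record
from cortcol.analysis import (
    categorize,
    compare_categorical,
    count_marked,
    frobenius_distance,
    isi_cv,
    mean_rates,
    numeric_difference,
    pairwise_frobenius,
    power_spectrum,
    rate_trace,
    response_matrix,
    synchrony_chi,
)


class TestMeanRates:
    def test_silent_record_is_zero(self):
        rec = make_record({"E23": [np.array([])] * 10})
        assert (mean_rates(rec, (0.0, 1000.0)) == 0.0).all()

    def test_rate_arithmetic(self):
        # 100 neurons, 600 spikes over 3 s -> 2.0 spikes/s
        trains = [np.linspace(10.0, 2990.0, 6) for _ in range(100)]
        rec = make_record({"E23": trains}, duration=3000.0)
        assert mean_rates(rec, (0.0, 3000.0))["E23"] == pytest.approx(2.0)

    def test_empty_window_rejected(self):
        rec = make_record({"E23": [np.array([1.0])]})
        with pytest.raises(ValueError):
            mean_rates(rec, (100.0, 100.0))


class TestRateTrace:
    def test_flat_for_constant_activity(self):
        rng = np.random.default_rng(0)
        trains = [np.sort(rng.uniform(0, 5000.0, 100)) for _ in range(50)]
        rec = make_record({"E4": trains}, duration=5000.0)
        tr = rate_trace(rec, "E4", window_ms=500.0)
        inner = tr[(tr.index > 500) & (tr.index < 4500)]
        assert inner.std() / inner.mean() < 0.2

    def test_rise_begins_half_window_before_onset(self):
        # spikes only after t* = 500 ms; the centred window makes the trace
        # lift off at t* - window/2
        trains = [np.arange(500.0, 900.0, 2.0)]
        rec = make_record({"E4": trains}, duration=1000.0)
        tr = rate_trace(rec, "E4", window_ms=100.0, step_ms=1.0)
        assert tr[tr.index < 448].max() == 0.0
        assert tr[(tr.index > 452) & (tr.index < 500)].min() > 0.0

    def test_single_spike_has_unit_area(self):
        rec = make_record({"E4": [np.array([500.0])] + [np.array([])] * 9},
                          duration=1000.0)
        tr = rate_trace(rec, "E4", window_ms=100.0, step_ms=1.0)
        area = tr.sum() * 1.0 / 1000.0      # integral over time, in spikes
        assert area == pytest.approx(1.0 / 10, rel=1e-6)


class TestIsiCv:
    def test_periodic_train_is_zero(self):
        rec = make_record({"E4": [np.arange(0.0, 1000.0, 10.0)]})
        cvs, mean_cv = isi_cv(rec, "E4")
        assert mean_cv == pytest.approx(0.0, abs=1e-12)

    def test_poisson_train_is_one(self):
        rng = np.random.default_rng(3)
        t = np.cumsum(rng.exponential(10.0, size=10_000))
        rec = make_record({"E4": [t]}, duration=float(t[-1] + 1))
        _, mean_cv = isi_cv(rec, "E4")
        assert mean_cv == pytest.approx(1.0, rel=0.02)

    def test_sparse_neurons_excluded(self):
        rec = make_record(
            {"E4": [np.array([1.0, 2.0]), np.arange(0.0, 100.0, 10.0)]}
        )
        cvs, _ = isi_cv(rec, "E4")
        assert len(cvs) == 1


class TestSynchrony:
    def test_identical_traces(self):
        v = np.sin(np.linspace(0, 10, 500))[:, None] * np.ones((1, 20))
        assert synchrony_chi(v) == pytest.approx(1.0)

    def test_independent_traces_decay_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(4000, 100))
        chi = synchrony_chi(v)
        assert 0.0 < chi < 0.2        # ~ N^-1/2 = 0.1

    def test_partial_correlation_recovers_shared_fraction(self):
        rng = np.random.default_rng(1)
        rho = 0.5
        shared = rng.normal(size=(8000, 1))
        private = rng.normal(size=(8000, 200))
        v = np.sqrt(rho) * shared + np.sqrt(1 - rho) * private
        assert synchrony_chi(v) == pytest.approx(np.sqrt(rho), abs=0.05)

    def test_degenerate_traces_flagged(self):
        assert np.isnan(synchrony_chi(np.ones((100, 5))))
        with pytest.raises(ValueError):
            synchrony_chi(np.ones((100,)))


class TestPowerSpectrum:
    def test_constant_trace_has_no_power(self):
        f, p = power_spectrum(np.full(4000, 7.0))
        assert np.allclose(p[f > 0], 0.0, atol=1e-12)

    def test_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(4000) / 1000.0
        f, p = power_spectrum(5.0 + np.sin(2 * np.pi * 10.0 * t))
        assert f[np.argmax(p)] == pytest.approx(10.0, abs=1.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(np.zeros(100), segment_ms=1000.0)


LABELS = ("A", "B", "C")


def series(vals):
    return pd.Series(dict(zip(LABELS, vals)), dtype=float)


class TestResponseMatrix:
    def test_identity_gives_zero(self):
        base = series([1.0, 2.0, 3.0])
        m = response_matrix(base, {g: base for g in LABELS}, labels=LABELS)
        assert np.allclose(m.values.to_numpy(), 0.0)
        assert not m.undefined.to_numpy().any()

    def test_percent_change_arithmetic(self):
        base = series([1.0, 2.0, 1.0])
        pert = {g: series([1.22, 1.5, 1.0]) for g in LABELS}
        m = response_matrix(base, pert, labels=LABELS)
        assert m.values.loc["A", "A"] == pytest.approx(22.0)
        assert m.values.loc["A", "B"] == pytest.approx(-25.0)
        assert m.values.loc["A", "C"] == pytest.approx(0.0)

    def test_zero_baseline_flagged_not_silent(self):
        base = series([0.0, 2.0, 3.0])
        pert = {g: series([1.0, 2.0, 3.0]) for g in LABELS}
        m = response_matrix(base, pert, labels=LABELS)
        assert np.isnan(m.values.loc["A", "A"])
        assert bool(m.undefined.loc["A", "A"])
        assert categorize(m).loc["A", "A"] == 0


class TestCategorize:
    @pytest.mark.parametrize(
        "value, expected",
        [(25.0, 1), (10.0, 0), (-30.0, -1), (20.0, 0), (-20.0, 0),
         (np.nan, 0)],
    )
    def test_threshold_rule(self, value, expected):
        df = pd.DataFrame([[value]])
        assert categorize(df, threshold=20.0).iloc[0, 0] == expected

    def test_scale_free(self):
        # percent changes are invariant under uniform rate rescaling
        base = series([1.0, 2.0, 4.0])
        pert = {g: series([1.5, 2.2, 4.0]) for g in LABELS}
        m1 = response_matrix(base, pert, labels=LABELS)
        m2 = response_matrix(
            10 * base, {g: 10 * v for g, v in pert.items()}, labels=LABELS
        )
        assert categorize(m1).equals(categorize(m2))


class TestCompareCategorical:
    def test_full_rule_table(self):
        reds = {(0, 1), (-1, 0), (-1, 1)}
        greens = {(1, -1), (1, 0), (0, -1)}
        for a in (-1, 0, 1):
            for b in (-1, 0, 1):
                out = compare_categorical(
                    pd.DataFrame([[a]]), pd.DataFrame([[b]])
                ).iloc[0, 0]
                if a == b:
                    assert out == "white"
                elif (a, b) in reds:
                    assert out == "red"
                else:
                    assert (a, b) in greens and out == "green"

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_categorical(pd.DataFrame([[0]]),
                                pd.DataFrame([[0, 1]]))


class TestNumericDifference:
    def test_equal_matrices(self):
        a = pd.DataFrame([[5.0, -3.0]])
        diff, flips = numeric_difference(a, a.copy())
        assert np.allclose(diff, 0.0)
        assert not flips.to_numpy().any()

    def test_worked_example(self):
        a = pd.DataFrame([[50.0]])
        b = pd.DataFrame([[30.0]])
        diff, flips = numeric_difference(a, b)
        assert diff.iloc[0, 0] == pytest.approx(-20.0)
        assert not flips.iloc[0, 0]

    def test_sign_flip_flagged(self):
        diff, flips = numeric_difference(
            pd.DataFrame([[5.0]]), pd.DataFrame([[-5.0]])
        )
        assert diff.iloc[0, 0] == pytest.approx(-10.0)
        assert bool(flips.iloc[0, 0])


class TestCountMarked:
    def test_small_example(self):
        m = np.zeros((16, 16), dtype=int)
        m[0, 1] = m[0, 2] = m[3, 4] = 1
        m[5, 6] = m[7, 8] = -1
        n, pos = count_marked(pd.DataFrame(m))
        assert (n, pos) == (5, 0.6)

    def test_full_matrix_excludes_diagonal(self):
        m = pd.DataFrame(np.ones((16, 16), dtype=int))
        n, pos = count_marked(m)
        assert n == 16 * 16 - 16 == 240
        assert pos == 1.0

    def test_empty(self):
        n, pos = count_marked(pd.DataFrame(np.zeros((4, 4), dtype=int)))
        assert n == 0 and np.isnan(pos)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(-1, 2, size=(16, 16))
        got, _ = count_marked(pd.DataFrame(m))
        brute = sum(
            m[i, j] != 0 for i in range(16) for j in range(16) if i != j
        )
        assert got == brute


class TestFrobenius:
    def test_identity_and_single_entry(self):
        a = np.zeros((4, 4))
        assert frobenius_distance(a, a) == 0.0
        b = a.copy()
        b[1, 2] = 7.5
        assert frobenius_distance(a, b) == pytest.approx(7.5)

    def test_masked_entries_ignored(self):
        a = np.array([[1.0, np.nan], [2.0, 3.0]])
        b = np.array([[2.0, np.nan], [2.0, 3.0]])
        assert frobenius_distance(a, b) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_norm_axioms(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.normal(size=(3, 8, 8))
        dab = frobenius_distance(a, b)
        assert dab >= 0.0
        assert dab == pytest.approx(frobenius_distance(b, a))
        assert frobenius_distance(a, c) <= dab + frobenius_distance(b, c) \
            + 1e-9
        assert frobenius_distance(a, a) == 0.0

    def test_pairwise_table(self):
        mats = {
            "x": pd.DataFrame(np.zeros((3, 3))),
            "y": pd.DataFrame(np.eye(3)),
        }
        table = pairwise_frobenius(mats)
        assert table.loc["x", "y"] == pytest.approx(np.sqrt(3.0))
        assert table.loc["y", "x"] == table.loc["x", "y"]
        assert table.loc["x", "x"] == 0.0
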