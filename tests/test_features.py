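import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from emgpr.features import (
    DataSplit,
    FeatureMatrix,
    FeatureSpec,
    extract_features,
    feature_column_names,
    largest_remainder_sizes,
    mav,
    slope_sign_changes,
    split_sets,
    waveform_length,
    zero_crossings,
)
from emgpr.preprocess import SegmentationSpec, WindowSet, movement_signals, segment_windows
from emgpr.sessions import select_channels

finite_windows = arrays(
    np.float64, st.integers(3, 50),
    elements=st.floats(-10, 10, allow_nan=False, allow_infinity=False),
)


# --- independent brute-force oracles ---------------------------------------

def mav_oracle(x):
    return sum(abs(v) for v in x) / len(x)


def wl_oracle(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


def zc_oracle(x, eps):
    signs = []
    prev = 0.0
    for v in x:
        if v > 0:
            prev = 1.0
        elif v < 0:
            prev = -1.0
        signs.append(prev)
    count = 0
    for i in range(len(x) - 1):
        if signs[i] * signs[i + 1] < 0 and abs(x[i] - x[i + 1]) > eps:
            count += 1
    return count


def ssc_oracle(x, eps):
    count = 0
    for i in range(1, len(x) - 1):
        d1 = x[i] - x[i - 1]
        d2 = x[i] - x[i + 1]
        if d1 * d2 > 0 and (abs(d1) > eps or abs(d2) > eps):
            count += 1
    return count


class TestMav:
    def test_alternating_unit(self):
        assert mav(np.array([1.0, -1.0, 1.0, -1.0])) == 1.0

    def test_zero_window(self):
        assert mav(np.zeros(10)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mav(np.array([]))

    def test_gaussian_matches_oracle(self, rng):
        x = rng.normal(size=400)
        assert mav(x) == pytest.approx(mav_oracle(x), abs=1e-12)


class TestWaveformLength:
    def test_square_steps(self):
        assert waveform_length(np.array([0.0, 1.0, 0.0, 1.0])) == 3.0

    def test_constant_window(self):
        assert waveform_length(np.full(10, 2.5)) == 0.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            waveform_length(np.array([1.0]))

    def test_random_matches_oracle(self, rng):
        x = rng.normal(size=400)
        assert waveform_length(x) == pytest.approx(wl_oracle(x), abs=1e-12)


class TestZeroCrossings:
    def test_alternating(self):
        assert zero_crossings(np.array([1.0, -1.0, 1.0, -1.0]), 0.0) == 3

    def test_monotone_ramp(self):
        assert zero_crossings(np.linspace(0.1, 1.0, 20), 0.0) == 0

    def test_zeros_inherit_previous_sign(self):
        # 1, 0, -1: the zero carries +, so one crossing (0 -> -1)
        assert zero_crossings(np.array([1.0, 0.0, -1.0]), 0.0) == 1

    def test_infinite_eps_kills_count(self, rng):
        x = rng.normal(size=100)
        assert zero_crossings(x, np.inf) == 0

    @given(finite_windows, st.floats(0, 5))
    @settings(max_examples=150, deadline=None)
    def test_matches_oracle(self, x, eps):
        assert zero_crossings(x, eps) == zc_oracle(x, eps)

    @given(finite_windows)
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_eps(self, x):
        counts = [zero_crossings(x, e) for e in (0.0, 0.5, 2.0, np.inf)]
        assert counts == sorted(counts, reverse=True)


class TestSlopeSignChanges:
    def test_zigzag(self):
        assert slope_sign_changes(np.array([0.0, 1.0, 0.0, 1.0, 0.0]), 0.0) == 3

    def test_monotone_ramp(self):
        assert slope_sign_changes(np.arange(10.0), 0.0) == 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            slope_sign_changes(np.array([1.0, 2.0]), 0.0)

    @given(finite_windows, st.floats(0, 5))
    @settings(max_examples=150, deadline=None)
    def test_matches_oracle(self, x, eps):
        assert slope_sign_changes(x, eps) == ssc_oracle(x, eps)

    @given(finite_windows)
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_eps(self, x):
        counts = [slope_sign_changes(x, e) for e in (0.0, 0.5, 2.0, np.inf)]
        assert counts == sorted(counts, reverse=True)


class TestScaleEquivariance:
    def test_mav_wl_linear_zc_ssc_invariant(self, rng):
        x = rng.normal(size=200)
        for scale in (0.5, 3.0, 100.0):
            assert mav(scale * x) == pytest.approx(scale * mav(x), rel=1e-12)
            assert waveform_length(scale * x) == pytest.approx(
                scale * waveform_length(x), rel=1e-12
            )
            assert zero_crossings(scale * x, 0.0) == zero_crossings(x, 0.0)
            assert slope_sign_changes(scale * x, 0.0) == slope_sign_changes(x, 0.0)


class TestExtractFeatures:
    def test_column_counts(self):
        assert len(feature_column_names(16, FeatureSpec())) == 64
        assert len(feature_column_names(8, FeatureSpec())) == 32

    def test_empty_window_set(self):
        ws = WindowSet(windows=[], signals={"a": np.zeros((10, 3))},
                       window_samples=5, increment_samples=5)
        fm = extract_features(ws, FeatureSpec())
        assert fm.values.shape == (0, 12)

    def test_column_ordering_channel_major(self, rng):
        sig = rng.normal(size=(20, 2))
        ws = WindowSet(windows=[("a", 0, 20)], signals={"a": sig},
                       window_samples=20, increment_samples=20)
        fm = extract_features(ws, FeatureSpec())
        assert fm.column_names[:4] == ["ch0_mav", "ch0_wl", "ch0_ssc", "ch0_zc"]
        assert fm.values[0, 0] == pytest.approx(mav(sig[:, 0]))
        assert fm.values[0, 4] == pytest.approx(mav(sig[:, 1]))

    def test_nonfinite_rejected(self):
        sig = np.full((20, 1), np.nan)
        ws = WindowSet(windows=[("a", 0, 20)], signals={"a": sig},
                       window_samples=20, increment_samples=20)
        with pytest.raises(ValueError, match="non-finite"):
            extract_features(ws, FeatureSpec())

    def test_commutes_with_select_channels(self, small_session):
        """Features on a channel subset == subset of columns computed on all."""
        spec = SegmentationSpec()
        subset = [0, 2]
        full_ws = segment_windows(
            movement_signals(small_session, spec), spec,
            small_session.protocol.sampling_rate,
        )
        fm_full = extract_features(full_ws, FeatureSpec())
        sub_session = select_channels(small_session, subset)
        sub_ws = segment_windows(
            movement_signals(sub_session, spec), spec,
            sub_session.protocol.sampling_rate,
        )
        fm_sub = extract_features(sub_ws, FeatureSpec())
        n_feat = len(FeatureSpec().features)
        cols = [c * n_feat + f for c in subset for f in range(n_feat)]
        np.testing.assert_allclose(fm_sub.values, fm_full.values[:, cols])

    def test_csv_round_trip(self, tmp_path, rng):
        fm = FeatureMatrix(
            values=rng.normal(size=(6, 4)),
            labels=np.array(["a", "a", "a", "b", "b", "b"], dtype=object),
            column_names=["ch0_mav", "ch0_wl", "ch0_ssc", "ch0_zc"],
        )
        fm.to_csv(tmp_path / "f.csv")
        back = FeatureMatrix.from_csv(tmp_path / "f.csv")
        np.testing.assert_allclose(back.values, fm.values)
        assert list(back.labels) == list(fm.labels)


class TestSplitSets:
    def _matrix(self, counts: dict[str, int]) -> FeatureMatrix:
        labels = np.array([c for c, n in counts.items() for _ in range(n)], dtype=object)
        return FeatureMatrix(
            values=np.zeros((len(labels), 1)), labels=labels, column_names=["x"]
        )

    def test_163_windows_largest_remainder(self):
        fm = self._matrix({"rest": 163})
        split = split_sets(fm, (0.40, 0.20, 0.40), rng_seed=0)
        assert (len(split.training), len(split.validation), len(split.test)) == (65, 33, 65)

    def test_all_training(self):
        fm = self._matrix({"a": 10})
        split = split_sets(fm, (1.0, 0.0, 0.0), rng_seed=0)
        assert len(split.training) == 10
        assert len(split.validation) == len(split.test) == 0

    def test_two_seeds_differ_equal_sizes(self):
        fm = self._matrix({"a": 50, "b": 50})
        s1 = split_sets(fm, rng_seed=1)
        s2 = split_sets(fm, rng_seed=2)
        assert len(s1.training) == len(s2.training)
        assert set(s1.training) != set(s2.training)

    def test_deterministic_per_seed(self):
        fm = self._matrix({"a": 50, "b": 50})
        s1 = split_sets(fm, rng_seed=9)
        s2 = split_sets(fm, rng_seed=9)
        np.testing.assert_array_equal(s1.training, s2.training)
        np.testing.assert_array_equal(s1.test, s2.test)

    def test_partition_covers_all_rows(self):
        fm = self._matrix({"a": 37, "b": 41, "c": 53})
        split = split_sets(fm, rng_seed=3)
        union = np.sort(np.concatenate([split.training, split.validation, split.test]))
        np.testing.assert_array_equal(union, np.arange(fm.n_rows))

    def test_stratified_within_one_window(self):
        fm = self._matrix({"a": 163, "b": 163})
        split = split_sets(fm, rng_seed=4)
        for cls in ("a", "b"):
            rows = np.flatnonzero(fm.labels == cls)
            n_tr = len(set(rows) & set(split.training))
            assert abs(n_tr - 0.4 * 163) <= 1

    def test_bad_proportions(self):
        fm = self._matrix({"a": 10})
        with pytest.raises(ValueError, match="sum to 1"):
            split_sets(fm, (0.5, 0.2, 0.2))

    def test_tiny_class_rejected(self):
        fm = self._matrix({"a": 2, "b": 10})
        with pytest.raises(ValueError, match="need >= 3"):
            split_sets(fm)

    @given(n=st.integers(1, 500))
    @settings(max_examples=100, deadline=None)
    def test_largest_remainder_sums(self, n):
        sizes = largest_remainder_sizes(n, (0.4, 0.2, 0.4))
        assert sum(sizes) == n
        assert all(abs(s - n * p) <= 1 for s, p in zip(sizes, (0.4, 0.2, 0.4)))
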