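import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from actiwin import (
    AlignmentError,
    DomainError,
    FeatureBankConfig,
    Window,
    extract_features,
    fuse,
    segment,
)
from actiwin import features as F
from actiwin.synthetic import ProtocolSchedule, default_schedule, generate

# subnormals excluded: scaling them can underflow to zero and change sign
# structure, which is a float-representation artifact, not a feature property
finite_floats = st.floats(
    min_value=-50, max_value=50, allow_nan=False, allow_subnormal=False
)


def _window(samples, placement="wrist", activity=1):
    return Window(placement, activity, np.asarray(samples, dtype=float), 0)


class TestScalarFeatures:
    @pytest.mark.parametrize(
        "fn,x,expected",
        [
            (F.mav, [3, -3, 3, -3], 3.0),
            (F.mav, [0, 0, 0, 0], 0.0),
            (F.mav, [1, 2, -3, -6], 3.0),
            (F.harmonic_mean, [1, 1, 1, 1], 1.0),
            (F.harmonic_mean, [1, 2, 4], 3 / 1.75),
            (F.harmonic_mean, [2, 0, 2], 0.0),
            (F.cumulative_length, [5, 5, 5], 0.0),
            (F.cumulative_length, [0, 1, 0, 1], 3.0),
            (F.cumulative_length, [0, 2, 5], 5.0),
            (F.zero_crossings, [1, 2, 3], 0),
            (F.zero_crossings, [1, -1, 1, -1], 3),
            (F.zero_crossings, [1, 0, -1], 0),
            (F.slope_sign_changes, [0, 1, 2, 3], 0),
            (F.slope_sign_changes, [0, 1, 0, 1, 0], 3),
            (F.slope_sign_changes, [0, 1, 1, 0], 0),
            (F.simple_squared_integral, [0, 0, 0], 0.0),
            (F.simple_squared_integral, [1, 2, 2, 4], 25.0),
        ],
    )
    def test_hand_computed_values(self, fn, x, expected):
        assert fn(x) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "window_id,x,expected",
        [
            (1, [0, 0, 0, 0], 0.0),
            (2, [0, 0, 0, 0], 0.0),
            (1, [1, 1, 1, 1], 0.875),  # weights 1,1,1,0.5
            (2, [1, 1, 1, 1], 0.75),  # weights 1,1,1,0
        ],
    )
    def test_weighted_mav(self, window_id, x, expected):
        assert F.wmav(x, window_id) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "eps,x,expected",
        [
            (1.0, [0, 2, 0, 2], 3),
            (5.0, [0, 2, 0, 2], 0),
            (1.0, [0, 1], 0),  # boundary: strict inequality
        ],
    )
    def test_willison_amplitude(self, eps, x, expected):
        assert F.willison_amplitude(x, eps) == expected

    @pytest.mark.parametrize(
        "x,expected",
        [
            ([1, 1, 1, 1], (0.0, 1.0, 0.0, 0.0)),  # guard: constant window
            ([1, -1, 1, -1], (1.0, 1.0, 0.0, 1.0)),
            ([0, 0, 0, 4], (3.0, 2.0, 6 / 3**1.5, None)),
        ],
    )
    def test_central_moments(self, x, expected):
        got = F.central_moments(x)
        for g, e in zip(got, expected):
            if e is not None:
                assert g == pytest.approx(e)

    def test_empty_and_short_series_raise(self):
        with pytest.raises(DomainError):
            F.mav([])
        with pytest.raises(DomainError):
            F.cumulative_length([1.0])
        with pytest.raises(DomainError):
            F.slope_sign_changes([1.0, 2.0])

    def test_axis_correlation_guards(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        w = _window(np.column_stack([x, x, np.full(100, 2.0)]))
        r_xy, r_xz, r_yz = F.axis_correlations(w)
        assert r_xy == pytest.approx(1.0)
        assert r_xz == 0.0 and r_yz == 0.0  # constant-axis guard
        w2 = _window(np.column_stack([x, -x, x]))
        assert F.axis_correlations(w2)[0] == pytest.approx(-1.0)


class TestOracleEquivalence:
    """Every feature must match an independent direct-from-formula implementation."""

    def test_thousand_random_series(self):
        rng = np.random.default_rng(2024)
        eps = 0.5
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            x = rng.standard_normal(n) * rng.uniform(0.1, 10)
            if rng.random() < 0.1:
                x = np.round(x)  # exercise exact zeros and ties
            xs = x.tolist()
            var, rms_, skew, kurt = F.central_moments(x)
            pairs = [
                (F.mav(x), oracles.mav(xs)),
                (F.wmav(x, 1), oracles.wmav(xs, 1)),
                (F.wmav(x, 2), oracles.wmav(xs, 2)),
                (F.harmonic_mean(x), oracles.harmonic_mean(xs)),
                (var, oracles.variance(xs)),
                (rms_, oracles.rms(xs)),
                (skew, oracles.skewness(xs)),
                (kurt, oracles.kurtosis(xs)),
                (F.cumulative_length(x), oracles.cumulative_length(xs)),
                (F.zero_crossings(x), oracles.zero_crossings(xs)),
                (F.willison_amplitude(x, eps), oracles.willison_amplitude(xs, eps)),
                (F.slope_sign_changes(x), oracles.slope_sign_changes(xs)),
                (F.simple_squared_integral(x), oracles.simple_squared_integral(xs)),
            ]
            for got, want in pairs:
                assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_vectorized_extraction_matches_scalar_path(self):
        """The (m, N) kernels used by extract_features agree with the scalar ops."""
        rng = np.random.default_rng(5)
        cfg = FeatureBankConfig()
        windows = [_window(rng.standard_normal((50, 3)) * 3) for _ in range(20)]
        fm = extract_features(windows, cfg)
        for i, w in enumerate(windows):
            for a, ax in enumerate(("x", "y", "z")):
                col = w.samples[:, a]
                var, rms_, skew, kurt = F.central_moments(col)
                expected = {
                    "mav": F.mav(col), "wmav1": F.wmav(col, 1), "wmav2": F.wmav(col, 2),
                    "hm": F.harmonic_mean(col), "variance": var, "rms": rms_,
                    "skewness": skew, "kurtosis": kurt,
                    "cl": F.cumulative_length(col), "zc": F.zero_crossings(col),
                    "wa": F.willison_amplitude(col, cfg.willison_threshold),
                    "ssc": F.slope_sign_changes(col),
                }
                for name, want in expected.items():
                    j = fm.names.index(f"wrist.{ax}.{name}")
                    assert fm.values[i, j] == pytest.approx(want, rel=1e-12, abs=1e-12)
            r = F.axis_correlations(w)
            for k, pair in enumerate(("xy", "xz", "yz")):
                j = fm.names.index(f"wrist.corr.{pair}")
                assert fm.values[i, j] == pytest.approx(r[k], rel=1e-10, abs=1e-12)


class TestFeatureProperties:
    @given(st.lists(finite_floats, min_size=4, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_mav_bounded_by_rms_and_ssi_identity(self, xs):
        x = np.asarray(xs)
        _, rms_, _, _ = F.central_moments(x)
        assert F.mav(x) <= rms_ + 1e-9
        assert F.simple_squared_integral(x) == pytest.approx(
            len(x) * rms_**2, rel=1e-9, abs=1e-9
        )

    @given(
        st.lists(finite_floats, min_size=4, max_size=40),
        st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_scaling_behavior(self, xs, c):
        x = np.asarray(xs)
        var0, rms0, skew0, kurt0 = F.central_moments(x)
        var1, rms1, skew1, kurt1 = F.central_moments(c * x)
        assert F.mav(c * x) == pytest.approx(c * F.mav(x), rel=1e-9, abs=1e-12)
        assert F.wmav(c * x, 1) == pytest.approx(c * F.wmav(x, 1), rel=1e-9, abs=1e-12)
        assert F.cumulative_length(c * x) == pytest.approx(
            c * F.cumulative_length(x), rel=1e-9, abs=1e-12
        )
        assert var1 == pytest.approx(c**2 * var0, rel=1e-9, abs=1e-12)
        assert rms1 == pytest.approx(c * rms0, rel=1e-9, abs=1e-12)
        assert skew1 == pytest.approx(skew0, rel=1e-7, abs=1e-9)
        assert kurt1 == pytest.approx(kurt0, rel=1e-7, abs=1e-9)
        assert F.zero_crossings(c * x) == F.zero_crossings(x)
        assert F.slope_sign_changes(c * x) == F.slope_sign_changes(x)
        eps = 0.5
        assert F.willison_amplitude(c * x, c * eps) == F.willison_amplitude(x, eps)

    def test_features_ignore_window_start_index(self):
        rng = np.random.default_rng(3)
        samples = rng.standard_normal((30, 3))
        a = extract_features([Window("wrist", 1, samples, 0)])
        b = extract_features([Window("wrist", 1, samples, 999)])
        np.testing.assert_array_equal(a.values, b.values)


class TestSegmentation:
    def test_single_activity_window_count(self):
        # 10 s at 100 Hz, 5 s window, 1 s slide -> floor((1000-500)/100)+1 = 6
        rec = generate(ProtocolSchedule((("walking", 10.0),)), seed=0)
        wins = segment(rec)
        assert all(len(w) == 6 for w in wins.values())
        assert all(len(w.samples) == 500 for w in wins["wrist"])

    def test_segment_shorter_than_window_yields_nothing(self):
        rec = generate(ProtocolSchedule((("walking", 3.0),)), seed=0)
        assert segment(rec) == {p: [] for p in rec.sensors}

    def test_windows_never_straddle_activity_boundaries(self):
        rec = generate(ProtocolSchedule((("walking", 10.0), ("running", 10.0))), seed=0)
        wins = segment(rec)["ankle"]
        assert len(wins) == 12
        labels = rec.labels
        for w in wins:
            assert len(set(labels[w.start : w.start + 500])) == 1
            assert labels[w.start] == w.activity

    def test_transient_segments_excluded_by_default(self):
        rec = generate(default_schedule(8.0, transient_seconds=6.0), seed=1)
        wins = segment(rec)["wrist"]
        assert all(w.activity != 0 for w in wins)
        with_trans = segment(rec, include_transient=True)["wrist"]
        assert any(w.activity == 0 for w in with_trans)

    def test_windows_with_too_many_missing_samples_dropped(self):
        rec = generate(ProtocolSchedule((("walking", 10.0),)), seed=0)
        # poke a 12%-missing stretch into the first window position only
        rec.sensors["wrist"].x[0:60] = np.nan
        wins = segment(rec)["wrist"]
        starts = [w.start for w in wins]
        assert 0 not in starts  # 60/500 = 12% > 10%
        assert 100 in starts  # second window has 20/500 = 4%, kept and filled
        assert all(np.isfinite(w.samples).all() for w in wins)


class TestFeatureMatrixAssembly:
    def test_default_width_is_39_per_sensor(self, short_recording):
        wins = segment(short_recording)
        fm = extract_features(wins["wrist"])
        assert fm.width == 39
        assert fm.names[0] == "wrist.x.mav" and fm.names[-1] == "wrist.corr.yz"

    def test_ssi_flag_gives_42(self, short_recording):
        cfg = FeatureBankConfig(include_ssi=True)
        fm = extract_features(segment(short_recording, cfg)["wrist"], cfg)
        assert fm.width == 42

    def test_empty_window_list_gives_empty_named_matrix(self):
        fm = extract_features([])
        assert fm.width == 39 and len(fm) == 0

    def test_fusion_width_117_and_alignment(self, short_recording):
        wins = segment(short_recording)
        mats = [extract_features(wins[p]) for p in ("wrist", "chest", "ankle")]
        fused = fuse(mats)
        assert fused.width == 117
        assert len(fused) == len(mats[0])
        assert fuse([mats[0]]) is mats[0]  # identity on a single matrix

    def test_fusion_rejects_mismatched_labels(self, short_recording):
        wins = segment(short_recording)
        a = extract_features(wins["wrist"])
        b = extract_features(wins["chest"])
        b.labels = b.labels.copy()
        b.labels[0] = 99
        with pytest.raises(AlignmentError):
            fuse([a, b])

    def test_all_values_finite(self, short_recording):
        wins = segment(short_recording)
        for p in ("wrist", "chest", "ankle"):
            fm = extract_features(wins[p])
            assert np.isfinite(fm.values).all()

    def test_csv_and_cache_roundtrip(self, tmp_path, short_recording):
        fm = extract_features(segment(short_recording)["chest"])
        fm.to_csv(tmp_path / "f.csv")
        back = type(fm).from_csv(tmp_path / "f.csv")
        assert back.names == fm.names
        np.testing.assert_array_equal(back.values, fm.values)
        np.testing.assert_array_equal(back.labels, fm.labels)
        fm.cache_save(tmp_path / "f.npz")
        cached = type(fm).cache_load(tmp_path / "f.npz")
        np.testing.assert_array_equal(cached.values, fm.values)
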