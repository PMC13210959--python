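"""Time-domain descriptors: worked examples, closed forms, brute-force
oracle equivalence, order relations and scale behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import emgintent.features as ft
from emgintent.windowing import WindowBatch, WindowSpec


# ---------------------------------------------------------------------------
# Independent brute-force oracles: literal loops over the definitions.


def _oracle(name, x):
    n = len(x)
    mav = sum(abs(v) for v in x) / n
    rms = math.sqrt(sum(v * v for v in x) / n)
    peak = max(abs(v) for v in x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    if name == "MAV":
        return mav
    if name == "VAR":
        return sum((v - mean) ** 2 for v in x) / (n - 1)
    if name == "RMS":
        return rms
    if name == "WF":
        return rms / mav
    if name == "SK":
        return (sum((v - mean) ** 3 for v in x) / n) / m2**1.5
    if name == "KU":
        return (sum((v - mean) ** 4 for v in x) / n) / m2**2
    if name == "IF":
        return peak / mav
    if name == "CF":
        return peak / rms
    raise KeyError(name)


class TestWorkedExamples:
    """Hand-checked values on the two-sample window [3, -4]."""

    CASES = {
        "MAV": 3.5,
        "VAR": 24.5,
        "RMS": math.sqrt(12.5),
        "WF": math.sqrt(12.5) / 3.5,
        "IF": 4 / 3.5,
        "CF": 4 / math.sqrt(12.5),
    }

    @pytest.mark.parametrize("name,expected", sorted(CASES.items()))
    def test_two_sample_window(self, name, expected):
        assert ft.FEATURE_FUNCS[name](np.array([3.0, -4.0])) == pytest.approx(
            expected, rel=1e-12
        )

    def test_constant_window_values(self):
        c = np.full(16, -2.5)
        assert ft.mav(c) == pytest.approx(2.5)
        assert ft.rms(c) == pytest.approx(2.5)
        assert ft.var(c) == 0.0
        assert ft.wf(c) == pytest.approx(1.0)
        assert ft.impulse_factor(c) == pytest.approx(1.0)
        assert ft.clearance_factor(c) == pytest.approx(1.0)

    def test_symmetric_window_has_zero_skewness(self):
        assert ft.sk(np.array([-1.0, 0.0, 1.0])) == pytest.approx(0.0, abs=1e-12)

    def test_four_point_skewness_matches_moment_arithmetic(self):
        x = [0.0, 0.0, 0.0, 1.0]
        assert ft.sk(np.array(x)) == pytest.approx(_oracle("SK", x), rel=1e-12)

    def test_alternating_window_kurtosis_is_one(self):
        x = np.tile([1.0, -1.0], 8)
        assert ft.ku(x) == pytest.approx(1.0, rel=1e-12)

    def test_gaussian_sample_variance_near_one(self, rng):
        x = rng.standard_normal(10_000)
        assert 0.9 <= ft.var(x) <= 1.1

    def test_gaussian_kurtosis_near_three(self, rng):
        x = rng.standard_normal(100_000)
        assert 2.9 <= ft.ku(x) <= 3.1


class TestClosedFormSine:
    """Full-period sine of amplitude A: MAV=2A/pi, RMS=A/sqrt(2),
    WF=pi/(2 sqrt 2), IF=pi/2, CF=sqrt(2)."""

    A = 2.7
    x = A * np.sin(2 * np.pi * np.arange(10_000) / 10_000)

    @pytest.mark.parametrize(
        "func,expected",
        [
            (ft.mav, 2 * A / np.pi),
            (ft.rms, A / math.sqrt(2)),
            (ft.wf, math.pi / (2 * math.sqrt(2))),
            (ft.impulse_factor, math.pi / 2),
            (ft.clearance_factor, math.sqrt(2)),
        ],
    )
    def test_sine_closed_forms(self, func, expected):
        assert func(self.x) == pytest.approx(expected, rel=0.01)


class TestOracleEquivalence:
    def test_all_descriptors_match_brute_force_on_random_windows(self, rng):
        for _ in range(1000):
            x = rng.normal(0, rng.uniform(0.1, 5.0), size=rng.integers(8, 64))
            for name, func in ft.FEATURE_FUNCS.items():
                got = func(x)
                want = _oracle(name, list(x))
                assert got == pytest.approx(want, rel=1e-12), name

    def test_vectorised_batch_path_matches_scalar_path(self, rng):
        data = rng.normal(size=(50, 40, 3))
        feats = ft._batch_features(data, list(ft.FEATURE_NAMES))
        for w in range(0, 50, 7):
            for ch in range(3):
                for fi, name in enumerate(ft.FEATURE_NAMES):
                    assert feats[w, ch, fi] == pytest.approx(
                        ft.FEATURE_FUNCS[name](data[w, :, ch]), rel=1e-10
                    )


finite_windows = arrays(
    np.float64,
    st.integers(8, 64),
    elements=st.floats(-100, 100, allow_nan=False, width=32),
)


class TestPropertyInvariants:
    @given(x=finite_windows)
    def test_order_relations_if_ge_cf_ge_1_and_wf_ge_1(self, x):
        if np.std(x) == 0 or ft.mav(x) == 0:
            return
        assert ft.impulse_factor(x) >= ft.clearance_factor(x) - 1e-12
        assert ft.clearance_factor(x) >= 1.0 - 1e-12
        assert ft.wf(x) >= 1.0 - 1e-12

    @given(x=finite_windows, a=st.floats(0.1, 50))
    def test_scale_behaviour(self, x, a):
        if np.std(x) == 0 or ft.mav(x) == 0:
            return
        assert ft.mav(a * x) == pytest.approx(a * ft.mav(x), rel=1e-9)
        assert ft.rms(a * x) == pytest.approx(a * ft.rms(x), rel=1e-9)
        assert ft.var(a * x) == pytest.approx(a**2 * ft.var(x), rel=1e-9)
        for name in ("WF", "SK", "KU", "IF", "CF"):
            f = ft.FEATURE_FUNCS[name]
            assert f(a * x) == pytest.approx(f(x), rel=1e-7, abs=1e-9), name

    @given(x=finite_windows)
    def test_skewness_is_odd_under_sign_flip(self, x):
        if np.std(x) == 0:
            return
        assert ft.sk(-x) == pytest.approx(-ft.sk(x), rel=1e-9, abs=1e-9)

    @given(x=finite_windows, a=st.floats(0.5, 10), b=st.floats(-5, 5))
    def test_kurtosis_shift_and_scale_invariant(self, x, a, b):
        if np.std(x) == 0:
            return
        assert ft.ku(a * x + b) == pytest.approx(ft.ku(x), rel=1e-6)


def _batch(data, labels=None, trials=None, names=None):
    n = data.shape[0]
    return WindowBatch(
        data,
        np.array(labels or ["y1"] * n, dtype=object),
        np.array(trials or range(n)),
        np.zeros(n, dtype=int),
        names or tuple(f"ch{i}" for i in range(data.shape[2])),
        WindowSpec(data.shape[1] / 500.0, data.shape[1] / 500.0, 500.0),
    )


class TestExtractFeatures:
    def test_single_feature_two_channels_gives_per_channel_rms(self, rng):
        data = rng.normal(size=(1, 50, 2))
        fm = ft.extract_features(_batch(data), ["RMS"])
        assert fm.X.shape == (1, 2)
        assert list(fm.X.columns) == ["ch0_RMS", "ch1_RMS"]
        assert fm.X.iloc[0, 0] == pytest.approx(ft.rms(data[0, :, 0]))

    def test_eight_channels_three_features_gives_24_columns(self, rng):
        data = rng.normal(size=(5, 50, 8))
        fm = ft.extract_features(_batch(data), ["RMS", "IF", "CF"])
        assert fm.X.shape == (5, 24)
        # channel-major, feature-minor ordering
        assert list(fm.X.columns[:3]) == ["ch0_RMS", "ch0_IF", "ch0_CF"]

    def test_all_zero_window_dropped_with_log(self, rng, caplog):
        data = rng.normal(size=(3, 50, 1))
        data[1] = 0.0
        with caplog.at_level("WARNING"):
            fm = ft.extract_features(_batch(data), ["WF"])
        assert len(fm) == 2
        assert "dropped 1" in caplog.text

    def test_duplicate_feature_deduplicated_with_warning(self, rng, caplog):
        data = rng.normal(size=(2, 50, 1))
        with caplog.at_level("WARNING"):
            fm = ft.extract_features(_batch(data), ["RMS", "RMS"])
        assert fm.X.shape == (2, 1)
        assert "duplicate" in caplog.text

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValueError):
            ft.extract_features(_batch(rng.normal(size=(1, 50, 1))), [])

    def test_channel_mean_layout(self, rng):
        data = rng.normal(size=(4, 50, 3))
        fm = ft.extract_features(_batch(data), ["RMS"], layout="channel_mean")
        assert fm.X.shape == (4, 1)
        expected = np.mean([ft.rms(data[0, :, c]) for c in range(3)])
        assert fm.X.iloc[0, 0] == pytest.approx(expected)


class TestSklearnTransformer:
    def test_transform_matches_extract_features(self, rng):
        data = rng.normal(size=(6, 50, 4))
        tr = ft.TimeDomainFeatures(subset=("RMS", "IF"))
        out = tr.fit_transform(data)
        fm = ft.extract_features(_batch(data), ["RMS", "IF"])
        np.testing.assert_allclose(out, fm.X.to_numpy())

    def test_get_feature_names_out(self, rng):
        tr = ft.TimeDomainFeatures(subset=("RMS",)).fit(rng.normal(size=(2, 50, 2)))
        assert list(tr.get_feature_names_out()) == ["ch0_RMS", "ch1_RMS"]

    def test_composes_with_sklearn_pipeline(self, rng):
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.pipeline import make_pipeline

        X = rng.normal(size=(40, 50, 2))
        X[20:] *= 5.0
        y = np.array([0] * 20 + [1] * 20)
        pipe = make_pipeline(
            ft.TimeDomainFeatures(subset=("RMS",)),
            RandomForestClassifier(n_estimators=10, random_state=0),
        )
        pipe.fit(X, y)
        assert pipe.score(X, y) == 1.0

    def test_get_params_roundtrip(self):
        tr = ft.TimeDomainFeatures(subset=("RMS", "CF"), layout="channel_mean")
        params = tr.get_params()
        tr2 = ft.TimeDomainFeatures(**params)
        assert tr2.get_params() == params
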