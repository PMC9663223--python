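"""Time-domain feature formulas against independent brute-force oracles."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fnirs_upb.features import (
    FeatureMatrix,
    apply_minmax,
    build_feature_matrix,
    extract_features,
    fit_minmax,
)
from fnirs_upb.preprocess import Epoch


def make_epoch(x, dn=1.0, n_pre=0, channel=0, trial=0, condition="Task1"):
    return Epoch(
        x=np.asarray(x, float), dn=dn, n_pre=n_pre, channel=channel, trial=trial,
        condition=condition, baseline_corrected=True,
    )


def brute_force_features(x, dn):
    """Naive per-definition loops, independent of the vectorized implementation."""
    n = len(x)
    sm = sum(x) / n
    sv = sum((v - sm) ** 2 for v in x) / (n - 1)
    if sv > 0:
        sd = sv**0.5
        kr = sum(((v - sm) / sd) ** 4 for v in x) / n
        sk = sum(((v - sm) / sd) ** 3 for v in x) / n
    else:
        kr = sk = 0.0
    slopes = [(x[i] - x[i - 1]) / dn for i in range(1, n)]
    ss = sum(slopes) / len(slopes)
    sa = sum(x) * dn
    return sm, sv, kr, sk, ss, sa


class TestExtractFeatures:
    def test_hand_computed_example(self):
        """x=[0,1,2,3], Δn=1: SM=1.5, SV=5/3, SS=1, SA=6, KR=0.9225, SK=0."""
        fv = extract_features(make_epoch([0, 1, 2, 3]))
        assert fv.sm == 1.5
        assert fv.sv == pytest.approx(5 / 3, rel=1e-12)
        assert fv.ss == pytest.approx(1.0, rel=1e-12)
        assert fv.sa == pytest.approx(6.0, rel=1e-12)
        # standardized 4th/3rd moments: mean(d^4)=2.5625, sigma^4=25/9
        assert fv.kr == pytest.approx(0.9225, rel=1e-12)
        assert fv.sk == pytest.approx(0.0, abs=1e-12)
        assert not fv.degenerate

    def test_constant_signal_flagged_degenerate(self):
        fv = extract_features(make_epoch([1.0, 1.0, 1.0, 1.0]))
        assert fv.sm == 1.0 and fv.sv == 0.0 and fv.ss == 0.0
        assert fv.sa == pytest.approx(4.0)
        assert fv.kr == 0.0 and fv.sk == 0.0
        assert fv.degenerate

    def test_agrees_with_brute_force_on_random_vectors(self, rng):
        for _ in range(500):
            n = int(rng.integers(3, 40))
            dn = float(rng.uniform(0.01, 2.0))
            x = rng.standard_normal(n) * rng.uniform(0.1, 10)
            fv = extract_features(make_epoch(x, dn=dn))
            expected = brute_force_features(list(x), dn)
            got = (fv.sm, fv.sv, fv.kr, fv.sk, fv.ss, fv.sa)
            for g, e in zip(got, expected):
                assert g == pytest.approx(e, rel=1e-10, abs=1e-10)

    def test_slope_mean_telescopes_to_endpoints(self, rng):
        x = rng.standard_normal(100)
        fv = extract_features(make_epoch(x, dn=0.5))
        assert fv.ss == pytest.approx((x[-1] - x[0]) / (99 * 0.5), rel=1e-12)

    def test_lstsq_slope_on_exact_line(self):
        x = 2.0 * np.arange(50) * 0.1 + 1.0
        fv = extract_features(make_epoch(x, dn=0.1), slope="lstsq")
        assert fv.ss == pytest.approx(2.0, rel=1e-8)

    def test_gaussian_moments_converge(self):
        """Kurtosis is the raw (non-excess) 4th moment: → 3 for a normal sample."""
        rng = np.random.default_rng(99)
        fv = extract_features(make_epoch(rng.standard_normal(1_000_000)))
        assert fv.kr == pytest.approx(3.0, abs=0.05)
        assert fv.sk == pytest.approx(0.0, abs=0.01)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
        seed=st.integers(0, 2**16),
    )
    def test_affine_transform_laws(self, a, b, seed):
        """KR/SK invariant under x→a·x+b (a>0); SM/SV/SS/SA follow closed forms."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(64)
        dn = 0.25
        f0 = extract_features(make_epoch(x, dn=dn))
        f1 = extract_features(make_epoch(a * x + b, dn=dn))
        assert f1.kr == pytest.approx(f0.kr, rel=1e-9)
        assert f1.sk == pytest.approx(f0.sk, rel=1e-9, abs=1e-9)
        assert f1.sm == pytest.approx(a * f0.sm + b, rel=1e-9, abs=1e-9)
        assert f1.sv == pytest.approx(a * a * f0.sv, rel=1e-9)
        assert f1.ss == pytest.approx(a * f0.ss, rel=1e-9, abs=1e-9)
        assert f1.sa == pytest.approx(a * f0.sa + b * 64 * dn, rel=1e-9, abs=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            extract_features(make_epoch([1.0, 2.0]))


class TestMinMax:
    def test_simple_column(self):
        X = np.array([[2.0], [4.0], [6.0]])
        scaler = fit_minmax(X)
        np.testing.assert_allclose(scaler.transform(X).ravel(), [0.0, 0.5, 1.0])

    def test_constant_column_zeroed_with_warning(self, caplog):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        with caplog.at_level(logging.WARNING, logger="fnirs_upb.features"):
            scaler = fit_minmax(X)
        assert any("constant" in r.message for r in caplog.records)
        out = scaler.transform(X)
        np.testing.assert_allclose(out[:, 0], 0.0)
        np.testing.assert_allclose(out[:, 1], [0.0, 0.5, 1.0])

    def test_fitted_rows_land_in_unit_interval(self, rng):
        X = rng.standard_normal((50, 6)) * 10
        rows = np.arange(0, 40)
        scaler = fit_minmax(X, rows)
        out = scaler.transform(X)
        assert out[rows].min() >= 0.0 and out[rows].max() <= 1.0

    def test_out_of_range_rows_may_extrapolate(self):
        X = np.array([[1.0], [2.0], [3.0], [0.0]])
        scaler = fit_minmax(X, np.array([0, 1, 2]))
        out = scaler.transform(X)
        assert out[3, 0] == pytest.approx(-0.5)  # below train min, not clipped


class TestBuildMatrix:
    def test_row_count_and_shape(self, default_subject):
        *_, fm = default_subject
        assert fm.X.shape == (150, 6)
        assert (fm.labels == "Task1").sum() == 75
        assert (fm.labels == "Task2").sum() == 75

    def test_shuffling_epochs_preserves_row_multiset(self, default_subject):
        _, _, _, epochs, fm = default_subject
        rng = np.random.default_rng(0)
        shuffled = list(epochs)
        rng.shuffle(shuffled)
        fm2 = build_feature_matrix(shuffled)
        order1 = np.lexsort(fm.X.T)
        order2 = np.lexsort(fm2.X.T)
        np.testing.assert_allclose(fm.X[order1], fm2.X[order2])

    def test_single_condition_rejected(self, default_subject):
        _, _, _, epochs, _ = default_subject
        only_task1 = [e for e in epochs if e.condition == "Task1"]
        with pytest.raises(ValueError, match="both conditions"):
            build_feature_matrix(only_task1)

    def test_trial_sample_unit_concatenates_channels(self, default_subject):
        _, _, _, epochs, _ = default_subject
        fm = build_feature_matrix(epochs, sample_unit="trial")
        assert fm.X.shape == (10, 90)
        assert len(fm.feature_names) == 90

    def test_apply_minmax_marks_rescaled(self, default_subject):
        *_, fm = default_subject
        out = apply_minmax(fit_minmax(fm.X), fm)
        assert out.rescaled
        assert out.X.min() >= 0.0 and out.X.max() <= 1.0
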