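"""Maximum lagged correlation features: filtering, lag search, Fisher
transform, nuisance regression, feature-set reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fnconn.datatypes import SubjectComponents
from fnconn.fnc import (
    LagSearchConfig,
    bandpass,
    fnc_vector,
    lagged_correlations,
    max_lagged_correlation,
    reduce_feature_set,
    regress_nuisance,
)

TR = 1.5


def _bandlimited(rng, T, tr=TR, band=(0.02, 0.12)):
    z = rng.standard_normal(T)
    F = np.fft.rfft(z)
    f = np.fft.rfftfreq(T, tr)
    F[(f < band[0]) | (f > band[1])] = 0
    x = np.fft.irfft(F, n=T)
    return (x - x.mean()) / x.std()


def _naive_lag_search(x, y, tr, interp_factor, max_lag):
    """Independent brute-force oracle: python-loop overlap correlation."""
    from scipy.interpolate import CubicSpline

    t = np.arange(len(x)) * tr
    dt = tr / interp_factor
    tt = np.arange((len(x) - 1) * interp_factor + 1) * dt
    xi, yi = CubicSpline(t, x)(tt), CubicSpline(t, y)(tt)
    kmax = int(np.floor(max_lag / dt + 1e-9))
    best = None
    for k in range(-kmax, kmax + 1):
        if k >= 0:
            a, b = xi[:len(xi) - k], yi[k:]
        else:
            a, b = xi[-k:], yi[:len(yi) + k]
        r = np.corrcoef(a, b)[0, 1]
        key = (-r, abs(k), k)
        if best is None or key < best[0]:
            best = (key, r, k * dt)
    return best[1], best[2]


class TestBandpass:
    def test_passband_sinusoid_retained(self):
        t = np.arange(400) * TR
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass(x, TR)
        assert y[50:-50].std() / x[50:-50].std() >= 0.9

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(400) * TR
        x = np.sin(2 * np.pi * 0.30 * t)
        y = bandpass(x, TR)
        assert y[50:-50].std() / x[50:-50].std() <= 0.1

    def test_zero_in_zero_out(self):
        np.testing.assert_allclose(bandpass(np.zeros(100), TR), 0.0)

    def test_length_preserved_and_2d(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((120, 4))
        assert bandpass(x, TR).shape == (120, 4)

    def test_cutoff_at_nyquist_rejected(self):
        cfg = LagSearchConfig(band=(0.017, 0.34))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(100), TR, cfg)


class TestMaxLaggedCorrelation:
    def test_identical_series(self):
        rng = np.random.default_rng(1)
        x = _bandlimited(rng, 200)
        r, lag = max_lagged_correlation(x, x, TR)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert lag == 0.0

    def test_exact_one_sample_shift(self):
        rng = np.random.default_rng(2)
        base = _bandlimited(rng, 201)
        x, y = base[1:], base[:-1]          # y[t] = x[t-1]: y lags x
        r, lag = max_lagged_correlation(x, y, TR,
                                        LagSearchConfig(interp_factor=1))
        assert r == pytest.approx(1.0, abs=1e-9)
        assert lag == pytest.approx(TR)

    def test_spectral_shift_with_noise_vs_dense_oracle(self):
        rng = np.random.default_rng(3)
        T = 200
        x = _bandlimited(rng, T)
        F = np.fft.rfft(x)
        f = np.fft.rfftfreq(T, TR)
        y = np.fft.irfft(F * np.exp(-2j * np.pi * f * 1.5), n=T)
        r0, _ = max_lagged_correlation(x, y, TR)
        xn = x + 10 ** -0.5 * rng.standard_normal(T)      # SNR 10
        yn = y + 10 ** -0.5 * rng.standard_normal(T)
        r, lag = max_lagged_correlation(xn, yn, TR)
        assert lag == pytest.approx(1.5, abs=0.3)
        assert r == pytest.approx(r0, abs=0.1)
        # dense brute-force search at lag_step TR/100 agrees
        r_o, lag_o = _naive_lag_search(xn, yn, TR, 100, 3.0)
        assert abs(lag - lag_o) <= TR / 10 + 1e-9
        assert r == pytest.approx(r_o, abs=0.01)

    def test_symmetry_negates_lag(self):
        rng = np.random.default_rng(4)
        x, y = _bandlimited(rng, 150), _bandlimited(rng, 150)
        r1, l1 = max_lagged_correlation(x, y, TR)
        r2, l2 = max_lagged_correlation(y, x, TR)
        assert r1 == pytest.approx(r2, abs=1e-10)
        assert l1 == pytest.approx(-l2, abs=1e-9)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None)
    def test_positive_scale_invariance(self, scale):
        rng = np.random.default_rng(5)
        x, y = _bandlimited(rng, 100), _bandlimited(rng, 100)
        r1, l1 = max_lagged_correlation(x, y, TR)
        r2, l2 = max_lagged_correlation(x * scale, y, TR)
        assert r1 == pytest.approx(r2, rel=1e-9)
        assert l1 == l2

    def test_zero_window_reduces_to_plain_correlation(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal(80), rng.standard_normal(80)
        cfg = LagSearchConfig(max_lag=0.0, interp_factor=1)
        r, lag = max_lagged_correlation(x, y, TR, cfg)
        assert lag == 0.0
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_near_constant_segment_returns_zero(self):
        x = np.ones(60)
        y = np.linspace(0, 1, 60)
        with pytest.warns(UserWarning, match="near-constant"):
            r, _ = max_lagged_correlation(x, y, TR,
                                          LagSearchConfig(interp_factor=1))
        assert r == 0.0

    def test_grid_matches_finer_bruteforce_on_random_pairs(self):
        # coarse lag grid (step TR/10) on the same interpolated series as
        # the exhaustive 10x-finer search
        cfg = LagSearchConfig(interp_factor=100, lag_step=TR / 10)
        rng = np.random.default_rng(7)
        for _ in range(5):
            x, y = _bandlimited(rng, 150), _bandlimited(rng, 150)
            r, lag = max_lagged_correlation(x, y, TR, cfg)
            r_o, lag_o = _naive_lag_search(x, y, TR, 100, cfg.max_lag)
            assert abs(lag - lag_o) <= TR / 10 + 1e-9
            assert r == pytest.approx(r_o, abs=1e-3)


class TestFNCVector:
    def _subject(self, K, T=120, seed=0):
        rng = np.random.default_rng(seed)
        tcs = np.column_stack([_bandlimited(rng, T) for _ in range(K)])
        return SubjectComponents(maps=np.zeros((K, 1)), tcs=tcs,
                                 subject_id="s0", tr=TR)

    @pytest.mark.parametrize("K,expected", [(9, 36), (2, 1), (20, 190)])
    def test_feature_count(self, K, expected):
        v = fnc_vector(self._subject(K), range(K))
        assert len(v.z_values) == expected
        assert len(v.pair_index) == expected

    def test_fisher_transform_applied(self):
        sub = self._subject(3, seed=1)
        v = fnc_vector(sub, [0, 1, 2])
        tcs = bandpass(sub.tcs, TR)
        r01, _ = max_lagged_correlation(tcs[:, 0], tcs[:, 1], TR)
        assert v.z_values[0] == pytest.approx(np.arctanh(r01), abs=1e-12)

    def test_perfect_correlation_clipped(self):
        sub = self._subject(2, seed=2)
        sub.tcs[:, 1] = sub.tcs[:, 0]
        with pytest.warns(UserWarning, match="clipped"):
            v = fnc_vector(sub, [0, 1])
        assert np.isfinite(v.z_values[0])

    def test_invalid_indices_rejected(self):
        with pytest.raises(ValueError, match="invalid component"):
            fnc_vector(self._subject(3), [0, 5])

    def test_pair_labels(self):
        v = fnc_vector(self._subject(3), [0, 1, 2], labels=["A", "B", "C"])
        assert v.pair_labels == ["A_B", "A_C", "B_C"]


class TestNuisanceRegression:
    def test_orthogonal_covariate_leaves_feature_unchanged(self):
        n = 40
        cov = np.column_stack([np.ones(n), np.zeros(n)])[:, :1]
        cov = np.sin(np.arange(n))[:, None]
        feat = np.cos(np.arange(n) * 2)[:, None]
        feat -= feat.mean()
        cov -= cov.mean()
        # orthogonalize exactly
        feat = feat - cov * (cov.T @ feat) / (cov.T @ cov)
        out = regress_nuisance(feat, cov)
        np.testing.assert_allclose(out, feat, atol=1e-10)

    def test_exact_linear_removal(self):
        rng = np.random.default_rng(8)
        cov = rng.standard_normal((30, 1))
        feat = 2.0 * cov + 5.0
        out = regress_nuisance(feat, cov)
        np.testing.assert_allclose(out, 5.0, atol=1e-10)

    def test_rank_deficient_covariates_warn(self):
        rng = np.random.default_rng(9)
        c = rng.standard_normal((20, 1))
        cov = np.hstack([c, 2 * c])
        with pytest.warns(UserWarning, match="rank-deficient"):
            regress_nuisance(rng.standard_normal((20, 3)), cov)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            regress_nuisance(np.zeros((3, 2)), np.zeros((3, 2)))


class TestReduceFeatureSet:
    @staticmethod
    def _labels(names):
        return [f"{a}_{b}" for i, a in enumerate(names) for b in names[i + 1:]]

    def test_medication_exclusion_counts(self):
        names = [f"IC{k}" for k in range(9)]
        labels = self._labels(names)
        assert len(labels) == 36
        keep = reduce_feature_set(labels, motor_label="IC7",
                                  extra_pair=("IC0", "IC3"))
        assert len(keep) == 27
        kept = [labels[i] for i in keep]
        assert all("IC7" not in l.split("_") for l in kept)
        assert "IC0_IC3" not in kept
        # ordering of survivors preserved
        assert kept == [l for l in labels if l in set(kept)]

    def test_empty_exclusion_is_identity(self):
        labels = self._labels(["A", "B", "C"])
        assert reduce_feature_set(labels, motor_label=None) == [0, 1, 2]

    def test_two_component_set_exhausted(self):
        assert reduce_feature_set(["A_B"], motor_label="A") == []

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            reduce_feature_set(["A_B"], motor_label="Z")
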