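"""Cohort generator: dimension contracts, covariance/lag realization,
group-effect editing, motion confound injection."""

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from fnconn.datatypes import SubjectComponents
from fnconn.fnc import LagSearchConfig, fnc_vector, motion_summary, regress_nuisance
from fnconn.synthetic import (
    CohortSpec,
    GroundTruth,
    generate_cohort,
    make_ground_truth,
    make_group_effect,
    realize_timecourses,
)


def dense_lag_oracle(x, y, tr, max_lag=3.0, step=0.01):
    """Independent brute-force lag search on a cubic-spline oversampling."""
    t = np.arange(len(x)) * tr
    fx, fy = CubicSpline(t, x), CubicSpline(t, y)
    tt = np.arange(0, t[-1], step)
    best = (-np.inf, 0.0)
    for lag in np.arange(-max_lag, max_lag + step / 2, step):
        ta = tt[(tt >= max(0, -lag)) & (tt <= t[-1] - max(0, lag))]
        r = np.corrcoef(fx(ta), fy(ta + lag))[0, 1]
        if r > best[0]:
            best = (r, lag)
    return best


class TestCohortSpec:
    def test_dimension_contract(self):
        spec = CohortSpec(n_per_group=2, n_timepoints=50, grid=(8, 8, 6),
                          n_components=3, seed=0)
        truth = make_ground_truth(spec)
        cohort = generate_cohort(spec, truth)
        assert cohort.n_subjects == 4
        for scan in cohort.scans:
            assert scan.data.shape == (50, 8 * 8 * 6)
        assert np.bincount(cohort.labels).tolist() == [2, 2]

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="4 x n_components"):
            CohortSpec(n_timepoints=20, n_components=9)

    def test_seed_reproducibility(self):
        spec = CohortSpec(n_per_group=2, n_timepoints=60, grid=(6, 6, 4),
                          n_components=3, seed=5)
        c1 = generate_cohort(spec, make_ground_truth(spec))
        c2 = generate_cohort(spec, make_ground_truth(spec))
        for a, b in zip(c1.scans, c2.scans):
            np.testing.assert_array_equal(a.data, b.data)
        for a, b in zip(c1.motion, c2.motion):
            np.testing.assert_array_equal(a, b)
        assert c1.covariates.equals(c2.covariates)


class TestTimecourseRealization:
    def test_identity_covariance_gives_uncorrelated_tcs(self):
        spec = CohortSpec(n_per_group=2, n_timepoints=200, grid=(6, 6, 4),
                          n_components=5, seed=3)
        truth = make_ground_truth(spec, base_pairs={}, lags_per_pair={},
                                  noise_sd=0.0, subject_variability_sd=0.0)
        cohort = generate_cohort(spec, truth)
        for u in cohort.clean_tcs:
            C = np.corrcoef(u.T)
            off = C[np.triu_indices(5, 1)]
            assert np.all(np.abs(off) < 0.2)

    def test_lagged_pair_realization(self):
        rng = np.random.default_rng(0)
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.6
        delays = np.array([0.0, 1.5, 0.0])
        u = realize_timecourses(rng, 1000, 1.5, C, delays)
        rho, lag = dense_lag_oracle(u[:, 0], u[:, 1], 1.5)
        assert rho == pytest.approx(0.6, abs=0.1)
        assert lag == pytest.approx(1.5, abs=0.5)

    def test_mean_fnc_converges_with_record_length(self):
        # group-mean max-lagged correlation approaches the target as T grows
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.5
        C[1, 2] = C[2, 1] = 0.3
        cfg = LagSearchConfig()
        errs = {}
        for T in (200, 2000):
            rng = np.random.default_rng(99)
            vals = []
            for _ in range(8):
                u = realize_timecourses(rng, T, 1.5, C, np.zeros(3))
                sc = SubjectComponents(maps=np.zeros((3, 1)), tcs=u,
                                       subject_id="s", tr=1.5)
                v = fnc_vector(sc, [0, 1, 2], tr=1.5, cfg=cfg)
                vals.append(np.tanh(v.z_values))
            mean = np.mean(vals, axis=0)
            target = np.array([C[0, 1], C[0, 2], C[1, 2]])
            errs[T] = np.abs(mean - target).max()
        assert errs[2000] <= 0.5 * errs[200] + 1e-3

    def test_inconsistent_pair_lags_rejected(self):
        spec = CohortSpec(n_per_group=1, n_timepoints=60, grid=(6, 6, 4),
                          n_components=3, seed=0)
        with pytest.raises(ValueError, match="inconsistent"):
            make_ground_truth(spec, base_pairs={(0, 1): 0.5, (0, 2): 0.5},
                              lags_per_pair={(0, 1): 1.5, (0, 2): 0.5,
                                             (1, 2): 1.0})


class TestGroundTruthValidation:
    def test_non_psd_target_rejected(self):
        spec = CohortSpec(n_per_group=1, n_timepoints=60, grid=(6, 6, 4),
                          n_components=3, seed=0)
        truth = make_ground_truth(spec)
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.9
        C[0, 2] = C[2, 0] = 0.9
        C[1, 2] = C[2, 1] = -0.9
        with pytest.raises(ValueError, match="positive semidefinite"):
            GroundTruth(spatial_maps=truth.spatial_maps,
                        tc_covariance_per_group=[np.eye(3), C])

    def test_lag_outside_window_rejected(self):
        spec = CohortSpec(n_per_group=1, n_timepoints=60, grid=(6, 6, 4),
                          n_components=3, seed=0)
        with pytest.raises(ValueError, match="exceeds the window|exceeds"):
            make_ground_truth(spec, lags_per_pair={(0, 1): 5.0})

    def test_json_roundtrip(self):
        spec = CohortSpec(n_per_group=1, n_timepoints=60, grid=(6, 6, 4),
                          n_components=3, seed=0)
        truth = make_ground_truth(spec)
        back = GroundTruth.from_json(truth.to_json())
        np.testing.assert_allclose(back.spatial_maps, truth.spatial_maps)
        assert back.lags_per_pair == truth.lags_per_pair


class TestGroupEffect:
    def _truth(self, K=4, base=0.6):
        spec = CohortSpec(n_per_group=1, n_timepoints=60, grid=(6, 6, 4),
                          n_components=K, seed=1)
        return make_ground_truth(spec, base_pairs={(1, 2): base},
                                 lags_per_pair={})

    def test_zero_delta_identity(self):
        truth = self._truth()
        out = make_group_effect(truth, [(1, 2)], 0.0)
        np.testing.assert_allclose(out.tc_covariance_per_group[0],
                                   out.tc_covariance_per_group[1])

    def test_delta_arithmetic(self):
        out = make_group_effect(self._truth(base=0.6), [(1, 2)], -0.3)
        # group2 = group1 - delta
        assert out.tc_covariance_per_group[1][1, 2] == pytest.approx(0.9)
        out = make_group_effect(self._truth(base=0.6), [(1, 2)], 0.3)
        assert out.tc_covariance_per_group[1][1, 2] == pytest.approx(0.3)

    def test_involution(self):
        truth = self._truth()
        fwd = make_group_effect(truth, [(1, 2)], 0.25)
        back = make_group_effect(fwd, [(1, 2)], -0.25)
        np.testing.assert_allclose(back.tc_covariance_per_group[1],
                                   truth.tc_covariance_per_group[1], atol=1e-12)

    def test_out_of_range_delta_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_group_effect(self._truth(base=0.6), [(1, 2)], -0.5)


class TestMotionConfound:
    def test_confound_injected_and_removed(self):
        spec = CohortSpec(n_per_group=12, n_timepoints=120, grid=(6, 6, 4),
                          n_components=4, seed=21)
        truth = make_ground_truth(spec, base_pairs={}, lags_per_pair={},
                                  noise_sd=0.0, motion_effect=0.8,
                                  subject_variability_sd=0.0)
        cohort = generate_cohort(spec, truth)
        cfg = LagSearchConfig()
        F = []
        for u, sid in zip(cohort.clean_tcs, cohort.covariates.subject_id):
            sc = SubjectComponents(maps=np.zeros((4, 1)), tcs=u,
                                   subject_id=sid, tr=spec.tr)
            F.append(fnc_vector(sc, range(4), tr=spec.tr, cfg=cfg).z_values)
        F = np.vstack(F)
        covs = np.vstack([motion_summary(m) for m in cohort.motion])
        # injected confound: motion magnitude correlates with FNC inflation
        pre = np.abs(np.corrcoef(covs.mean(axis=1), F.mean(axis=1))[0, 1])
        assert pre > 0.3
        resid = regress_nuisance(F, covs)
        for j in range(covs.shape[1]):
            for p in range(F.shape[1]):
                assert abs(np.corrcoef(covs[:, j], resid[:, p])[0, 1]) < 0.05


def test_cohort_save_load_roundtrip(tmp_path, noisy_cohort):
    _, _, cohort = noisy_cohort
    cohort.save(tmp_path)
    assert len(list(tmp_path.glob("*_bold.nii"))) == cohort.n_subjects
    from fnconn.synthetic import Cohort

    back = Cohort.load(tmp_path)
    assert back.n_subjects == cohort.n_subjects
    np.testing.assert_allclose(back.scans[0].data, cohort.scans[0].data,
                               rtol=0, atol=1e-6)
    np.testing.assert_array_equal(back.labels, cohort.labels)
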