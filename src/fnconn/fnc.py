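"""Functional network connectivity features: maximum lagged correlation.

For every pair of selected component time-courses the statistic is the
maximum, over lags in a +/-3 s window, of the Pearson correlation between
the overlapping segments of the two series, one of them shifted by the
lag.  Time-courses are bandpass filtered (zero-phase Butterworth,
0.017-0.15 Hz) and cubic-spline interpolated to a sub-TR grid first so
that delays smaller than the TR are detectable.  The per-pair maxima are
Fisher z-transformed (z = arctanh r) and nuisance covariates (motion
summaries, age) are regressed out across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from fnconn.datatypes import FNCVector, SubjectComponents, canonical_pairs

__all__ = [
    "LagSearchConfig",
    "bandpass",
    "interpolate",
    "lagged_correlations",
    "max_lagged_correlation",
    "fnc_vector",
    "cohort_features",
    "regress_nuisance",
    "NuisanceRegressor",
    "motion_summary",
    "reduce_feature_set",
]

_VAR_EPS = 1e-12


@dataclass
class LagSearchConfig:
    """Parameters of the lagged-correlation search.

    ``max_lag`` is the half-width of the lag window in seconds (the search
    covers −max_lag..+max_lag); ``interp_factor`` is the sub-TR
    interpolation factor (grid step TR/interp_factor); ``lag_step``
    defaults to that grid step and must be an integer multiple of it;
    ``band`` and ``filter_order`` define the zero-phase Butterworth
    bandpass; ``mean_center=False`` selects the uncentered (cosine)
    variant of the overlap correlation.
    """

    max_lag: float = 3.0
    lag_step: float | None = None
    interp_factor: int = 10
    band: tuple = (0.017, 0.15)
    filter_order: int = 5
    mean_center: bool = True

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValueError("max_lag must be non-negative")
        if self.interp_factor < 1:
            raise ValueError("interp_factor must be >= 1")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band cutoffs must satisfy 0 < low < high")

    def grid_step(self, tr: float) -> float:
        return tr / self.interp_factor

    def lag_shifts(self, tr: float) -> np.ndarray:
        """Integer sample shifts on the interpolated grid covering the
        lag window."""
        dt = self.grid_step(tr)
        step = self.lag_step if self.lag_step is not None else dt
        ratio = step / dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"lag_step {step} is not an integer multiple of the "
                f"interpolated sampling interval {dt}"
            )
        kstep = int(round(ratio))
        kmax = int(np.floor(self.max_lag / dt + 1e-9))
        return np.arange(-kmax, kmax + 1, kstep)


def bandpass(tc: np.ndarray, tr: float, cfg: LagSearchConfig | None = None) -> np.ndarray:
    """Zero-phase Butterworth bandpass of one or more time-courses.

    ``tc`` may be 1-D (one series) or 2-D (time x series); the output has
    the input's length.  Cutoffs at or above the Nyquist frequency are
    rejected.
    """
    cfg = cfg or LagSearchConfig()
    nyq = 0.5 / tr
    low, high = cfg.band
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq:.4f} Hz")
    tc = np.asarray(tc, float)
    if tc.shape[0] <= 3 * cfg.filter_order:
        raise ValueError("time-course too short for the requested filter order")
    sos = butter(cfg.filter_order, [low, high], btype="bandpass", fs=1.0 / tr,
                 output="sos")
    return sosfiltfilt(sos, tc, axis=0)


def interpolate(tc: np.ndarray, tr: float, interp_factor: int) -> np.ndarray:
    """Cubic-spline interpolation of a series to a TR/interp_factor grid."""
    tc = np.asarray(tc, float)
    if interp_factor == 1:
        return tc.copy()
    T = tc.shape[0]
    t = np.arange(T) * tr
    tf = np.arange((T - 1) * interp_factor + 1) * (tr / interp_factor)
    return CubicSpline(t, tc, axis=0)(tf)


def _overlap_corr(x: np.ndarray, y: np.ndarray, shifts: np.ndarray,
                  mean_center: bool = True) -> np.ndarray:
    """Correlation of the overlapping segments of x and y for each integer
    shift k (positive k: y shifted later, i.e. x[t] against y[t+k])."""
    n = x.size
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cx2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cy2 = np.concatenate([[0.0], np.cumsum(y * y)])
    rho = np.empty(shifts.size)
    for i, k in enumerate(shifts):
        if k >= 0:
            m = n - k
            sx, sx2 = cx[m], cx2[m]
            sy, sy2 = cy[n] - cy[k], cy2[n] - cy2[k]
            sxy = float(x[:m] @ y[k:])
        else:
            m = n + k
            sx, sx2 = cx[n] - cx[-k], cx2[n] - cx2[-k]
            sy, sy2 = cy[m], cy2[m]
            sxy = float(x[-k:] @ y[:m])
        if m < 3:
            rho[i] = np.nan
            continue
        if mean_center:
            vx = sx2 - sx * sx / m
            vy = sy2 - sy * sy / m
            cov = sxy - sx * sy / m
        else:
            vx, vy, cov = sx2, sy2, sxy
        if vx < _VAR_EPS or vy < _VAR_EPS:
            warnings.warn("near-constant segment in lag search; correlation set to 0")
            rho[i] = 0.0
        else:
            rho[i] = cov / np.sqrt(vx * vy)
    return rho


def lagged_correlations(x: np.ndarray, y: np.ndarray, tr: float,
                        cfg: LagSearchConfig | None = None):
    """Interpolate a pair and return (lags_seconds, rho_at_each_lag)."""
    cfg = cfg or LagSearchConfig()
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ValueError("time-courses must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 timepoints")
    xi = interpolate(x, tr, cfg.interp_factor)
    yi = interpolate(y, tr, cfg.interp_factor)
    shifts = cfg.lag_shifts(tr)
    dt = cfg.grid_step(tr)
    if xi.size < 2 * max(1, shifts.max()):
        raise ValueError("series too short for the requested lag window")
    rho = _overlap_corr(xi, yi, shifts, mean_center=cfg.mean_center)
    return shifts * dt, rho


def max_lagged_correlation(x: np.ndarray, y: np.ndarray, tr: float,
                           cfg: LagSearchConfig | None = None):
    """Maximum lagged correlation of a pair of time-courses.

    Returns ``(rho_max, lag_at_max)`` where the maximum is over the signed
    correlation on the lag grid.  Positive lag means ``y`` is shifted
    later relative to ``x`` (y lags x).  Ties are broken toward the
    smallest absolute lag, then toward the negative lag.
    """
    lags, rho = lagged_correlations(x, y, tr, cfg)
    valid = np.isfinite(rho)
    lags, rho = lags[valid], rho[valid]
    best = np.max(rho)
    tied = np.where(rho >= best - 1e-12)[0]
    # smallest |lag| first, then negative before positive
    order = sorted(tied, key=lambda i: (abs(lags[i]), lags[i]))
    i = order[0]
    return float(rho[i]), float(lags[i])


def fnc_vector(subject: SubjectComponents, selected, tr: float | None = None,
               cfg: LagSearchConfig | None = None, labels=None,
               prefiltered: bool = False) -> FNCVector:
    """FNC feature vector of one subject.

    Computes, for every pair of the ``selected`` components in canonical
    upper-triangle order, the Fisher z of the maximum lagged correlation
    of their (bandpassed, interpolated) time-courses, along with the lag
    at which the maximum occurred.
    """
    cfg = cfg or LagSearchConfig()
    tr = tr if tr is not None else subject.tr
    selected = list(selected)
    bad = [i for i in selected if not 0 <= i < subject.n_components]
    if bad:
        raise ValueError(f"invalid component indices {bad}")
    tcs = subject.tcs[:, selected]
    if not prefiltered:
        tcs = bandpass(tcs, tr, cfg)
    pairs = canonical_pairs(len(selected))
    z = np.empty(len(pairs))
    lag = np.empty(len(pairs))
    for p, (a, b) in enumerate(pairs):
        r, l = max_lagged_correlation(tcs[:, a], tcs[:, b], tr, cfg)
        if abs(r) >= 1.0:
            warnings.warn("|rho| = 1 clipped before Fisher transform")
            r = np.sign(r) * (1.0 - 1e-7)
        z[p] = np.arctanh(r)
        lag[p] = l
    pair_labels = []
    if labels is not None:
        labels = list(labels)
        pair_labels = [f"{labels[a]}_{labels[b]}" for a, b in pairs]
    return FNCVector(z_values=z, lags=lag, pair_index=pairs,
                     subject_id=subject.subject_id, pair_labels=pair_labels)


def cohort_features(vectors) -> "np.ndarray":
    """Stack per-subject FNC vectors into a (subjects x pairs) matrix."""
    vectors = list(vectors)
    ref = vectors[0].pair_index
    for v in vectors[1:]:
        if v.pair_index != ref:
            raise ValueError("FNC vectors have inconsistent pair ordering")
    return np.vstack([v.z_values for v in vectors])


def motion_summary(motion: np.ndarray) -> np.ndarray:
    """Per-subject scalar summary of a (T, 6) motion table: the mean
    absolute first difference of each of the six parameters."""
    motion = np.asarray(motion, float)
    return np.abs(np.diff(motion, axis=0)).mean(axis=0)


def regress_nuisance(features: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residualize cohort features on nuisance covariates.

    Per feature column, ordinary least-squares residuals after regressing
    on the covariates plus an intercept; the fitted intercept is added
    back so that the features keep their level (a feature that is an
    exact linear function of the covariates residualizes to its
    intercept).
    """
    reg = NuisanceRegressor().fit(features, covariates)
    return reg.transform(features, covariates)


class NuisanceRegressor:
    """OLS nuisance removal with separate fit/transform.

    Fitting on the training cohort only (and then transforming train and
    test with the same coefficients) keeps test subjects out of the
    coefficient estimation.
    """

    def __init__(self) -> None:
        self.coef_ = None

    @staticmethod
    def _design(covariates: np.ndarray) -> np.ndarray:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        return C

    def fit(self, features: np.ndarray, covariates: np.ndarray) -> "NuisanceRegressor":
        F = np.asarray(features, float)
        C = self._design(covariates)
        if np.isnan(C).any():
            raise ValueError("covariates contain missing values")
        if F.shape[0] < C.shape[1] + 2:
            raise ValueError("need at least c + 2 subjects for c covariates")
        design = np.hstack([np.ones((C.shape[0], 1)), C])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn("rank-deficient covariates; collinear directions dropped")
        beta, *_ = np.linalg.lstsq(design, F, rcond=None)
        self.coef_ = beta[1:]          # intercept stays in the features
        return self

    def transform(self, features: np.ndarray, covariates: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("fit before transform")
        F = np.asarray(features, float)
        C = self._design(covariates)
        return F - C @ self.coef_


def reduce_feature_set(pair_labels, motor_label: str, extra_pair=None,
                       sep: str = "_"):
    """Indices of the features surviving the medication-robustness
    exclusion: every pair containing the motor component is dropped, plus
    one named extra pair; ordering of the survivors is preserved.

    ``pair_labels`` are strings "A_B"; ``extra_pair`` is a (label, label)
    tuple.  Unknown labels are rejected.
    """
    pair_labels = list(pair_labels)
    parts = [tuple(p.split(sep)) for p in pair_labels]
    known = {l for pr in parts for l in pr}
    if motor_label is not None and motor_label not in known:
        raise ValueError(f"unknown motor label {motor_label!r}")
    drop = set()
    if motor_label is not None:
        drop = {i for i, pr in enumerate(parts) if motor_label in pr}
    if extra_pair is not None:
        a, b = extra_pair
        if a not in known or b not in known:
            raise ValueError(f"unknown labels in extra pair {extra_pair!r}")
        hit = [i for i, pr in enumerate(parts) if set(pr) == {a, b}]
        if not hit:
            raise ValueError(f"pair {extra_pair!r} not present")
        drop |= set(hit)
    return [i for i in range(len(pair_labels)) if i not in drop]
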