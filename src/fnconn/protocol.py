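"""Train/test classification protocol with LOOCV hyperparameter selection.

The end-to-end protocol mirrors a leakage-safe two-group study design:
the cohort is split once into disjoint training and test sets; group ICA,
component selection, nuisance-regression coefficients and all
hyperparameter choices use training subjects only; a second, independent
ICA is fitted on the test subjects and its components are matched to the
training decomposition before test features are extracted.  Performance
is reported per classifier as a confusion matrix, accuracy, sensitivity,
specificity, PPV, NPV and a Wilson score interval on accuracy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fnconn.classifiers import Classifier, default_roster
from fnconn.fnc import (
    LagSearchConfig,
    NuisanceRegressor,
    cohort_features,
    fnc_vector,
    motion_summary,
    reduce_feature_set,
)
from fnconn.gica import GroupICA
from fnconn.netsel import TemplateSet, match_components, select_components

__all__ = [
    "LabeledFeatures",
    "EvalReport",
    "ProtocolResult",
    "split_cohort",
    "loocv_grid_search",
    "train_predict",
    "evaluate",
    "wilson_interval",
    "run_protocol",
]


@dataclass
class LabeledFeatures:
    """Feature matrix with binary labels (0 = control, 1 = patient)."""

    matrix: np.ndarray
    labels: np.ndarray
    subject_ids: list
    feature_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.labels = np.asarray(self.labels).astype(int)
        if np.isnan(self.matrix).any():
            raise ValueError("features contain missing values")
        if len(np.unique(self.labels)) != 2:
            raise ValueError("both classes must be present")

    def subset(self, idx) -> "LabeledFeatures":
        idx = np.asarray(idx, int)
        return LabeledFeatures(self.matrix[idx], self.labels[idx],
                               [self.subject_ids[i] for i in idx],
                               self.feature_names)


def split_cohort(labels, n_train_per_class: int, seed: int = 0):
    """Stratified random train/test split of subject indices.

    Returns ``(train_idx, test_idx)``, disjoint and reproducible for a
    fixed seed; all subjects not drawn into training go to test.
    """
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    train = []
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        if len(idx) <= n_train_per_class:
            raise ValueError(
                f"class {c} has {len(idx)} subjects, cannot hold out a test "
                f"set after taking {n_train_per_class} for training"
            )
        train.extend(rng.permutation(idx)[:n_train_per_class])
    train = np.sort(np.asarray(train))
    test = np.setdiff1d(np.arange(len(labels)), train)
    return train, test


def loocv_grid_search(X, y, classifier: Classifier, grid):
    """Leave-one-out hyperparameter selection on the training set.

    For each grid point the classifier is refitted once per training
    subject (n folds = n subjects) and scored on the held-out subject;
    the point minimizing the mean validation error wins, ties resolving
    to the earliest grid entry (grids are ordered simple-to-complex).

    Returns ``(best_params, best_error, errors_per_point)``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    n = len(y)
    errors = []
    for params in grid:
        wrong = 0
        degenerate = False
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            try:
                clf = classifier.clone_with(**params).fit(X[mask], y[mask])
                wrong += int(clf.predict(X[i:i + 1])[0] != y[i])
            except Exception:
                degenerate = True
                break
        errors.append(np.inf if degenerate else wrong / n)
    errors = np.asarray(errors)
    if not np.isfinite(errors).any():
        warnings.warn("all grid points degenerate; keeping the first")
        best = 0
    else:
        best = int(np.argmin(errors))          # argmin takes the first minimum
    return dict(grid[best]), float(errors[best]), errors


def train_predict(classifier: Classifier, train: LabeledFeatures,
                  test: LabeledFeatures):
    """Fit on the training set and predict the test set labels."""
    if train.matrix.shape[1] != test.matrix.shape[1]:
        raise ValueError("train/test feature spaces differ")
    clf = classifier.fit(train.matrix, train.labels)
    return clf.predict(test.matrix)


def wilson_interval(k: int, n: int, conf: float = 0.95):
    """Wilson score interval for a binomial proportion k/n."""
    from scipy.stats import norm

    if n <= 0:
        raise ValueError("n must be positive")
    z = norm.ppf(0.5 + conf / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    # clamp to [0, 1] and guard the p-in-interval invariant against
    # floating-point round-off at k = 0 or k = n
    return min(max(center - half, 0.0), p), max(min(center + half, 1.0), p)


@dataclass
class EvalReport:
    """Test-set performance of one classifier."""

    classifier: str
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    wilson_low: float
    wilson_high: float
    chosen_hyperparameters: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "classifier", "tp", "fp", "tn", "fn", "accuracy", "sensitivity",
            "specificity", "ppv", "npv", "wilson_low", "wilson_high", "seed")}
        d["chosen_hyperparameters"] = dict(self.chosen_hyperparameters)
        return d


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def evaluate(predictions, truth, positive_class: int = 1,
             classifier: str = "classifier", chosen=None,
             seed=None) -> EvalReport:
    """Confusion-matrix metrics with a Wilson interval on accuracy.

    The patient class is positive by convention.  Undefined ratios (zero
    denominator) are reported as NaN, never as 0.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions/truth length mismatch")
    pos_p = predictions == positive_class
    pos_t = truth == positive_class
    tp = int(np.sum(pos_p & pos_t))
    fp = int(np.sum(pos_p & ~pos_t))
    tn = int(np.sum(~pos_p & ~pos_t))
    fn = int(np.sum(~pos_p & pos_t))
    n = len(truth)
    lo, hi = wilson_interval(tp + tn, n)
    return EvalReport(
        classifier=classifier, tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        wilson_low=lo, wilson_high=hi,
        chosen_hyperparameters=dict(chosen or {}), seed=seed)


@dataclass
class ProtocolResult:
    """Outcome of the end-to-end split/ICA/FNC/classification protocol."""

    reports: list                      # list of EvalReport
    train: LabeledFeatures
    test: LabeledFeatures
    selection: object                  # SelectionResult on the training ICA
    matching: dict                     # train->test component matching
    provenance: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            d = r.to_dict()
            d["parameters"] = ", ".join(f"{k}={v}" for k, v in
                                        d.pop("chosen_hyperparameters").items())
            rows.append(d)
        return pd.DataFrame(rows).set_index("classifier")

    def summary(self) -> str:
        df = self.to_frame()
        cols = ["accuracy", "sensitivity", "specificity", "ppv", "npv",
                "wilson_low", "wilson_high", "parameters"]
        lines = [
            "Classification protocol",
            "=" * 60,
            f"train subjects: {len(self.train.labels)}   "
            f"test subjects: {len(self.test.labels)}   "
            f"features: {self.train.matrix.shape[1]}",
            "",
            df[cols].to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


def _features_for(components_list, selected, labels, tr, cfg):
    vectors = [fnc_vector(c, selected, tr=tr, cfg=cfg, labels=labels)
               for c in components_list]
    return cohort_features(vectors), vectors[0].pair_labels


def cohort_fnc_features(cohort, templates: TemplateSet | None = None,
                        n_components: int | None = None, d1: int | None = None,
                        cfg: LagSearchConfig | None = None, seed: int = 0,
                        n_ica_runs: int = 5, regress_motion: bool = True):
    """All-subject group ICA -> selection -> back-reconstruction -> FNC.

    The descriptive group-statistics route (no train/test split): fits one
    group ICA on the whole cohort, selects components against the
    templates (the generator's ground-truth maps by default), extracts
    each subject's FNC vector and optionally regresses motion summaries
    out across subjects.

    Returns ``(features, pair_labels, selection)`` with ``features`` of
    shape (subjects, pairs) in Fisher-z units.
    """
    cfg = cfg or LagSearchConfig()
    if templates is None:
        templates = TemplateSet(
            templates={f"IC{k}": m for k, m in enumerate(cohort.truth.spatial_maps)})
    K = n_components or cohort.truth.n_components
    res = GroupICA(cohort.scans, n_components=K, d1=d1).fit(seed=seed,
                                                            n_runs=n_ica_runs)
    selection = select_components(res, templates)
    comps = [res.back_reconstruct(s) for s in cohort.scans]
    tr = cohort.scans[0].tr
    F, _ = _features_for(comps, selection.indices, selection.labels, tr, cfg)
    if regress_motion and cohort.motion:
        covs = np.vstack([motion_summary(m) for m in cohort.motion])
        F = NuisanceRegressor().fit(F, covs).transform(F, covs)
    pair_labels = [f"{selection.labels[a]}_{selection.labels[b]}"
                   for a in range(len(selection.labels))
                   for b in range(a + 1, len(selection.labels))]
    return F, pair_labels, selection


def run_protocol(cohort, templates: TemplateSet | None = None,
                 roster=None, feature_variant: str = "full",
                 n_train_per_class: int = 16, n_components: int | None = None,
                 d1: int | None = None,
                 cfg: LagSearchConfig | None = None, seed: int = 0,
                 n_ica_runs: int = 5, regress_motion: bool = True,
                 regress_age: bool = False, motor_label: str | None = None,
                 extra_pair=None) -> ProtocolResult:
    """Run the full classification protocol on a cohort.

    Stages: stratified split -> training-set group ICA -> template
    component selection -> back-reconstruction and FNC features ->
    (optional) nuisance regression fitted on training subjects ->
    independent test-set ICA matched to training components -> LOOCV
    hyperparameter search -> test-set evaluation.

    ``feature_variant='reduced'`` additionally drops every pair involving
    ``motor_label`` plus the one ``extra_pair``, mirroring the
    medication-robustness analysis.
    """
    cfg = cfg or LagSearchConfig()
    if templates is None:
        templates = TemplateSet(
            templates={f"IC{k}": m for k, m in enumerate(cohort.truth.spatial_maps)})
    if feature_variant not in ("full", "reduced"):
        raise ValueError(f"unknown feature variant {feature_variant!r}")

    def stage(name):
        return f"protocol stage '{name}' failed"

    rng = np.random.default_rng(seed)
    split_seed, ica_seed_train, ica_seed_test = rng.integers(0, 2**31 - 1, 3)

    train_idx, test_idx = split_cohort(cohort.labels, n_train_per_class,
                                       seed=int(split_seed))
    tr = cohort.scans[0].tr
    K = n_components or cohort.truth.n_components

    # --- training-side ICA + selection
    try:
        train_model = GroupICA([cohort.scans[i] for i in train_idx],
                               n_components=K, d1=d1)
        train_res = train_model.fit(seed=int(ica_seed_train), n_runs=n_ica_runs)
    except Exception as e:
        raise RuntimeError(stage("train ICA")) from e
    selection = select_components(train_res, templates)
    if len(selection.indices) < 2:
        raise RuntimeError(stage("component selection")
                           + f": only {len(selection.indices)} components matched")

    # --- training features
    try:
        train_comps = [train_res.back_reconstruct(cohort.scans[i]) for i in train_idx]
        F_train, pair_labels = _features_for(train_comps, selection.indices,
                                             selection.labels, tr, cfg)
    except Exception as e:
        raise RuntimeError(stage("train FNC")) from e

    # --- test-side ICA, matched to training
    try:
        test_model = GroupICA([cohort.scans[i] for i in test_idx],
                              n_components=K, d1=d1)
        test_res = test_model.fit(seed=int(ica_seed_test), n_runs=n_ica_runs)
    except Exception as e:
        raise RuntimeError(stage("test ICA")) from e
    matching = match_components(train_res, test_res, selection.indices)
    test_selected = [matching["mapping"][i] for i in selection.indices]
    signs = np.array([matching["sign"][i] for i in selection.indices], float)

    try:
        test_comps = []
        for i in test_idx:
            c = test_res.back_reconstruct(cohort.scans[i])
            c.tcs = c.tcs[:, test_selected] * signs[None, :]
            c.maps = c.maps[test_selected] * signs[:, None]
            test_comps.append(c)
        F_test, _ = _features_for(test_comps, list(range(len(test_selected))),
                                  selection.labels, tr, cfg)
    except Exception as e:
        raise RuntimeError(stage("test FNC")) from e

    # --- nuisance regression (coefficients from training subjects only)
    covs_train, covs_test = [], []
    if regress_motion:
        covs_train.append(np.vstack([motion_summary(cohort.motion[i]) for i in train_idx]))
        covs_test.append(np.vstack([motion_summary(cohort.motion[i]) for i in test_idx]))
    if regress_age:
        age = cohort.covariates["age"].to_numpy(float)
        covs_train.append(age[train_idx, None])
        covs_test.append(age[test_idx, None])
    if covs_train:
        reg = NuisanceRegressor().fit(F_train, np.hstack(covs_train))
        F_train = reg.transform(F_train, np.hstack(covs_train))
        F_test = reg.transform(F_test, np.hstack(covs_test))

    # --- feature variant
    if feature_variant == "reduced":
        keep = reduce_feature_set(pair_labels, motor_label, extra_pair)
        F_train, F_test = F_train[:, keep], F_test[:, keep]
        pair_labels = [pair_labels[i] for i in keep]

    train = LabeledFeatures(F_train, cohort.labels[train_idx],
                            [cohort.scans[i].subject_id for i in train_idx],
                            pair_labels)
    test = LabeledFeatures(F_test, cohort.labels[test_idx],
                           [cohort.scans[i].subject_id for i in test_idx],
                           pair_labels)

    # --- classify
    if roster is None:
        roster = default_roster(train.matrix, seed=seed)
    reports = []
    for clf, grid in roster:
        try:
            chosen = {}
            if grid:
                chosen, _, _ = loocv_grid_search(train.matrix, train.labels,
                                                 clf, grid)
                clf = clf.clone_with(**chosen)
            pred = train_predict(clf, train, test)
        except Exception as e:
            raise RuntimeError(stage(f"classifier {clf.name}")) from e
        reports.append(evaluate(pred, test.labels, classifier=clf.name,
                                chosen=chosen, seed=seed))

    provenance = {
        "seed": int(seed),
        "split_seed": int(split_seed),
        "ica_seed_train": int(ica_seed_train),
        "ica_seed_test": int(ica_seed_test),
        "ica_seeds_train": list(train_res.stability.seeds),
        "ica_seeds_test": list(test_res.stability.seeds),
        "train_ids": [cohort.scans[i].subject_id for i in train_idx],
        "test_ids": [cohort.scans[i].subject_id for i in test_idx],
        "feature_variant": feature_variant,
        "n_components": int(K),
        "regress_motion": bool(regress_motion),
        "regress_age": bool(regress_age),
    }
    return ProtocolResult(reports=reports, train=train, test=test,
                          selection=selection, matching=matching,
                          provenance=provenance)
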