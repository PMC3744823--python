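"""Group-level descriptive statistics on FNC features.

Within-group one-sample t-tests (is each pair's mean z nonzero?),
between-group two-sample t-tests (pooled variance by default), and
Benjamini-Hochberg FDR correction.  These tests are descriptive only and
are never used for feature selection upstream of classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult",
    "one_sample_t",
    "two_sample_t",
    "two_sample_t_from_stats",
    "fdr_correct",
    "group_difference",
    "plot_fnc_matrix",
]


@dataclass
class GroupTestResult:
    """Per-pair test results, FDR-corrected."""

    mean_g1: np.ndarray
    t_value: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    mean_g2: np.ndarray | None = None
    difference: np.ndarray | None = None       # group1 - group2 mean
    q: float = 0.05
    pair_labels: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        d = {"mean_g1": self.mean_g1, "t": self.t_value, "p": self.p_value,
             "significant": self.significant}
        if self.mean_g2 is not None:
            d["mean_g2"] = self.mean_g2
            d["difference"] = self.difference
        idx = self.pair_labels if self.pair_labels else None
        return pd.DataFrame(d, index=idx)


def _degenerate_p(mean: np.ndarray) -> np.ndarray:
    """Zero-variance convention: p = 0 if the mean differs from the null,
    else 1."""
    return np.where(np.abs(mean) > 0, 0.0, 1.0)


def one_sample_t(features: np.ndarray, group_mask=None, q: float = 0.05,
                 pair_labels=None) -> GroupTestResult:
    """Per-pair one-sample t-test of zero mean within one group.

    ``features`` is (subjects x pairs); ``group_mask`` selects the group's
    rows (all rows if omitted).  Zero-variance columns fall back to the
    degenerate convention (p = 0 for nonzero mean, 1 otherwise) with a
    warning.
    """
    F = np.asarray(features, float)
    if group_mask is not None:
        F = F[np.asarray(group_mask, bool)]
    n = F.shape[0]
    if n < 2:
        raise ValueError("group size must be >= 2")
    mean = F.mean(axis=0)
    sd = F.std(axis=0, ddof=1)
    degenerate = sd < 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    if degenerate.any():
        warnings.warn("zero-variance feature column(s) in one-sample t-test")
        t = np.where(degenerate, np.where(np.abs(mean) > 0, np.inf, 0.0), t)
        p = np.where(degenerate, _degenerate_p(mean), p)
    sig, _ = fdr_correct(p, q)
    return GroupTestResult(mean_g1=mean, t_value=t, p_value=p, significant=sig,
                           q=q, pair_labels=list(pair_labels or []))


def two_sample_t(features: np.ndarray, mask1, mask2, pooled: bool = True,
                 q: float = 0.05, pair_labels=None) -> GroupTestResult:
    """Per-pair two-sample t-test between two groups.

    Pooled-variance (Student) by default — the groups are equal-sized by
    design — with Welch available via ``pooled=False``.  The reported
    difference is group1 − group2.
    """
    F = np.asarray(features, float)
    F1 = F[np.asarray(mask1, bool)]
    F2 = F[np.asarray(mask2, bool)]
    if F1.shape[0] < 2 or F2.shape[0] < 2:
        raise ValueError("each group must have >= 2 subjects")
    res = sps.ttest_ind(F1, F2, axis=0, equal_var=pooled)
    t, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    mean1, mean2 = F1.mean(axis=0), F2.mean(axis=0)
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn("zero-variance feature column(s) in two-sample t-test")
        diff = mean1 - mean2
        t = np.where(bad, np.where(np.abs(diff) > 0, np.inf * np.sign(diff), 0.0), t)
        p = np.where(bad, _degenerate_p(diff), p)
    sig, _ = fdr_correct(p, q)
    return GroupTestResult(mean_g1=mean1, mean_g2=mean2, t_value=t, p_value=p,
                           significant=sig, difference=mean1 - mean2, q=q,
                           pair_labels=list(pair_labels or []))


def two_sample_t_from_stats(mean1, sd1, n1, mean2, sd2, n2):
    """Pooled two-sample t-test from summary statistics; returns (t, p)."""
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=True)
    return float(res.statistic), float(res.pvalue)


def fdr_correct(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up at level ``q``.

    Returns
    -------
    significant : boolean array (input order)
    threshold : the largest rejected p-value (0.0 when nothing is rejected)
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    thresh = float(p[reject].max()) if reject.any() else 0.0
    return reject, thresh


def group_difference(features: np.ndarray, labels, q: float = 0.05,
                     pair_labels=None) -> dict:
    """Convenience bundle: within-group one-sample tests and the
    between-group two-sample test (control = label 0, patient = 1)."""
    labels = np.asarray(labels)
    m1, m2 = labels == 0, labels == 1
    return {
        "group1": one_sample_t(features, m1, q=q, pair_labels=pair_labels),
        "group2": one_sample_t(features, m2, q=q, pair_labels=pair_labels),
        "between": two_sample_t(features, m1, m2, q=q, pair_labels=pair_labels),
    }


def plot_fnc_matrix(values, pair_index, n_components, component_labels=None,
                    significant=None, ax=None, title=None, cmap="coolwarm"):
    """Heatmap of a per-pair statistic arranged as a component x component
    matrix (the layout used for mean-correlation / t-value figures);
    significant pairs are circled."""
    import matplotlib.pyplot as plt

    M = np.full((n_components, n_components), np.nan)
    for v, (i, j) in zip(values, pair_index):
        M[i, j] = M[j, i] = v
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    vmax = np.nanmax(np.abs(M)) or 1.0
    im = ax.imshow(M, cmap=cmap, vmin=-vmax, vmax=vmax)
    if significant is not None:
        for s, (i, j) in zip(significant, pair_index):
            if s:
                ax.scatter([j, i], [i, j], facecolors="none", edgecolors="k", s=120)
    ticks = range(n_components)
    ax.set_xticks(ticks)
    ax.set_yticks(ticks)
    if component_labels is not None:
        ax.set_xticklabels(component_labels, rotation=90)
        ax.set_yticklabels(component_labels)
    if title:
        ax.set_title(title)
    plt.colorbar(im, ax=ax)
    return ax
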