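"""Group spatial ICA with PCA back-reconstruction.

The decomposition follows the standard temporal-concatenation group ICA
scheme for fMRI: each subject's (timepoints x voxels) matrix is reduced by
a subject-level temporal PCA, the reduced matrices are stacked over
subjects and reduced again to the model order K (estimated by the minimum
description length criterion when not given), and the whitened group data
are unmixed by Infomax ICA.  Decomposition reliability is assessed
ICASSO-style by repeating ICA from several random starts and clustering
the pooled components; the final components are cluster centrotypes.
Subject-specific maps and time-courses are recovered by propagating the
group mixing matrix back through each subject's PCA reducer (PCA
compression and projection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from fnconn.datatypes import SubjectComponents, SubjectScan

__all__ = [
    "SubjectReducer",
    "StabilityReport",
    "GroupICA",
    "GroupICAResults",
    "reduce_subject",
    "estimate_order_mdl",
    "infomax_ica",
    "icasso_stability",
    "back_reconstruct",
    "amari_index",
]


# ---------------------------------------------------------------------------
# subject-level PCA


@dataclass
class SubjectReducer:
    """Temporal PCA reducer of one subject (kept for back-reconstruction)."""

    basis: np.ndarray          # (T, d1), orthonormal columns
    eigenvalues: np.ndarray    # (d1,)
    total_variance: float
    subject_id: str

    @property
    def explained_variance_ratio(self) -> float:
        return float(self.eigenvalues.sum() / self.total_variance)


def reduce_subject(scan: SubjectScan, d1: int):
    """Reduce a scan's time dimension to its ``d1`` dominant principal
    directions.

    The data are time-demeaned per voxel; the reducer basis holds the top
    eigenvectors of the temporal covariance and is retained so that
    subject maps and time-courses can later be back-reconstructed.

    Returns
    -------
    reduced : ndarray, shape (d1, voxels)
    reducer : SubjectReducer
    """
    T = scan.n_timepoints
    if d1 > T:
        raise ValueError(f"d1={d1} exceeds the number of timepoints {T}")
    X = scan.data - scan.data.mean(axis=0, keepdims=True)
    C = (X @ X.T) / scan.n_voxels
    lam, U = np.linalg.eigh(C)
    order = np.argsort(lam)[::-1][:d1]
    lam, U = lam[order], U[:, order]
    reduced = U.T @ X
    reducer = SubjectReducer(basis=U, eigenvalues=np.clip(lam, 0.0, None),
                             total_variance=float(np.trace(C)),
                             subject_id=scan.subject_id)
    return reduced, reducer


# ---------------------------------------------------------------------------
# MDL model order


def estimate_order_mdl(data: np.ndarray, max_order: int | None = None) -> int:
    """Estimate the number of sources by the minimum description length
    criterion on the eigenvalue spectrum.

    ``data`` is (channels, samples); the criterion balances the log ratio
    of arithmetic to geometric mean of the trailing eigenvalues (the
    Gaussian log-likelihood of an isotropic noise floor) against the
    parameter-count penalty ``0.5 k (2p - k + 1) ln N``.

    Returns the argmin order; a degenerate (flat) spectrum returns 0 with
    a warning.
    """
    X = np.asarray(data, float)
    p, N = X.shape
    if N <= p:
        warnings.warn(
            f"MDL with {N} samples for {p} channels is unreliable (need N > p)"
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    lam = np.linalg.eigvalsh((Xc @ Xc.T) / N)[::-1]
    lam = np.clip(lam, 1e-300, None)
    if lam.max() / lam.min() < 1.0 + 1e-9:
        warnings.warn("degenerate (flat) eigenvalue spectrum; returning order 0")
        return 0
    kmax = p - 1 if max_order is None else min(max_order, p - 1)
    loglam = np.log(lam)
    mdl = np.empty(kmax + 1)
    for k in range(kmax + 1):
        tail = lam[k:]
        am = tail.mean()
        log_gm = loglam[k:].mean()
        mdl[k] = N * (p - k) * (np.log(am) - log_gm) \
            + 0.5 * k * (2 * p - k + 1) * np.log(N)
    return int(np.argmin(mdl))


# ---------------------------------------------------------------------------
# Infomax ICA


def _fix_signs(sources: np.ndarray, unmixing: np.ndarray):
    """Flip each component so its largest-|value| sample is positive."""
    idx = np.argmax(np.abs(sources), axis=1)
    signs = np.sign(sources[np.arange(sources.shape[0]), idx])
    signs[signs == 0] = 1.0
    return sources * signs[:, None], unmixing * signs[:, None]


def infomax_ica(X: np.ndarray, seed: int = 0, learning_rate: float = 0.1,
                max_iter: int = 500, tol: float = 1e-6):
    """Infomax ICA with the logistic nonlinearity and natural-gradient
    updates, on whitened data.

    Parameters
    ----------
    X : ndarray, shape (K, samples)
        Whitened data (unit covariance).
    seed : int
        Seed of the random orthonormal initial unmixing matrix.

    Returns
    -------
    unmixing : (K, K); mixing : (K, K), its inverse;
    sources : (K, samples); converged : bool; n_iter : int

    Notes
    -----
    The learning rate is annealed when successive natural-gradient
    directions oscillate (negative inner product); components are
    sign-fixed so that each source's largest-magnitude value is positive.
    Non-convergence returns the best iterate with ``converged=False``.
    """
    K, N = X.shape
    rng = np.random.default_rng(seed)
    W = np.linalg.qr(rng.standard_normal((K, K)))[0]
    lr = learning_rate
    I = np.eye(K)
    prev_grad = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U = W @ X
        Y = 1.0 / (1.0 + np.exp(-U))
        grad = (I + (1.0 - 2.0 * Y) @ U.T / N) @ W
        if prev_grad is not None:
            cos = np.sum(grad * prev_grad) / (
                np.linalg.norm(grad) * np.linalg.norm(prev_grad) + 1e-30)
            if cos < 0.5:           # successive directions diverge by > 60 deg
                lr *= 0.9
        prev_grad = grad
        step = lr * grad
        W = W + step
        if np.linalg.norm(step) / max(np.linalg.norm(W), 1e-12) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"Infomax did not converge in {max_iter} iterations")
    sources = W @ X
    sources, W = _fix_signs(sources, W)
    mixing = np.linalg.inv(W)
    return W, mixing, sources, converged, it


def amari_index(P: np.ndarray) -> float:
    """Amari separation index of a product ``P = W_est @ A_true``.

    0 for a perfect separation (P a scaled permutation), normalized to at
    most 1; invariant to row/column permutation and scaling.
    """
    P = np.abs(np.asarray(P, float))
    K = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * K * (K - 1)))


# ---------------------------------------------------------------------------
# ICASSO-style stability


@dataclass
class StabilityReport:
    """Repeated-run ICA stability summary.

    ``cluster_quality[k]`` is the mean intra-cluster minus mean
    extra-cluster absolute spatial correlation of cluster k, in [0, 1] for
    compact well-separated clusters.  ``centroid_assignments[r, c]`` is
    the cluster that run r's component c fell into.
    """

    n_runs: int
    cluster_quality: np.ndarray
    centroid_assignments: np.ndarray
    seeds: list = field(default_factory=list)
    low_stability: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "cluster_quality": np.asarray(self.cluster_quality).tolist(),
            "centroid_assignments": np.asarray(self.centroid_assignments).tolist(),
            "seeds": [int(s) for s in self.seeds],
            "low_stability": [int(c) for c in self.low_stability],
        }


def icasso_stability(X: np.ndarray, n_components: int, n_runs: int = 10,
                     seeds=None, **ica_kwargs):
    """Repeat Infomax from ``n_runs`` random starts and cluster the pooled
    components by absolute spatial correlation.

    Components are clustered by average-linkage agglomeration on
    ``1 - |r|`` cut at ``n_components`` clusters; each cluster's
    centrotype (the member with maximal summed intra-cluster similarity)
    becomes a final component.

    Returns
    -------
    report : StabilityReport
    centrotypes : ndarray (n_components, samples), sign-fixed
    unmixing : ndarray (n_components, K) mapping the whitened input to the
        centrotype sources.
    """
    if seeds is None:
        seeds = list(range(n_runs))
    seeds = list(seeds)
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    K = n_components
    runs = [infomax_ica(X, seed=s, **ica_kwargs) for s in seeds]
    pooled = np.vstack([r[2] for r in runs])             # (n_runs*K, N)
    pooled_W = np.vstack([r[0] for r in runs])

    if n_runs == 1:
        warnings.warn("single-run stability is degenerate; quality set to 1.0")
        report = StabilityReport(
            n_runs=1, cluster_quality=np.ones(K),
            centroid_assignments=np.arange(K)[None, :], seeds=seeds)
        return report, runs[0][2], runs[0][0]

    Z = pooled - pooled.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    Z = Z / norms
    S = np.abs(Z @ Z.T)                                  # similarity
    np.fill_diagonal(S, 1.0)
    D = squareform(np.clip(1.0 - S, 0.0, None), checks=False)
    labels = fcluster(linkage(D, method="average"), t=K, criterion="maxclust") - 1
    n_found = len(np.unique(labels))
    low_stability = []
    if n_found < K:
        warnings.warn(f"only {n_found} clusters found for {K} components")
        low_stability = list(range(n_found, K))

    quality = np.full(K, np.nan)
    centro_idx = np.full(K, -1, dtype=int)
    for c in range(n_found):
        members = np.where(labels == c)[0]
        others = np.where(labels != c)[0]
        Sin = S[np.ix_(members, members)]
        intra = 1.0 if len(members) == 1 else \
            (Sin.sum() - len(members)) / (len(members) * (len(members) - 1))
        extra = S[np.ix_(members, others)].mean() if len(others) else 0.0
        quality[c] = intra - extra
        centro_idx[c] = members[np.argmax(Sin.sum(axis=1))]
    # order clusters by quality (most stable first) for a deterministic output
    found = np.argsort(-np.nan_to_num(quality, nan=-np.inf))[:n_found]
    quality = quality[found]
    centro_idx = centro_idx[found]
    relabel = {int(old): new for new, old in enumerate(found)}
    assignments = np.array([relabel.get(int(l), -1) for l in labels]).reshape(n_runs, K)

    centrotypes = pooled[centro_idx]
    unmixing = pooled_W[centro_idx]
    centrotypes, unmixing = _fix_signs(centrotypes, unmixing)
    report = StabilityReport(n_runs=n_runs, cluster_quality=quality,
                             centroid_assignments=assignments, seeds=seeds,
                             low_stability=low_stability)
    return report, centrotypes, unmixing


# ---------------------------------------------------------------------------
# model / results


class GroupICA:
    """Group spatial ICA model for a multi-subject cohort.

    Parameters
    ----------
    scans : sequence of SubjectScan
        Subjects on a common grid/mask and TR.
    n_components : int, optional
        Model order K; estimated by MDL on the concatenated reduced data
        when omitted.
    d1 : int, optional
        Subject-level PCA dimension (default 80, clamped to T−1 for short
        desk-scale runs).
    max_order : int, optional
        Cap on the MDL search.

    Examples
    --------
    >>> model = GroupICA(scans, n_components=9)
    >>> res = model.fit(seed=0, n_runs=10)
    >>> subj = res.back_reconstruct(scans[0])
    """

    def __init__(self, scans, n_components: int | None = None,
                 d1: int | None = None, max_order: int | None = None):
        scans = list(scans)
        if not scans:
            raise ValueError("need at least one scan")
        grid0, mask0, tr0 = scans[0].grid, scans[0].mask, scans[0].tr
        for s in scans[1:]:
            if s.grid != grid0 or not np.array_equal(s.mask, mask0):
                raise ValueError(f"scan {s.subject_id}: grid/mask mismatch")
        self.scans = scans
        self.tr = tr0
        self.grid, self.mask = grid0, mask0
        T = scans[0].n_timepoints
        self.d1 = min(d1 if d1 is not None else 80, T - 1)
        self.n_components = n_components
        self.max_order = max_order

    def fit(self, seed: int = 0, n_runs: int = 10, **ica_kwargs) -> "GroupICAResults":
        reduced, reducers = [], []
        for scan in self.scans:
            r, red = reduce_subject(scan, self.d1)
            reduced.append(r)
            reducers.append(red)
        R = np.vstack(reduced)                       # (M*d1, V)

        K = self.n_components
        if K is None:
            K = estimate_order_mdl(R, max_order=self.max_order)
            if K < 1:
                raise ValueError("MDL estimated order < 1; supply n_components")
        self.n_components = K

        V = R.shape[1]
        Rc = R - R.mean(axis=1, keepdims=True)
        C = (Rc @ Rc.T) / V
        lam, U = np.linalg.eigh(C)
        order = np.argsort(lam)[::-1][:K]
        lam, U = np.clip(lam[order], 1e-12, None), U[:, order]
        whitener = (U / np.sqrt(lam)).T              # (K, M*d1)
        G = whitener @ Rc                            # whitened, unit covariance

        seeds = [seed + r for r in range(n_runs)]
        stability, centrotypes, unmix = icasso_stability(
            G, K, n_runs=n_runs, seeds=seeds, **ica_kwargs)
        mixing = np.linalg.pinv(unmix)

        maps = centrotypes
        zmaps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
        dewhiten = U * np.sqrt(lam)                  # (M*d1, K)
        return GroupICAResults(
            model=self, subject_reducers=reducers, whitener=whitener,
            dewhiten=dewhiten, unmixing=unmix, mixing=mixing,
            group_maps=zmaps, raw_sources=maps, order_K=K,
            stability=stability, seed=seed)


@dataclass
class GroupICAResults:
    """Fitted group ICA: reducers, unmixing/mixing, maps, stability."""

    model: GroupICA
    subject_reducers: list
    whitener: np.ndarray       # (K, M*d1)
    dewhiten: np.ndarray       # (M*d1, K)
    unmixing: np.ndarray       # (K, K) on whitened group data
    mixing: np.ndarray         # (K, K)
    group_maps: np.ndarray     # (K, V), z-scored over mask
    raw_sources: np.ndarray    # (K, V), unscaled centrotype sources
    order_K: int
    stability: StabilityReport
    seed: int = 0

    @property
    def d1(self) -> int:
        return self.model.d1

    def _subject_block(self, s: int) -> np.ndarray:
        """De-reduction block G_s A (d1 x K) of subject s."""
        return self.dewhiten[s * self.d1:(s + 1) * self.d1, :] @ self.mixing

    @property
    def group_tcs(self) -> np.ndarray:
        """Aggregate time-courses: subject back-reconstructed TCs stacked
        over subjects, (M*T, K)."""
        return np.vstack([
            self.back_reconstruct(scan).tcs for scan in self.model.scans
        ])

    def back_reconstruct(self, scan: SubjectScan) -> SubjectComponents:
        """Recover subject-specific maps and time-courses by PCA
        compression and projection."""
        return back_reconstruct(self, scan)

    def summary(self) -> str:
        q = np.asarray(self.stability.cluster_quality, float)
        lines = [
            "Group spatial ICA",
            "=" * 44,
            f"subjects:            {len(self.model.scans)}",
            f"subject-level PCA:   d1 = {self.d1}",
            f"model order K:       {self.order_K}",
            f"ICASSO runs:         {self.stability.n_runs}",
            f"stability (min/med): {np.nanmin(q):.3f} / {np.nanmedian(q):.3f}",
            f"seed:                {self.seed}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "order_K": int(self.order_K),
            "d1": int(self.d1),
            "seed": int(self.seed),
            "n_subjects": len(self.model.scans),
            "unmixing": self.unmixing.tolist(),
            "mixing": self.mixing.tolist(),
            "stability": self.stability.to_dict(),
        }


def back_reconstruct(results: GroupICAResults, scan: SubjectScan) -> SubjectComponents:
    """Back-reconstruct one subject's maps and time-courses from a fitted
    group ICA.

    The subject's data are compressed through its stored PCA reducer (or a
    freshly computed one for an unseen scan), the group mixing matrix is
    propagated through the subject's de-reduction block to give subject
    time-courses, and subject maps are the projection of the reduced data
    onto those components, z-scored over the mask.
    """
    if scan.grid != results.model.grid or not np.array_equal(scan.mask, results.model.mask):
        raise ValueError(f"scan {scan.subject_id}: grid/mask mismatch with model")
    ids = [r.subject_id for r in results.subject_reducers]
    if scan.subject_id in ids:
        s = ids.index(scan.subject_id)
        reducer = results.subject_reducers[s]
        X = scan.data - scan.data.mean(axis=0, keepdims=True)
        reduced = reducer.basis.T @ X
        GsA = results._subject_block(s)
    else:
        # unseen scan: project through a fresh reducer and the mean block
        reduced, reducer = reduce_subject(scan, results.d1)
        GsA = np.mean([results._subject_block(s) for s in range(len(ids))], axis=0)
    maps = np.linalg.pinv(GsA) @ reduced              # (K, V)
    tcs = reducer.basis @ GsA                         # (T, K)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    zmaps = (maps - maps.mean(axis=1, keepdims=True)) / sd
    return SubjectComponents(maps=zmaps, tcs=tcs, subject_id=scan.subject_id,
                             tr=scan.tr)
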