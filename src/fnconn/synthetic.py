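"""Synthetic two-group resting-state cohorts with known network ground truth.

The generator emulates the structure of a two-group (control/patient)
resting-state fMRI study: each subject's data is a linear mixture of a few
spatially compact networks whose band-limited time-courses realize a
group-specific lagged correlation structure, plus Gaussian voxel noise and
an optional motion confound.  Because the ground truth (maps, covariances,
lags, labels) is known, every downstream stage — group ICA,
back-reconstruction, lagged-correlation features, group statistics,
classification — can be tested by parameter recovery.

Time-courses are realized with *exact* in-band covariance: the empirical
covariance of the band-limited innovations is whitened before the target
Cholesky factor is applied, so the zero-lag correlation of the generated
time-courses equals the target exactly rather than within sampling error.
Lags are realized by spectral (FFT phase) delays of whole components.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fnconn.datatypes import SubjectScan

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "Cohort",
    "make_ground_truth",
    "generate_cohort",
    "make_group_effect",
]

# latent signals live comfortably inside the 0.017-0.15 Hz analysis band
LATENT_BAND = (0.02, 0.12)


@dataclass
class CohortSpec:
    """Size and sampling parameters of a synthetic cohort.

    Defaults mirror the acquisition conventions of a 5-minute resting run
    sampled at TR = 1.5 s, at a desk-scale voxel grid.
    """

    n_per_group: int = 28
    n_timepoints: int = 200
    tr: float = 1.5
    grid: tuple = (12, 12, 8)
    n_components: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = tuple(int(g) for g in self.grid)
        for name in ("n_per_group", "n_timepoints", "n_components"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(g <= 0 for g in self.grid):
            raise ValueError("grid entries must be positive")
        if self.n_timepoints < 4 * self.n_components:
            raise ValueError(
                "n_timepoints must be at least 4 x n_components "
                f"({self.n_timepoints} < {4 * self.n_components})"
            )

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid))


@dataclass
class GroundTruth:
    """Ground-truth generative parameters of a synthetic cohort.

    Parameters
    ----------
    spatial_maps : ndarray, shape (K, voxels)
        Non-negative-peaked smooth blob weight maps on the flattened grid.
    tc_covariance_per_group : list of ndarray, each (K, K)
        Target zero-lag correlation matrix of the component time-courses
        for each group (symmetric, unit diagonal, positive semidefinite).
    lags_per_pair : dict mapping (i, j) -> float
        Target lag in seconds at which the named pair's correlation peaks
        (positive lag: component j lags component i).  Realized through
        per-component delays, so the pair lags must be mutually consistent.
    noise_sd : float
        Standard deviation of the i.i.d. Gaussian voxel noise, in units of
        the unit-variance component time-courses.
    motion_effect : float
        Coupling of the (per-subject-scaled) motion signal into every
        component time-course; 0 disables the confound.
    subject_variability_sd : float
        SD of band-limited subject-specific time-course perturbations.
    """

    spatial_maps: np.ndarray
    tc_covariance_per_group: list
    lags_per_pair: dict = field(default_factory=dict)
    noise_sd: float = 0.5
    motion_effect: float = 0.0
    subject_variability_sd: float = 0.1
    max_lag: float = 3.0
    overlap_threshold: float = 0.3

    def __post_init__(self) -> None:
        self.spatial_maps = np.asarray(self.spatial_maps, float)
        self.tc_covariance_per_group = [
            np.asarray(c, float) for c in self.tc_covariance_per_group
        ]
        self.validate()

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]

    def validate(self) -> None:
        K = self.n_components
        for g, C in enumerate(self.tc_covariance_per_group):
            if C.shape != (K, K):
                raise ValueError(f"group {g}: covariance shape {C.shape} != ({K},{K})")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError(f"group {g}: covariance target is not symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-10):
                raise ValueError(f"group {g}: covariance target diagonal is not 1")
            lam = np.linalg.eigvalsh(C)
            if lam.min() < -1e-10:
                raise ValueError(
                    f"group {g}: covariance target is not positive semidefinite "
                    f"(min eigenvalue {lam.min():.3g})"
                )
        for (i, j), lag in self.lags_per_pair.items():
            if not (0 <= i < K and 0 <= j < K and i != j):
                raise ValueError(f"invalid pair {(i, j)}")
            if abs(lag) > self.max_lag:
                raise ValueError(
                    f"pair {(i, j)}: |lag| {abs(lag)} exceeds window {self.max_lag}"
                )
        self.component_delays()  # raises if pair lags are inconsistent
        # blob overlap check (identifiability of the spatial ICA)
        Z = self.spatial_maps - self.spatial_maps.mean(axis=1, keepdims=True)
        Z /= np.linalg.norm(Z, axis=1, keepdims=True)
        R = np.abs(Z @ Z.T)
        np.fill_diagonal(R, 0.0)
        if R.max() > self.overlap_threshold:
            i, j = np.unravel_index(np.argmax(R), R.shape)
            warnings.warn(
                f"spatial maps {i} and {j} overlap (|r|={R.max():.2f} > "
                f"{self.overlap_threshold}); ICA identifiability may suffer"
            )

    def component_delays(self) -> np.ndarray:
        """Per-component delays (seconds) realizing ``lags_per_pair``.

        Pair (i, j) with lag L is realized as delay[j] - delay[i] = L.
        Raises if the requested pair lags admit no consistent assignment.
        """
        K = self.n_components
        delay = np.full(K, np.nan)
        for (i, j), lag in sorted(self.lags_per_pair.items()):
            di = 0.0 if np.isnan(delay[i]) else delay[i]
            if np.isnan(delay[i]):
                delay[i] = di
            want = di + lag
            if np.isnan(delay[j]):
                delay[j] = want
            elif abs(delay[j] - want) > 1e-9:
                raise ValueError(
                    f"lags_per_pair are inconsistent at pair {(i, j)}: "
                    f"component {j} would need delay {want} but already has "
                    f"{delay[j]}"
                )
        return np.nan_to_num(delay, nan=0.0)

    def to_json(self) -> str:
        d = {
            "spatial_maps": self.spatial_maps.tolist(),
            "tc_covariance_per_group": [c.tolist() for c in self.tc_covariance_per_group],
            "lags_per_pair": {f"{i},{j}": v for (i, j), v in self.lags_per_pair.items()},
            "noise_sd": self.noise_sd,
            "motion_effect": self.motion_effect,
            "subject_variability_sd": self.subject_variability_sd,
            "max_lag": self.max_lag,
            "overlap_threshold": self.overlap_threshold,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "GroundTruth":
        d = json.loads(s)
        d["spatial_maps"] = np.asarray(d["spatial_maps"])
        d["tc_covariance_per_group"] = [np.asarray(c) for c in d["tc_covariance_per_group"]]
        d["lags_per_pair"] = {
            tuple(int(x) for x in k.split(",")): v for k, v in d["lags_per_pair"].items()
        }
        return cls(**d)


@dataclass
class Cohort:
    """A generated cohort: scans, labels, motion tables, covariates, truth."""

    scans: list                    # list of SubjectScan
    labels: np.ndarray             # 0 = control, 1 = patient
    motion: list                   # per-subject (T, 6) arrays
    covariates: pd.DataFrame       # subject_id, group, age
    truth: GroundTruth
    clean_tcs: list = None         # per-subject noiseless (T, K) component TCs

    @property
    def n_subjects(self) -> int:
        return len(self.scans)

    def save(self, outdir) -> None:
        """Write the cohort to disk: one 4D NIfTI per subject, TSV tables,
        ground truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for scan, mot in zip(self.scans, self.motion):
            scan.to_nifti().to_filename(str(outdir / f"{scan.subject_id}_bold.nii"))
            pd.DataFrame(
                mot, columns=["tx", "ty", "tz", "rx", "ry", "rz"]
            ).to_csv(outdir / f"{scan.subject_id}_motion.tsv", sep="\t", index=False)
        self.covariates.to_csv(outdir / "participants.tsv", sep="\t", index=False)
        (outdir / "ground_truth.json").write_text(self.truth.to_json())

    @classmethod
    def load(cls, indir) -> "Cohort":
        indir = Path(indir)
        cov = pd.read_csv(indir / "participants.tsv", sep="\t")
        truth = GroundTruth.from_json((indir / "ground_truth.json").read_text())
        scans, motion = [], []
        for sid in cov["subject_id"]:
            scans.append(SubjectScan.from_nifti(indir / f"{sid}_bold.nii", subject_id=sid))
            motion.append(
                pd.read_csv(indir / f"{sid}_motion.tsv", sep="\t").to_numpy()
            )
        labels = (cov["group"] == "patient").to_numpy().astype(int)
        return cls(scans=scans, labels=labels, motion=motion, covariates=cov,
                   truth=truth)


# ---------------------------------------------------------------------------
# ground-truth construction helpers


def _gaussian_blob(grid, center, sigmas) -> np.ndarray:
    axes = [np.arange(g, dtype=float) for g in grid]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    d = ((X - center[0]) / sigmas[0]) ** 2 + ((Y - center[1]) / sigmas[1]) ** 2 \
        + ((Z - center[2]) / sigmas[2]) ** 2
    return np.exp(-0.5 * d).ravel()


def make_spatial_maps(grid, n_components, rng, sigma_scale=0.08) -> np.ndarray:
    """Anisotropic Gaussian blobs at quasi-uniform jittered centers.

    Centers are drawn from a shuffled lattice so that blobs stay apart and
    the pairwise spatial correlation remains below the identifiability
    threshold.
    """
    grid = tuple(grid)
    # lattice with enough cells for the requested components
    n_cells = [1, 1, 1]
    while np.prod(n_cells) < n_components:
        n_cells[int(np.argmin(n_cells))] *= 2
    centers = []
    for ix in range(n_cells[0]):
        for iy in range(n_cells[1]):
            for iz in range(n_cells[2]):
                centers.append([
                    (ix + 0.5) * grid[0] / n_cells[0],
                    (iy + 0.5) * grid[1] / n_cells[1],
                    (iz + 0.5) * grid[2] / n_cells[2],
                ])
    centers = np.asarray(centers)
    order = rng.permutation(len(centers))[:n_components]
    maps = []
    for c in centers[order]:
        jitter = rng.uniform(-0.5, 0.5, size=3)
        sig = sigma_scale * np.asarray(grid) * rng.uniform(0.8, 1.2, size=3)
        maps.append(_gaussian_blob(grid, c + jitter, sig))
    return np.asarray(maps)


def make_ground_truth(
    spec: CohortSpec,
    base_pairs: dict | None = None,
    lags_per_pair: dict | None = None,
    noise_sd: float = 0.5,
    motion_effect: float = 0.0,
    subject_variability_sd: float = 0.1,
) -> GroundTruth:
    """Build a default :class:`GroundTruth` for ``spec``.

    ``base_pairs`` maps component pairs to their baseline correlation
    (shared by both groups until :func:`make_group_effect` is applied).
    Defaults give a few moderately coupled network pairs, one of them
    lagged, which is what the downstream recovery tests exercise.
    """
    rng = np.random.default_rng(spec.seed)
    K = spec.n_components
    if base_pairs is None:
        base_pairs = {}
        if K >= 2:
            base_pairs[(0, 1)] = 0.5
        if K >= 4:
            base_pairs[(2, 3)] = 0.4
        if K >= 6:
            base_pairs[(4, 5)] = 0.3
    if lags_per_pair is None:
        lags_per_pair = {(0, 1): 1.5} if K >= 2 else {}
    C = np.eye(K)
    for (i, j), r in base_pairs.items():
        C[i, j] = C[j, i] = r
    maps = make_spatial_maps(spec.grid, K, rng)
    return GroundTruth(
        spatial_maps=maps,
        tc_covariance_per_group=[C.copy(), C.copy()],
        lags_per_pair=dict(lags_per_pair),
        noise_sd=noise_sd,
        motion_effect=motion_effect,
        subject_variability_sd=subject_variability_sd,
    )


def make_group_effect(truth: GroundTruth, pairs, delta: float) -> GroundTruth:
    """Return a copy of ``truth`` whose group-2 correlation targets differ
    from group 1 by ``delta`` (group1 − group2) exactly on ``pairs``.

    Raises if any modified entry leaves (−1, 1) or the resulting matrix is
    no longer positive semidefinite.
    """
    out = copy.deepcopy(truth)
    C2 = out.tc_covariance_per_group[1].copy()
    for (i, j) in pairs:
        new = C2[i, j] - delta
        if not (-1.0 < new < 1.0):
            raise ValueError(
                f"delta={delta} pushes pair {(i, j)} to {new}, outside (-1, 1)"
            )
        C2[i, j] = C2[j, i] = new
    lam = np.linalg.eigvalsh(C2)
    if lam.min() < -1e-10:
        raise ValueError(
            f"delta={delta} breaks positive semidefiniteness of the group-2 "
            f"covariance target (min eigenvalue {lam.min():.3g})"
        )
    out.tc_covariance_per_group[1] = C2
    return out


# ---------------------------------------------------------------------------
# time-course realization


def _bandlimited_noise(rng, n_timepoints, n_signals, tr, band=LATENT_BAND) -> np.ndarray:
    """Unit-variance Gaussian signals with support restricted to ``band``."""
    z = rng.standard_normal((n_timepoints, n_signals))
    F = np.fft.rfft(z, axis=0)
    f = np.fft.rfftfreq(n_timepoints, d=tr)
    keep = (f >= band[0]) & (f <= band[1])
    F[~keep] = 0.0
    x = np.fft.irfft(F, n=n_timepoints, axis=0)
    x -= x.mean(axis=0)
    x /= x.std(axis=0)
    return x


def _spectral_delay(x: np.ndarray, delays: np.ndarray, tr: float) -> np.ndarray:
    """Delay column k of ``x`` by ``delays[k]`` seconds (circular FFT shift)."""
    T = x.shape[0]
    F = np.fft.rfft(x, axis=0)
    f = np.fft.rfftfreq(T, d=tr)
    F *= np.exp(-2j * np.pi * f[:, None] * delays[None, :])
    return np.fft.irfft(F, n=T, axis=0)


def realize_timecourses(rng, n_timepoints, tr, corr, delays) -> np.ndarray:
    """Band-limited unit-variance TCs whose zero-lag correlation equals
    ``corr`` exactly, then per-component spectral delays applied."""
    K = corr.shape[0]
    z = _bandlimited_noise(rng, n_timepoints, K, tr)
    # whiten the realized covariance exactly, then impose the target
    emp = (z.T @ z) / n_timepoints
    z = z @ np.linalg.inv(np.linalg.cholesky(emp)).T
    # PSD target may be singular; use eigenvalue square root
    lam, V = np.linalg.eigh(corr)
    L = V @ np.diag(np.sqrt(np.clip(lam, 0.0, None))) @ V.T
    u = z @ L.T
    if np.any(delays != 0.0):
        u = _spectral_delay(u, np.asarray(delays, float), tr)
    return u


def _motion_table(rng, n_timepoints, amplitude) -> np.ndarray:
    """Six smooth random-walk rigid-body motion parameters."""
    from scipy.ndimage import gaussian_filter1d

    steps = rng.standard_normal((n_timepoints, 6)) * 0.02 * amplitude
    walk = np.cumsum(steps, axis=0)
    return gaussian_filter1d(walk, sigma=2.0, axis=0)


def generate_cohort(spec: CohortSpec, truth: GroundTruth) -> Cohort:
    """Generate a balanced two-group cohort from ``spec`` and ``truth``.

    Each subject's data matrix is ``tcs @ spatial_maps`` plus i.i.d.
    Gaussian voxel noise; group-2 subjects use the group-2 correlation
    target.  Deterministic for a fixed ``spec.seed``.
    """
    if truth.n_components != spec.n_components:
        raise ValueError(
            f"truth has {truth.n_components} components, spec expects "
            f"{spec.n_components}"
        )
    if truth.spatial_maps.shape[1] != spec.n_voxels:
        raise ValueError("truth spatial maps do not match the spec grid")
    rng = np.random.default_rng(spec.seed)
    delays = truth.component_delays()
    mask = np.ones(spec.n_voxels, dtype=bool)

    scans, motion, clean_tcs, rows = [], [], [], []
    labels = np.repeat([0, 1], spec.n_per_group)
    age_mean_sd = {0: (36.5, 11.3), 1: (39.7, 10.1)}
    for s, g in enumerate(labels):
        sid = f"sub-{s:03d}"
        C = truth.tc_covariance_per_group[g]
        u = realize_timecourses(rng, spec.n_timepoints, spec.tr, C, delays)
        if truth.subject_variability_sd > 0:
            u = u + truth.subject_variability_sd * _bandlimited_noise(
                rng, spec.n_timepoints, spec.n_components, spec.tr
            )
        amp = float(rng.lognormal(mean=0.0, sigma=0.5))
        mot = _motion_table(rng, spec.n_timepoints, amp)
        if truth.motion_effect > 0:
            msig = _bandlimited_noise(rng, spec.n_timepoints, 1, spec.tr)[:, 0]
            u = u + truth.motion_effect * amp * msig[:, None]
        clean_tcs.append(u)
        X = u @ truth.spatial_maps
        if truth.noise_sd > 0:
            X = X + truth.noise_sd * rng.standard_normal(X.shape)
        scans.append(SubjectScan(data=X, tr=spec.tr, grid=spec.grid, mask=mask,
                                 subject_id=sid))
        motion.append(mot)
        mu, sd = age_mean_sd[g]
        rows.append({
            "subject_id": sid,
            "group": "patient" if g == 1 else "control",
            "age": float(np.round(rng.normal(mu, sd), 1)),
        })
    return Cohort(scans=scans, labels=labels, motion=motion,
                  covariates=pd.DataFrame(rows), truth=truth,
                  clean_tcs=clean_tcs)
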