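"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SubjectScan:
    """One subject's masked 4D time-series in matrix form.

    Parameters
    ----------
    data : ndarray, shape (timepoints, voxels)
        BOLD signal, one row per volume, one column per in-mask voxel.
    tr : float
        Repetition time in seconds.
    grid : tuple of int
        Voxel grid shape ``(nx, ny, nz)``.
    mask : ndarray of bool, shape (nx*ny*nz,)
        Analysis mask in flattened (C-order) voxel space; ``data`` columns
        correspond to ``True`` entries.
    subject_id : str
    """

    data: np.ndarray
    tr: float
    grid: tuple
    mask: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool).ravel()
        self.grid = tuple(int(g) for g in self.grid)
        if self.mask.size != int(np.prod(self.grid)):
            raise ValueError(
                f"mask size {self.mask.size} does not match grid {self.grid}"
            )
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (timepoints x voxels)")
        if self.data.shape[1] != int(self.mask.sum()):
            raise ValueError(
                f"data has {self.data.shape[1]} voxel columns but mask selects "
                f"{int(self.mask.sum())}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def to_nifti(self):
        """Return the scan as a 4D :class:`nibabel.Nifti1Image` (x, y, z, t)."""
        import nibabel as nib

        vol = np.zeros((int(np.prod(self.grid)), self.n_timepoints))
        vol[self.mask, :] = self.data.T
        vol4d = vol.reshape(self.grid + (self.n_timepoints,))
        img = nib.Nifti1Image(vol4d, affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, float(self.tr)))
        return img

    @classmethod
    def from_nifti(cls, path, subject_id: str, mask: np.ndarray | None = None,
                   tr: float | None = None) -> "SubjectScan":
        """Load a 4D NIfTI file; ``tr`` defaults to the header's time zoom."""
        import nibabel as nib

        img = nib.load(str(path))
        vol4d = np.asarray(img.get_fdata())
        if vol4d.ndim != 4:
            raise ValueError(f"{path}: expected a 4D image, got {vol4d.ndim}D")
        grid = vol4d.shape[:3]
        if tr is None:
            tr = float(img.header.get_zooms()[3])
        flat = vol4d.reshape(-1, vol4d.shape[3])
        if mask is None:
            mask = np.ones(flat.shape[0], dtype=bool)
        return cls(data=flat[np.asarray(mask, bool).ravel(), :].T, tr=tr,
                   grid=grid, mask=mask, subject_id=subject_id)


@dataclass
class SubjectComponents:
    """Back-reconstructed subject-specific spatial maps and time-courses.

    ``maps`` rows are z-scored over the in-mask voxels; ``tcs`` are in
    signal units (one column per component).
    """

    maps: np.ndarray          # (K, voxels), z-scored over mask
    tcs: np.ndarray           # (timepoints, K)
    subject_id: str
    tr: float = 1.5

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, float)
        self.tcs = np.asarray(self.tcs, float)
        if not np.all(np.isfinite(self.tcs)):
            raise ValueError("time-courses contain non-finite values")
        if self.maps.shape[0] != self.tcs.shape[1]:
            raise ValueError("maps/tcs component count mismatch")

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]


@dataclass
class FNCVector:
    """Per-subject FNC feature vector.

    ``z_values[p]`` is the Fisher z (arctanh) of the maximum lagged
    correlation of pair ``pair_index[p]``; ``lags[p]`` is the lag (seconds)
    at which that maximum occurred.  Pairs are in canonical upper-triangle
    order of the selected components: (0,1), (0,2), ..., (1,2), ...
    """

    z_values: np.ndarray
    lags: np.ndarray
    pair_index: list            # list of (i, j) tuples, i < j in selection order
    subject_id: str
    pair_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, float)
        self.lags = np.asarray(self.lags, float)
        n = len(self.pair_index)
        if self.z_values.shape != (n,) or self.lags.shape != (n,):
            raise ValueError("z_values/lags length must match pair_index")


def canonical_pairs(n: int) -> list:
    """Upper-triangle pair ordering: (0,1), (0,2), ..., (n-2,n-1)."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]
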