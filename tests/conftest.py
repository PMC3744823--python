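"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

from fnconn.synthetic import CohortSpec, generate_cohort, make_ground_truth


@pytest.fixture(scope="session")
def clean_cohort():
    """6-subject noiseless cohort (no voxel noise, no subject variability):
    the ground truth is exactly recoverable."""
    spec = CohortSpec(n_per_group=3, n_timepoints=200, n_components=6,
                      grid=(10, 10, 8), seed=11)
    truth = make_ground_truth(spec, noise_sd=0.0, subject_variability_sd=0.0)
    return spec, truth, generate_cohort(spec, truth)


@pytest.fixture(scope="session")
def noisy_cohort():
    """6-subject cohort at the default noise level."""
    spec = CohortSpec(n_per_group=3, n_timepoints=200, n_components=6,
                      grid=(10, 10, 8), seed=12)
    truth = make_ground_truth(spec)
    return spec, truth, generate_cohort(spec, truth)


@pytest.fixture(scope="session")
def laplacian_mixture():
    """3 Laplacian sources through a random square mixing, with whitening."""
    rng = np.random.default_rng(42)
    S = rng.laplace(size=(3, 5000))
    A = rng.standard_normal((3, 3))
    X = A @ S
    Xc = X - X.mean(axis=1, keepdims=True)
    lam, U = np.linalg.eigh(Xc @ Xc.T / X.shape[1])
    whitener = (U / np.sqrt(lam)).T
    return {"S": S, "A": A, "white": whitener @ Xc, "whitener": whitener}
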