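"""Shared fixtures: random linear-Gaussian problems and simulated fits."""

import numpy as np
import pytest

from bdc import (
    DesignMatrix,
    GaussianDensity,
    ScalarGaussian,
    SimulationConfig,
    TimeseriesData,
    fit_dataset,
    fit_glm_vb,
    generate_dataset,
)


def random_spd(rng: np.random.Generator, d: int) -> np.ndarray:
    """A well-conditioned random symmetric positive-definite matrix."""
    a = rng.normal(size=(d, d))
    return a @ a.T + d * np.eye(d)


def make_linear_gaussian_fit(rng, n=40, p=4, tau=None, tol=1e-12):
    """A random subject fit with *known* noise precision (conjugate case).

    Returns (fit, data, design, tau); the fit's free energy equals the
    analytic linear-Gaussian log evidence, so these fits serve as exact
    ground truth for reduction and group-level computations.
    """
    labels = [f"b{j}" for j in range(p)]
    X = DesignMatrix(rng.normal(size=(n, p)), labels)
    prior = GaussianDensity(
        rng.normal(size=p) * 0.3, np.diag(rng.uniform(0.3, 2.0, p)), labels
    )
    tau = tau if tau is not None else rng.uniform(0.5, 4.0)
    beta = rng.normal(size=p)
    y = TimeseriesData(X.values @ beta + rng.normal(0, tau**-0.5, n))
    fit = fit_glm_vb(
        y, X, prior, noise_prior=ScalarGaussian(np.log(tau), 0.0), tol=tol, max_iter=200
    )
    return fit, y, X, tau


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def snr_pair_fits():
    """Subject fits for a low/high SNR dataset pair (shared study design)."""
    cfg = SimulationConfig(n_subjects=16, snr_grid=np.array([0.01, 0.5]), master_seed=77)
    return cfg, {
        f"snr{snr:.3f}": fit_dataset(generate_dataset(cfg, 0, k), cfg)
        for k, snr in enumerate(cfg.snr_grid)
    }
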