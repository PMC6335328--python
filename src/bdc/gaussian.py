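"""Gaussian and categorical information-theoretic primitives.

Every quantity in this package is ultimately a statement about a Gaussian
density (a parameter prior or posterior) or a categorical density (a
posterior over models). This module holds those two containers and the
exact closed-form information measures defined on them: differential
(negative) entropy, KL-divergence between Gaussians, KL-divergence of a
categorical posterior from the flat prior, and the softmax map from log
model evidences to posterior model probabilities.

All information quantities are in nats (natural log).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_solve

__all__ = [
    "GaussianDensity",
    "CategoricalDensity",
    "EvidenceLabel",
    "DegeneratePosteriorError",
    "logdet_psd",
    "negative_entropy",
    "kl_gaussian",
    "kl_categorical",
    "softmax_from_logevidence",
    "evidence_label",
    "probability_from_difference",
]

#: Relative diagonal jitter allowed when factorizing a nominally-PSD matrix.
JITTER_REL = 1e-8

#: Condition-number ceiling beyond which a posterior is declared degenerate.
CONDITION_LIMIT = 1e12

LOG_2PI_E = np.log(2.0 * np.pi * np.e)


class DegeneratePosteriorError(np.linalg.LinAlgError):
    """Raised when a covariance submatrix is numerically singular."""


@dataclass(frozen=True)
class GaussianDensity:
    """A labelled multivariate normal density N(mean, cov).

    The universal currency for priors and posteriors: first-level
    parameter densities, group-level effect densities, and reduced-model
    posteriors are all instances of this type.

    Parameters
    ----------
    mean : (d,) array
    cov : (d, d) symmetric positive semi-definite array
    labels : d parameter names
    """

    mean: np.ndarray
    cov: np.ndarray
    labels: tuple[str, ...]

    def __init__(self, mean, cov, labels=None):
        mean = np.atleast_1d(np.asarray(mean, dtype=float))
        cov = np.atleast_2d(np.asarray(cov, dtype=float))
        d = mean.shape[0]
        if labels is None:
            labels = tuple(f"p{i}" for i in range(d))
        else:
            labels = tuple(str(x) for x in labels)
        if cov.shape != (d, d):
            raise ValueError(f"covariance shape {cov.shape} does not match mean of length {d}")
        if len(labels) != d:
            raise ValueError(f"{len(labels)} labels for {d} parameters")
        scale = np.abs(cov).max() or 1.0
        if not np.allclose(cov, cov.T, rtol=1e-10, atol=1e-10 * scale):
            raise ValueError("covariance is not symmetric")
        cov = 0.5 * (cov + cov.T)
        w = np.linalg.eigvalsh(cov)
        if w.min() < -1e-10 * max(w.max(), 1e-300):
            raise ValueError(f"covariance is not positive semi-definite (min eigenvalue {w.min():g})")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        object.__setattr__(self, "labels", labels)

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    def indices_of(self, subset: Sequence[str] | Sequence[int] | None) -> np.ndarray:
        """Resolve a subset of labels (or integer indices) to indices."""
        if subset is None:
            return np.arange(self.dim)
        subset = list(subset)
        if len(subset) == 0:
            raise ValueError("empty parameter subset")
        if all(isinstance(s, (int, np.integer)) for s in subset):
            idx = np.asarray(subset, dtype=int)
            if idx.min() < 0 or idx.max() >= self.dim:
                raise IndexError(f"index out of range for {self.dim} parameters")
            return idx
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [s for s in subset if s not in pos]
        if missing:
            raise KeyError(f"unknown parameter labels: {missing}")
        return np.asarray([pos[s] for s in subset], dtype=int)

    def marginal(self, subset) -> "GaussianDensity":
        """Marginal density over a subset of parameters."""
        idx = self.indices_of(subset)
        return GaussianDensity(
            self.mean[idx], self.cov[np.ix_(idx, idx)], [self.labels[i] for i in idx]
        )

    def precision(self) -> np.ndarray:
        """Inverse covariance, via a jittered Cholesky factorization."""
        c, _ = _chol_psd(self.cov)
        return cho_solve((c, True), np.eye(self.dim))


@dataclass(frozen=True)
class CategoricalDensity:
    """A discrete probability distribution over a set of models."""

    probabilities: np.ndarray
    model_ids: tuple[str, ...]

    def __init__(self, probabilities, model_ids=None):
        p = np.atleast_1d(np.asarray(probabilities, dtype=float))
        if model_ids is None:
            model_ids = tuple(f"m{i}" for i in range(p.shape[0]))
        else:
            model_ids = tuple(str(x) for x in model_ids)
        if len(model_ids) != p.shape[0]:
            raise ValueError("model_ids length does not match probabilities")
        if (p < 0).any():
            raise ValueError("negative probability")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "model_ids", model_ids)

    @property
    def k(self) -> int:
        return self.probabilities.shape[0]


#: Kass–Raftery evidence bins, lower-edge inclusive, in nats.
EVIDENCE_BINS = (
    ("inconclusive", 0.0, 1.1),
    ("positive", 1.1, 3.0),
    ("strong", 3.0, 5.0),
    ("very_strong", 5.0, np.inf),
)


@dataclass(frozen=True)
class EvidenceLabel:
    """A Kass–Raftery evidence category for a log-evidence difference."""

    category: str
    lower: float
    upper: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.category.replace("_", " ") + " evidence"


def _chol_psd(matrix: np.ndarray, what: str = "matrix"):
    """Cholesky factor of a symmetric PSD matrix with bounded diagonal jitter.

    Adds up to ``JITTER_REL * trace/d`` to the diagonal before giving up.
    Returns (lower_factor, jitter_used).
    """
    a = np.asarray(matrix, dtype=float)
    d = a.shape[0]
    scale = np.trace(a) / d if np.trace(a) > 0 else 1.0
    jitter = 0.0
    for _ in range(4):
        try:
            return np.linalg.cholesky(a + jitter * np.eye(d)), jitter
        except np.linalg.LinAlgError:
            jitter = JITTER_REL * scale if jitter == 0.0 else jitter * 10.0
            if jitter > 10 * JITTER_REL * scale:
                break
    raise np.linalg.LinAlgError(
        f"{what} is not positive definite even after diagonal jitter of {jitter:g}"
    )


def logdet_psd(matrix: np.ndarray) -> float:
    """Log-determinant of a symmetric positive-definite matrix.

    Uses a Cholesky factorization with the package-wide jitter policy
    (at most 1e-8 of the mean diagonal added before failing loudly).
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if not np.allclose(matrix, matrix.T, rtol=1e-8, atol=1e-8 * max(np.abs(matrix).max(), 1e-300)):
        raise ValueError("logdet_psd requires a symmetric matrix")
    c, _ = _chol_psd(matrix)
    return 2.0 * float(np.sum(np.log(np.diag(c))))


def negative_entropy(density: GaussianDensity, subset=None) -> float:
    """Negative differential entropy of a Gaussian marginal, in nats.

    For the marginal over the chosen parameters with covariance S,
    returns -0.5 * ln|2*pi*e*S|. Larger values mean a more certain
    (more precise) posterior; this is the parameter-certainty measure.
    """
    idx = density.indices_of(subset)
    sub = density.cov[np.ix_(idx, idx)]
    w = np.linalg.eigvalsh(0.5 * (sub + sub.T))
    if w.min() <= 0 or w.max() / w.min() > CONDITION_LIMIT:
        bad = [density.labels[i] for i in idx]
        raise DegeneratePosteriorError(
            f"degenerate-posterior: covariance over {bad} is singular "
            f"(condition number above {CONDITION_LIMIT:g})"
        )
    d = idx.shape[0]
    return -0.5 * (d * LOG_2PI_E + float(np.sum(np.log(w))))


def kl_gaussian(q: GaussianDensity, p: GaussianDensity) -> float:
    """KL-divergence D(q || p) between multivariate normals, in nats.

    With q = N(mu1, S1) the posterior and p = N(mu0, S0) the prior:

        D = 0.5 * ( tr(S0^-1 S1) + (mu0-mu1)' S0^-1 (mu0-mu1)
                    - k + ln det S0 / det S1 )

    This is the information gained about the parameters in moving from
    prior to posterior (Bayesian surprise).
    """
    if q.dim != p.dim:
        raise ValueError(f"dimension mismatch: {q.dim} vs {p.dim}")
    if q.labels != p.labels:
        raise ValueError(f"label mismatch: {q.labels} vs {p.labels}")
    k = q.dim
    c0, _ = _chol_psd(p.cov, "prior covariance")
    solve0 = lambda b: cho_solve((c0, True), b)
    trace_term = float(np.trace(solve0(q.cov)))
    dm = p.mean - q.mean
    maha = float(dm @ solve0(dm))
    logdet0 = 2.0 * float(np.sum(np.log(np.diag(c0))))
    logdet1 = logdet_psd(q.cov)
    kl = 0.5 * (trace_term + maha - k + logdet0 - logdet1)
    # exact formula can go fractionally negative through rounding
    return max(kl, 0.0)


def kl_categorical(posterior: CategoricalDensity) -> float:
    """KL-divergence of a categorical posterior from the flat prior, nats.

    sum_i P_i ln P_i + ln k, with 0 ln 0 = 0. Zero when all models are
    equally likely; ln k when one model takes all the mass.
    """
    p = posterior.probabilities
    nz = p > 0
    val = float(np.sum(p[nz] * np.log(p[nz]))) + np.log(posterior.k)
    return min(max(val, 0.0), np.log(posterior.k))


def softmax_from_logevidence(F, model_ids=None) -> CategoricalDensity:
    """Posterior model probabilities from log evidences under flat priors.

    p_i proportional to exp(F_i), computed with log-sum-exp stabilization;
    invariant to adding a constant to all F.
    """
    F = np.atleast_1d(np.asarray(F, dtype=float))
    if F.size < 1:
        raise ValueError("need at least one log evidence")
    if not np.all(np.isfinite(F)):
        raise ValueError("log evidences must be finite")
    z = F - F.max()
    w = np.exp(z)
    return CategoricalDensity(w / w.sum(), model_ids)


def probability_from_difference(delta: float) -> float:
    """Percent probability that the first of two alternatives is better.

    Maps a log-evidence difference of ``delta`` nats through the two-way
    softmax: 100 * e^delta / (1 + e^delta). 0 nats -> 50%.
    """
    delta = float(delta)
    if not np.isfinite(delta):
        raise ValueError("difference must be finite")
    return 100.0 / (1.0 + np.exp(-delta))


def evidence_label(delta: float) -> EvidenceLabel:
    """Kass–Raftery evidence category for a non-negative difference in nats.

    [0, 1.1) inconclusive; [1.1, 3) positive; [3, 5) strong; [5, inf)
    very strong. Boundary values fall in the upper bin.
    """
    delta = float(delta)
    if delta < 0 or not np.isfinite(delta):
        raise ValueError(f"evidence difference must be a finite non-negative value, got {delta}")
    for name, lo, hi in EVIDENCE_BINS:
        if lo <= delta < hi:
            return EvidenceLabel(name, lo, hi)
    raise AssertionError("unreachable")
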