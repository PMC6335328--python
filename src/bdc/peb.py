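"""Bayesian model reduction and the group-level parametric empirical Bayes model.

Two pieces of machinery live here.

**Bayesian model reduction (BMR).** For a model whose likelihood is
(approximately) Gaussian in its parameters, the posterior and log
evidence under *modified priors* follow analytically from the fitted
full model, without touching the data. Writing precisions P = inv(C),
the data enter only through the likelihood curvature A = qP - pP and
linear term b = qP qE - pP pE recovered from the full prior (pE, pC)
and posterior (qE, qC); any new prior can then be combined with (A, b)
in closed form. Parameters "switched off" (prior variance zero, mean
fixed at the prior mean) are handled by exact removal of those
dimensions, not by a large-precision surrogate.

**Parametric empirical Bayes (PEB).** Subject-level parameter estimates
theta_i are modelled by a group-level Bayesian GLM

    theta_i = beta + eps_i,   eps_i ~ N(0, (Q0 + exp(-gamma) Q1)^-1)

with beta the group-mean effects (prior taken from the first level) and
a single log-precision parameter gamma controlling between-subject
variability (prior N(0, 1/16): between-subject variance expected ~16x
smaller than the within-subject prior). Each subject contributes its
full posterior density - means *and* covariances - through the BMR
likelihood (A_i, b_i). Given gamma, the beta posterior is conjugate;
gamma is optimized by Gauss-Newton with step-halving and given a Laplace
(Gaussian) posterior. The free energy is the Laplace-approximate log
evidence of the whole hierarchy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gaussian import GaussianDensity, _chol_psd, logdet_psd
from .glm import ModelFit, ScalarGaussian

__all__ = [
    "ReducedPriorSpec",
    "GroupModel",
    "InvalidReductionError",
    "bayesian_model_reduction",
    "reduce_gaussian",
    "fit_peb",
    "empirical_bayes_update",
    "default_covariance_components",
    "PebConfig",
]

LOG_2PI = np.log(2.0 * np.pi)


class InvalidReductionError(ValueError):
    """The requested reduced prior yields a non-PD posterior precision."""


@dataclass(frozen=True)
class ReducedPriorSpec:
    """A reduced-model specification.

    ``switched_off`` parameters have their prior variance set to zero and
    their value fixed at the full prior mean; they are removed exactly.
    ``replacement`` optionally substitutes a new prior over the retained
    parameters (labels must match the retained set); otherwise the
    retained block of the full prior is kept.
    """

    switched_off: tuple[str, ...] = ()
    replacement: GaussianDensity | None = None

    def __init__(self, switched_off=(), replacement=None):
        object.__setattr__(self, "switched_off", tuple(sorted(str(s) for s in switched_off)))
        object.__setattr__(self, "replacement", replacement)

    @property
    def model_id(self) -> str:
        return "full" if not self.switched_off else "-" + "-".join(self.switched_off)


@dataclass(frozen=True)
class GroupModel:
    """A fitted group-level PEB model.

    ``beta_posterior``/``beta_prior`` are densities over the group-mean
    effects of the parameters taken to the group level (conditioned on
    the posterior gamma). ``switched_off`` records parameters pruned at
    the group level (fixed at their prior means).
    """

    n_subjects: int
    beta_prior: GaussianDensity
    beta_posterior: GaussianDensity
    gamma_prior: ScalarGaussian
    gamma_posterior: ScalarGaussian
    Q0: np.ndarray
    Q1: np.ndarray
    free_energy: float
    switched_off: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.beta_posterior.labels

    @property
    def n_params(self) -> int:
        return self.beta_posterior.dim

    def between_subject_cov(self) -> np.ndarray:
        """Expected between-subject covariance at the posterior gamma."""
        prec = self.Q0 + np.exp(-self.gamma_posterior.mean) * self.Q1
        c, _ = _chol_psd(prec, "between-subject precision")
        eye = np.eye(prec.shape[0])
        from scipy.linalg import cho_solve

        return cho_solve((c, True), eye)


@dataclass(frozen=True)
class PebConfig:
    """Tunables for the PEB fit."""

    gamma_prior: ScalarGaussian = ScalarGaussian(0.0, 1.0 / 16.0)
    q0_scale: float = 1.0 / 128.0
    q1_scale: float = 16.0
    tol: float = 1e-4
    max_iter: int = 64


def default_covariance_components(n_params: int, config: PebConfig = PebConfig()):
    """Between-subject precision components (Q0, Q1).

    Q0 = (1/128) I is the precision floor; Q1 = 16 I is the prior
    precision component, so at gamma = 0 the between-subject variance is
    about 1/16 of the unit within-subject prior variance.
    """
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    eye = np.eye(n_params)
    return config.q0_scale * eye, config.q1_scale * eye


def _likelihood_terms(prior: GaussianDensity, posterior: GaussianDensity):
    """Gaussian likelihood curvature/linear terms implied by a fit.

    Returns (A, b, pP, qP) with A = qP - pP, b = qP qE - pP pE; A is the
    data's contribution to the posterior precision and b its linear term.
    """
    pP = prior.precision()
    qP = posterior.precision()
    A = qP - pP
    b = qP @ posterior.mean - pP @ prior.mean
    return A, b, pP, qP


def reduce_gaussian(
    prior: GaussianDensity,
    posterior: GaussianDensity,
    spec: ReducedPriorSpec,
) -> tuple[GaussianDensity, float]:
    """Posterior and log-evidence change under a reduced prior.

    Exact for models whose likelihood is Gaussian in the parameters
    (linear-Gaussian models); the usual Laplace approximation otherwise.
    Returns the reduced posterior over the *retained* parameters and
    delta_F = ln p(y | reduced) - ln p(y | full) in nats.
    """
    if prior.labels != posterior.labels:
        raise ValueError("prior and posterior labels differ")
    labels = prior.labels
    unknown = set(spec.switched_off) - set(labels)
    if unknown:
        raise KeyError(f"cannot switch off unknown parameters: {sorted(unknown)}")
    if len(spec.switched_off) == len(labels):
        raise InvalidReductionError("cannot switch off every parameter")

    off = np.asarray([lab in spec.switched_off for lab in labels])
    keep = ~off
    kept_labels = tuple(lab for lab in labels if lab not in spec.switched_off)

    A, b, pP, qP = _likelihood_terms(prior, posterior)
    f_off = prior.mean[off]  # switched-off values pinned at the prior mean

    if spec.replacement is not None:
        if spec.replacement.labels != kept_labels:
            raise ValueError(
                f"replacement prior labels {spec.replacement.labels} "
                f"do not match retained labels {kept_labels}"
            )
        r_prior = spec.replacement
    else:
        r_prior = prior.marginal(list(kept_labels))

    rP = r_prior.precision()
    A_rr = A[np.ix_(keep, keep)]
    sP = A_rr + rP
    sP = 0.5 * (sP + sP.T)
    try:
        c, _ = _chol_psd(sP, "reduced posterior precision")
    except np.linalg.LinAlgError as exc:
        raise InvalidReductionError(f"invalid reduction {spec.model_id}: {exc}") from exc
    from scipy.linalg import cho_solve

    rhs = b[keep] - A[np.ix_(keep, off)] @ f_off + rP @ r_prior.mean
    sE = cho_solve((c, True), rhs)
    sC = cho_solve((c, True), np.eye(sP.shape[0]))
    sC = 0.5 * (sC + sC.T)

    logdet_sP = 2.0 * float(np.sum(np.log(np.diag(c))))
    dF = 0.5 * (
        logdet_psd(rP) - logdet_sP - logdet_psd(pP) + logdet_psd(qP)
    ) + 0.5 * (
        float(sE @ sP @ sE)
        - float(r_prior.mean @ rP @ r_prior.mean)
        - float(posterior.mean @ qP @ posterior.mean)
        + float(prior.mean @ pP @ prior.mean)
    )
    if off.any():
        dF += float(b[off] @ f_off) - 0.5 * float(f_off @ A[np.ix_(off, off)] @ f_off)

    return GaussianDensity(sE, sC, kept_labels), float(dF)


def bayesian_model_reduction(full, reduced: ReducedPriorSpec):
    """BMR on a subject-level ``ModelFit`` or a group-level ``GroupModel``.

    Returns (reduced_posterior, delta_F). For a GroupModel the reduction
    acts on the group-effect density, conditional on the posterior gamma.
    """
    if isinstance(full, ModelFit):
        return reduce_gaussian(full.prior, full.posterior, reduced)
    if isinstance(full, GroupModel):
        return reduce_gaussian(full.beta_prior, full.beta_posterior, reduced)
    raise TypeError(f"cannot reduce object of type {type(full).__name__}")


def _subject_terms(fits, param_subset):
    """Per-subject likelihood terms over the group-modelled parameters."""
    marg_priors = [f.prior.marginal(param_subset) for f in fits]
    marg_posts = [f.posterior.marginal(param_subset) for f in fits]
    labels = marg_priors[0].labels
    for mp in marg_priors[1:]:
        if mp.labels != labels:
            raise ValueError("subject fits have inconsistent parameter labels")
    A = np.stack([_likelihood_terms(p, q)[0] for p, q in zip(marg_priors, marg_posts)])
    b = np.stack(
        [
            q.precision() @ q.mean - p.precision() @ p.mean
            for p, q in zip(marg_priors, marg_posts)
        ]
    )
    # constants tying subject free energies to the hierarchical evidence
    cs = []
    for f, p, q in zip(fits, marg_priors, marg_posts):
        pP, qP = p.precision(), q.precision()
        cs.append(
            f.free_energy
            - 0.5 * (logdet_psd(pP) - logdet_psd(qP))
            - 0.5 * (float(q.mean @ qP @ q.mean) - float(p.mean @ pP @ p.mean))
        )
    return labels, marg_priors, A, b, float(np.sum(cs))


def _conditional_evidence(gamma, A, b, Q0, Q1, prior_mean, prior_prec, c_sum):
    """ln p(data | gamma) with beta integrated out, plus the beta posterior.

    A: (N, M, M) subject likelihood curvatures; b: (N, M) linear terms.
    """
    n_sub, m = b.shape
    Pi_b = Q0 + np.exp(-gamma) * Q1
    Mi = A + Pi_b[None, :, :]
    try:
        Mi_inv = np.linalg.inv(Mi)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise np.linalg.LinAlgError(f"singular marginal precision at gamma={gamma}") from exc
    sign, logdet_Mi = np.linalg.slogdet(Mi)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError(f"non-PD marginal precision at gamma={gamma}")
    logdet_Pib = logdet_psd(Pi_b)

    Mi_inv_b = np.einsum("nij,nj->ni", Mi_inv, b)
    d_sum = c_sum + float(
        n_sub * 0.5 * logdet_Pib
        - 0.5 * np.sum(logdet_Mi)
        + 0.5 * np.einsum("ni,ni->", b, Mi_inv_b)
    )
    # beta-likelihood precision G_i = Pib - Pib Mi^-1 Pib and linear term
    G = Pi_b[None] - np.einsum("ij,njk,kl->nil", Pi_b, Mi_inv, Pi_b)
    l = np.einsum("ij,nj->ni", Pi_b, Mi_inv_b)

    sP = G.sum(axis=0) + prior_prec
    sP = 0.5 * (sP + sP.T)
    sE = np.linalg.solve(sP, l.sum(axis=0) + prior_prec @ prior_mean)
    J = (
        d_sum
        + 0.5 * (logdet_psd(prior_prec) - logdet_psd(sP))
        + 0.5 * (float(sE @ sP @ sE) - float(prior_mean @ prior_prec @ prior_mean))
    )
    return J, sE, sP


def fit_peb(
    subject_fits: list[ModelFit],
    param_subset=None,
    config: PebConfig = PebConfig(),
    beta_prior: GaussianDensity | None = None,
) -> GroupModel:
    """Fit the group-level PEB model to a set of subject fits.

    Only the parameters named by ``param_subset`` (default: all shared
    parameters) are taken to the group level; the between-subject design
    is the group mean (1_N (x) I_M). Subject posterior covariances - not
    just means - enter through the BMR likelihood terms, so uncertain
    subjects are automatically down-weighted. The group-level prior on
    beta defaults to the (shared) first-level prior; pass ``beta_prior``
    to override.
    """
    if len(subject_fits) < 2:
        raise ValueError("PEB needs at least 2 subjects")
    if param_subset is not None and len(list(param_subset)) == 0:
        raise ValueError("param_subset must be non-empty")
    labels, marg_priors, A, b, c_sum = _subject_terms(subject_fits, param_subset)
    m = len(labels)
    Q0, Q1 = default_covariance_components(m, config)

    if beta_prior is None:
        beta_prior = marg_priors[0]
    elif beta_prior.labels != labels:
        raise ValueError("beta_prior labels do not match the group parameters")
    prior_prec = beta_prior.precision()
    prior_mean = beta_prior.mean

    g_prior = config.gamma_prior

    def objective(gamma):
        J, sE, sP = _conditional_evidence(
            gamma, A, b, Q0, Q1, prior_mean, prior_prec, c_sum
        )
        if g_prior.variance > 0:
            J += -0.5 * (
                LOG_2PI
                + np.log(g_prior.variance)
                + (gamma - g_prior.mean) ** 2 / g_prior.variance
            )
        return J, sE, sP

    if g_prior.variance == 0.0:
        # gamma clamped: conditional model, no hyperparameter search
        gamma = g_prior.mean
        J, sE, sP = objective(gamma)
        gamma_post = ScalarGaussian(gamma, 0.0)
        F = J
        converged = True
    else:
        gamma = 0.0
        h = 1e-3
        J = objective(gamma)[0]
        converged = False
        for _ in range(config.max_iter):
            Jp = objective(gamma + h)[0]
            Jm = objective(gamma - h)[0]
            grad = (Jp - Jm) / (2 * h)
            hess = (Jp - 2 * J + Jm) / (h * h)
            if hess >= 0:  # not locally concave: fall back to gradient step
                step = np.clip(grad, -1.0, 1.0)
            else:
                step = -grad / hess
            step = float(np.clip(step, -4.0, 4.0))
            # step-halving: never decrease the objective
            new_J = None
            for _halve in range(12):
                cand = gamma + step
                cand_J = objective(cand)[0]
                if cand_J >= J - 1e-12:
                    new_J = cand_J
                    break
                step *= 0.5
            if new_J is None:
                converged = True
                break
            dJ, dg = new_J - J, step
            gamma, J = cand, new_J
            if abs(dg) < config.tol and abs(dJ) < config.tol:
                converged = True
                break
        Jp = objective(gamma + h)[0]
        Jm = objective(gamma - h)[0]
        hess = (Jp - 2 * J + Jm) / (h * h)
        v_lap = -1.0 / hess if hess < 0 else g_prior.variance
        # marginalize the hyperparameter by quadrature around the mode:
        # conditioning beta on the gamma mode alone understates uncertainty
        nodes = gamma + np.sqrt(v_lap) * np.linspace(-5.0, 5.0, 21)
        Js, means, covs = [], [], []
        for g in nodes:
            Jg, sEg, sPg = objective(g)
            Js.append(Jg)
            means.append(sEg)
            covs.append(np.linalg.inv(sPg))
        Js = np.asarray(Js)
        w = np.exp(Js - Js.max())
        w /= w.sum()
        g_mean = float(w @ nodes)
        g_var = float(w @ (nodes - g_mean) ** 2)
        gamma_post = ScalarGaussian(g_mean, g_var)
        # trapezoid marginal evidence over the gamma grid
        dg = nodes[1] - nodes[0]
        F = float(Js.max() + np.log(np.trapezoid(np.exp(Js - Js.max()), dx=dg)))
        means = np.asarray(means)
        sE = w @ means
        sC = np.einsum("k,kij->ij", w, np.asarray(covs))
        sC += np.einsum("k,ki,kj->ij", w, means - sE, means - sE)
        beta_posterior = GaussianDensity(sE, 0.5 * (sC + sC.T), labels)
        if not converged:
            warnings.warn("fit_peb: gamma optimization did not converge", RuntimeWarning)

    if g_prior.variance == 0.0:
        sC = np.linalg.inv(sP)
        sC = 0.5 * (sC + sC.T)
        beta_posterior = GaussianDensity(sE, sC, labels)
    return GroupModel(
        n_subjects=len(subject_fits),
        beta_prior=beta_prior,
        beta_posterior=beta_posterior,
        gamma_prior=g_prior,
        gamma_posterior=gamma_post,
        Q0=Q0,
        Q1=Q1,
        free_energy=float(F),
        meta={"converged": converged, "param_subset": list(labels)},
    )


def empirical_bayes_update(subject_fit: ModelFit, group: GroupModel) -> ModelFit:
    """Re-evaluate a subject's fit under group-derived empirical priors.

    The subject's prior over the group-modelled parameters becomes the
    group posterior predictive for one subject: mean = the group-mean
    posterior expectation, covariance = between-subject covariance plus
    the uncertainty of the group mean itself. Parameters pruned at the
    group level stay switched off. Applied analytically via BMR; the
    returned fit's free energy is the original plus delta_F.
    """
    group_labels = set(group.labels) | set(group.switched_off)
    missing = group_labels - set(subject_fit.labels)
    if missing:
        raise ValueError(f"subject fit lacks group parameters: {sorted(missing)}")

    pred_cov = group.between_subject_cov() + group.beta_posterior.cov
    new_prior = GaussianDensity(group.beta_posterior.mean, pred_cov, group.labels)

    # retained = subject params minus those pruned at the group level
    kept = tuple(l for l in subject_fit.labels if l not in group.switched_off)
    if kept != group.labels:
        # subject carries parameters outside the group subset: keep their
        # original priors, with zero cross-covariance to the group block
        extra = [l for l in kept if l not in group.labels]
        base = subject_fit.prior.marginal(list(kept))
        mean = base.mean.copy()
        cov = base.cov.copy()
        gidx = [kept.index(l) for l in group.labels]
        mean[gidx] = new_prior.mean
        cov[np.ix_(gidx, gidx)] = new_prior.cov
        for l in extra:
            i = kept.index(l)
            cov[i, gidx] = 0.0
            cov[gidx, i] = 0.0
        replacement = GaussianDensity(mean, cov, kept)
    else:
        replacement = new_prior

    spec = ReducedPriorSpec(switched_off=group.switched_off, replacement=replacement)
    post, dF = reduce_gaussian(subject_fit.prior, subject_fit.posterior, spec)
    return ModelFit(
        prior=replacement,
        posterior=post,
        noise_logprecision=subject_fit.noise_logprecision,
        free_energy=subject_fit.free_energy + dF,
        meta={**subject_fit.meta, "empirical_bayes": True},
    )
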