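"""The dataset-comparison pipeline and the three outcome measures.

Given several candidate datasets - each a set of per-subject Bayesian
fits with the same subjects and the same model structure - the pipeline

1. fits one *pooled* group model over all subjects of all datasets
   (deliberately blind to dataset membership, to avoid bias),
2. prunes it to a parsimonious common architecture,
3. re-evaluates every subject under empirical priors taken from the
   pruned group posterior,
4. fits a separate group (PEB) model per dataset, and
5. scores each dataset with three information measures:

   (a) **parameter certainty** - the negative entropy
       -0.5 ln|2 pi e Sigma| of the group posterior over the parameters
       of interest, reported relative to the worst dataset;
   (b) **information gain over parameters** - the KL-divergence from the
       group-level priors to posteriors, again relative to the worst;
   (c) **information gain over models** - the KL-divergence from a flat
       prior over a shared model space to the softmax posterior over
       model evidences; absolute, bounded by ln k.

Differences between datasets, in nats, map to probabilities through the
two-way softmax and to Kass-Raftery evidence categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gaussian import (
    CategoricalDensity,
    EvidenceLabel,
    evidence_label,
    kl_categorical,
    kl_gaussian,
    negative_entropy,
)
from .glm import ModelFit
from .model_space import build_comparison_space, enumerate_submodels, score_model_space
from .peb import GroupModel, PebConfig, empirical_bayes_update, fit_peb
from .model_space import greedy_prune

__all__ = [
    "CompareOptions",
    "DatasetComparison",
    "pooled_group_model",
    "measure_parameter_certainty",
    "measure_parameter_info_gain",
    "measure_model_info_gain",
    "compare_datasets",
]


@dataclass(frozen=True)
class CompareOptions:
    """Options for :func:`compare_datasets`.

    space : "auto" builds the comparison space from the pooled group
        model (retaining reductions within 3 nats of the full model);
        "full" enumerates every on/off permutation of the retained
        parameters (excluding the all-off model); or pass an explicit
        list of ``ReducedPriorSpec``.
    skip_pruning : bypass the pooled pruning and empirical-Bayes update
        (for users with strong priors about the architecture).
    reference : dataset id to anchor the relative measures at; default
        anchors at the minimum (the worst dataset).
    """

    space: object = "auto"
    skip_pruning: bool = False
    prune_threshold: float = 0.0
    retain_threshold: float = -3.0
    max_models: int = 64
    reference: str | None = None
    peb: PebConfig = field(default_factory=PebConfig)


@dataclass(frozen=True)
class DatasetComparison:
    """Per-dataset outcome measures and pairwise comparisons."""

    dataset_ids: tuple[str, ...]
    certainty_rel: np.ndarray
    param_info_gain_rel: np.ndarray
    model_info_gain_abs: np.ndarray
    model_posteriors: dict[str, CategoricalDensity]
    pairwise_probabilities: dict[str, np.ndarray]
    labels: dict[str, list[list[EvidenceLabel]]]
    n_models: int
    group_models: dict[str, GroupModel] = field(default_factory=dict, repr=False)
    model_space_ids: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        """One row per dataset with the three measures and the best model."""
        best = []
        for d in self.dataset_ids:
            post = self.model_posteriors[d]
            i = int(np.argmax(post.probabilities))
            best.append((post.model_ids[i], float(post.probabilities[i])))
        return pd.DataFrame(
            {
                "dataset": self.dataset_ids,
                "certainty_rel": self.certainty_rel,
                "param_info_gain_rel": self.param_info_gain_rel,
                "model_info_gain": self.model_info_gain_abs,
                "best_model": [b[0] for b in best],
                "best_model_prob": [b[1] for b in best],
            }
        )


def pooled_group_model(all_fits: list[ModelFit], param_subset=None, config=PebConfig()) -> GroupModel:
    """One PEB fit over the pooled subjects of every dataset.

    The pooled model is blind to dataset membership; it only serves to
    define a common (pruned) architecture that no dataset is favored by.
    """
    return fit_peb(all_fits, param_subset=param_subset, config=config)


def _relative(values: np.ndarray, dataset_ids, reference: str | None) -> np.ndarray:
    if reference is None:
        anchor = float(np.min(values))
    else:
        anchor = float(values[list(dataset_ids).index(reference)])
    return values - anchor


def measure_parameter_certainty(
    groups: dict[str, GroupModel], subset=None, reference: str | None = None
) -> np.ndarray:
    """Measure (a): negative entropy of each group posterior, in relative nats."""
    ids = list(groups)
    vals = np.array([negative_entropy(groups[d].beta_posterior, subset) for d in ids])
    return _relative(vals, ids, reference)


def measure_parameter_info_gain(
    groups: dict[str, GroupModel], subset=None, reference: str | None = None
) -> np.ndarray:
    """Measure (b): KL from group priors to posteriors, in relative nats."""
    ids = list(groups)
    vals = []
    for d in ids:
        g = groups[d]
        post, prior = g.beta_posterior, g.beta_prior
        if subset is not None:
            post, prior = post.marginal(subset), prior.marginal(subset)
        vals.append(kl_gaussian(post, prior))
    return _relative(np.asarray(vals), ids, reference)


def measure_model_info_gain(
    groups: dict[str, GroupModel], specs
) -> tuple[np.ndarray, dict[str, CategoricalDensity]]:
    """Measure (c): KL from the flat model prior, per dataset, absolute nats.

    The same model space is applied to every dataset so that all are
    scored against identical hypotheses.
    """
    vals, posteriors = [], {}
    for d, g in groups.items():
        space = score_model_space(g, specs)
        posteriors[d] = space.posterior
        vals.append(kl_categorical(space.posterior))
    return np.asarray(vals), posteriors


def _pairwise(values: np.ndarray):
    """Pairwise softmax probabilities (%) and evidence labels from a vector."""
    delta = values[:, None] - values[None, :]
    prob = 100.0 / (1.0 + np.exp(-delta))
    labels = [
        [evidence_label(abs(float(d))) for d in row]
        for row in delta
    ]
    return prob, labels


def compare_datasets(
    dataset_fits: dict[str, list[ModelFit]],
    param_subset=None,
    options: CompareOptions = CompareOptions(),
) -> DatasetComparison:
    """Run the full Bayesian data comparison over several datasets.

    ``dataset_fits`` maps dataset id -> per-subject fits; every dataset
    must contribute the same number of subjects fitted with the same
    parameter labels (a repeated-measures design). Deterministic given
    its inputs.
    """
    ids = tuple(sorted(dataset_fits))
    if len(ids) < 2:
        raise ValueError("need at least two datasets to compare")
    sizes = {d: len(dataset_fits[d]) for d in ids}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"datasets have unequal subject counts: {sizes}")
    label_sets = {dataset_fits[d][0].labels for d in ids}
    if len(label_sets) != 1:
        raise ValueError("datasets were fitted with different model structures")

    # steps 2-3: pooled architecture search and empirical-Bayes update
    try:
        all_fits = [f for d in ids for f in dataset_fits[d]]
        pooled = pooled_group_model(all_fits, param_subset, options.peb)
    except Exception as exc:
        raise RuntimeError(f"[pooled-model] {exc}") from exc

    if options.skip_pruning:
        pruned = pooled
        updated = {
            d: [
                _marginal_fit(f, param_subset) for f in dataset_fits[d]
            ]
            for d in ids
        }
    else:
        try:
            pruned = greedy_prune(pooled, options.prune_threshold)
        except Exception as exc:
            raise RuntimeError(f"[pruning] {exc}") from exc
        try:
            updated = {
                d: [empirical_bayes_update(f, pruned) for f in dataset_fits[d]]
                for d in ids
            }
        except Exception as exc:
            raise RuntimeError(f"[empirical-bayes-update] {exc}") from exc

    # step 4: one group model per dataset. The group-level prior on beta
    # stays the canonical first-level prior (not the empirical prior the
    # subjects now carry), so switched-off parameters are fixed at zero
    # and datasets are scored against the same null.
    try:
        groups = {
            d: fit_peb(updated[d], config=options.peb, beta_prior=pruned.beta_prior)
            for d in ids
        }
    except Exception as exc:
        raise RuntimeError(f"[per-dataset-peb] {exc}") from exc

    # shared model space
    try:
        if isinstance(options.space, str) and options.space == "auto":
            space = build_comparison_space(
                pruned, options.retain_threshold, options.max_models
            )
            specs = space.specs
        elif isinstance(options.space, str) and options.space == "full":
            specs = enumerate_submodels(pruned.labels)
        elif isinstance(options.space, str):
            raise ValueError(f"unknown model-space mode {options.space!r}")
        else:
            specs = list(options.space)
    except Exception as exc:
        raise RuntimeError(f"[model-space] {exc}") from exc

    # step 5: the three measures
    try:
        cert = measure_parameter_certainty(groups, reference=options.reference)
        gain = measure_parameter_info_gain(groups, reference=options.reference)
        model_gain, posteriors = measure_model_info_gain(groups, specs)
    except Exception as exc:
        raise RuntimeError(f"[measures] {exc}") from exc

    pairwise, labels = {}, {}
    for name, vec in (("certainty", cert), ("param_info_gain", gain), ("model_info_gain", model_gain)):
        prob, lab = _pairwise(vec)
        pairwise[name] = prob
        labels[name] = lab

    k = len(next(iter(posteriors.values())).probabilities)
    return DatasetComparison(
        dataset_ids=ids,
        certainty_rel=cert,
        param_info_gain_rel=gain,
        model_info_gain_abs=model_gain,
        model_posteriors=posteriors,
        pairwise_probabilities=pairwise,
        labels=labels,
        n_models=k,
        group_models=groups,
        model_space_ids=tuple(s.model_id for s in specs),
    )


def _marginal_fit(fit: ModelFit, param_subset) -> ModelFit:
    """Restrict a fit to the parameters of interest without re-estimation."""
    if param_subset is None:
        return fit
    return ModelFit(
        prior=fit.prior.marginal(param_subset),
        posterior=fit.posterior.marginal(param_subset),
        noise_logprecision=fit.noise_logprecision,
        free_energy=fit.free_energy,
        meta=fit.meta,
    )
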