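"""Construction and scoring of model spaces over a group model.

A "model" here is a pattern of group-level parameters switched on or
off (off = prior variance zero). Three routes to a model space:

- ``enumerate_submodels``: all on/off permutations of the parameters
  (2^p, optionally excluding the model with everything off) - the route
  used for small simulation spaces.
- ``build_comparison_space``: breadth-first search over successive
  single-parameter eliminations, retaining a candidate only while its
  log evidence stays within 3 nats of the full model (an odds ratio of
  about 20): the automated "plausible but hard to disambiguate" set.
- ``greedy_prune``: backward elimination of parameters whose removal
  does not lower the group free energy at all; used to fix a single
  parsimonious architecture before datasets are compared.

Scoring a space evaluates every reduction by BMR and softmaxes the log
evidences into posterior model probabilities under flat model priors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .gaussian import CategoricalDensity, softmax_from_logevidence
from .peb import GroupModel, InvalidReductionError, ReducedPriorSpec, bayesian_model_reduction

__all__ = [
    "ModelSpace",
    "enumerate_submodels",
    "greedy_prune",
    "build_comparison_space",
    "score_model_space",
]

#: enumeration cap: 2^16 models is already past any sensible exhaustive search
MAX_ENUM_PARAMS = 16


@dataclass(frozen=True)
class ModelSpace:
    """A scored set of reduced models.

    ``free_energies`` are log evidences relative to the full model
    (which is always present and has value 0 by construction);
    ``posterior`` is their softmax under flat model priors.
    """

    specs: tuple[ReducedPriorSpec, ...]
    free_energies: np.ndarray
    posterior: CategoricalDensity

    def __post_init__(self):
        ids = [s.model_id for s in self.specs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate models in space")
        if "full" not in ids:
            raise ValueError("model space must contain the full model")

    @property
    def k(self) -> int:
        return len(self.specs)

    @property
    def model_ids(self) -> tuple[str, ...]:
        return tuple(s.model_id for s in self.specs)

    def to_frame(self) -> pd.DataFrame:
        """One row per model: switched-off labels, delta-F, posterior."""
        return pd.DataFrame(
            {
                "model": self.model_ids,
                "switched_off": [";".join(s.switched_off) for s in self.specs],
                "delta_F": self.free_energies,
                "posterior_prob": self.posterior.probabilities,
            }
        )


def enumerate_submodels(labels, include_empty: bool = False) -> list[ReducedPriorSpec]:
    """All on/off permutations of ``labels`` as reduced-prior specs.

    Returns 2^p specs (or 2^p - 1 when the all-off "empty" model is
    excluded, the default), in deterministic order: lexicographic by the
    sorted switched-off set, full model first.
    """
    labels = [str(l) for l in labels]
    p = len(labels)
    if p < 1:
        raise ValueError("need at least one parameter")
    if p > MAX_ENUM_PARAMS:
        raise ValueError(
            f"{p} parameters would enumerate {2**p} models; "
            "use build_comparison_space for large spaces"
        )
    subsets = []
    for r in range(p + 1):
        for combo in itertools.combinations(sorted(labels), r):
            if not include_empty and len(combo) == p:
                continue
            subsets.append(combo)
    subsets.sort()
    return [ReducedPriorSpec(switched_off=s) for s in subsets]


def score_model_space(group: GroupModel, specs) -> ModelSpace:
    """Evaluate each reduced model against the fitted full group model.

    Log evidences come from BMR; models whose reduction is numerically
    invalid are dropped with a warning. Posterior probabilities are the
    softmax of the (relative) log evidences under flat model priors.
    """
    specs = list(specs)
    if not any(len(s.switched_off) == 0 and s.replacement is None for s in specs):
        specs = [ReducedPriorSpec()] + specs
    kept, dFs = [], []
    for spec in specs:
        try:
            _, dF = bayesian_model_reduction(group, spec)
        except InvalidReductionError as exc:
            warnings.warn(f"dropping model {spec.model_id}: {exc}", RuntimeWarning)
            continue
        kept.append(spec)
        dFs.append(dF)
    dFs = np.asarray(dFs)
    posterior = softmax_from_logevidence(dFs, model_ids=[s.model_id for s in kept])
    return ModelSpace(specs=tuple(kept), free_energies=dFs, posterior=posterior)


def greedy_prune(group: GroupModel, prune_threshold: float = 0.0) -> GroupModel:
    """Backward-eliminate group parameters that do not support the evidence.

    Each pass evaluates every single-parameter switch-off by BMR and
    removes the one with the largest evidence *increase*, provided
    delta_F >= prune_threshold (default 0: removal must not lower the
    evidence). Ties break by label order. Stops when no removal
    qualifies, or when only one parameter would remain.
    """
    current = group
    while current.n_params > 1:
        best_label, best_dF, best_post = None, -np.inf, None
        for lab in current.labels:  # label order = deterministic tie-break
            spec = ReducedPriorSpec(switched_off=(lab,))
            try:
                post, dF = bayesian_model_reduction(current, spec)
            except InvalidReductionError:
                continue
            if dF > best_dF:
                best_label, best_dF, best_post = lab, dF, post
        if best_label is None or best_dF < prune_threshold:
            break
        current = replace(
            current,
            beta_prior=current.beta_prior.marginal(list(best_post.labels)),
            beta_posterior=best_post,
            Q0=np.eye(best_post.dim) * current.Q0[0, 0],
            Q1=np.eye(best_post.dim) * current.Q1[0, 0],
            free_energy=current.free_energy + best_dF,
            switched_off=tuple(sorted(current.switched_off + (best_label,))),
        )
    if current.n_params == 1 and current is not group:
        warnings.warn(
            "greedy_prune stopped with a single parameter remaining", RuntimeWarning
        )
    return current


def build_comparison_space(
    group: GroupModel,
    retain_threshold: float = -3.0,
    max_models: int = 64,
) -> ModelSpace:
    """Automated comparison space of similar, hard-to-discriminate models.

    Breadth-first search over successive single-parameter eliminations:
    a candidate is retained iff its cumulative log-evidence change
    relative to the *full* model is strictly greater than
    ``retain_threshold`` (default -3 nats, i.e. no more than ~e^3 = 20
    times less probable than the full model). The space always includes
    the full model and is capped at ``max_models`` by keeping the
    highest-evidence reductions.
    """
    labels = group.labels
    retained: dict[tuple[str, ...], float] = {(): 0.0}
    frontier = [()]
    while frontier:
        next_frontier = []
        for off in frontier:
            remaining = [l for l in labels if l not in off]
            if len(remaining) <= 1:
                continue  # never consider the empty model
            for lab in remaining:
                cand = tuple(sorted(off + (lab,)))
                if cand in retained:
                    continue
                spec = ReducedPriorSpec(switched_off=cand)
                try:
                    _, dF = bayesian_model_reduction(group, spec)
                except InvalidReductionError:
                    continue
                if dF > retain_threshold:
                    retained[cand] = dF
                    next_frontier.append(cand)
        frontier = next_frontier

    items = sorted(retained.items(), key=lambda kv: (kv[0] != (), -kv[1], kv[0]))
    if len(items) > max_models:
        items = items[:max_models]
    items.sort(key=lambda kv: kv[0])
    specs = [ReducedPriorSpec(switched_off=off) for off, _ in items]
    return score_model_space(group, specs)
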