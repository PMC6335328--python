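"""Serialization of fits, group models and comparison reports.

Fits travel as structured JSON ("fit containers"): explicit dimension
fields, row-major covariance flattening, and a format version checked
on read. JSON keeps the containers diffable and readable from any
language; round-trips preserve every float bit (numbers are serialized
via Python floats, i.e. IEEE-754 doubles rendered by repr).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


from .gaussian import GaussianDensity
from .glm import ModelFit, ScalarGaussian
from .peb import GroupModel
from .pipeline import DatasetComparison

__all__ = ["FORMAT_VERSION", "write_fits", "read_fits", "write_report"]

FORMAT_VERSION = 1


def _density_to_dict(d: GaussianDensity) -> dict:
    return {
        "dim": d.dim,
        "labels": list(d.labels),
        "mean": d.mean.tolist(),
        "cov": d.cov.ravel(order="C").tolist(),
    }


def _density_from_dict(obj: dict) -> GaussianDensity:
    dim = int(obj["dim"])
    cov = np.asarray(obj["cov"], dtype=float)
    if cov.size != dim * dim:
        raise ValueError(f"covariance has {cov.size} entries, expected {dim * dim}")
    return GaussianDensity(
        np.asarray(obj["mean"], dtype=float),
        cov.reshape(dim, dim, order="C"),
        obj["labels"],
    )


def _fit_to_dict(fit) -> dict:
    if isinstance(fit, ModelFit):
        return {
            "model_kind": "first-level",
            "prior": _density_to_dict(fit.prior),
            "posterior": _density_to_dict(fit.posterior),
            "noise_logprecision": {
                "mean": fit.noise_logprecision.mean,
                "variance": fit.noise_logprecision.variance,
            },
            "free_energy": fit.free_energy,
            "meta": fit.meta,
        }
    if isinstance(fit, GroupModel):
        return {
            "model_kind": "group",
            "n_subjects": fit.n_subjects,
            "beta_prior": _density_to_dict(fit.beta_prior),
            "beta_posterior": _density_to_dict(fit.beta_posterior),
            "gamma_prior": {"mean": fit.gamma_prior.mean, "variance": fit.gamma_prior.variance},
            "gamma_posterior": {
                "mean": fit.gamma_posterior.mean,
                "variance": fit.gamma_posterior.variance,
            },
            "Q0": fit.Q0.ravel(order="C").tolist(),
            "Q1": fit.Q1.ravel(order="C").tolist(),
            "free_energy": fit.free_energy,
            "switched_off": list(fit.switched_off),
            "meta": fit.meta,
        }
    raise TypeError(f"cannot serialize object of type {type(fit).__name__}")


def _fit_from_dict(obj: dict):
    kind = obj.get("model_kind")
    if kind == "first-level":
        return ModelFit(
            prior=_density_from_dict(obj["prior"]),
            posterior=_density_from_dict(obj["posterior"]),
            noise_logprecision=ScalarGaussian(
                float(obj["noise_logprecision"]["mean"]),
                float(obj["noise_logprecision"]["variance"]),
            ),
            free_energy=float(obj["free_energy"]),
            meta=dict(obj.get("meta", {})),
        )
    if kind == "group":
        beta_post = _density_from_dict(obj["beta_posterior"])
        m = beta_post.dim
        return GroupModel(
            n_subjects=int(obj["n_subjects"]),
            beta_prior=_density_from_dict(obj["beta_prior"]),
            beta_posterior=beta_post,
            gamma_prior=ScalarGaussian(
                float(obj["gamma_prior"]["mean"]), float(obj["gamma_prior"]["variance"])
            ),
            gamma_posterior=ScalarGaussian(
                float(obj["gamma_posterior"]["mean"]),
                float(obj["gamma_posterior"]["variance"]),
            ),
            Q0=np.asarray(obj["Q0"], dtype=float).reshape(m, m, order="C"),
            Q1=np.asarray(obj["Q1"], dtype=float).reshape(m, m, order="C"),
            free_energy=float(obj["free_energy"]),
            switched_off=tuple(obj.get("switched_off", [])),
            meta=dict(obj.get("meta", {})),
        )
    raise ValueError(f"unknown model_kind {kind!r}")


def write_fits(fits, path) -> None:
    """Write a list of ModelFit/GroupModel objects (or one) to JSON."""
    if isinstance(fits, (ModelFit, GroupModel)):
        fits = [fits]
    payload = {
        "format_version": FORMAT_VERSION,
        "fits": [_fit_to_dict(f) for f in fits],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fits(path) -> list:
    """Read a fit container; validates version and density invariants."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"truncated or malformed fit container {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"fit container {path} has format version {version!r}; "
            f"this reader supports {FORMAT_VERSION}"
        )
    return [_fit_from_dict(obj) for obj in payload["fits"]]


def write_report(comparison: DatasetComparison, out_dir) -> Path:
    """Write the comparison as a CSV table plus a human-readable summary.

    Returns the CSV path. Columns: dataset, certainty_rel,
    param_info_gain_rel, model_info_gain, best_model, best_model_prob.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = comparison.to_frame()
    csv_path = out_dir / "comparison.csv"
    frame.to_csv(csv_path, index=False, float_format="%.12g")

    lines = ["Bayesian data comparison", "=" * 24, ""]
    lines.append(frame.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    lines.append("")
    lines.append(f"model space: {comparison.n_models} models "
                 f"(max information gain ln k = {np.log(comparison.n_models):.2f} nats)")
    for name, title in (
        ("certainty", "parameter certainty"),
        ("param_info_gain", "information gain (parameters)"),
        ("model_info_gain", "information gain (models)"),
    ):
        lines.append("")
        lines.append(f"pairwise comparisons - {title}")
        prob = comparison.pairwise_probabilities[name]
        ids = comparison.dataset_ids
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if j <= i:
                    continue
                delta = np.log(prob[i, j] / (100.0 - prob[i, j])) if 0 < prob[i, j] < 100 else np.inf
                better, worse, pct = (a, b, prob[i, j]) if prob[i, j] >= 50 else (b, a, prob[j, i])
                lab = comparison.labels[name][i][j]
                lines.append(
                    f"  {better} vs {worse}: {abs(delta):.2f} nats = {pct:.2f}% ({lab})"
                )
    (out_dir / "comparison.txt").write_text("\n".join(lines) + "\n")
    return csv_path
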