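# bdc — Bayesian data comparison

Which of several datasets is **best for inference**? Classical likelihood-ratio
machinery (F-tests, Bayes factors) cannot answer this: it compares models
fitted to *the same* data, never the data themselves. `bdc` implements
Bayesian data comparison — a framework for scoring candidate datasets (e.g.
the same subjects scanned under different fMRI acquisition protocols) by the
quality of the group-level inferences they support.

Each dataset is fitted subject-by-subject with a Bayesian model (here, a
variational Bayesian GLM; any probabilistic fit with a Gaussian posterior
works). Subject posteriors are summarized at the group level with a
hierarchical Bayesian GLM estimated by **parametric empirical Bayes (PEB)**:

```
theta_i = beta + eps_i,     eps_i ~ N(0, (Q0 + e^{-gamma} Q1)^{-1})
```

where `beta` holds the group-mean effects and a single log-precision
hyperparameter `gamma` captures between-subject variability. Each dataset's
group model is then scored with three information measures, all in nats:

- **(a) parameter certainty** — the negative entropy `-1/2 ln|2 pi e Sigma|`
  of the group posterior over the parameters of interest (higher = more
  precise estimates); reported relative to the worst dataset;
- **(b) information gain over parameters** — the KL-divergence from the
  group-level priors to posteriors (how much the data taught us about the
  parameters); relative to the worst dataset;
- **(c) information gain over models** — the KL-divergence from a flat prior
  over a space of `k` competing reduced models to the softmax posterior over
  their log evidences (how well the dataset separates hypotheses); absolute,
  bounded by `ln k`.

Reduced-model evidences come from **Bayesian model reduction (BMR)**, which
computes posteriors and log evidences under modified priors analytically from
the fitted full model. The model space is built automatically: the pooled
group model (blind to dataset membership) is pruned of redundant parameters,
and single-parameter eliminations are explored breadth-first, keeping every
model within 3 nats (~20-fold odds) of the full model. Differences between
datasets map to probabilities through the two-way softmax
`p = e^delta / (1 + e^delta)` and to the conventional Kass–Raftery labels
(1.1–3 nats "positive", 3–5 "strong", >5 "very strong" evidence).

A built-in simulation module generates multi-subject GLM datasets across a
grid of signal-to-noise ratios (SNR = modelled-signal variance over residual
variance) and re-derives the face-validity results for the whole pipeline.

## Worked example

Compare two simulated datasets — the same 16 subjects "scanned" at SNR 0.01
and at SNR 0.5 — using the enumerated 7-model space over the three
experimental effects:

```python
import numpy as np
from bdc import (CompareOptions, SimulationConfig, compare_datasets,
                 evidence_label, fit_dataset, generate_dataset,
                 probability_from_difference)

cfg = SimulationConfig(n_subjects=16, snr_grid=np.array([0.01, 0.5]),
                       master_seed=0)
fits = {f"snr{snr:.2f}": fit_dataset(generate_dataset(cfg, 0, k), cfg)
        for k, snr in enumerate(cfg.snr_grid)}
comp = compare_datasets(fits, options=CompareOptions(space="full"))
print(comp.to_frame().to_string(index=False))

i, j = comp.dataset_ids.index("snr0.50"), comp.dataset_ids.index("snr0.01")
d = comp.certainty_rel[i] - comp.certainty_rel[j]
print(f"certainty difference: {d:.2f} nats = "
      f"{probability_from_difference(d):.2f}% ({evidence_label(abs(d))})")
```

prints

```
dataset  certainty_rel  param_info_gain_rel  model_info_gain best_model  best_model_prob
snr0.01       0.000000             0.000000         1.446514       full         0.849551
snr0.50       1.984784             2.326396         1.925248       full         0.996959

certainty difference: 1.98 nats = 87.92% (positive evidence)
```

Read this as: the high-SNR dataset yields group parameter estimates about
2 nats more certain than the low-SNR dataset — an 88% probability that it is
the better dataset on this measure ("positive evidence" on the Kass–Raftery
scale) — its posteriors gain 2.3 nats more information from the data, and it
nearly saturates the model-discrimination ceiling (`ln 7 = 1.95` nats for the
7-model space), identifying the generating (full) model with probability
0.997 versus 0.850 for the noisy dataset.

The same analysis is available from the shell:

```sh
bdc fit-glm --response y.csv --design X.csv --out subj01.json
bdc compare --fits mb1=ds1.json --fits mb4=ds4.json --space auto --out report/
bdc simulate --seed 1 --reduced --out sweep/
bdc report report/
```

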