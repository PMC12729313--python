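# asircast

Interpretable forecasting of sex–age stratified incidence panels
(age-standardized rates per 100,000) with a dual-pathway deep network:

- **Data layer** — long-format CSV ingestion with strict validation, per-series
  Z-score standardization fitted on the training years only (leakage-free), and
  a synthetic-panel generator with known ground-truth dynamics (linear,
  logistic, or piecewise trends; configurable noise and male–female offsets).
- **Features** — each standardized series is expanded into six columns
  (original, 3-year trailing mean, residual, 3-year rolling SD, male−female
  gap, EWMA), giving 144 model inputs for the canonical 24-series panel;
  10-year sliding windows with next-year targets and a walk-forward
  train/test split at a boundary year.
- **Model** — per-timestep input projection (affine + batch norm + ReLU),
  stacked BiLSTM, multi-scale multi-head attention over short/medium/long lag
  windows, a shared ReLU layer with one affine head per sex–age group, and a
  learnable convex fusion with a linear pathway on the time-averaged inputs.
  Ensembles average members trained from perturbed seeds. Everything runs on a
  small reverse-mode autodiff engine over NumPy (no deep-learning framework
  required).
- **Training** — Adam with cosine learning-rate annealing, global-norm
  gradient clipping, early stopping on a time-ordered validation tail, and
  the five standard regression metrics (MAE, MSE, RMSE, MAPE, R²).
- **PSO** — particle swarm hyperparameter search with linearly decaying
  inertia, per-dimension random coefficients, velocity clamping, and a mixed
  continuous/integer search space decoded by nearest-admissible rounding.
- **Interpretability** — exact Shapley enumeration for small models, a
  gradient/path-integration approximation for the full network, global and
  stratified group importance tables, local signed decompositions, and the
  deep-vs-linear pathway contribution split.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (structural counts,
equation oracles against scalar reimplementations, swarm analytics, Shapley
axioms, stochastic method-behavior analogues on synthetic panels, and
leakage guards). The full suite takes a couple of minutes on one CPU.

## CLI

```sh
# generate a synthetic panel (CSV + ground-truth JSON)
asircast simulate --out panel.csv --trend piecewise --changepoint-year 2010 --seed 1

# full pipeline: simulate -> featurize -> train -> evaluate (-> explain)
asircast run --simulate --outdir artifacts/ --seed 1 --explain

# on real data, with PSO search and the five-configuration ablation table
asircast run --input panel.csv --outdir artifacts/ --pso --ablation
```

`run` writes the scaler, feature manifest, metrics, per-year predictions,
training history, optional PSO trace / ablation table / attribution exports,
and a fully resolved config for reproduction. Exit codes: 0 success,
2 config error, 3 data validation error, 4 numerical failure.

A YAML file passed via `--config` may override any of the `hyperparameters`,
`training`, `swarm`, or `synthetic` sections, e.g.

```yaml
hyperparameters: {d_h: 32, n_lstm_layers: 1}
training: {max_epochs: 200}
```

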