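# spectune

Automated one-dimensional CNN model selection for spectroscopic regression.

Chemometric deep-learning models — for example 1D-CNNs that estimate soil
organic carbon (SOC, g·kg⁻¹) from visible–near-infrared (vis–NIR) diffuse
reflectance spectra — are usually tuned by hand, which is slow, hard to
reproduce, and says nothing about *which* hyperparameters actually matter.
`spectune` automates the whole loop for anyone modelling fixed-length 1-D
signals:

* a **parametric, tree-structured hyperparameter space** for 1D-CNNs:
  Conv-blocks (convolution → optional batch-norm → activation → optional
  pooling → optional dropout), FC-blocks (dense → optional batch-norm →
  activation → optional dropout) and a linear output unit, plus ON/OFF state
  flags for five spectral preprocessing channels — reflectance R, absorbance
  ABS = log₁₀(1/R), ABS + 1st/2nd derivative, and ABS + standard normal
  variate;
* a **TPE Bayesian optimiser** (tree-structured Parzen estimator) that
  minimises the k-fold cross-validated RMSE

      objective(λ) = (1/k) Σᵢ RMSE(λ, D_train⁽ⁱ⁾, D_valid⁽ⁱ⁾)

  over configurations λ, with a **random-search baseline** producing
  schema-identical histories for comparison;
* **functional-ANOVA hyperparameter importance**: a random-forest surrogate
  fitted to the search history, with each hyperparameter's main-effect
  variance fraction computed by *exact* cell-volume marginal integration of
  every tree;
* a **synthetic vis–NIR generator** (4201-point spectra on 400–2500 nm,
  broad overlapping Gaussian absorption bands, right-skewed positive target
  driving the band depths) so the whole pipeline is testable without any
  external spectral library;
* a self-contained vectorised **numpy training backend** (conv/BN/pooling/
  dropout/dense layers with hand-derived backprop, Adagrad/RMSProp/Adam,
  early stopping) — no deep-learning framework required.

See `docs/methods.md` for the model, numerical choices and limitations.

## Worked example

Generate 200 synthetic spectra, downsample 1:20 to the 211-point working
grid, and run a small 10-trial TPE search with 2-fold cross-validation and a
reduced epoch budget:

```bash
spectune simulate --n 200 --seed 1 --downsample 20 --out spectra.csv
spectune optimize --data spectra.csv --trials 10 --folds 2 --seed 0 \
    --epochs-cap 60 --patience 10 --out-dir run/
```

which logs one line per trial and ends with the best configuration found:

```
INFO spectune: trial 0 [startup] objective=40.6121 best=40.6121 status=ok
INFO spectune: trial 1 [startup] objective=46.0109 best=40.6121 status=infeasible
...
INFO spectune: trial 5 [tpe] objective=28.3776 best=28.3776 status=ok
...
best objective 28.3776 at trial 5; artefacts in run
```

The objective is the cross-validated RMSE in target units (g·kg⁻¹ for the
SOC role); `status=infeasible` marks configurations whose width arithmetic
collapses — they receive a finite penalty (2 × sd of the target) instead of
training. `run/` contains `history.jsonl` (one trial per line),
`best_config.json`, `convergence.csv` (running best per trial),
`space.json` and `run_config.json` — enough to resume (`--resume`) or to
analyse importance:

```bash
spectune importance --history run/history.jsonl --space-file run/space.json \
    --out importance.csv
```

A dry-run of the architecture builder reproduces a model's exact layer table
without training. For the reference optimal SOC model (4 input channels, one
Conv-block: 55 filters, kernel 5, stride 4, Same padding, SELU; FC-blocks of
251 and 219 nodes) on a 211-point input:

```bash
python - <<'PY'
from spectune import build, optimal_lucas_config
arch = build(optimal_lucas_config(), input_width=211, input_channels=4)
for ly in arch.layers[:4]:
    print(ly.layer_type, ly.params, ly.output_width)
print("parameters:", arch.n_parameters)
PY
```

```
convolutional {'kernel': 5, 'filters': 55, 'stride': 4, 'padding': 'Same'} 53
activation {'activation': 'SELU'} 53
flatten {} 2915
dense {'units': 251} 251
parameters: 789419
```

— the conv layer maps 211 points to ceil(211/4) = 53, and flattening 53 × 55
filters gives the 2915-wide dense input.

## Data format

Spectra tables are delimited text: header = wavelengths in nm plus a
`target` column, one row per sample, reflectance in (0, 1]. Search spaces
serialise to YAML/JSON; histories to JSON-lines.
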