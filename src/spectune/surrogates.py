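"""Deterministic surrogate objectives for fast optimiser benchmarking.

Training a network per trial is the real objective, but optimiser behaviour
(convergence, conditional sampling, importance analysis) is best exercised on
objectives that cost microseconds. Two are packaged:

* ``cnn_proxy`` — a deterministic function on the full model space shaped
  like the real problem's known landscape: training-related hyperparameters
  (optimiser, batch size, epoch budget) matter most, a single Conv-block is
  best, the absorbance first-derivative channel helps a little, and the
  remaining hyperparameters have mild effects. Its values are on the RMSE
  scale (g/kg role).
* ``quadratic`` — a separable quadratic bowl on a small continuous space,
  minimised at x = 0.3 in every coordinate.
"""

from __future__ import annotations

import math

from .space import Configuration, HyperparameterDef, SearchSpace

__all__ = ["cnn_proxy_objective", "quadratic_objective", "quadratic_space", "get_surrogate"]


def cnn_proxy_objective(config: Configuration) -> float:
    """RMSE-scale proxy for the spectroscopic 1D-CNN objective."""
    v = config.values
    value = 10.0
    epochs = float(v["epochs"])
    lo_e, hi_e = 1.0, 1500.0
    value += 6.0 * (hi_e - epochs) / (hi_e - lo_e)
    batch = float(v["batch_size"])
    value += 4.0 * abs(math.log(batch / 1000.0)) / math.log(1000.0 / 16.0)
    value += {"Adam": 0.0, "RMSProp": 1.5, "Adagrad": 3.0}[v["optimiser"]]
    value += 2.0 * (int(v["n_conv_blocks"]) - 1)
    value += 0.3 * (int(v["n_fc_blocks"]) - 1)
    if v.get("channel_abs_d1") == "ON":
        value -= 0.7
    value += 0.3 * abs(int(v["conv1_kernel"]) - 5) / 8.0
    value += 0.5 * abs(float(v["fc_dropout_rate"]) - 0.22)
    return value


def quadratic_space(n_dims: int = 3) -> SearchSpace:
    return SearchSpace(
        [HyperparameterDef(f"x{i + 1}", "continuous", (0.0, 1.0)) for i in range(n_dims)]
    )


def quadratic_objective(config: Configuration) -> float:
    return sum((float(x) - 0.3) ** 2 for x in config.values.values())


def get_surrogate(name: str):
    """Resolve a packaged surrogate by name -> (space_factory, objective)."""
    if name in ("cnn_proxy", "cnn-proxy"):
        from .space import default_space

        return (lambda: default_space(n_samples=17607)), cnn_proxy_objective
    if name == "quadratic":
        return quadratic_space, quadratic_objective
    raise ValueError(f"unknown surrogate {name!r}")
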