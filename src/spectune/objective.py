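"""The k-fold cross-validated RMSE objective.

A hyperparameter configuration λ is scored by training its 1D-CNN on each of
k cross-validation folds and averaging the validation-fold RMSEs:

    objective(λ) = (1/k) Σ_i RMSE(λ, D_train^(i), D_valid^(i))

Infeasible architectures and diverged trainings receive a finite penalty
(twice the target's standard deviation — strictly worse than the trivial
mean predictor) so the optimiser gets an informative signal instead of an
exception.

Fold hygiene: channel standardisation statistics, the target scaler and the
early-stopping monitor split are all computed from the training side of each
fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .builder import InfeasibleArchitectureError, build, channel_states_from_config
from .datasets import SpectraDataset
from .preprocessing import ChannelScaler, assemble
from .space import Configuration

__all__ = [
    "FoldSplit",
    "ObjectiveValue",
    "TrainingSettings",
    "kfold_split",
    "rmse",
    "evaluate",
    "penalty_objective",
]


@dataclass(frozen=True)
class FoldSplit:
    """A k-fold partition: assignments[i] is the fold index of sample i."""

    k: int
    assignments: np.ndarray
    seed: int

    def train_valid(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        valid = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, valid


@dataclass
class ObjectiveValue:
    """Mean and per-fold cross-validated RMSE for one configuration."""

    mean_rmse: float
    fold_rmses: list[float] = field(default_factory=list)
    status: str = "ok"  # ok | infeasible | failed
    detail: str = ""

    def __post_init__(self) -> None:
        if self.status == "ok" and self.fold_rmses:
            assert np.isclose(self.mean_rmse, float(np.mean(self.fold_rmses)))


@dataclass(frozen=True)
class TrainingSettings:
    """Early stopping and backend settings; epochs come from the configuration.

    monitor_fraction of each training fold is held out to monitor early
    stopping (never the validation fold). Learning rates default to the
    backend's per-optimiser values.
    """

    monitor_fraction: float = 0.15
    patience: int = 50
    min_delta: float = 0.0
    seed: int = 0
    learning_rate: float | None = None
    max_epochs_cap: int | None = None  # optional hard cap for desk-scale runs

    def __post_init__(self) -> None:
        if not 0.0 < self.monitor_fraction < 1.0:
            raise ValueError("monitor_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def kfold_split(n: int, k: int, seed: int = 0) -> FoldSplit:
    """Random permutation partitioned into k near-equal folds (sizes differ
    by at most one); deterministic given the seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for fold, size in enumerate(sizes):
        assignments[perm[start : start + size]] = fold
        start += size
    return FoldSplit(k=k, assignments=assignments, seed=seed)


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error sqrt(mean((y - yhat)^2))."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def monitor_split(
    train_idx: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split a fold's training rows into (fit, monitor) subsets for early
    stopping; the monitor never touches the fold's validation rows."""
    n_tr = len(train_idx)
    n_mon = min(max(1, int(round(fraction * n_tr))), n_tr - 1)
    order = rng.permutation(n_tr)
    return train_idx[order[n_mon:]], train_idx[order[:n_mon]]


def penalty_objective(ds: SpectraDataset) -> float:
    """Penalty for infeasible/failed trials: 2 x sd(target), strictly worse
    than predicting the mean."""
    return 2.0 * float(np.std(ds.target))


def evaluate(
    config: Configuration,
    ds: SpectraDataset,
    k: int = 10,
    settings: TrainingSettings | None = None,
) -> ObjectiveValue:
    """Cross-validated mean RMSE of the 1D-CNN described by `config`.

    Per fold: assemble the ON channels, standardise them with statistics
    fitted on the training rows, z-scale the target on the training rows,
    train with the configuration's optimiser / batch size / epoch budget
    under early stopping, predict the validation fold and score RMSE in the
    original target units.
    """
    settings = settings or TrainingSettings()
    penalty = penalty_objective(ds)
    states = channel_states_from_config(config)
    if states.n_active == 0:
        return ObjectiveValue(penalty, [], "infeasible", "no input channels ON")
    try:
        arch = build(config, input_width=ds.n_points, input_channels=states.n_active)
    except InfeasibleArchitectureError as exc:
        return ObjectiveValue(penalty, [], "infeasible", str(exc))

    stack = assemble(ds, states)
    split = kfold_split(ds.n_samples, k, seed=settings.seed)
    max_epochs = int(config["epochs"])
    if settings.max_epochs_cap is not None:
        max_epochs = min(max_epochs, settings.max_epochs_cap)
    fold_rmses: list[float] = []
    for fold in range(k):
        tr, va = split.train_valid(fold)
        scaler = ChannelScaler().fit(stack, rows=tr)
        scaled = scaler.transform(stack)
        # channels-first layout for the network
        x_all = np.transpose(scaled.data, (0, 2, 1))
        y_mu = float(ds.target[tr].mean())
        y_sd = float(ds.target[tr].std()) or 1.0
        y_all = (ds.target - y_mu) / y_sd

        fold_rng = np.random.default_rng([settings.seed, fold])
        fit_idx, mon_idx = monitor_split(tr, settings.monitor_fraction, fold_rng)

        network = nn.build_network(arch, fold_rng)
        try:
            predictor = nn.train_network(
                network,
                optimiser_name=config["optimiser"],
                batch_size=int(config["batch_size"]),
                max_epochs=max_epochs,
                x_train=x_all[fit_idx],
                y_train=y_all[fit_idx],
                x_monitor=x_all[mon_idx],
                y_monitor=y_all[mon_idx],
                rng=fold_rng,
                patience=settings.patience,
                min_delta=settings.min_delta,
                learning_rate=settings.learning_rate,
            )
        except nn.TrainingDivergedError as exc:
            return ObjectiveValue(penalty, [], "failed", f"fold {fold}: {exc}")
        pred = predictor.predict(x_all[va]) * y_sd + y_mu
        fold_rmses.append(rmse(ds.target[va], pred))
    return ObjectiveValue(float(np.mean(fold_rmses)), fold_rmses, "ok")
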