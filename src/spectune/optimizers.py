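"""Search-history bookkeeping, random search, and the TPE Bayesian optimiser.

The tree-structured Parzen estimator (TPE) starts with uniformly sampled
startup trials, then repeatedly: splits the history H into "good" trials
(objectives below the γ-quantile) and "bad" trials, fits per-hyperparameter
densities l (good) and g (bad), draws candidates from l respecting the
conditional tree (parents first, children only when active), and evaluates
the candidate maximising Σ [log l(x) - log g(x)] over its active
hyperparameters — the Expected-Improvement ranking for this surrogate.

Numeric hyperparameters use 1-D Gaussian Parzen mixtures truncated to the
domain and blended with a uniform prior; categoricals and flags use
Laplace-smoothed category counts. Conditional hyperparameters are estimated
only from trials in which they were active. Failed/penalised trials keep
their penalty objective and therefore land on the "bad" side naturally.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .objective import ObjectiveValue
from .space import Configuration, HyperparameterDef, SearchSpace, sample_uniform, validate

__all__ = [
    "Trial",
    "History",
    "TPEParams",
    "random_search",
    "split_history",
    "density_estimators",
    "tpe_suggest",
    "tpe_optimize",
]


@dataclass
class Trial:
    index: int
    config: Configuration
    objective: ObjectiveValue
    elapsed: float = 0.0
    origin: str = "random"  # startup | tpe | random

    def to_record(self) -> dict:
        return {
            "index": self.index,
            "origin": self.origin,
            "config": self.config.values,
            "mean_rmse": self.objective.mean_rmse,
            "fold_rmses": self.objective.fold_rmses,
            "status": self.objective.status,
            "detail": self.objective.detail,
            "elapsed": self.elapsed,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Trial":
        return cls(
            index=rec["index"],
            config=Configuration(values=rec["config"]),
            objective=ObjectiveValue(
                mean_rmse=rec["mean_rmse"],
                fold_rmses=list(rec.get("fold_rmses", [])),
                status=rec.get("status", "ok"),
                detail=rec.get("detail", ""),
            ),
            elapsed=rec.get("elapsed", 0.0),
            origin=rec.get("origin", "random"),
        )


@dataclass
class History:
    """Ordered trials plus the space they were drawn from."""

    space: SearchSpace
    trials: list[Trial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def append(self, trial: Trial) -> None:
        self.trials.append(trial)

    @property
    def best_index(self) -> int:
        if not self.trials:
            raise ValueError("empty history")
        return int(np.argmin([t.objective.mean_rmse for t in self.trials]))

    @property
    def best_trial(self) -> Trial:
        return self.trials[self.best_index]

    def running_best(self) -> list[float]:
        out, best = [], np.inf
        for t in self.trials:
            best = min(best, t.objective.mean_rmse)
            out.append(best)
        return out

    def save_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.trials:
                fh.write(json.dumps(t.to_record()) + "\n")

    @classmethod
    def load_jsonl(cls, path, space: SearchSpace) -> "History":
        trials = []
        for line in Path(path).read_text().splitlines():
            if line.strip():
                trials.append(Trial.from_record(json.loads(line)))
        return cls(space=space, trials=trials)


@dataclass(frozen=True)
class TPEParams:
    """TPE internals: startup budget, good/bad quantile γ, candidate count,
    kernel bandwidth rule (Scott, floored at a fraction of the domain width)
    and the uniform-prior blending weight."""

    n_startup: int = 12
    gamma: float = 0.15
    n_candidates: int = 24
    bandwidth_floor_frac: float = 0.01
    prior_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_startup < 1 or self.n_candidates < 1:
            raise ValueError("n_startup and n_candidates must be >= 1")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must be in (0, 1)")


def _as_objective(result) -> ObjectiveValue:
    if isinstance(result, ObjectiveValue):
        return result
    value = float(result)
    return ObjectiveValue(mean_rmse=value, fold_rmses=[value], status="ok")


def _run_trial(objective_fn, config, index, origin) -> Trial:
    t0 = time.perf_counter()
    try:
        obj = _as_objective(objective_fn(config))
    except Exception as exc:  # recorded, search continues
        obj = ObjectiveValue(mean_rmse=float("inf"), fold_rmses=[], status="failed",
                             detail=repr(exc))
    return Trial(index=index, config=config, objective=obj,
                 elapsed=time.perf_counter() - t0, origin=origin)


def random_search(
    space: SearchSpace,
    objective_fn,
    n_trials: int,
    seed: int = 0,
    history: History | None = None,
    callback=None,
) -> History:
    """Evaluate n_trials independent uniform samples of the space."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    history = history if history is not None else History(space=space)
    while len(history) < n_trials:
        i = len(history)
        rng = np.random.default_rng([seed, i])
        config = sample_uniform(space, rng)
        trial = _run_trial(objective_fn, config, i, "random")
        history.append(trial)
        if callback:
            callback(trial)
    return history


def split_history(history: History, gamma: float) -> tuple[list[Trial], list[Trial]]:
    """Good = trials below the γ-quantile of the objective (at least one),
    bad = the rest; ties broken by trial index."""
    done = [t for t in history.trials if t.objective is not None]
    if len(done) < 2:
        raise ValueError("need at least 2 completed trials to split")
    order = sorted(done, key=lambda t: (t.objective.mean_rmse, t.index))
    n_good = max(1, int(np.ceil(gamma * len(done))))
    return order[:n_good], order[n_good:]


# ---------------------------------------------------------------------------
# Parzen densities
# ---------------------------------------------------------------------------


class _NumericParzen:
    """Truncated-Gaussian mixture over observed values blended with a uniform
    prior; integers are sampled continuously then rounded to the lattice."""

    def __init__(self, obs, lo, hi, integer, prior_weight, bandwidth_floor_frac):
        self.obs = np.asarray(obs, dtype=float)
        self.lo, self.hi = float(lo), float(hi)
        self.integer = integer
        self.prior_weight = prior_weight
        width = max(self.hi - self.lo, 1e-12)
        n = len(self.obs)
        sigma = self.obs.std() if n > 1 else 0.0
        scott = sigma * n ** (-0.2) if n else 0.0
        # Two floors keep early exploration alive: kernels never collapse
        # below the lattice spacing on integer domains, and while few points
        # are observed the bandwidth stays a sizeable fraction of the domain
        # (shrinking as evidence accumulates), so the sampler cannot freeze
        # on the first good cluster it finds.
        floor = max(
            bandwidth_floor_frac * width,
            width / min(100.0, n + 2.0) if n else 0.0,
            0.5 if integer else 0.0,
        )
        self.h = max(scott, floor)
        self.width = width
        self._weights = np.full(n + 1, 1.0)
        self._weights[0] = prior_weight
        self._weights /= self._weights.sum()
        if n:
            a = (self.lo - self.obs) / self.h
            b = (self.hi - self.obs) / self.h
            self._norm = stats.norm.cdf(b) - stats.norm.cdf(a)
            self._norm = np.maximum(self._norm, 1e-300)

    def pdf(self, x: float) -> float:
        total = self.prior_weight / self.width
        if len(self.obs):
            z = (x - self.obs) / self.h
            total += float(np.sum(np.exp(-0.5 * z * z) / (self.h * np.sqrt(2 * np.pi))
                                  / self._norm))
        return total / (len(self.obs) + self.prior_weight)

    def sample(self, rng: np.random.Generator) -> float:
        j = rng.choice(len(self._weights), p=self._weights)
        if j == 0:
            x = rng.uniform(self.lo, self.hi)
        else:
            mu = self.obs[j - 1]
            a, b = (self.lo - mu) / self.h, (self.hi - mu) / self.h
            x = float(stats.truncnorm.rvs(a, b, loc=mu, scale=self.h, random_state=rng))
        if self.integer:
            x = int(np.clip(round(x), self.lo, self.hi))
        return x


class _CategoricalDensity:
    """Laplace-smoothed category distribution:
    p(c) = (count_c + w) / (n + K·w) with prior weight w."""

    def __init__(self, categories, counts, prior_weight):
        self.categories = list(categories)
        counts = np.asarray(counts, dtype=float)
        self.probs = (counts + prior_weight) / (counts.sum() + prior_weight * len(counts))

    def pdf(self, value) -> float:
        return float(self.probs[self.categories.index(value)])

    def sample(self, rng: np.random.Generator):
        return self.categories[rng.choice(len(self.categories), p=self.probs)]


def _fit_density(d: HyperparameterDef, trials: list[Trial], params: TPEParams):
    active_vals = [t.config.values[d.name] for t in trials if d.name in t.config.values]
    if d.kind in ("integer", "continuous"):
        return _NumericParzen(
            active_vals, d.domain[0], d.domain[1], d.kind == "integer",
            params.prior_weight, params.bandwidth_floor_frac,
        )
    counts = [sum(1 for v in active_vals if v == c) for c in d.domain]
    return _CategoricalDensity(d.domain, counts, params.prior_weight)


def density_estimators(
    good: list[Trial], bad: list[Trial], space: SearchSpace, params: TPEParams
) -> dict[str, tuple]:
    """Per-hyperparameter (l, g) densities. Conditionals are estimated only
    from trials where they were active; with no active observations a density
    degrades to its uniform prior."""
    return {d.name: (_fit_density(d, good, params), _fit_density(d, bad, params))
            for d in space}


def _lg_ratio(densities, name: str, value) -> float:
    l_d, g_d = densities[name]
    return float(np.log(max(l_d.pdf(value), 1e-300)) - np.log(max(g_d.pdf(value), 1e-300)))


def _pick_value(d: HyperparameterDef, densities, params: TPEParams, rng):
    """Maximise log l - log g for one hyperparameter: exactly over the whole
    domain when it is finite (categoricals/flags), over n_candidates draws
    from l otherwise."""
    if d.kind in ("categorical", "flag"):
        l_d, g_d = densities[d.name]
        # direct ratio (not log difference) so exact ties stay ties and are
        # broken by domain order
        scores = [l_d.pdf(c) / max(g_d.pdf(c), 1e-300) for c in d.domain]
        return d.domain[int(np.argmax(scores))]
    l_d = densities[d.name][0]
    cands = [l_d.sample(rng) for _ in range(params.n_candidates)]
    scores = [_lg_ratio(densities, d.name, c) for c in cands]
    return cands[int(np.argmax(scores))]


def tpe_suggest(
    space: SearchSpace,
    history: History,
    params: TPEParams,
    rng: np.random.Generator,
) -> Configuration:
    """Propose the next configuration.

    Below the startup budget this is a uniform draw. Otherwise each active
    hyperparameter is set to the value maximising its own log l - log g
    (walking parents before children so conditionals are only assigned when
    active): the factored Expected-Improvement rule of practical TPE
    implementations. Finite domains are maximised by enumeration; numeric
    domains over n_candidates draws from l.
    """
    if len(history) < params.n_startup:
        return sample_uniform(space, rng)
    good, bad = split_history(history, params.gamma)
    densities = density_estimators(good, bad, space, params)
    values: dict = {}
    for d in space:
        if space.is_active(d.name, values):
            values[d.name] = _pick_value(d, densities, params, rng)
    channel_flags = [d for d in space if d.group == "input_channel"]
    if channel_flags and all(values.get(d.name) != "ON" for d in channel_flags):
        # all-OFF is invalid; turn ON the channel whose ON state scores best
        best = max(channel_flags, key=lambda d: _lg_ratio(densities, d.name, "ON"))
        values[best.name] = "ON"
    config = Configuration(values=values)
    assert not validate(space, config)
    return config


def tpe_optimize(
    space: SearchSpace,
    objective_fn,
    n_trials: int,
    params: TPEParams | None = None,
    history: History | None = None,
    callback=None,
) -> History:
    """Run TPE for a fixed trial budget; resumable from a partial history.

    Trial i's proposal depends only on (seed, i) and the history content, so
    an interrupted run resumed from its serialised history reproduces the
    uninterrupted one.
    """
    params = params or TPEParams()
    if n_trials < params.n_startup:
        raise ValueError("n_trials must be >= n_startup")
    history = history if history is not None else History(space=space)
    while len(history) < n_trials:
        i = len(history)
        rng = np.random.default_rng([params.seed, i])
        if i < params.n_startup:
            config, origin = sample_uniform(space, rng), "startup"
        else:
            config, origin = tpe_suggest(space, history, params, rng), "tpe"
        trial = _run_trial(objective_fn, config, i, origin)
        history.append(trial)
        if callback:
            callback(trial)
    return history
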