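"""Tree-structured hyperparameter space for 1D-CNN spectroscopic models.

The space is mixed-typed (integers, continuous values, categoricals and
ON/OFF flags) and conditional: a hyperparameter may only be active when its
parent takes particular values (e.g. pool size exists only when the pooling
state of its Conv-block is ON, and Conv-block 2's hyperparameters exist only
when at least two Conv-blocks are requested). Conditions form a tree, which
is what makes Parzen-estimator optimisation applicable.

`default_space` builds the full model space: five input-channel states,
block counts, per-block convolution / pooling / dense hyperparameters, shared
dropout rates, the optimiser family, batch size and the epoch budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "HyperparameterDef",
    "SearchSpace",
    "Configuration",
    "default_space",
    "validate",
    "sample_uniform",
    "optimal_lucas_config",
    "ACTIVATIONS",
    "OPTIMISERS",
]

ACTIVATIONS = ("ReLU", "LeakyReLU", "ELU", "SELU", "Swish")
OPTIMISERS = ("Adagrad", "RMSProp", "Adam")
FLAG_DOMAIN = ("ON", "OFF")

KINDS = ("integer", "continuous", "categorical", "flag")
GROUPS = ("input_channel", "conv_block", "fc_block", "other")


@dataclass(frozen=True)
class HyperparameterDef:
    """One hyperparameter: its type, domain, optional parent condition, group.

    `condition` is (parent_name, accepted_parent_values): the hyperparameter
    is active only when its parent is active and takes one of those values.
    """

    name: str
    kind: str
    domain: tuple
    condition: tuple[str, tuple] | None = None
    group: str = "other"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.kind in ("integer", "continuous"):
            lo, hi = self.domain
            if lo > hi:
                raise ValueError(f"{self.name}: empty domain [{lo}, {hi}]")
        elif len(self.domain) == 0:
            raise ValueError(f"{self.name}: empty category list")
        if self.kind == "flag" and tuple(self.domain) != FLAG_DOMAIN:
            raise ValueError(f"{self.name}: flag domain must be {FLAG_DOMAIN}")

    def contains(self, value) -> bool:
        if self.kind == "integer":
            return float(value) == int(value) and self.domain[0] <= value <= self.domain[1]
        if self.kind == "continuous":
            return self.domain[0] <= value <= self.domain[1]
        return value in self.domain


@dataclass
class SearchSpace:
    """Ordered hyperparameter definitions; parents precede their children."""

    defs: list[HyperparameterDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for d in self.defs:
            if d.name in seen:
                raise ValueError(f"duplicate hyperparameter name {d.name!r}")
            if d.condition is not None and d.condition[0] not in seen:
                raise ValueError(
                    f"{d.name}: condition parent {d.condition[0]!r} must be defined earlier"
                )
            seen.add(d.name)
        self._by_name = {d.name: d for d in self.defs}

    def __iter__(self):
        return iter(self.defs)

    def __len__(self) -> int:
        return len(self.defs)

    def get(self, name: str) -> HyperparameterDef:
        return self._by_name[name]

    def names(self) -> list[str]:
        return [d.name for d in self.defs]

    def is_active(self, name: str, values: dict) -> bool:
        """Walk the condition chain: active iff every ancestor condition holds."""
        d = self._by_name[name]
        while d.condition is not None:
            parent, accepted = d.condition
            if values.get(parent) not in accepted:
                return False
            d = self._by_name[parent]
        return True

    def is_always_active(self, name: str) -> bool:
        """Structurally unconditional: every ancestor condition covers its
        parent's whole domain (e.g. Conv-block 1 when at least one block is
        always present)."""
        d = self._by_name[name]
        while d.condition is not None:
            parent, accepted = d.condition
            pdef = self._by_name[parent]
            if pdef.kind == "integer":
                lo, hi = pdef.domain
                full = all(v in accepted for v in range(int(lo), int(hi) + 1))
            elif pdef.kind == "continuous":
                full = False
            else:
                full = all(v in accepted for v in pdef.domain)
            if not full:
                return False
            d = pdef
        return True

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        out = []
        for d in self.defs:
            item = {"name": d.name, "kind": d.kind, "domain": list(d.domain), "group": d.group}
            if d.condition is not None:
                item["condition"] = {"parent": d.condition[0], "values": list(d.condition[1])}
            out.append(item)
        return {"hyperparameters": out}

    @classmethod
    def from_dict(cls, payload: dict) -> "SearchSpace":
        defs = []
        for item in payload["hyperparameters"]:
            cond = None
            if "condition" in item:
                cond = (item["condition"]["parent"], tuple(item["condition"]["values"]))
            defs.append(
                HyperparameterDef(
                    name=item["name"],
                    kind=item["kind"],
                    domain=tuple(item["domain"]),
                    condition=cond,
                    group=item.get("group", "other"),
                )
            )
        return cls(defs)

    def save(self, path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(payload, sort_keys=False))
        else:
            path.write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path) -> "SearchSpace":
        path = Path(path)
        text = path.read_text()
        payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(payload)


@dataclass
class Configuration:
    """One concrete hyperparameter assignment (the optimisation variable)."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, name):
        return self.values[name]

    def get(self, name, default=None):
        return self.values.get(name, default)

    def to_json(self) -> str:
        return json.dumps(self.values, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Configuration":
        return cls(values=json.loads(text))


_CHANNEL_FLAGS = (
    ("channel_reflectance", "Reflectance state"),
    ("channel_absorbance", "Absorbance state"),
    ("channel_abs_d1", "ABS+D1 state"),
    ("channel_abs_d2", "ABS+D2 state"),
    ("channel_abs_snv", "ABS+SNV state"),
)


def default_space(
    n_samples: int,
    input_width: int = 211,
    conv_blocks: tuple[int, int] = (1, 4),
    fc_blocks: tuple[int, int] = (1, 3),
    filters: tuple[int, int] = (4, 64),
    kernel: tuple[int, int] = (2, 10),
    stride: tuple[int, int] = (2, 10),
    pool_size: tuple[int, int] = (2, 5),
    pool_stride: tuple[int, int] = (1, 3),
    nodes: tuple[int, int] = (5, 256),
    dropout_rate: tuple[float, float] = (0.0, 0.5),
    epochs: tuple[int, int] = (100, 1500),
    batch_min: int = 16,
) -> SearchSpace:
    """The full 1D-CNN hyperparameter space.

    Batch size spans [batch_min, n_samples] (17,607 for the reference soil
    library). Block hyperparameters are indexed per block; blocks beyond the
    active count are inactive conditionals. Ranges that the problem leaves
    open (block counts, pool size/stride) default to small, configurable
    windows.
    """
    if n_samples < batch_min:
        raise ValueError(f"n_samples must be >= {batch_min}")
    defs: list[HyperparameterDef] = []
    for name, _label in _CHANNEL_FLAGS:
        defs.append(HyperparameterDef(name, "flag", FLAG_DOMAIN, group="input_channel"))

    defs.append(HyperparameterDef("n_conv_blocks", "integer", conv_blocks, group="other"))
    defs.append(HyperparameterDef("n_fc_blocks", "integer", fc_blocks, group="other"))

    def _block_cond(count_name: str, i: int, lo: int, hi: int):
        accepted = tuple(range(i, hi + 1))
        # When even the minimum count includes block i, keep the condition
        # (structural always-active detection handles it) for uniformity.
        return (count_name, accepted)

    c_lo, c_hi = conv_blocks
    for i in range(1, c_hi + 1):
        cond = _block_cond("n_conv_blocks", i, c_lo, c_hi)
        g = "conv_block"
        defs.append(HyperparameterDef(f"conv{i}_filters", "integer", filters, cond, g))
        defs.append(HyperparameterDef(f"conv{i}_kernel", "integer", kernel, cond, g))
        defs.append(HyperparameterDef(f"conv{i}_stride", "integer", stride, cond, g))
        defs.append(
            HyperparameterDef(f"conv{i}_padding", "categorical", ("Same", "Valid"), cond, g)
        )
        defs.append(HyperparameterDef(f"conv{i}_batch_norm", "flag", FLAG_DOMAIN, cond, g))
        defs.append(HyperparameterDef(f"conv{i}_activation", "categorical", ACTIVATIONS, cond, g))
        defs.append(HyperparameterDef(f"conv{i}_pooling", "flag", FLAG_DOMAIN, cond, g))
        pcond = (f"conv{i}_pooling", ("ON",))
        defs.append(
            HyperparameterDef(f"conv{i}_pool_type", "categorical", ("Average", "Max"), pcond, g)
        )
        defs.append(HyperparameterDef(f"conv{i}_pool_size", "integer", pool_size, pcond, g))
        defs.append(HyperparameterDef(f"conv{i}_pool_stride", "integer", pool_stride, pcond, g))
        defs.append(
            HyperparameterDef(f"conv{i}_pool_padding", "categorical", ("Same", "Valid"), pcond, g)
        )
        defs.append(HyperparameterDef(f"conv{i}_dropout", "flag", FLAG_DOMAIN, cond, g))

    f_lo, f_hi = fc_blocks
    for j in range(1, f_hi + 1):
        cond = _block_cond("n_fc_blocks", j, f_lo, f_hi)
        g = "fc_block"
        defs.append(HyperparameterDef(f"fc{j}_nodes", "integer", nodes, cond, g))
        defs.append(HyperparameterDef(f"fc{j}_batch_norm", "flag", FLAG_DOMAIN, cond, g))
        defs.append(HyperparameterDef(f"fc{j}_activation", "categorical", ACTIVATIONS, cond, g))
        defs.append(HyperparameterDef(f"fc{j}_dropout", "flag", FLAG_DOMAIN, cond, g))

    defs.append(HyperparameterDef("conv_dropout_rate", "continuous", dropout_rate, group="other"))
    defs.append(HyperparameterDef("fc_dropout_rate", "continuous", dropout_rate, group="other"))
    defs.append(HyperparameterDef("optimiser", "categorical", OPTIMISERS, group="other"))
    defs.append(HyperparameterDef("batch_size", "integer", (batch_min, n_samples), group="other"))
    defs.append(HyperparameterDef("epochs", "integer", epochs, group="other"))
    return SearchSpace(defs)


def validate(space: SearchSpace, config: Configuration) -> list[str]:
    """Return the list of invariant violations (empty iff valid).

    Checks assignment of every active hyperparameter, absence of orphaned
    conditional values, domain membership, and >= 1 ON input channel.
    """
    violations: list[str] = []
    values = config.values
    known = set(space.names())
    for name in values:
        if name not in known:
            violations.append(f"unknown hyperparameter {name!r}")
    for d in space:
        active = space.is_active(d.name, values)
        present = d.name in values
        if active and not present:
            violations.append(f"{d.name}: active but unassigned")
        elif not active and present:
            violations.append(f"{d.name}: assigned but its condition does not hold")
        elif present and not d.contains(values[d.name]):
            violations.append(f"{d.name}: value {values[d.name]!r} outside domain {d.domain}")
    channel_flags = [d.name for d in space if d.group == "input_channel"]
    if channel_flags and all(values.get(n) != "ON" for n in channel_flags):
        violations.append("all input channels are OFF (need at least one ON)")
    return violations


def _draw(d: HyperparameterDef, rng: np.random.Generator):
    if d.kind == "integer":
        lo, hi = d.domain
        return int(rng.integers(int(lo), int(hi) + 1))
    if d.kind == "continuous":
        return float(rng.uniform(d.domain[0], d.domain[1]))
    return d.domain[int(rng.integers(len(d.domain)))]


def sample_uniform(space: SearchSpace, rng: np.random.Generator) -> Configuration:
    """Draw every active hyperparameter uniformly over its domain.

    Parents are drawn before children so conditionals are drawn only when
    active. The (rare) all-channels-OFF draw is rejected and the channel
    flags redrawn, so the result always passes `validate`.
    """
    values: dict = {}
    for d in space:
        if space.is_active(d.name, values):
            values[d.name] = _draw(d, rng)
    channel_flags = [d for d in space if d.group == "input_channel"]
    while channel_flags and all(values.get(d.name) != "ON" for d in channel_flags):
        for d in channel_flags:
            values[d.name] = _draw(d, rng)
    return Configuration(values=values)


def optimal_lucas_config() -> Configuration:
    """The reported optimal model for the soil library: four input channels,
    one Conv-block (conv 55 filters, kernel 5, stride 4, Same, SELU; BN,
    pooling and dropout all OFF), two FC-blocks (251 and 219 nodes, ELU and
    Swish, BN and dropout ON, dropout rate 0.22), Adam, batch 1105,
    1448 epochs."""
    return Configuration(
        values={
            "channel_reflectance": "ON",
            "channel_absorbance": "ON",
            "channel_abs_d1": "ON",
            "channel_abs_d2": "ON",
            "channel_abs_snv": "OFF",
            "n_conv_blocks": 1,
            "n_fc_blocks": 2,
            "conv1_filters": 55,
            "conv1_kernel": 5,
            "conv1_stride": 4,
            "conv1_padding": "Same",
            "conv1_batch_norm": "OFF",
            "conv1_activation": "SELU",
            "conv1_pooling": "OFF",
            "conv1_dropout": "OFF",
            "fc1_nodes": 251,
            "fc1_batch_norm": "ON",
            "fc1_activation": "ELU",
            "fc1_dropout": "ON",
            "fc2_nodes": 219,
            "fc2_batch_norm": "ON",
            "fc2_activation": "Swish",
            "fc2_dropout": "ON",
            "conv_dropout_rate": 0.0,
            "fc_dropout_rate": 0.22,
            "optimiser": "Adam",
            "batch_size": 1105,
            "epochs": 1448,
        }
    )
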