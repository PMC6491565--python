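"""Run configuration: one YAML/JSON file with per-command sections.

Layout::

    seed: 0
    output_dir: runs/demo
    cohort:
      path: cohort.csv          # or an inline generator spec:
      # spec: {n: 20000, prevalences: [0.35, 0.05, 0.5], ...}
    split:
      train_fraction: 0.7
    network:                    # NetworkSpec fields
      variant: BR
    train:                      # TrainConfig fields; loss is a sub-mapping
      loss: {kind: CL2, gamma: 2.0}
    sweep:
      grid: {gamma: [0, 2]}

Unknown keys anywhere are rejected before any work happens. Command-line
flags override the scalar `seed` and `output_dir`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import SchemaError
from .losses import LossConfig
from .model import TrainConfig
from .network import NetworkSpec
from .simulate import CohortSpec

_TOP_KEYS = {"seed", "output_dir", "cohort", "split", "network", "train", "sweep"}


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise SchemaError(f"unknown keys {sorted(unknown)} in {where} section")


@dataclass
class RunConfig:
    """Validated run configuration shared by all commands."""

    seed: int = 0
    output_dir: Path = Path("runs/groupnet")
    cohort_path: Path | None = None
    cohort_spec: CohortSpec | None = None
    train_fraction: float = 0.7
    network: NetworkSpec = field(default_factory=NetworkSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    sweep_grid: dict | None = None
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _parse_loss(d: dict) -> LossConfig:
    _check_keys(d, {"kind", "gamma", "use_absolute_alpha", "reduction"}, "train.loss")
    return LossConfig(**d)


def _parse_train(d: dict, seed: int) -> TrainConfig:
    d = dict(d)
    _check_keys(
        d,
        {"learning_rate", "epochs", "batch_size", "optimizer", "loss",
         "dropout_rate", "seed", "shuffle"},
        "train",
    )
    loss = _parse_loss(d.pop("loss", {}))
    d.setdefault("seed", seed)
    return TrainConfig(loss=loss, **d)


def load_run_config(path, seed: int | None = None, output_dir=None) -> RunConfig:
    """Load and validate a run config; flags override the scalar fields."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise SchemaError("run config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top-level")

    cfg_seed = int(seed if seed is not None else raw.get("seed", 0))

    cohort_sec = raw.get("cohort", {})
    _check_keys(cohort_sec, {"path", "spec"}, "cohort")
    if "path" in cohort_sec and "spec" in cohort_sec:
        raise SchemaError("cohort section takes either 'path' or 'spec', not both")
    cohort_spec = None
    if "spec" in cohort_sec:
        spec_dict = dict(cohort_sec["spec"])
        spec_dict.setdefault("seed", cfg_seed)
        cohort_spec = CohortSpec.from_dict(spec_dict)

    split_sec = raw.get("split", {})
    _check_keys(split_sec, {"train_fraction"}, "split")

    network = NetworkSpec.from_dict(raw.get("network", {}))
    train = _parse_train(raw.get("train", {}), cfg_seed)

    sweep_sec = raw.get("sweep", {})
    _check_keys(sweep_sec, {"grid"}, "sweep")

    return RunConfig(
        seed=cfg_seed,
        output_dir=Path(output_dir if output_dir is not None else
                        raw.get("output_dir", "runs/groupnet")),
        cohort_path=Path(cohort_sec["path"]) if "path" in cohort_sec else None,
        cohort_spec=cohort_spec,
        train_fraction=float(split_sec.get("train_fraction", 0.7)),
        network=network,
        train=train,
        sweep_grid=sweep_sec.get("grid"),
        raw=raw,
    )
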