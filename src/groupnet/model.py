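"""Model/Results interface: fit a GroupNet to an examination cohort.

Follows the modelling-object convention: :class:`GroupNet` is constructed
from the data (a cohort, a train/test split, a network architecture) and
``fit`` returns a :class:`GroupNetFitResults` object carrying the trained
weights, per-epoch loss traces, and evaluation/summary helpers.

Training recipe defaults are the selected hyper-parameters of the source
study: learning rate 0.002, 20 epochs, batch size 128, dropout 0.5, tanh
activation, focusing parameter gamma = 2, Adam.

The BR variant trains its three disjoint disease heads jointly. Under the
correlated loss, head k's objective is its own loss plus the other heads'
losses weighted by the pairwise label correlations alpha (estimated on
training labels only); because the parameter sets are disjoint and alpha
symmetric, the exact gradient of the summed objective w.r.t. head k is
(1 + sum of incoming alphas) times the head's own loss gradient, which is
what the loop applies.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import (
    CohortTable,
    Scaler,
    SplitIndices,
    lp_encode,
    pmcc_matrix,
    split_cohort,
    standardize,
)
from .exceptions import ConfigError, ValidationError
from .losses import LossConfig, head_gradient_weights, softmax_loss_and_grad
from .metrics import MetricsReport, evaluate_model
from .network import GroupNetwork, NetworkSpec
from .nnet import make_optimizer

OPTIMIZERS = ("Adam", "SGD")


@dataclass
class TrainConfig:
    """Training hyper-parameters (defaults: the selected recipe)."""

    learning_rate: float = 0.002
    epochs: int = 20
    batch_size: int = 128
    optimizer: str = "Adam"
    loss: LossConfig = field(default_factory=lambda: LossConfig(kind="FL", gamma=2.0))
    dropout_rate: float | None = None  # None: use the network spec's rate
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValidationError("epochs and batch_size must be positive")
        if self.optimizer not in OPTIMIZERS:
            raise ValidationError(f"optimizer must be one of {OPTIMIZERS}")


def _batches(n: int, batch_size: int, rng: np.random.Generator, shuffle: bool):
    order = rng.permutation(n) if shuffle else np.arange(n)
    for start in range(0, n, batch_size):  # last partial batch kept
        yield order[start : start + batch_size]


class GroupNet:
    """A GroupNet classifier bound to a cohort.

    Parameters
    ----------
    cohort:
        The raw cohort; features are z-scored internally on training-row
        statistics unless ``standardize=False``.
    network:
        Architecture. Defaults to the BR variant with the {2, 2, 2, 1}
        group block.
    split:
        Train/test rows. If omitted, a stratified 70/30 split seeded by
        the fit seed is drawn at fit time.
    """

    def __init__(
        self,
        cohort: CohortTable,
        network: NetworkSpec | None = None,
        split: SplitIndices | None = None,
        standardize: bool = True,
    ) -> None:
        self.cohort = cohort
        self.network_spec = network if network is not None else NetworkSpec()
        self.split = split
        self._standardize = standardize

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, network: NetworkSpec | None = None, **kwargs
    ) -> "GroupNet":
        """Build from a DataFrame in the canonical f001..f062, H, D, FL layout."""
        from .cohort import LABEL_NAMES

        label_cols = list(LABEL_NAMES)
        feat_cols = [c for c in df.columns if c not in label_cols]
        cohort = CohortTable(
            features=df[feat_cols].to_numpy(dtype=float),
            labels=df[label_cols].to_numpy(),
        )
        return cls(cohort, network=network, **kwargs)

    # ------------------------------------------------------------------

    def _prepare(self, config: TrainConfig):
        split = self.split if self.split is not None else split_cohort(
            self.cohort, 0.7, seed=config.seed
        )
        if self._standardize:
            cohort_std, scaler = standardize(self.cohort, split)
        else:
            cohort_std, scaler = self.cohort, None
        spec = self.network_spec
        if config.dropout_rate is not None and config.dropout_rate != spec.dropout_rate:
            spec = replace(spec, dropout_rate=config.dropout_rate)
        return split, cohort_std, scaler, spec

    def fit(self, config: TrainConfig | None = None) -> "GroupNetFitResults":
        """Train on the training rows; deterministic given the config seed."""
        config = config if config is not None else TrainConfig()
        split, cohort_std, scaler, spec = self._prepare(config)
        network = GroupNetwork(spec, seed=config.seed)
        train_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        network.set_dropout_rng(
            np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        )
        x = cohort_std.features[split.train_rows]
        labels = cohort_std.labels[split.train_rows]
        t0 = time.perf_counter()
        if spec.variant == "LP":
            if config.loss.is_correlated:
                raise ConfigError("correlated loss applies to the BR variant only")
            trace, alpha = self._fit_lp(network, x, labels, config, train_rng), None
        else:
            alpha = self._resolve_alpha(config.loss, labels)
            trace = self._fit_br(network, x, labels, config, train_rng, alpha)
        wall = time.perf_counter() - t0
        return GroupNetFitResults(
            model=self,
            network=network,
            config=config,
            split=split,
            scaler=scaler,
            cohort_std=cohort_std,
            loss_trace=trace,
            alpha=alpha,
            wall_clock=wall,
        )

    @staticmethod
    def _resolve_alpha(loss: LossConfig, train_labels: np.ndarray) -> np.ndarray:
        """Alpha matrix for BR training: zero coupling unless correlated loss."""
        if not loss.is_correlated:
            return np.eye(3)
        if loss.alpha is not None:
            return loss.effective_alpha()
        alpha = pmcc_matrix(train_labels)
        return np.abs(alpha) if loss.use_absolute_alpha else alpha

    def _fit_lp(self, network, x, labels, config, rng) -> np.ndarray:
        y = lp_encode(labels)
        net = network.nets[0]
        opt = make_optimizer(
            config.optimizer, net.parameters(), config.learning_rate
        )
        gamma = config.loss.base_gamma
        trace = np.empty(config.epochs)
        for epoch in range(config.epochs):
            batch_losses = []
            for idx in _batches(len(y), config.batch_size, rng, config.shuffle):
                logits = net.forward(x[idx][:, None, :], train=True)
                loss, dlogits = softmax_loss_and_grad(logits, y[idx], gamma)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/inf loss at epoch {epoch + 1}; "
                        "try a smaller learning rate"
                    )
                net.backward(dlogits)
                opt.step()
                batch_losses.append(loss)
            trace[epoch] = float(np.mean(batch_losses))
        return trace

    def _fit_br(self, network, x, labels, config, rng, alpha) -> np.ndarray:
        gamma = config.loss.base_gamma
        weights = head_gradient_weights(alpha)
        off = alpha - np.diag(np.diag(alpha))
        opts = [
            make_optimizer(config.optimizer, net.parameters(), config.learning_rate)
            for net in network.nets
        ]
        trace = np.empty((config.epochs, 3))
        for epoch in range(config.epochs):
            batch_cl = []
            for idx in _batches(len(labels), config.batch_size, rng, config.shuffle):
                xb = x[idx][:, None, :]
                head_losses = np.empty(3)
                head_grads = []
                for k, net in enumerate(network.nets):
                    logits = net.forward(xb, train=True)
                    loss, dlogits = softmax_loss_and_grad(
                        logits, labels[idx, k], gamma
                    )
                    head_losses[k] = loss
                    head_grads.append(dlogits)
                if not np.all(np.isfinite(head_losses)):
                    raise RuntimeError(
                        f"NaN/inf loss at epoch {epoch + 1}; "
                        "try a smaller learning rate"
                    )
                # CL_k = loss_k + sum_{i != k} alpha_ki loss_i, logged per head;
                # gradient of sum_k CL_k w.r.t. head k = weights[k] * solo grad
                cl = head_losses + off @ head_losses
                for k, net in enumerate(network.nets):
                    net.backward(head_grads[k] * weights[k])
                    opts[k].step()
                batch_cl.append(cl)
            trace[epoch] = np.mean(batch_cl, axis=0)
        return trace


@dataclass
class GroupNetFitResults:
    """Results of one fit: weights, traces, and evaluation helpers."""

    model: GroupNet
    network: GroupNetwork
    config: TrainConfig
    split: SplitIndices
    scaler: Scaler | None
    cohort_std: CohortTable
    loss_trace: np.ndarray
    alpha: np.ndarray | None
    wall_clock: float

    def predict(self, features: np.ndarray | None = None) -> np.ndarray:
        """Probabilities on given raw features (scaled with the fit scaler),
        or on the test rows when omitted."""
        if features is None:
            x = self.cohort_std.features[self.split.test_rows]
        else:
            x = self.scaler.transform(features) if self.scaler else np.asarray(features)
        return self.network.predict(x)

    def evaluate(self, json_path=None) -> MetricsReport:
        return evaluate_model(
            self.network, self.cohort_std, self.split, json_path=json_path
        )

    def weights_hash(self) -> str:
        return self.network.weights_checksum()

    def save_weights(self, path) -> None:
        self.network.save_weights(path)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "GroupNet fit results",
            "====================",
            self.network.summary(),
            f"loss: {cfg.loss.kind} (gamma={cfg.loss.base_gamma}), "
            f"optimizer {cfg.optimizer}, lr {cfg.learning_rate}, "
            f"epochs {cfg.epochs}, batch {cfg.batch_size}, seed {cfg.seed}",
            f"train rows: {len(self.split.train_rows)}, "
            f"test rows: {len(self.split.test_rows)}",
            f"final training loss: "
            f"{np.atleast_1d(self.loss_trace[-1]).round(4).tolist()}",
            f"wall clock: {self.wall_clock:.1f} s",
        ]
        if self.alpha is not None:
            lines.append(f"alpha matrix:\n{np.round(self.alpha, 4)}")
        report = self.evaluate()
        lines.append("test metrics:")
        lines.append(report.table())
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers and the sweep harness


def train_lp(
    cohort: CohortTable,
    split: SplitIndices,
    net: NetworkSpec,
    cfg: TrainConfig,
) -> GroupNetFitResults:
    """Fit the LP (8-class) variant; thin wrapper over :class:`GroupNet`."""
    if net.variant != "LP":
        raise ConfigError("train_lp requires an LP network spec")
    return GroupNet(cohort, network=net, split=split).fit(cfg)


def train_br(
    cohort: CohortTable,
    split: SplitIndices,
    net: NetworkSpec,
    cfg: TrainConfig,
    alpha: np.ndarray | None = None,
) -> GroupNetFitResults:
    """Fit the BR variant; `alpha` overrides the training-label PMCC matrix."""
    if net.variant != "BR":
        raise ConfigError("train_br requires a BR network spec")
    if alpha is not None:
        cfg = replace(cfg, loss=replace(cfg.loss, alpha=np.asarray(alpha, float)))
    return GroupNet(cohort, network=net, split=split).fit(cfg)


#: sweepable hyper-parameter dimensions and where each one lives
SWEEP_DIMENSIONS = (
    "epochs",
    "learning_rate",
    "batch_size",
    "kernel_size",
    "dropout_rate",
    "activation",
    "gamma",
)


def sweep(
    cohort: CohortTable,
    grid: dict[str, list],
    base_net: NetworkSpec,
    base_cfg: TrainConfig,
    split: SplitIndices | None = None,
) -> pd.DataFrame:
    """Train one model per grid point and tabulate its test metrics.

    Supports the seven swept dimensions (epochs, learning rate, batch
    size, kernel size, dropout rate, activation, gamma). A grid point
    that is invalid for the architecture is recorded as a failed cell and
    the sweep continues. Rows are sorted by weighted F1, descending, with
    a deterministic tie-break on the grid order.
    """
    unknown = set(grid) - set(SWEEP_DIMENSIONS)
    if unknown:
        raise ConfigError(f"unknown sweep dimensions {sorted(unknown)}")
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValidationError("sweep grid must be a non-empty mapping of lists")
    if split is None:
        split = split_cohort(cohort, 0.7, seed=base_cfg.seed)

    keys = list(grid)
    rows = []
    for order, values in enumerate(itertools.product(*(grid[k] for k in keys))):
        point = dict(zip(keys, values))
        row: dict = {**point, "grid_order": order}
        try:
            net = base_net
            cfg = base_cfg
            if "kernel_size" in point:
                net = replace(
                    net, block=replace(net.block, kernel_size=point["kernel_size"])
                )
            if "dropout_rate" in point:
                net = replace(net, dropout_rate=point["dropout_rate"])
            if "activation" in point:
                net = replace(net, activation=point["activation"])
            for key in ("epochs", "learning_rate", "batch_size"):
                if key in point:
                    cfg = replace(cfg, **{key: point[key]})
            if "gamma" in point:
                cfg = replace(cfg, loss=replace(cfg.loss, gamma=point["gamma"]))
            result = GroupNet(cohort, network=net, split=split).fit(cfg)
            report = result.evaluate()
            row.update(
                failed=False,
                error="",
                accuracy=report.accuracy,
                subset_accuracy=report.subset_accuracy,
                precision_weighted=report.precision_weighted,
                recall_weighted=report.recall_weighted,
                f1_weighted=report.f1_weighted,
            )
        except (ConfigError, ValidationError, RuntimeError) as exc:
            row.update(
                failed=True,
                error=str(exc),
                accuracy=np.nan,
                subset_accuracy=np.nan,
                precision_weighted=np.nan,
                recall_weighted=np.nan,
                f1_weighted=np.nan,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["f1_weighted", "grid_order"],
        ascending=[False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
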