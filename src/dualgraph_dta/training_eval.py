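"""Training loop, cross-validation, metrics, ablations, Y-scrambling.

Metric conventions
------------------
* CI (concordance index): fraction of label-discordant pairs ordered
  correctly by the predictions, ties in the prediction counting 1/2
  (Gonen-Heller convention).
* rm^2: Roy & Roy external-validation metric
  rm^2 = r^2 * (1 - sqrt(|r^2 - r0^2|)) with r the Pearson correlation of
  (y, yhat) and r0^2 the through-origin coefficient of determination of y
  on yhat (slope k = sum(y*yhat)/sum(yhat^2)). The symmetric averaged
  variant is available via ``variant="average"``.
* Classification metrics (ACC, AUC, BA, MCC, F1) use threshold 0.5; AUC is
  rank-based and threshold-free.

Validation procedures
---------------------
* ``cross_validate``: record-level k-fold CV (k=5 default); within each
  fold's complement a fraction is held out for early stopping.
* ``run_ablation``: trains one of the six assembly variants (full, w/o MG,
  w/o PG, w/o MG/PG, w/o AM -> GCN, w/o DAM -> GAT) under an identical
  protocol.
* ``y_scramble``: for each seed, permutes the labels across *all* of train,
  validation and test, retrains, and reports metrics next to the
  unscrambled run. A genuine model must beat every scrambled replicate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as skm

from .autodiff import Adam, Tensor, as_tensor, gather_rows, glorot
from .data_io import make_cv_folds
from .gnn_core import GraphEncoderConfig, _AttentionLayer, _GCNLayer
from .model import ABLATION_VARIANTS, DualGraphModel, ModelConfig, PairDataset
from .synthetic_data import dictionary_lookup_batch

logger = logging.getLogger(__name__)

REGRESSION_METRICS = ("mse", "mae", "pearson_r", "ci", "rm2")
CLASSIFICATION_METRICS = ("acc", "auc", "ba", "mcc", "f1")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def concordance_index(y: np.ndarray, y_hat: np.ndarray) -> float:
    """CI over all pairs with y_i != y_j; prediction ties count 0.5."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("y and y_hat must be equal-length 1-D arrays, n >= 2")
    dy = y[:, None] - y[None, :]
    dp = y_hat[:, None] - y_hat[None, :]
    mask = dy > 0
    n_pairs = int(mask.sum())
    if n_pairs == 0:
        raise ValueError("concordance index undefined: all labels equal")
    concordant = (dp[mask] > 0).sum() + 0.5 * (dp[mask] == 0).sum()
    return float(concordant / n_pairs)


def rm_squared(y: np.ndarray, y_hat: np.ndarray, variant: str = "plain") -> float:
    """Roy & Roy rm^2; ``variant="average"`` gives the symmetric mean form."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if len(y) < 3 or y.shape != y_hat.shape:
        raise ValueError("need equal-length arrays with n >= 3")
    if np.var(y) == 0 or np.var(y_hat) == 0:
        raise ValueError("rm^2 undefined for zero-variance inputs")

    def _one_direction(obs: np.ndarray, pred: np.ndarray) -> float:
        r2 = stats.pearsonr(obs, pred)[0] ** 2
        k = float(np.sum(obs * pred) / np.sum(pred**2))
        ss_res = float(np.sum((obs - k * pred) ** 2))
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        r0_2 = 1.0 - ss_res / ss_tot
        return r2 * (1.0 - np.sqrt(abs(r2 - r0_2)))

    if variant == "plain":
        return _one_direction(y, y_hat)
    if variant == "average":
        return 0.5 * (_one_direction(y, y_hat) + _one_direction(y_hat, y))
    raise ValueError("variant must be 'plain' or 'average'")


def regression_metrics(y: np.ndarray, y_hat: np.ndarray) -> dict[str, float]:
    """MSE, MAE, Pearson r, CI and rm^2 of a regression run."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    out = {
        "mse": float(skm.mean_squared_error(y, y_hat)),
        "mae": float(skm.mean_absolute_error(y, y_hat)),
        "pearson_r": float(stats.pearsonr(y, y_hat)[0]) if np.var(y_hat) > 0 else 0.0,
        "ci": concordance_index(y, y_hat),
    }
    try:
        out["rm2"] = rm_squared(y, y_hat)
    except ValueError:
        out["rm2"] = float("nan")
    return out


def classification_metrics(y_bin: np.ndarray, p_hat: np.ndarray) -> dict[str, float]:
    """ACC, AUC, BA, MCC and F1 at threshold 0.5."""
    y = np.asarray(y_bin)
    p = np.asarray(p_hat, dtype=np.float64)
    if set(np.unique(y)) - {0, 1} or p.min() < 0 or p.max() > 1:
        raise ValueError("y must be binary and p_hat within [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    pred = (p >= 0.5).astype(int)
    return {
        "acc": float(skm.accuracy_score(y, pred)),
        "auc": float(skm.roc_auc_score(y, p)),
        "ba": float(skm.balanced_accuracy_score(y, pred)),
        "mcc": float(skm.matthews_corrcoef(y, pred)),
        "f1": float(skm.f1_score(y, pred)),
    }


@dataclass
class MetricsReport:
    """Per-fold metrics plus mean +/- sd summaries."""

    task: str  # "regression" | "classification"
    per_fold: list[dict[str, float]] = field(default_factory=list)

    @property
    def metric_names(self) -> tuple[str, ...]:
        return REGRESSION_METRICS if self.task == "regression" else CLASSIFICATION_METRICS

    def mean(self, name: str) -> float:
        return float(np.mean([f[name] for f in self.per_fold]))

    def sd(self, name: str) -> float:
        return float(np.std([f[name] for f in self.per_fold]))

    def summary(self) -> dict[str, dict[str, float]]:
        return {m: {"mean": self.mean(m), "sd": self.sd(m)} for m in self.metric_names
                if all(m in f for f in self.per_fold)}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 60
    batch_size: int = 128
    learning_rate: float = 3e-3
    optimizer: str = "adam"
    seed: int = 0
    loss: str = "mse"  # or "bce"
    early_stop_patience: int = 15
    device: str = "cpu"  # hint only; execution is always CPU NumPy

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss not in ("mse", "bce"):
            raise ValueError("loss must be 'mse' or 'bce'")


@dataclass
class TrainResult:
    model: DualGraphModel
    history: list[dict[str, float]]
    best_epoch: int


def _loss_tensor(pred: Tensor, y: np.ndarray, kind: str) -> Tensor:
    target = as_tensor(y)
    if kind == "mse":
        return ((pred - target) ** 2).mean()
    eps = 1e-9
    p = pred * (1 - 2 * eps) + eps  # clamp away from {0,1}
    return -(target * p.log() + (1 - target) * (1 - p).log()).mean()


def _snapshot(model: DualGraphModel) -> dict:
    return {
        "params": [p.data.copy() for p in model.parameters()],
        "bn": [
            (bn.running_mean.copy(), bn.running_var.copy())
            for bn in (model.fusion.bn1, model.fusion.bn2)
        ],
    }


def _restore(model: DualGraphModel, snap: dict) -> None:
    for p, d in zip(model.parameters(), snap["params"]):
        p.data = d.copy()
    for bn, (rm, rv) in zip((model.fusion.bn1, model.fusion.bn2), snap["bn"]):
        bn.running_mean, bn.running_var = rm.copy(), rv.copy()


def train_model(
    dataset: PairDataset,
    model: DualGraphModel | ModelConfig,
    config: TrainConfig,
    train_idx: np.ndarray | None = None,
    val_idx: np.ndarray | None = None,
) -> TrainResult:
    """Seeded mini-batch Adam training with early stopping on validation loss.

    Returns the best-validation checkpoint (restored in-place). Raises
    ``FloatingPointError`` if the loss goes non-finite.
    """
    rng = np.random.default_rng(config.seed)
    if isinstance(model, ModelConfig):
        model = DualGraphModel(model, rng)
    if train_idx is None:
        train_idx = np.arange(len(dataset))
    train_idx = np.asarray(train_idx, dtype=np.intp)
    y = dataset.labels
    if config.loss == "mse":
        # standardise regression targets on the training partition
        model.label_mean = float(y[train_idx].mean())
        model.label_sd = float(max(y[train_idx].std(), 1e-8))
        y = (y - model.label_mean) / model.label_sd
    opt = Adam(model.parameters(), lr=config.learning_rate)
    best = {"loss": np.inf, "epoch": -1, "snap": _snapshot(model)}
    history: list[dict[str, float]] = []
    stale = 0
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            if len(batch) < 2:  # batch-norm needs >= 2 rows
                continue
            opt.zero_grad()
            pred = model.forward(dataset, batch, training=True, rng=rng)
            loss = _loss_tensor(pred, y[batch], config.loss)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
        epoch_loss /= len(order)
        entry = {"epoch": epoch, "train_loss": epoch_loss}
        if val_idx is not None and len(val_idx):
            val_pred = model.predict(dataset, val_idx)
            val_true = dataset.labels[val_idx]
            val_loss = float(np.mean((val_pred - val_true) ** 2)) if config.loss == "mse" \
                else float(_loss_tensor(as_tensor(val_pred), val_true, "bce").data)
            entry["val_loss"] = val_loss
            if val_loss < best["loss"] - 1e-12:
                best = {"loss": val_loss, "epoch": epoch, "snap": _snapshot(model)}
                stale = 0
            else:
                stale += 1
                if stale > config.early_stop_patience:
                    history.append(entry)
                    break
        history.append(entry)
        logger.debug("epoch %d: %s", epoch, entry)
    if val_idx is not None and best["epoch"] >= 0:
        _restore(model, best["snap"])
    return TrainResult(model=model, history=history, best_epoch=best["epoch"])


def holdout_split(
    n: int, fractions: tuple[float, float, float] = (0.7, 0.15, 0.15), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random train/validation/test index split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def _evaluate(model: DualGraphModel, dataset: PairDataset, idx: np.ndarray,
              task: str) -> dict[str, float]:
    pred = model.predict(dataset, idx)
    y = dataset.labels[idx]
    if task == "classification":
        return classification_metrics(y.astype(int), np.clip(pred, 0, 1))
    return regression_metrics(y, pred)


def _task_of(model_config: ModelConfig) -> str:
    return "classification" if model_config.head_mode == "classification" else "regression"


def cross_validate(
    dataset: PairDataset,
    k: int = 5,
    config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    val_fraction: float = 0.1,
) -> MetricsReport:
    """k-fold CV; each fold's complement donates ``val_fraction`` for early stopping."""
    config = config or TrainConfig()
    model_config = model_config or ModelConfig.reduced()
    split = make_cv_folds(range(len(dataset)), k=k, seed=config.seed)
    report = MetricsReport(task=_task_of(model_config))
    for fold in range(k):
        test_idx = np.asarray(split.fold_indices(fold), dtype=np.intp)
        rest = np.asarray(
            [i for i in range(len(dataset)) if split.fold_of[i] != fold], dtype=np.intp
        )
        rng = np.random.default_rng(config.seed * 1000 + fold)
        rest = rng.permutation(rest)
        n_val = max(2, int(round(val_fraction * len(rest))))
        val_idx, train_idx = rest[:n_val], rest[n_val:]
        fold_cfg = dataclasses.replace(config, seed=config.seed * 1000 + fold)
        result = train_model(dataset, model_config, fold_cfg, train_idx, val_idx)
        report.per_fold.append(_evaluate(result.model, dataset, test_idx, report.task))
        logger.info("fold %d: %s", fold, report.per_fold[-1])
    return report


def run_ablation(
    dataset: PairDataset,
    variant: str,
    config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    mode: str = "holdout",
    k: int = 5,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> MetricsReport:
    """Train and evaluate one architecture variant under a shared protocol."""
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"variant must be one of {ABLATION_VARIANTS}")
    config = config or TrainConfig()
    base = model_config or ModelConfig.reduced()
    variant_config = base.for_variant(variant)
    if mode == "cv":
        return cross_validate(dataset, k=k, config=config, model_config=variant_config)
    if mode != "holdout":
        raise ValueError("mode must be 'holdout' or 'cv'")
    train_idx, val_idx, test_idx = holdout_split(len(dataset), fractions, config.seed)
    result = train_model(dataset, variant_config, config, train_idx, val_idx)
    report = MetricsReport(task=_task_of(variant_config))
    report.per_fold.append(_evaluate(result.model, dataset, test_idx, report.task))
    return report


def y_scramble(
    dataset: PairDataset,
    seeds: Sequence[int] = tuple(range(1, 11)),
    config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> tuple[list[MetricsReport], MetricsReport]:
    """Label-permutation validation.

    For each seed the labels of the whole dataset (train, validation and
    test alike) are shuffled and the full protocol re-run. Returns the
    scrambled reports and the unscrambled reference report.
    """
    config = config or TrainConfig()
    model_config = model_config or ModelConfig.reduced()
    train_idx, val_idx, test_idx = holdout_split(len(dataset), fractions, config.seed)

    def _run(ds: PairDataset) -> MetricsReport:
        result = train_model(ds, model_config, config, train_idx, val_idx)
        rep = MetricsReport(task=_task_of(model_config))
        rep.per_fold.append(_evaluate(result.model, ds, test_idx, rep.task))
        return rep

    original = _run(dataset)
    scrambled = []
    for s in seeds:
        perm = np.random.default_rng(s).permutation(len(dataset))
        scrambled.append(_run(dataset.with_labels(dataset.labels[perm])))
    return scrambled, original


# ---------------------------------------------------------------------------
# evaluation artefacts
# ---------------------------------------------------------------------------

def evaluation_report(y: np.ndarray, y_hat: np.ndarray, out_dir: str | Path,
                      grid_size: int = 256) -> dict[str, float]:
    """Write plottable evaluation artefacts and return the metrics.

    Emits ``scatter.csv`` (actual vs predicted, for a scatter-density plot),
    ``kde.csv`` (Gaussian kernel-density curves of both distributions,
    Scott's-rule bandwidth) and ``metrics.json``.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "scatter.csv", "w") as fh:
        fh.write("actual,predicted\n")
        for a, b in zip(y, y_hat):
            fh.write(f"{a:.6f},{b:.6f}\n")
    lo = min(y.min(), y_hat.min())
    hi = max(y.max(), y_hat.max())
    pad = 0.25 * (hi - lo + 1e-9)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    kde_y = stats.gaussian_kde(y)(grid)
    kde_p = stats.gaussian_kde(y_hat)(grid)
    with open(out / "kde.csv", "w") as fh:
        fh.write("value,density_actual,density_predicted\n")
        for g, a, b in zip(grid, kde_y, kde_p):
            fh.write(f"{g:.6f},{a:.8f},{b:.8f}\n")
    m = regression_metrics(y, y_hat)
    (out / "metrics.json").write_text(json.dumps(m, indent=2))
    return m


# ---------------------------------------------------------------------------
# dictionary-lookup testbed (dynamic vs static attention)
# ---------------------------------------------------------------------------

def dictionary_lookup_error(
    variant: str,
    n_graphs: int = 20,
    k: int = 6,
    seed: int = 0,
    epochs: int = 400,
    hidden: int = 16,
    lr: float = 2e-2,
) -> float:
    """Final training MSE of a one-layer encoder on the key-lookup task.

    Each query node must output the value of the key sharing its id. Static
    attention (GAT) and uniform aggregation (GCN) cannot condition the
    neighbour ranking on the query, so their fit error stays near the
    variance of the values; dynamic attention (GATv2) can drive it far
    lower.
    """
    data = dictionary_lookup_batch(n_graphs, k, seed)
    feats = data["node_features"]
    n_nodes, dim = feats.shape
    rng = np.random.default_rng(seed)
    cfg = GraphEncoderConfig(
        n_layers=1, hidden_dim=hidden, variant=variant, n_heads=1,
        activation="identity",
    )
    from .gnn_core import add_self_loops

    edge_index, edge_feats = add_self_loops(
        data["edge_index"], np.zeros((len(data["edge_index"]), 0)), n_nodes
    )
    if variant == "gcn":
        layer = _GCNLayer(dim, hidden, cfg, rng)
    else:
        layer = _AttentionLayer(dim, hidden, 1, 0, cfg, concat_heads=False, rng=rng)
    w_out = glorot(rng, (hidden, 1))
    params = layer.parameters() + [w_out]
    opt = Adam(params, lr=lr)
    targets = as_tensor(data["targets"].reshape(-1, 1))
    final = np.inf
    for _ in range(epochs):
        opt.zero_grad()
        h = layer.forward(as_tensor(feats), edge_index, edge_feats, n_nodes)
        pred = gather_rows(h, data["query_idx"]) @ w_out
        loss = ((pred - targets) ** 2).mean()
        loss.backward()
        opt.step()
        final = float(loss.data)
    return final


# ---------------------------------------------------------------------------
# hyperparameter-search hook (disabled by default)
# ---------------------------------------------------------------------------

def hpo_hook(objective: Callable[[dict], float] | None = None,
             search_space: dict | None = None, n_trials: int = 0) -> None:
    """Placeholder for an external Bayesian-optimisation driver.

    Hyperparameters are plain config inputs in this package; the hook only
    validates its arguments and refuses to run trials.
    """
    if n_trials > 0:
        raise NotImplementedError(
            "hyperparameter search is not bundled; drive TrainConfig externally"
        )


__all__ = [
    "TrainConfig",
    "TrainResult",
    "MetricsReport",
    "concordance_index",
    "rm_squared",
    "regression_metrics",
    "classification_metrics",
    "train_model",
    "holdout_split",
    "cross_validate",
    "run_ablation",
    "y_scramble",
    "evaluation_report",
    "dictionary_lookup_error",
    "hpo_hook",
    "REGRESSION_METRICS",
    "CLASSIFICATION_METRICS",
]
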