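"""Training protocol: splits, regression metrics, early-stopped Adam, k-fold CV.

The protocol mirrors the reference setup: mean-squared-error loss minimized
with Adam (lr 0.001) for at most 1000 epochs, early-stopped when validation
RMSE has not improved for 60 consecutive epochs, with the best-epoch weights
restored; hyperparameters are compared by mean validation RMSE over 10-fold
cross-validation.

Randomness is derived from one master seed via ``numpy.random.SeedSequence``:
child 0 shuffles minibatches, child 1 drives dropout.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .featurization import MolecularGraph
from .models import ModelConfig, MultiGNNRegressor, batch_graphs, build_model


class TrainingDivergedError(RuntimeError):
    """The loss became non-finite during training."""


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    max_epochs: int = 1000
    patience: int = 60
    batch_size: int = 32
    test_fraction: float = 0.2
    validation_fraction: float = 0.1   # of the training partition, final fits
    cv_folds: int = 10
    seed: int = 0
    min_improvement: float = 1e-6      # strict decrease required to reset patience

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class RegressionMetrics:
    rmse: float
    r_squared: float
    pearson_r: float
    n: int


# -- metrics ------------------------------------------------------------------

def rmse(predicted, observed) -> float:
    """Root mean squared error."""
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    if predicted.size == 0:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def r_squared(predicted, observed) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for zero-variance observations")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    # centered form of (N*sum(xy) - sum(x)sum(y)) / sqrt(...) for stability
    xc = x - x.mean()
    yc = y - y.mean()
    den_x = np.sum(xc * xc)
    den_y = np.sum(yc * yc)
    if den_x <= 0 or den_y <= 0:
        raise ValueError("Pearson r undefined for zero-variance input")
    return float(np.sum(xc * yc) / np.sqrt(den_x * den_y))


def evaluate(model: MultiGNNRegressor, graphs: list[MolecularGraph]) -> RegressionMetrics:
    """Evaluation-mode metrics of a model on a labeled set."""
    signal, labels = batch_graphs(graphs)
    preds = model.predict(signal)
    return RegressionMetrics(rmse=rmse(preds, labels),
                             r_squared=r_squared(preds, labels),
                             pearson_r=pearson_r(preds, labels),
                             n=len(graphs))


# -- splitting ----------------------------------------------------------------

def split_dataset(dataset: list, test_fraction: float = 0.2,
                  seed: int = 0) -> tuple[list, list]:
    """Seeded random train/test split with |test| = round(fraction * n)."""
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    n_test = int(round(test_fraction * n))
    if n_test == 0 or n_test == n:
        raise ValueError(
            f"test_fraction={test_fraction} yields an empty split for n={n}")
    order = np.random.default_rng(seed).permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [dataset[i] for i in range(n) if i not in test_idx]
    test = [dataset[i] for i in sorted(test_idx)]
    return train, test


# -- training loop ------------------------------------------------------------

def train(model: MultiGNNRegressor, train_set: list[MolecularGraph],
          val_set: list[MolecularGraph], config: TrainConfig) -> MultiGNNRegressor:
    """Early-stopped MSE/Adam training; restores the best validation epoch.

    Labels are internally standardized to the training set's mean and
    standard deviation (the fitted transform is stored on the model and
    undone by ``model.predict``); the monitored validation RMSE and all
    reported metrics stay on the original pIC50 scale.

    Appends one record per epoch to ``model.history`` with the epoch's mean
    training loss and validation RMSE.
    """
    from .autodiff import Adam, Tensor

    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    ids = {id(g) for g in train_set}
    if any(id(g) in ids for g in val_set):
        raise ValueError("train and validation sets must be disjoint")

    train_labels = np.array([g.label for g in train_set], dtype=np.float64)
    model.label_mean = float(train_labels.mean())
    scale = float(train_labels.std())
    model.label_scale = scale if scale > 0 else 1.0

    ss = np.random.SeedSequence(config.seed)
    shuffle_rng, dropout_rng = [np.random.default_rng(c) for c in ss.spawn(2)]
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    val_signal, val_labels = batch_graphs(val_set)

    best_rmse = np.inf
    best_state = model.state_arrays()
    epochs_since_improvement = 0

    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(len(train_set))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[start:start + config.batch_size]]
            signal, labels = batch_graphs(batch)
            target = (labels - model.label_mean) / model.label_scale
            preds = model.forward(signal, training=True, rng=dropout_rng)
            residual = preds - Tensor(target)
            loss = (residual * residual).mean()
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch} (lr={config.learning_rate})")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(batch)
        epoch_loss /= len(train_set)

        val_rmse = rmse(model.predict(val_signal), val_labels)
        model.history.append({"epoch": epoch, "train_loss": epoch_loss,
                              "val_rmse": val_rmse})

        if val_rmse < best_rmse - config.min_improvement:
            best_rmse = val_rmse
            best_state = model.state_arrays()
            epochs_since_improvement = 0
        else:
            epochs_since_improvement += 1
            if epochs_since_improvement >= config.patience:
                break

    model.load_state_arrays(best_state)
    return model


def fit(dataset: list[MolecularGraph], model_config: ModelConfig,
        train_config: TrainConfig) -> tuple[MultiGNNRegressor, dict]:
    """Split, train with an internal validation holdout, and report metrics."""
    train_part, test_part = split_dataset(dataset, train_config.test_fraction,
                                          seed=train_config.seed)
    inner_train, val_part = split_dataset(
        train_part, train_config.validation_fraction, seed=train_config.seed + 1)
    model = build_model(model_config)
    train(model, inner_train, val_part, train_config)
    m_train = evaluate(model, train_part)
    m_test = evaluate(model, test_part)
    metrics = {
        "architecture": model_config.architecture,
        "seed": train_config.seed,
        "rmse_train": m_train.rmse, "rmse_test": m_test.rmse,
        "r2_train": m_train.r_squared, "r2_test": m_test.r_squared,
        "epochs_run": len(model.history),
    }
    return model, metrics


# -- cross-validation ---------------------------------------------------------

def cross_validate(dataset: list[MolecularGraph],
                   candidate_configs: list[ModelConfig],
                   train_config: TrainConfig | None = None,
                   folds: int = 10, seed: int = 0):
    """Select the candidate with the lowest mean validation RMSE over k folds.

    Each fold is validated exactly once; fold sizes differ by at most one.
    Returns ``(best_config, results)`` where results maps each candidate
    index to its per-fold validation RMSEs.
    """
    if not candidate_configs:
        raise ValueError("empty candidate config list")
    if folds > len(dataset):
        raise ValueError("more folds than samples")
    train_config = train_config or TrainConfig()
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    results: dict[int, list[float]] = {}
    for ci, config in enumerate(candidate_configs):
        fold_rmses = []
        for fold, (train_idx, val_idx) in enumerate(splitter.split(dataset)):
            model = build_model(config)
            train(model,
                  [dataset[i] for i in train_idx],
                  [dataset[i] for i in val_idx],
                  train_config)
            signal, labels = batch_graphs([dataset[i] for i in val_idx])
            fold_rmses.append(rmse(model.predict(signal), labels))
        results[ci] = fold_rmses
    means = {ci: float(np.mean(v)) for ci, v in results.items()}
    best = min(means, key=means.get)
    return candidate_configs[best], results
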