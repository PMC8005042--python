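"""Composite graph regressors: GIAN, GIAT, SGCA, and single-layer baselines.

Each architecture chains one or two graph layer blocks (batch normalization
between blocks), pools node embeddings to one vector per molecule, and feeds
a fixed fully connected head 100 -> 200 -> 300 -> 200 -> 1 whose last layer
is unactivated. Dropout is applied to the output of ARMA blocks (rate 0.35)
and GAT blocks (rate 0.06) during training only.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, scatter_add
from .featurization import MolecularGraph, build_schema
from . import layers as L
from .layers import (ARMAParams, BatchNormParams, GATParams, GINParams,
                     GraphSignal, LinearParams, SGCParams)

ARCHITECTURES = ("GIAN", "GIAT", "SGCA", "GIN", "GAT", "ARMA", "SGC")

DROPOUT_ARMA = 0.35
DROPOUT_GAT = 0.06


class ConfigurationError(ValueError):
    """Invalid model configuration."""


@dataclass
class ModelConfig:
    """Architecture and hyperparameters of one regressor."""

    architecture: str = "GIAN"
    input_width: int = 46
    gnn_hidden_width: int = 100
    fc_widths: tuple[int, ...] = (200, 300, 200, 1)
    dropout_arma: float = DROPOUT_ARMA
    dropout_gat: float = DROPOUT_GAT
    arma_k: int = 1
    arma_t: int = 1
    gat_heads: int = 1
    sgc_k: int = 2
    pooling: str = "sum"
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(
                f"unknown architecture {self.architecture!r}; "
                f"expected one of {ARCHITECTURES}")
        if self.pooling not in ("sum", "mean"):
            raise ConfigurationError(f"unknown pooling {self.pooling!r}")
        if self.fc_widths[-1] != 1:
            raise ConfigurationError("final FC layer must have width 1")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "fc_widths" in d:
            d["fc_widths"] = tuple(d["fc_widths"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ModelConfig":
        """Load from a YAML or JSON config file."""
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class MultiGNNRegressor:
    """A built (possibly trained) graph regressor with its parameter state."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.history: list[dict] = []
        # Affine label transform fitted by the trainer (predictions from
        # `predict` are returned on the original pIC50 scale).
        self.label_mean = 0.0
        self.label_scale = 1.0
        rng = np.random.default_rng(config.seed)
        d_in, d_h = config.input_width, config.gnn_hidden_width

        first, second = {
            "GIAN": ("gin", "arma"), "GIAT": ("gin", "gat"),
            "SGCA": ("sgc", "arma"), "GIN": ("gin", None),
            "GAT": ("gat", None), "ARMA": ("arma", None), "SGC": ("sgc", None),
        }[config.architecture]

        self.blocks: list[tuple[str, object]] = []
        self.blocks.append((first, self._init_block(first, rng, d_in, d_h)))
        if second is not None:
            self.blocks.append(("bn", BatchNormParams.init(d_h)))
            self.blocks.append((second, self._init_block(second, rng, d_h, d_h)))

        self.fc: list[LinearParams] = []
        widths = (d_h,) + tuple(config.fc_widths)
        for w_in, w_out in zip(widths[:-1], widths[1:]):
            self.fc.append(LinearParams.init(rng, w_in, w_out))

    def _init_block(self, kind: str, rng, d_in: int, d_out: int):
        if kind == "gin":
            return GINParams.init(rng, d_in, d_out)
        if kind == "gat":
            return GATParams.init(rng, d_in, d_out)
        if kind == "arma":
            return ARMAParams.init(rng, d_in, d_out,
                                   K=self.config.arma_k, T=self.config.arma_t)
        if kind == "sgc":
            return SGCParams.init(rng, d_in, d_out, K=self.config.sgc_k)
        raise ConfigurationError(kind)

    # -- parameters -----------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for _, params in self.blocks:
            out.extend(params.tensors())
        for lin in self.fc:
            out.append(lin.W)
            if lin.b is not None:
                out.append(lin.b)
        return out

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data.copy() for p in self.parameters()]
        for kind, params in self.blocks:
            if kind == "bn":
                arrays.append(params.running_mean.copy())
                arrays.append(params.running_var.copy())
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrays):
            p.data = np.array(a, dtype=np.float64)
        extra = arrays[len(params):]
        i = 0
        for kind, block in self.blocks:
            if kind == "bn":
                block.running_mean = np.array(extra[i])
                block.running_var = np.array(extra[i + 1])
                i += 2

    # -- forward --------------------------------------------------------------
    def forward(self, batch: GraphSignal, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Predict one pIC50 per graph in the batch."""
        x = batch.x if isinstance(batch.x, Tensor) else Tensor(batch.x)
        if x.data.shape[1] != self.config.input_width:
            raise L.ContractError(
                f"node feature width {x.data.shape[1]} != "
                f"{self.config.input_width}")
        signal = GraphSignal(x=x, edge_index=batch.edge_index, batch=batch.batch)

        for kind, params in self.blocks:
            if kind == "gin":
                signal = L.gin_update(signal, params)
            elif kind == "gat":
                _, _, signal = L.gat_attention(signal, params)
                signal = self._dropout(signal, self.config.dropout_gat,
                                       training, rng)
            elif kind == "arma":
                signal = L.arma_layer(signal, params)
                signal = self._dropout(signal, self.config.dropout_arma,
                                       training, rng)
            elif kind == "sgc":
                signal = L.sgc_propagate(signal, params)
            elif kind == "bn":
                if training:
                    signal = signal.with_x(L.batch_norm_train(signal.x, params))
                else:
                    signal = signal.with_x(L.batch_norm_inference(signal.x, params))

        pooled = readout(signal, mode=self.config.pooling)
        h = pooled
        for i, lin in enumerate(self.fc):
            h = lin.apply(h)
            if i < len(self.fc) - 1:
                h = h.relu()
        return h.reshape(-1)

    def predict(self, batch: GraphSignal) -> np.ndarray:
        """Evaluation-mode pIC50 predictions on the original label scale."""
        out = self.forward(batch, training=False).data
        return out * self.label_scale + self.label_mean

    @staticmethod
    def _dropout(signal: GraphSignal, rate: float, training: bool,
                 rng: np.random.Generator | None) -> GraphSignal:
        if not training or rate <= 0:
            return signal
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        x = signal.x
        shape = (x.data if isinstance(x, Tensor) else x).shape
        mask = (rng.random(shape) >= rate) / (1.0 - rate)
        return signal.with_x(x * mask)

    # -- persistence ----------------------------------------------------------
    CHECKPOINT_VERSION = 1

    def save(self, path) -> None:
        """Write a single-file checkpoint (config JSON + parameter arrays)."""
        meta = json.dumps({"version": self.CHECKPOINT_VERSION,
                           "config": {**asdict(self.config),
                                      "fc_widths": list(self.config.fc_widths)},
                           "label_mean": self.label_mean,
                           "label_scale": self.label_scale})
        arrays = {f"arr_{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, __meta__=np.array(meta), **arrays)

    @classmethod
    def load(cls, path) -> "MultiGNNRegressor":
        archive = np.load(path, allow_pickle=False)
        meta = json.loads(str(archive["__meta__"]))
        model = cls(ModelConfig.from_dict(meta["config"]))
        model.label_mean = meta.get("label_mean", 0.0)
        model.label_scale = meta.get("label_scale", 1.0)
        arrays = [archive[f"arr_{i}"] for i in range(len(archive.files) - 1)]
        model.load_state_arrays(arrays)
        return model


def build_model(config: ModelConfig) -> MultiGNNRegressor:
    """Build an untrained regressor; parameters are seeded from config.seed."""
    return MultiGNNRegressor(config)


def readout(signal: GraphSignal, mode: str = "sum") -> Tensor:
    """Pool node embeddings to one row per graph (sum by default)."""
    x = signal.x if isinstance(signal.x, Tensor) else Tensor(signal.x)
    batch = signal.batch
    if batch is None:
        batch = np.zeros(x.data.shape[0], dtype=np.int64)
    if x.data.shape[0] == 0:
        raise L.ContractError("cannot pool an empty batch")
    n_graphs = int(batch.max()) + 1
    counts = np.bincount(batch, minlength=n_graphs)
    if (counts == 0).any():
        raise L.ContractError("batch contains an empty graph")
    pooled = scatter_add(x, batch, n_graphs)
    if mode == "mean":
        pooled = pooled * (1.0 / counts.reshape(-1, 1))
    elif mode != "sum":
        raise ConfigurationError(f"unknown pooling {mode!r}")
    return pooled


def forward(model: MultiGNNRegressor, batch: GraphSignal,
            training: bool = False, rng=None) -> np.ndarray:
    """Functional forward pass returning a NumPy vector of predictions."""
    out = model.forward(batch, training=training, rng=rng)
    return out.data if not training else out


def batch_graphs(graphs: list[MolecularGraph]) -> tuple[GraphSignal, np.ndarray]:
    """Concatenate molecules into one disjoint-union GraphSignal.

    Returns the batched signal and the label vector (NaN where unlabeled).
    """
    if not graphs:
        raise ValueError("empty graph list")
    feats, edges, batch_ids, labels = [], [], [], []
    offset = 0
    for i, g in enumerate(graphs):
        feats.append(g.node_features)
        edges.append(g.edge_index + offset)
        batch_ids.append(np.full(g.n_atoms, i, dtype=np.int64))
        labels.append(np.nan if g.label is None else g.label)
        offset += g.n_atoms
    signal = GraphSignal(
        x=np.concatenate(feats, axis=0),
        edge_index=np.concatenate(edges, axis=1),
        batch=np.concatenate(batch_ids),
    )
    return signal, np.array(labels, dtype=np.float64)
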