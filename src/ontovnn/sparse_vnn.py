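"""The two-branch sparse visible neural network.

The model couples

* a **VNN branch** whose layers mirror a layered ontology: layer ``s``
  computes ``O(s) = f(W(s) I(s) + b(s))`` with ``f = tanh`` and a sparse
  weight matrix ``W(s)`` whose nonzero pattern is exactly the hierarchy's
  connectivity mask (``k`` neurons per node);
* a dense **drug branch** over the 2048-bit Morgan fingerprint;
* a **fusion head** that concatenates the two branch outputs, passes them
  through one hidden layer and emits a single scalar — the predicted
  normalized AUDRC.

Weights off the mask do not exist as parameters, so they are exactly zero
before and after any amount of training.  Normalization is either a batch
normalization placed after each activation ("post"), or an
independent-component (IC) block — batch normalization plus dropout — placed
before each weight layer ("ic").  Everything is plain NumPy/SciPy with
hand-written backward passes; the layer classes cache what they need during
the forward pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from .ontology import LayeredHierarchy, SparseConnectivity, build_connectivity

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "SparseVNNModel",
    "compile_model",
    "train",
    "TrainResult",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The presets reproduce the published layer dimensions: the mutation
    preset uses a (100, 50, 6) drug branch, a 6-neuron VNN output and a
    6-neuron fusion layer; the expression preset uses (200, 100, 50), 30 and
    40.  ``k`` neurons represent each ontology node (default 6).
    """

    k: int = 6
    norm_variant: str = "post"  # "post" | "ic" | "none"
    dropout: float = 0.15  # used by the IC variant only
    drug_layers: tuple[int, ...] = (100, 50, 6)
    vnn_output: int = 6
    fusion: int = 6
    drug_input_dim: int = 2048
    activation: str = "tanh"  # "tanh" | "linear" (linear for diagnostics)
    freeze_virtual: bool = False  # pin virtual-node connections at identity (ablation)

    def __post_init__(self) -> None:
        if self.norm_variant not in ("post", "ic", "none"):
            raise ValueError(f"unknown norm_variant {self.norm_variant!r}")
        if self.activation not in ("tanh", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @classmethod
    def mutation_preset(cls, **overrides) -> "ModelConfig":
        base = dict(k=6, drug_layers=(100, 50, 6), vnn_output=6, fusion=6,
                    norm_variant="post")
        base.update(overrides)
        return cls(**base)

    @classmethod
    def expression_preset(cls, **overrides) -> "ModelConfig":
        base = dict(k=6, drug_layers=(200, 100, 50), vnn_output=30, fusion=40,
                    norm_variant="ic")
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (gradient descent with momentum, MSE loss)."""

    learning_rate: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 2e-3
    epochs: int = 400
    batch_size: int = 20000
    seed: int = 0
    decay_bias_and_norm: bool = False  # weight decay excluded from bias/norm params

    def __post_init__(self) -> None:
        for name in ("learning_rate", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Elementary layers (forward caches what backward needs)
# ---------------------------------------------------------------------------


class Param:
    """A trainable array with its gradient and a weight-decay flag.

    ``trainable`` (optional boolean mask of the same shape) pins individual
    entries: masked-out entries receive no gradient, decay or momentum.
    """

    __slots__ = ("value", "grad", "decay", "name", "trainable")

    def __init__(self, value: np.ndarray, decay: bool, name: str):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay
        self.name = name
        self.trainable = None


class SparseLinear:
    """Affine map whose weight matrix exists only on a binary mask.

    Weights are stored as the ``data`` vector of a CSR matrix built from the
    mask, so off-mask entries are not parameters at all and gradient masking
    holds by construction.
    """

    def __init__(self, mask: sp.csr_matrix, rng: np.random.Generator, name: str):
        mask = mask.tocsr().astype(float)
        mask.sum_duplicates()
        self.W = mask.copy()
        self.out_dim, self.in_dim = mask.shape
        row_nnz = np.diff(self.W.indptr)
        fan = np.repeat(np.maximum(row_nnz, 1), row_nnz).astype(float)
        bound = 1.0 / np.sqrt(fan)
        self.W.data = rng.uniform(-1.0, 1.0, size=self.W.nnz) * bound
        self.b = np.zeros(self.out_dim)
        self._rows = np.repeat(np.arange(self.out_dim), row_nnz)
        self._cols = self.W.indices.copy()
        self.pW = Param(self.W.data, decay=True, name=f"{name}.W")
        self.pb = Param(self.b, decay=False, name=f"{name}.b")
        self.params = [self.pW, self.pb]

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # dense (out, in) outer product is fine at desk scale; restrict to nnz
        G = dy.T @ self._x
        self.pW.grad += G[self._rows, self._cols]
        self.pb.grad += dy.sum(axis=0)
        return dy @ self.W

    def to_dense(self) -> np.ndarray:
        return self.W.toarray()


class DenseLinear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, name: str):
        bound = 1.0 / np.sqrt(in_dim)
        self.W = rng.uniform(-bound, bound, size=(out_dim, in_dim))
        self.b = np.zeros(out_dim)
        self.pW = Param(self.W, decay=True, name=f"{name}.W")
        self.pb = Param(self.b, decay=False, name=f"{name}.b")
        self.params = [self.pW, self.pb]

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.pW.grad += dy.T @ self._x
        self.pb.grad += dy.sum(axis=0)
        return dy @ self.W


class Tanh:
    params: list = []

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._y**2)


class Identity:
    params: list = []

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy


class BatchNorm:
    """Per-neuron batch normalization with running statistics for evaluation."""

    def __init__(self, dim: int, name: str, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.pg = Param(self.gamma, decay=False, name=f"{name}.gamma")
        self.pb = Param(self.beta, decay=False, name=f"{name}.beta")
        self.params = [self.pg, self.pb]

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        if train and x.shape[0] > 1:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train_batch = train and x.shape[0] > 1
        return self.gamma * self._xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.pg.grad += (dy * self._xhat).sum(axis=0)
        self.pb.grad += dy.sum(axis=0)
        n = dy.shape[0]
        dxhat = dy * self.gamma
        if not self._train_batch:
            return dxhat / self._std
        return (
            dxhat - dxhat.mean(axis=0) - self._xhat * (dxhat * self._xhat).mean(axis=0)
        ) / self._std

    def eval_scale(self) -> np.ndarray:
        """Affine slope in evaluation mode (used when folding for attribution)."""
        return self.gamma / np.sqrt(self.running_var + self.eps)


class Dropout:
    params: list = []

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


def _affine_block(linear, act_cls, norm_variant, dropout, in_dim, out_dim, name,
                  final: bool = False):
    """Wrap a linear layer with activation/normalization per the variant.

    "post": linear -> act -> batchnorm;  "ic": batchnorm+dropout -> linear ->
    act;  "none": linear -> act.  ``final`` layers get no activation or norm.
    """
    layers = []
    if norm_variant == "ic" and not final:
        layers.append(BatchNorm(in_dim, name=f"{name}.icnorm"))
        layers.append(Dropout(dropout))
    layers.append(linear)
    if not final:
        layers.append(act_cls())
        if norm_variant == "post":
            layers.append(BatchNorm(out_dim, name=f"{name}.postnorm"))
    return layers


@dataclass
class SparseVNNModel:
    """Compiled two-branch model; see the module docstring for the layout.

    ``vnn_interfaces`` marks, for every hierarchy layer ``s``, the position in
    ``vnn_layers`` *after* which the layer-``s`` node activations (the vector
    fed onward) are available — the hook used by DeepLIFT.
    """

    config: ModelConfig
    hierarchy: LayeredHierarchy
    connectivity: SparseConnectivity
    vnn_layers: list
    drug_layers: list
    head_layers: list
    vnn_interfaces: list[tuple[int, int]]  # (position in vnn_layers, hierarchy layer s)
    vnn_width: int = field(init=False)

    def __post_init__(self) -> None:
        self.vnn_width = self.config.vnn_output

    # -- forward ------------------------------------------------------------

    def _run(self, layers, x, train, rng):
        for layer in layers:
            x = layer.forward(x, train, rng)
        return x

    def forward(self, cell_features: np.ndarray, fingerprints: np.ndarray,
                train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        """Predict AUDRC for a batch of (cell, drug) pairs; returns shape (n,)."""
        cx = np.atleast_2d(np.asarray(cell_features, dtype=float))
        dx = np.atleast_2d(np.asarray(fingerprints, dtype=float))
        if cx.shape[1] != len(self.hierarchy.genes):
            raise ValueError(
                f"cell feature length {cx.shape[1]} != gene count {len(self.hierarchy.genes)}"
            )
        if dx.shape[1] != self.config.drug_input_dim:
            raise ValueError(
                f"fingerprint length {dx.shape[1]} != drug input width {self.config.drug_input_dim}"
            )
        if cx.shape[0] != dx.shape[0]:
            raise ValueError("cell and drug batches differ in length")
        v = self._run(self.vnn_layers, cx, train, rng)
        d = self._run(self.drug_layers, dx, train, rng)
        self._vnn_out_width = v.shape[1]
        h = np.concatenate([v, d], axis=1)
        out = self._run(self.head_layers, h, train, rng)
        return out[:, 0]

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backpropagate d(loss)/d(output); returns input gradients."""
        g = dout[:, None]
        for layer in reversed(self.head_layers):
            g = layer.backward(g)
        gv, gd = g[:, : self._vnn_out_width], g[:, self._vnn_out_width:]
        for layer in reversed(self.vnn_layers):
            gv = layer.backward(gv)
        for layer in reversed(self.drug_layers):
            gd = layer.backward(gd)
        return gv, gd

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> list[Param]:
        out = []
        for layer in (*self.vnn_layers, *self.drug_layers, *self.head_layers):
            out.extend(layer.params)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All parameters plus normalization running statistics, by name."""
        out = {}
        for i, layer in enumerate((*self.vnn_layers, *self.drug_layers, *self.head_layers)):
            for p in layer.params:
                out[f"{i}:{p.name}"] = p.value
            if isinstance(layer, BatchNorm):
                out[f"{i}:{layer.pg.name}.running_mean"] = layer.running_mean
                out[f"{i}:{layer.pg.name}.running_var"] = layer.running_var
        return out


def _freeze_virtual_connections(lin: SparseLinear, hierarchy: LayeredHierarchy,
                                node_order: list[str], k: int,
                                is_gene_layer: bool) -> None:
    """Pin the weights of virtual (pass-through) nodes and exclude them from
    training: identity blocks between node layers, a uniform average over the
    carried genes at the gene layer, biases 0.  The hyperbolic tangent still
    applies, so the pass-through is exact only in the small-activation regime.
    """
    rows, cols = lin._rows, lin._cols
    virt_entry = np.array(
        [node_order[r // k] in hierarchy.virtual_nodes for r in rows], dtype=bool
    )
    if not virt_entry.any():
        return
    if is_gene_layer:
        row_nnz = np.diff(lin.W.indptr)
        per_entry = np.repeat(np.maximum(row_nnz, 1), row_nnz)
        lin.W.data[virt_entry] = 1.0 / per_entry[virt_entry]
    else:
        identity = (rows % k) == (cols % k)
        lin.W.data[virt_entry] = np.where(identity[virt_entry], 1.0, 0.0)
    lin.pW.trainable = (~virt_entry).astype(float)
    virt_bias = np.array(
        [node_order[b // k] in hierarchy.virtual_nodes for b in range(lin.out_dim)],
        dtype=bool,
    )
    lin.b[virt_bias] = 0.0
    lin.pb.trainable = (~virt_bias).astype(float)


def compile_model(
    hierarchy: LayeredHierarchy,
    connectivity: SparseConnectivity,
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
) -> SparseVNNModel:
    """Build a :class:`SparseVNNModel` with seeded, reproducible initialization."""
    if connectivity.k != config.k:
        raise ValueError(
            f"connectivity was built with k={connectivity.k} but config.k={config.k}"
        )
    rng = np.random.default_rng(seed)
    act = Tanh if config.activation == "tanh" else Identity

    vnn_layers: list = []
    interfaces: list[tuple[int, int]] = []
    in_dim = len(connectivity.genes)
    for s, mask in enumerate(connectivity.masks, start=1):
        lin = SparseLinear(mask, rng, name=f"vnn{s}")
        if config.freeze_virtual:
            _freeze_virtual_connections(
                lin, hierarchy, connectivity.node_order[s - 1], config.k,
                is_gene_layer=(s == 1),
            )
        vnn_layers.extend(
            _affine_block(lin, act, config.norm_variant, config.dropout,
                          in_dim, mask.shape[0], name=f"vnn{s}")
        )
        interfaces.append((len(vnn_layers), s))
        in_dim = mask.shape[0]
    # root block (k neurons) -> VNN output width
    lin = DenseLinear(in_dim, config.vnn_output, rng, name="vnn_out")
    vnn_layers.extend(
        _affine_block(lin, act, config.norm_variant, config.dropout,
                      in_dim, config.vnn_output, name="vnn_out")
    )

    drug_layers: list = []
    in_dim = config.drug_input_dim
    for i, width in enumerate(config.drug_layers):
        lin = DenseLinear(in_dim, width, rng, name=f"drug{i}")
        drug_layers.extend(
            _affine_block(lin, act, config.norm_variant, config.dropout,
                          in_dim, width, name=f"drug{i}")
        )
        in_dim = width

    head_layers: list = []
    concat = config.vnn_output + config.drug_layers[-1]
    lin = DenseLinear(concat, config.fusion, rng, name="fusion")
    head_layers.extend(
        _affine_block(lin, act, config.norm_variant, config.dropout,
                      concat, config.fusion, name="fusion")
    )
    head_layers.append(DenseLinear(config.fusion, 1, rng, name="out"))

    return SparseVNNModel(
        config=config,
        hierarchy=hierarchy,
        connectivity=connectivity,
        vnn_layers=vnn_layers,
        drug_layers=drug_layers,
        head_layers=head_layers,
        vnn_interfaces=interfaces,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    train_mse: list[float]
    val_mse: list[float]
    best_epoch: int


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def train(
    model: SparseVNNModel,
    cell_X: np.ndarray,
    drug_X: np.ndarray,
    y: np.ndarray,
    tcfg: TrainConfig = TrainConfig(),
    val_idx: np.ndarray | None = None,
    validation_fraction: float = 0.1,
) -> TrainResult:
    """Gradient descent with momentum on the mean squared error.

    A validation subset (``val_idx`` if given, else a random
    ``validation_fraction`` of the pairs) is monitored each epoch and the
    best-validation parameter state is restored at the end.  The batch size
    auto-clamps to the dataset size.  Off-mask sparse weights cannot change
    because they are not parameters.
    """
    cell_X = np.asarray(cell_X, dtype=float)
    drug_X = np.asarray(drug_X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 1:
        raise ValueError("training requires at least one pair")
    rng = np.random.default_rng(tcfg.seed)

    if val_idx is None:
        perm = rng.permutation(n)
        n_val = int(round(validation_fraction * n))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
    else:
        val_idx = np.asarray(val_idx, dtype=int)
        train_idx = np.setdiff1d(np.arange(n), val_idx)
    if len(train_idx) == 0:
        raise ValueError("validation split left no training pairs")

    params = model.parameters()
    velocity = [np.zeros_like(p.value) for p in params]
    batch = min(tcfg.batch_size, len(train_idx))

    history_train, history_val = [], []
    best_val = np.inf
    best_epoch = -1
    best_state = None

    for epoch in range(tcfg.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(order), batch):
            idx = order[start : start + batch]
            model.zero_grad()
            pred = model.forward(cell_X[idx], drug_X[idx], train=True, rng=rng)
            err = pred - y[idx]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {epoch}; "
                    "reduce the learning rate or check the inputs"
                )
            epoch_loss += loss * len(idx)
            model.backward(2.0 * err / len(idx))
            for p, v in zip(params, velocity):
                g = p.grad
                if p.decay or tcfg.decay_bias_and_norm:
                    g = g + tcfg.weight_decay * p.value
                if p.trainable is not None:
                    g = g * p.trainable
                v *= tcfg.momentum
                v -= tcfg.learning_rate * g
                p.value += v
        history_train.append(epoch_loss / len(order))

        if len(val_idx):
            val_pred = model.forward(cell_X[val_idx], drug_X[val_idx], train=False)
            val_loss = _mse(val_pred, y[val_idx])
        else:
            val_loss = history_train[-1]
        history_val.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}

    if best_state is not None:
        for k, v in model.state_arrays().items():
            v[...] = best_state[k]
    return TrainResult(train_mse=history_train, val_mse=history_val, best_epoch=best_epoch)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_model(model: SparseVNNModel, path) -> None:
    """Self-describing checkpoint: config + hierarchy + all arrays (npz)."""
    meta = {
        "config": asdict(model.config),
        "hierarchy": model.hierarchy.to_dict(),
    }
    arrays = {k: np.asarray(v) for k, v in model.state_arrays().items()}
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_model(path) -> SparseVNNModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = meta["config"]
    cfg["drug_layers"] = tuple(cfg["drug_layers"])
    config = ModelConfig(**cfg)
    hierarchy = LayeredHierarchy.from_dict(meta["hierarchy"])
    connectivity = build_connectivity(hierarchy, config.k)
    model = compile_model(hierarchy, connectivity, config, seed=0)
    for k, v in model.state_arrays().items():
        v[...] = arrays[k]
    return model
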