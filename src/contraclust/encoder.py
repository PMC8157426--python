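"""MLP encoder, NT-Xent contrastive loss, and the representation trainer.

The encoder is a small stack of affine layers; after every hidden layer
except the final (representation) layer a batch-normalisation step and a
nonlinearity are applied.  Training minimises the normalised-temperature
cross-entropy (NT-Xent) contrastive loss over pairs of gene-masked views of
each mini-batch, with Adam and a cosine learning-rate schedule.  The whole
stack — forward, backward, optimiser — is implemented in numpy: the network
is tiny (about 1e5 parameters) and one CPU trains it in seconds.

Rows passed to :func:`nt_xent_loss` are arranged as consecutive positive
pairs: rows ``2k`` and ``2k+1`` are the two views of sample ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .augment import AugmentConfig, make_views
from .io import Embedding, ValidationError
from .preprocessing import PreprocessedMatrix

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class EncoderConfig:
    """Architecture of the encoder.

    ``layer_sizes`` lists the width of every affine layer; the last entry is
    the embedding size.  With ``norm_after_hidden`` a batch-norm step (two
    parameter vectors, scale and shift) follows every non-final layer.
    """

    input_dim: int
    layer_sizes: List[int] = field(default_factory=lambda: [200, 40, 60])
    norm_after_hidden: bool = True
    activation: str = "relu"

    def __post_init__(self) -> None:
        if not 1 <= len(self.layer_sizes) <= 8:
            raise ValidationError("layer_sizes must have 1..8 entries")
        if any(int(s) < 2 for s in self.layer_sizes):
            raise ValidationError("all layer sizes must be >= 2")
        if self.input_dim < 2:
            raise ValidationError("input_dim must be >= 2")
        if self.activation not in ("relu", "tanh"):
            raise ValidationError(f"unknown activation {self.activation!r}")


@dataclass
class TrainConfig:
    """Optimisation settings for the representation phase."""

    epochs: int = 30
    batch_size: int = 200
    learning_rate: float = 0.4
    scheduler: str = "cosine"
    temperature: float = 0.5
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ValidationError("batch_size must be >= 2")
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0")
        if self.scheduler not in ("cosine", "constant"):
            raise ValidationError(f"unknown scheduler {self.scheduler!r}")
        if self.optimizer != "adam":
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")


# ---------------------------------------------------------------------------
# Layers


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)  # uniform fan-in init
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = rng.uniform(-bound, bound, size=n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x if training else None
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def n_params(self) -> int:
        return self.W.size + self.b.size


class _BatchNorm:
    """Per-feature normalisation with learned scale/shift and running stats."""

    def __init__(self, width: int):
        self.gamma = np.ones(width)
        self.beta = np.zeros(width)
        self.dgamma = np.zeros(width)
        self.dbeta = np.zeros(width)
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = x.shape[0]
            unbiased = var * m / max(m - 1, 1)
            self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
            self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * unbiased
            self._inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            self._xhat = (x - mu) * self._inv_std
            return self.gamma * self._xhat + self.beta
        inv_std = 1.0 / np.sqrt(self.running_var + _BN_EPS)
        return self.gamma * (x - self.running_mean) * inv_std + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        m = g.shape[0]
        self.dgamma = (g * xhat).sum(axis=0)
        self.dbeta = g.sum(axis=0)
        dxhat = g * self.gamma
        return (
            inv_std
            / m
            * (m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def n_params(self) -> int:
        return self.gamma.size + self.beta.size


class _Activation:
    def __init__(self, kind: str):
        self.kind = kind

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if self.kind == "relu":
            out = np.maximum(x, 0.0)
        else:  # tanh
            out = np.tanh(x)
        self._out = out if training else None
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.kind == "relu":
            return g * (self._out > 0)
        return g * (1.0 - self._out**2)

    def params(self):
        return []

    def n_params(self) -> int:
        return 0


class MLPEncoder:
    """Stack of affine layers with optional batch-norm + activation."""

    def __init__(self, cfg: EncoderConfig, seed: int):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.layers: list = []
        widths = [cfg.input_dim] + [int(s) for s in cfg.layer_sizes]
        n_affine = len(cfg.layer_sizes)
        for i in range(n_affine):
            self.layers.append(_Linear(widths[i], widths[i + 1], rng))
            if i < n_affine - 1:  # hidden layers only, not the representation
                if cfg.norm_after_hidden:
                    self.layers.append(_BatchNorm(widths[i + 1]))
                self.layers.append(_Activation(cfg.activation))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)


def build_encoder(cfg: EncoderConfig, seed: int = 0) -> MLPEncoder:
    """Construct an encoder with deterministic initialisation under ``seed``."""
    return MLPEncoder(cfg, seed)


def count_parameters(cfg: EncoderConfig) -> int:
    """Number of trainable parameters for an architecture.

    Each affine layer contributes ``in*out + out``; each normalised hidden
    layer adds ``2 * width`` (scale and shift vectors).
    """
    widths = [cfg.input_dim] + [int(s) for s in cfg.layer_sizes]
    total = sum(widths[i] * widths[i + 1] + widths[i + 1] for i in range(len(cfg.layer_sizes)))
    if cfg.norm_after_hidden:
        total += sum(2 * int(s) for s in cfg.layer_sizes[:-1])
    return total


# ---------------------------------------------------------------------------
# NT-Xent loss


def _nt_xent_loss_grad(z: np.ndarray, tau: float) -> Tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. the raw (un-normalised) embeddings.

    Rows 2k and 2k+1 form a positive pair.  Cosine similarities are
    temperature-scaled; each row's positive is contrasted against all other
    2N-2 rows (self excluded).  Softmax is computed via logsumexp so no
    overflow occurs for any tau >= 0.01.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2 or z.shape[0] % 2 != 0:
        raise ValidationError("embeddings must form N >= 1 positive pairs (2N rows)")
    if not np.all(np.isfinite(z)):
        raise ValidationError("embeddings must be finite")
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms == 0):
        raise ValidationError("zero-norm embedding row")
    u = z / norms[:, None]
    two_n = z.shape[0]
    s = u @ u.T
    logits = s / tau
    np.fill_diagonal(logits, -np.inf)  # self-similarity excluded
    mx = logits.max(axis=1, keepdims=True)
    expm = np.exp(logits - mx)
    denom = expm.sum(axis=1, keepdims=True)
    log_p = logits - (mx + np.log(denom))
    probs = expm / denom

    pos = np.arange(two_n) ^ 1  # pair partner: 2k <-> 2k+1
    loss = float(-log_p[np.arange(two_n), pos].mean())

    # dL/dS, then through S = U U^T and the row normalisation
    a = probs.copy()
    a[np.arange(two_n), pos] -= 1.0
    a /= tau * two_n
    np.fill_diagonal(a, 0.0)
    du = (a + a.T) @ u
    dz = (du - (du * u).sum(axis=1, keepdims=True) * u) / norms[:, None]
    return loss, dz


def nt_xent_loss(z_views: np.ndarray, tau: float = 0.5) -> float:
    """Mean NT-Xent loss over all 2N ordered positive pairs."""
    return _nt_xent_loss_grad(z_views, tau)[0]


# ---------------------------------------------------------------------------
# Optimiser and schedule


class _Adam:
    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self, params) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (p, g) in enumerate(params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def cosine_lr(lr0: float, epoch: int, total_epochs: int) -> float:
    """Half-cosine decay from ``lr0`` towards 0, stepped per epoch."""
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * epoch / total_epochs))


# ---------------------------------------------------------------------------
# Training


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    """Shuffled mini-batch index slices; a final batch of <2 cells is dropped."""
    perm = rng.permutation(n)
    if n <= batch_size:
        yield perm
        return
    for start in range(0, n, batch_size):
        idx = perm[start : start + batch_size]
        if idx.size >= 2:
            yield idx


def _train_loop(
    pm: PreprocessedMatrix,
    ecfg: EncoderConfig,
    tcfg: TrainConfig,
    acfg: AugmentConfig,
) -> Tuple[MLPEncoder, List[float]]:
    """Shared training loop behind :func:`train` and the estimator.

    Per epoch the cells are shuffled into mini-batches; for each batch two
    gene-masked views are built, both views are encoded by the *same*
    network (concatenated, so batch-norm sees the joint statistics), the
    NT-Xent loss is evaluated and one Adam step is taken.
    """
    if pm.n_cells < 4:
        raise ValidationError("need at least 4 cells to train")
    if ecfg.input_dim != pm.n_genes:
        raise ValidationError(
            f"encoder input_dim {ecfg.input_dim} != matrix width {pm.n_genes}"
        )

    seeds = np.random.SeedSequence(tcfg.seed).spawn(2)
    init_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    model = build_encoder(ecfg, seed=init_seed)
    rng = np.random.default_rng(seeds[1])
    opt = _Adam(model.parameters(), lr=tcfg.learning_rate)

    X = pm.values
    history: List[float] = []
    for epoch in range(tcfg.epochs):
        if tcfg.scheduler == "cosine":
            opt.lr = cosine_lr(tcfg.learning_rate, epoch, tcfg.epochs)
        epoch_losses = []
        for idx in _iter_batches(X.shape[0], tcfg.batch_size, rng):
            v1, v2 = make_views(X[idx], acfg, rng)
            both = np.empty((2 * idx.size, X.shape[1]))
            both[0::2] = v1
            both[1::2] = v2
            z = model.forward(both, training=True)
            loss, dz = _nt_xent_loss_grad(z, tcfg.temperature)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite contrastive loss at epoch {epoch}; "
                    "lower the learning rate or check the input scaling"
                )
            model.backward(dz)
            opt.step(model.parameters())
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)))
    return model, history


def train(
    pm: PreprocessedMatrix,
    ecfg: Optional[EncoderConfig] = None,
    tcfg: Optional[TrainConfig] = None,
    acfg: Optional[AugmentConfig] = None,
) -> Tuple[Embedding, List[float]]:
    """Train the encoder contrastively and return the cell embedding.

    After the final epoch the un-augmented matrix is pushed through the
    encoder in evaluation mode to produce one embedding row per cell.
    """
    ecfg = ecfg or EncoderConfig(input_dim=pm.n_genes)
    tcfg = tcfg or TrainConfig()
    acfg = acfg or AugmentConfig()
    model, history = _train_loop(pm, ecfg, tcfg, acfg)
    z_full = model.forward(pm.values, training=False)
    return Embedding(z_full, pm.cell_ids), history


# ---------------------------------------------------------------------------
# Estimator


class ContrastiveEmbedding(TransformerMixin, BaseEstimator):
    """Contrastive representation learner for preprocessed expression data.

    A scikit-learn transformer: ``fit(X)`` trains the encoder on an
    ``(n, d')`` real matrix (rows are cells), ``transform(X)`` maps data of
    the same width through the trained encoder in evaluation mode.

    Parameters mirror the training recipe: a ``[200, 40, 60]`` MLP trained
    for 30 epochs with Adam, initial learning rate 0.4 under cosine decay,
    batch size 200, temperature 0.5, and 90% gene masking per view.
    """

    def __init__(
        self,
        layer_sizes=(200, 40, 60),
        norm_after_hidden: bool = True,
        activation: str = "relu",
        epochs: int = 30,
        batch_size: int = 200,
        learning_rate: float = 0.4,
        scheduler: str = "cosine",
        temperature: float = 0.5,
        mask_ratio: float = 0.9,
        noise_std: float = 0.0,
        rescale_survivors: bool = True,
        random_state: int = 0,
    ):
        self.layer_sizes = layer_sizes
        self.norm_after_hidden = norm_after_hidden
        self.activation = activation
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.scheduler = scheduler
        self.temperature = temperature
        self.mask_ratio = mask_ratio
        self.noise_std = noise_std
        self.rescale_survivors = rescale_survivors
        self.random_state = random_state

    def _configs(self, input_dim: int):
        ecfg = EncoderConfig(
            input_dim=input_dim,
            layer_sizes=list(self.layer_sizes),
            norm_after_hidden=self.norm_after_hidden,
            activation=self.activation,
        )
        tcfg = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            scheduler=self.scheduler,
            temperature=self.temperature,
            seed=self.random_state,
        )
        acfg = AugmentConfig(
            mask_ratio=self.mask_ratio,
            noise_std=self.noise_std,
            rescale_survivors=self.rescale_survivors,
        )
        return ecfg, tcfg, acfg

    def fit(self, X, y=None):
        pm = _as_preprocessed(X)
        ecfg, tcfg, acfg = self._configs(pm.n_genes)
        model, history = _train_loop(pm, ecfg, tcfg, acfg)
        self.model_ = model
        self.loss_history_ = history
        self.n_features_in_ = pm.n_genes
        self.embedding_ = model.forward(pm.values, training=False)
        self.cell_ids_ = pm.cell_ids
        return self

    def transform(self, X):
        if not hasattr(self, "model_"):
            raise ValidationError("ContrastiveEmbedding is not fitted")
        pm = _as_preprocessed(X)
        if pm.n_genes != self.n_features_in_:
            raise ValidationError("feature width differs from the fitted data")
        return self.model_.forward(pm.values, training=False)

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


def _as_preprocessed(X) -> PreprocessedMatrix:
    if isinstance(X, PreprocessedMatrix):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("expected a 2-D matrix")
    n, d = X.shape
    return PreprocessedMatrix(
        values=X,
        cell_ids=np.array([f"cell_{i}" for i in range(n)], dtype=object),
        selected_genes=np.array([f"gene_{j}" for j in range(d)], dtype=object),
    )
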