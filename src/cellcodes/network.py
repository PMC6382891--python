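"""Neural-network substrate: layers, activations, losses, SGD training.

Everything here is plain NumPy.  The networks involved are small sequential
stacks of fully connected layers and elementwise nonlinearities, trained by
per-sample stochastic gradient descent, so an explicit forward/backward
implementation is compact, dependency-free and easy to verify against
finite-difference gradients (see the test suite).

Layer vocabulary (compact architecture strings, e.g. ``"L300, G, L30"``):

====== ==================== =======================================
token  kind                 formula
====== ==================== =======================================
L<n>   linear               x @ W.T + b, W is (n, in)
R      relu                 max(0, x)
S      sigmoid              1 / (1 + e^-x)
G      logsigmoid           log(1 / (1 + e^-x))
T      tanh                 (e^x - e^-x) / (e^x + e^-x)
SP     softplus             log(1 + e^x)
SH<l>  softshrink           x -/+ lambda outside [-lambda, lambda], else 0
SM     softmax              e^{x_i} / sum_j e^{x_j}
====== ==================== =======================================

Training follows per-sample SGD with an inverse-time learning-rate decay
that restarts at the beginning of every epoch (warm restart): at update
step ``t`` within an epoch the effective rate is ``lr / (1 + decay * t)``.
One *iteration* is one full shuffled pass over the training samples with an
update after each sample; an epoch consists of ``iterations_per_epoch``
such passes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "TrainConfig",
    "TrainedModel",
    "activation",
    "mse_loss",
    "cross_entropy_loss",
    "softmax",
    "parse_arch",
    "arch_string",
    "init_params",
    "forward",
    "train",
]

ACTIVATION_KINDS = frozenset(
    {"relu", "sigmoid", "logsigmoid", "tanh", "softplus", "softshrink", "softmax"}
)
_TOKEN_TO_KIND = {
    "R": "relu",
    "S": "sigmoid",
    "G": "logsigmoid",
    "T": "tanh",
    "SP": "softplus",
    "SM": "softmax",
}
_KIND_TO_TOKEN = {v: k for k, v in _TOKEN_TO_KIND.items()}


@dataclass(frozen=True)
class LayerSpec:
    """One layer: a linear map or a named nonlinearity."""

    kind: str
    in_size: Optional[int] = None
    out_size: Optional[int] = None
    lam: Optional[float] = None  # softshrink threshold

    def __post_init__(self):
        if self.kind == "linear":
            if not (self.in_size and self.out_size):
                raise ValueError("linear layer needs in_size and out_size")
        elif self.kind == "softshrink":
            if self.lam is None or self.lam <= 0:
                raise ValueError("softshrink needs a positive lambda")
        elif self.kind not in ACTIVATION_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")


@dataclass(frozen=True)
class NetworkSpec:
    """Encoder/decoder (and optional classifier branch) layer stacks.

    The encoder maps a profile of ``input_size`` genes to a ``code_size``
    bottleneck; the decoder maps the code back.  A classifier branch, when
    present, maps the code to class scores and must end with softmax.
    """

    encoder: tuple[LayerSpec, ...]
    decoder: tuple[LayerSpec, ...]
    code_size: int
    classifier: Optional[tuple[LayerSpec, ...]] = None

    def __post_init__(self):
        enc_out = _stack_out_size(self.encoder)
        dec_in = _stack_in_size(self.decoder)
        if enc_out != self.code_size:
            raise ValueError(
                f"encoder output {enc_out} != code_size {self.code_size}"
            )
        if dec_in != self.code_size:
            raise ValueError(
                f"decoder input {dec_in} != code_size {self.code_size}"
            )
        if self.classifier is not None:
            if self.classifier[-1].kind != "softmax":
                raise ValueError("classifier branch must end with softmax")
            if _stack_in_size(self.classifier) != self.code_size:
                raise ValueError("classifier input must equal code_size")

    @property
    def input_size(self) -> int:
        return _stack_in_size(self.encoder)

    @property
    def output_size(self) -> int:
        return _stack_out_size(self.decoder)

    @property
    def n_classes(self) -> Optional[int]:
        if self.classifier is None:
            return None
        return _stack_out_size(self.classifier)

    @classmethod
    def symmetric(
        cls,
        encoder: Sequence[LayerSpec],
        classifier: Optional[Sequence[LayerSpec]] = None,
    ) -> "NetworkSpec":
        """Build the spec whose decoder mirrors the encoder layer by layer.

        Linear layers are transposed in size; nonlinearities keep their
        kind.  The mirrored decoder of ``[L(a,b), G, L(b,c)]`` is
        ``[L(c,b), G, L(b,a)]``, ending linearly so reconstruction targets
        are unbounded.
        """
        encoder = tuple(encoder)
        decoder = []
        for layer in reversed(encoder):
            if layer.kind == "linear":
                decoder.append(
                    LayerSpec("linear", in_size=layer.out_size, out_size=layer.in_size)
                )
            else:
                decoder.append(layer)
        return cls(
            encoder=encoder,
            decoder=tuple(decoder),
            code_size=_stack_out_size(encoder),
            classifier=tuple(classifier) if classifier is not None else None,
        )


def _stack_in_size(layers: Sequence[LayerSpec]) -> int:
    for layer in layers:
        if layer.kind == "linear":
            return layer.in_size
    raise ValueError("layer stack contains no linear layer")


def _stack_out_size(layers: Sequence[LayerSpec]) -> int:
    for layer in reversed(layers):
        if layer.kind == "linear":
            return layer.out_size
    raise ValueError("layer stack contains no linear layer")


def parse_arch(text: str, input_size: int) -> tuple[LayerSpec, ...]:
    """Parse a compact architecture string into chained layer specs.

    ``parse_arch("L300, G, L30", 1000)`` gives a 1000->300 linear layer, a
    logsigmoid layer and a 300->30 linear layer.
    """
    if input_size < 1:
        raise ValueError("input_size must be >= 1")
    layers: list[LayerSpec] = []
    size = input_size
    for raw in text.split(","):
        tok = raw.strip()
        if not tok:
            raise ValueError(f"empty token in architecture string {text!r}")
        upper = tok.upper()
        if upper.startswith("SH"):
            try:
                lam = float(tok[2:])
            except ValueError as exc:
                raise ValueError(f"malformed softshrink token {tok!r}") from exc
            layers.append(LayerSpec("softshrink", lam=lam))
        elif upper in _TOKEN_TO_KIND:
            layers.append(LayerSpec(_TOKEN_TO_KIND[upper]))
        elif upper.startswith("L"):
            try:
                out = int(tok[1:])
            except ValueError as exc:
                raise ValueError(f"malformed linear token {tok!r}") from exc
            if out < 1:
                raise ValueError(f"linear size must be >= 1 in token {tok!r}")
            layers.append(LayerSpec("linear", in_size=size, out_size=out))
            size = out
        else:
            raise ValueError(f"unknown architecture token {tok!r}")
    return tuple(layers)


def arch_string(layers: Sequence[LayerSpec]) -> str:
    """Inverse of :func:`parse_arch` (sizes implied by the chain)."""
    toks = []
    for layer in layers:
        if layer.kind == "linear":
            toks.append(f"L{layer.out_size}")
        elif layer.kind == "softshrink":
            toks.append(f"SH{layer.lam:g}")
        else:
            toks.append(_KIND_TO_TOKEN[layer.kind])
    return ", ".join(toks)


# -- activations and losses ------------------------------------------------

def softmax(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    shifted = x - x.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def activation(kind: str, x: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Apply a named nonlinearity elementwise (softmax: over the last axis)."""
    x = np.asarray(x, dtype=float)
    if kind == "relu":
        return np.maximum(0.0, x)
    if kind == "sigmoid":
        # 1/(1+e^-x), stable on both tails
        return np.exp(-np.logaddexp(0.0, -x))
    if kind == "logsigmoid":
        return -np.logaddexp(0.0, -x)
    if kind == "tanh":
        return np.tanh(x)
    if kind == "softplus":
        return np.logaddexp(0.0, x)
    if kind == "softshrink":
        return np.where(x > lam, x - lam, np.where(x < -lam, x + lam, 0.0))
    if kind == "softmax":
        return softmax(x)
    raise ValueError(f"unknown activation kind {kind!r}")


def _activation_grad(kind: str, x: np.ndarray, out: np.ndarray, lam: float) -> np.ndarray:
    """d activation / d x evaluated elementwise (not valid for softmax)."""
    if kind == "relu":
        return (x > 0).astype(float)
    if kind == "sigmoid":
        return out * (1.0 - out)
    if kind == "logsigmoid":
        # d/dx log sigmoid(x) = 1 - sigmoid(x) = sigmoid(-x)
        return np.exp(-np.logaddexp(0.0, x))
    if kind == "tanh":
        return 1.0 - out**2
    if kind == "softplus":
        return np.exp(-np.logaddexp(0.0, -x))
    if kind == "softshrink":
        return (np.abs(x) > lam).astype(float)
    raise ValueError(f"no elementwise gradient for {kind!r}")


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


def cross_entropy_loss(logits: np.ndarray, c: int) -> float:
    """``-x_c + log(sum_j e^{x_j})`` computed log-sum-exp-stably."""
    logits = np.asarray(logits, dtype=float).ravel()
    if not 0 <= c < logits.size:
        raise IndexError(f"class index {c} out of range for {logits.size} classes")
    m = logits.max()
    return float(-logits[c] + m + np.log(np.exp(logits - m).sum()))


# -- parameters ------------------------------------------------------------

def init_params(
    layers: Sequence[LayerSpec], rng: np.random.Generator
) -> list[Optional[tuple[np.ndarray, np.ndarray]]]:
    """Uniform fan-in-scaled init (+-1/sqrt(fan_in)); None for non-linear layers."""
    params = []
    for layer in layers:
        if layer.kind == "linear":
            bound = 1.0 / np.sqrt(layer.in_size)
            W = rng.uniform(-bound, bound, size=(layer.out_size, layer.in_size))
            b = rng.uniform(-bound, bound, size=layer.out_size)
            params.append((W, b))
        else:
            params.append(None)
    return params


def forward(
    layers: Sequence[LayerSpec],
    params: Sequence,
    x: np.ndarray,
    keep_cache: bool = False,
):
    """Run a batch (n, features) or single vector through a layer stack.

    With ``keep_cache`` returns ``(out, cache)`` where cache holds each
    layer's input (and output for activations) for backpropagation.
    """
    single = x.ndim == 1
    h = np.atleast_2d(np.asarray(x, dtype=float))
    cache = []
    for layer, p in zip(layers, params):
        if layer.kind == "linear":
            W, b = p
            out = h @ W.T + b
        else:
            out = activation(layer.kind, h, lam=layer.lam or 0.5)
        if keep_cache:
            cache.append((h, out))
        h = out
    if single:
        h = h[0]
    if keep_cache:
        return h, cache
    return h


def _forward1(layers, params, x):
    """Single-sample forward pass on 1-D vectors (training fast path)."""
    h = x
    cache = []
    for layer, p in zip(layers, params):
        if layer.kind == "linear":
            W, b = p
            out = W @ h + b
        else:
            out = activation(layer.kind, h, lam=layer.lam or 0.5)
        cache.append((h, out))
        h = out
    return h, cache


def _backward1_update(layers, params, cache, grad_out, lr, l2, ger):
    """Single-sample fused backprop + SGD update on 1-D vectors.

    For each linear layer the input gradient is computed from the
    pre-update weights, then the rank-1 update ``W -= lr * outer(grad, h)``
    is applied in place via BLAS ger — exactly plain SGD, with no gradient
    temporaries.
    """
    grad = grad_out
    for i in range(len(layers) - 1, -1, -1):
        layer = layers[i]
        h_in, h_out = cache[i]
        if layer.kind == "linear":
            W, b = params[i]
            grad_in = grad @ W
            if l2 > 0:
                W *= 1.0 - lr * l2
            # W is C-ordered (out, in); W.T is F-ordered so ger updates in place
            ger(-lr, h_in, grad, a=W.T, overwrite_a=1)
            b -= lr * grad
            grad = grad_in
        elif layer.kind == "softmax":
            grad = h_out * (grad - float(grad @ h_out))
        else:
            grad = grad * _activation_grad(layer.kind, h_in, h_out, layer.lam or 0.5)
    return grad


def backward(
    layers: Sequence[LayerSpec],
    params: Sequence,
    cache: Sequence,
    grad_out: np.ndarray,
):
    """Backpropagate ``dL/d out`` through a stack.

    Returns ``(grad_in, grads)`` where grads aligns with params
    ((dW, db) tuples for linear layers, None otherwise).
    """
    grad = np.atleast_2d(grad_out)
    grads: list = [None] * len(layers)
    for i in range(len(layers) - 1, -1, -1):
        layer = layers[i]
        h_in, h_out = cache[i]
        if layer.kind == "linear":
            W, _ = params[i]
            grads[i] = (grad.T @ h_in, grad.sum(axis=0))
            grad = grad @ W
        elif layer.kind == "softmax":
            # J^T g = s * (g - <g, s>)
            dot = (grad * h_out).sum(axis=-1, keepdims=True)
            grad = h_out * (grad - dot)
        else:
            grad = grad * _activation_grad(layer.kind, h_in, h_out, layer.lam or 0.5)
    return grad, grads


# -- training --------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """SGD hyperparameters.

    ``learning_rate`` defaults to 0.002, the middle of the 0.001-0.003
    range that works for log2-scale profiles; ``epochs`` x
    ``iterations_per_epoch`` full passes are performed with the decayed
    rate restarting every epoch.  ``loss_weights`` weight the
    reconstruction (MSE) and classification (cross-entropy) criteria when
    a classifier branch is present.  ``input_noise_sd`` > 0 trains a
    denoising network: fresh Gaussian noise corrupts each presented input
    while the clean profile remains the reconstruction target.
    """

    learning_rate: float = 0.002
    epochs: int = 200
    iterations_per_epoch: int = 100
    decay: float = 0.001
    loss_weights: tuple[float, float] = (0.5, 0.5)
    input_noise_sd: float = 0.0
    l2: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.iterations_per_epoch < 1:
            raise ValueError("iterations_per_epoch must be >= 1")
        if self.decay < 0 or self.input_noise_sd < 0 or self.l2 < 0:
            raise ValueError("decay, input_noise_sd and l2 must be >= 0")
        w_mse, w_ce = self.loss_weights
        if w_mse < 0 or w_ce < 0:
            raise ValueError("loss weights must be non-negative")


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainedModel:
    """A trained network: spec, weights and the per-epoch loss log."""

    spec: NetworkSpec
    encoder_params: list
    decoder_params: list
    classifier_params: Optional[list] = None
    training_log: list = field(default_factory=list)
    gene_ids: Optional[list] = None
    class_labels: Optional[list] = None
    #: per-gene offset subtracted before the encoder and added back after the
    #: decoder (gene means when trained with centering)
    input_offset: Optional[np.ndarray] = None

    def encode_array(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.input_offset is not None:
            x = x - self.input_offset
        return forward(self.spec.encoder, self.encoder_params, x)

    def decode_array(self, codes: np.ndarray) -> np.ndarray:
        codes = np.asarray(codes, dtype=float)
        if codes.ndim == 2 and codes.shape[1] != self.spec.code_size:
            raise ValueError(
                f"code width {codes.shape[1]} != code_size {self.spec.code_size}"
            )
        if codes.ndim == 1 and codes.size != self.spec.code_size:
            raise ValueError(
                f"code width {codes.size} != code_size {self.spec.code_size}"
            )
        out = forward(self.spec.decoder, self.decoder_params, codes)
        if self.input_offset is not None:
            out = out + self.input_offset
        return out

    def classifier_logits(self, codes: np.ndarray) -> np.ndarray:
        if self.spec.classifier is None:
            raise ValueError("model has no classifier branch")
        return forward(
            self.spec.classifier[:-1],
            self.classifier_params[:-1],
            codes,
        )

    # -- persistence (npz container, shape-checked on load) ---------------
    def save(self, path) -> None:
        arrays = {}
        for name, params in (
            ("enc", self.encoder_params),
            ("dec", self.decoder_params),
            ("cls", self.classifier_params or []),
        ):
            for i, p in enumerate(params):
                if p is not None:
                    arrays[f"{name}{i}_W"], arrays[f"{name}{i}_b"] = p
        meta = {
            "encoder": [asdict(l) for l in self.spec.encoder],
            "decoder": [asdict(l) for l in self.spec.decoder],
            "classifier": (
                [asdict(l) for l in self.spec.classifier]
                if self.spec.classifier
                else None
            ),
            "code_size": self.spec.code_size,
            "training_log": self.training_log,
            "gene_ids": self.gene_ids,
            "class_labels": self.class_labels,
        }
        if self.input_offset is not None:
            arrays["input_offset"] = self.input_offset
        arrays["meta"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"].tobytes()).decode("utf-8"))

        def mklayers(items):
            return tuple(LayerSpec(**d) for d in items) if items else None

        spec = NetworkSpec(
            encoder=mklayers(meta["encoder"]),
            decoder=mklayers(meta["decoder"]),
            code_size=meta["code_size"],
            classifier=mklayers(meta["classifier"]),
        )

        def mkparams(name, layers):
            params = []
            for i, layer in enumerate(layers):
                if layer.kind == "linear":
                    W = data[f"{name}{i}_W"]
                    b = data[f"{name}{i}_b"]
                    if W.shape != (layer.out_size, layer.in_size):
                        raise ValueError(
                            f"{name}[{i}]: stored weight shape {W.shape} does "
                            f"not match spec ({layer.out_size}, {layer.in_size})"
                        )
                    params.append((W, b))
                else:
                    params.append(None)
            return params

        return cls(
            spec=spec,
            encoder_params=mkparams("enc", spec.encoder),
            decoder_params=mkparams("dec", spec.decoder),
            classifier_params=(
                mkparams("cls", spec.classifier) if spec.classifier else None
            ),
            training_log=meta["training_log"],
            gene_ids=meta["gene_ids"],
            class_labels=meta["class_labels"],
            input_offset=(
                data["input_offset"] if "input_offset" in data.files else None
            ),
        )


def _sample_losses(model: TrainedModel, X: np.ndarray, y: Optional[np.ndarray]):
    """Full-batch reconstruction MSE and mean CE (None without classifier)."""
    codes = model.encode_array(X)
    recon = model.decode_array(codes)
    mse = float(np.mean((recon - X) ** 2))
    ce = None
    if model.spec.classifier is not None and y is not None:
        logits = model.classifier_logits(codes)
        m = logits.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logits - m).sum(axis=1))
        ce = float(np.mean(lse - logits[np.arange(len(y)), y]))
    return mse, ce


def train(
    spec: NetworkSpec,
    X: np.ndarray,
    labels: Optional[np.ndarray] = None,
    cfg: TrainConfig = TrainConfig(),
    test_X: Optional[np.ndarray] = None,
    test_labels: Optional[np.ndarray] = None,
    gene_ids: Optional[list] = None,
    class_labels: Optional[list] = None,
    center: bool = False,
) -> TrainedModel:
    """Train an (optionally classifier-) autoencoder by per-sample SGD.

    Parameters
    ----------
    X : (n_samples, n_genes) array — one row per profile.
    labels : integer class indices, required iff `spec` has a classifier.
    test_X, test_labels : optional held-out set monitored per epoch.
    center : subtract the per-gene training mean before the encoder and add
        it back after the decoder (stored on the model; equivalent to
        absorbing gene means into the output biases, and it conditions
        per-sample SGD much better on uncentered log2 data).

    The training log records, per epoch, the full-batch train loss
    components (and test losses when a test set is given).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be (n_samples, n_genes) with >= 1 sample")
    if X.shape[1] != spec.input_size:
        raise ValueError(
            f"input has {X.shape[1]} genes, spec expects {spec.input_size}"
        )
    has_classifier = spec.classifier is not None
    if has_classifier and labels is None:
        raise ValueError("spec has a classifier branch: labels are required")
    if not has_classifier and labels is not None:
        raise ValueError("labels given but spec has no classifier branch")
    if labels is not None:
        labels = np.asarray(labels, dtype=int)
        if labels.shape != (X.shape[0],):
            raise ValueError("labels must align with the rows of X")
        if labels.min() < 0 or labels.max() >= spec.n_classes:
            raise ValueError("label outside [0, n_classes)")

    offset = None
    if center:
        offset = X.mean(axis=0)
        X = X - offset
        if test_X is not None:
            test_X = np.asarray(test_X, dtype=float) - offset

    root = np.random.SeedSequence(cfg.seed)
    rng_init, rng_shuffle, rng_noise = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    enc_params = init_params(spec.encoder, rng_init)
    dec_params = init_params(spec.decoder, rng_init)
    cls_params = init_params(spec.classifier, rng_init) if has_classifier else None

    model = TrainedModel(
        spec=spec,
        encoder_params=enc_params,
        decoder_params=dec_params,
        classifier_params=cls_params,
        gene_ids=list(gene_ids) if gene_ids is not None else None,
        class_labels=list(class_labels) if class_labels is not None else None,
    )

    n = X.shape[0]
    w_mse, w_ce = cfg.loss_weights if has_classifier else (1.0, 0.0)
    n_genes = X.shape[1]
    # classifier branch minus the final softmax: CE is computed on logits
    cls_layers = spec.classifier[:-1] if has_classifier else None
    cls_p = cls_params[:-1] if has_classifier else None

    # the SGD loop runs in float32: updates are memory-bound and the extra
    # precision buys nothing at these loss scales
    from scipy.linalg.blas import sger

    X32 = np.ascontiguousarray(X, dtype=np.float32)
    for plist in (enc_params, dec_params, cls_params or []):
        for i, p in enumerate(plist):
            if p is not None:
                plist[i] = (
                    np.ascontiguousarray(p[0], dtype=np.float32),
                    np.ascontiguousarray(p[1], dtype=np.float32),
                )
    if has_classifier:
        cls_p = cls_params[:-1]
    mse_scale = np.float32(2.0 / n_genes * w_mse)

    for epoch in range(cfg.epochs):
        step = 0
        for _ in range(cfg.iterations_per_epoch):
            order = rng_shuffle.permutation(n)
            for idx in order:
                lr = cfg.learning_rate / (1.0 + cfg.decay * step)
                step += 1
                target = X32[idx]
                x_in = target
                if cfg.input_noise_sd > 0:
                    x_in = (
                        target
                        + rng_noise.normal(0.0, cfg.input_noise_sd, size=target.shape)
                    ).astype(np.float32)
                code, enc_cache = _forward1(spec.encoder, enc_params, x_in)
                recon, dec_cache = _forward1(spec.decoder, dec_params, code)
                # dL/d recon for MSE = 2 (recon - target) / n_genes
                grad_recon = mse_scale * (recon - target)
                grad_code = _backward1_update(
                    spec.decoder, dec_params, dec_cache, grad_recon, lr, cfg.l2, sger
                )
                if has_classifier and w_ce > 0:
                    logits, cls_cache = _forward1(cls_layers, cls_p, code)
                    probs = softmax(logits).astype(np.float32)
                    probs[labels[idx]] -= 1.0
                    grad_code_cls = _backward1_update(
                        cls_layers,
                        cls_p,
                        cls_cache,
                        probs * np.float32(w_ce),
                        lr,
                        cfg.l2,
                        sger,
                    )
                    grad_code = grad_code + grad_code_cls
                _backward1_update(
                    spec.encoder, enc_params, enc_cache, grad_code, lr, cfg.l2, sger
                )

        entry = {"epoch": epoch + 1}
        entry["train_mse"], train_ce = _sample_losses(model, X, labels)
        if train_ce is not None:
            entry["train_ce"] = train_ce
            entry["train_loss"] = w_mse * entry["train_mse"] + w_ce * train_ce
        else:
            entry["train_loss"] = entry["train_mse"]
        if test_X is not None:
            entry["test_mse"], test_ce = _sample_losses(
                model, np.asarray(test_X, dtype=float), test_labels
            )
            if test_ce is not None:
                entry["test_ce"] = test_ce
        if not np.isfinite(entry["train_loss"]):
            raise TrainingDivergedError(
                f"non-finite training loss at epoch {epoch + 1}; "
                "reduce the learning rate"
            )
        model.training_log.append(entry)

    for plist in (enc_params, dec_params, cls_params or []):
        for i, p in enumerate(plist):
            if p is not None:
                plist[i] = (p[0].astype(float), p[1].astype(float))
    model.input_offset = offset
    return model


def loss_and_grads(
    spec: NetworkSpec,
    enc_params,
    dec_params,
    cls_params,
    x: np.ndarray,
    label: Optional[int] = None,
    loss_weights: tuple[float, float] = (0.5, 0.5),
):
    """Single-sample total loss and analytic parameter gradients.

    Exposed so finite-difference gradient verification can drive exactly
    the computation the training loop uses.
    """
    has_classifier = spec.classifier is not None
    w_mse, w_ce = loss_weights if has_classifier else (1.0, 0.0)
    n_genes = x.size
    code, enc_cache = forward(spec.encoder, enc_params, x[None, :], True)
    recon, dec_cache = forward(spec.decoder, dec_params, code, True)
    loss = w_mse * float(np.mean((recon[0] - x) ** 2))
    grad_recon = (2.0 / n_genes) * (recon - x[None, :]) * w_mse
    grad_code, dec_grads = backward(spec.decoder, dec_params, dec_cache, grad_recon)
    cls_grads = None
    if has_classifier:
        cls_layers = spec.classifier[:-1]
        cls_p = cls_params[:-1]
        logits, cls_cache = forward(cls_layers, cls_p, code, True)
        loss += w_ce * cross_entropy_loss(logits[0], label)
        probs = softmax(logits)
        grad_logits = probs.copy()
        grad_logits[0, label] -= 1.0
        grad_code_cls, cls_grads = backward(
            cls_layers, cls_p, cls_cache, grad_logits * w_ce
        )
        grad_code = grad_code + grad_code_cls
        cls_grads = cls_grads + [None]  # align with the softmax layer
    _, enc_grads = backward(spec.encoder, enc_params, enc_cache, grad_code)
    return loss, enc_grads, dec_grads, cls_grads
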