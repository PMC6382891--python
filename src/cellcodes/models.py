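"""Concrete autoencoder architectures and the Model/Results fitting API.

The central object is the *cell identity code* (CIC): the value of the
bottleneck layer when a gene expression profile (GEP) is pushed through the
encoder.  Decoding a CIC yields the *reproduced expression profile* (REP).

Two model classes follow the familiar model/results pattern:

>>> model = CICAutoencoder(matrix, arch="selected", code_size=30)
>>> res = model.fit(epochs=20, seed=1)
>>> cic = res.encode(matrix)          # CICMatrix, samples x 30
>>> rep = res.decode(cic)             # ExpressionMatrix (the REPs)
>>> print(res.summary())

``ClassifierAutoencoder`` adds a classification branch on the code layer
and trains with a weighted sum of reconstruction MSE and cross-entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, check_annotations
from .network import (
    LayerSpec,
    NetworkSpec,
    TrainConfig,
    TrainedModel,
    parse_arch,
    arch_string,
    softmax,
    train,
)

__all__ = [
    "CICMatrix",
    "selected_architecture",
    "candidate_architectures",
    "classifier_autoencoder",
    "encode",
    "decode",
    "classify",
    "CICAutoencoder",
    "ClassifierAutoencoder",
    "CICAutoencoderResults",
    "ClassifierAutoencoderResults",
]

DEFAULT_CODE_SIZE = 30
#: first-stage compression of the selected architecture (input -> input/10)
HIDDEN_COMPRESSION = 10


@dataclass
class CICMatrix:
    """Cell identity codes for a set of samples, with component statistics.

    ``component_mean[i]`` and ``component_sd[i]`` are the mean and sample
    standard deviation of component i over the provided samples — the
    C-bar and sigma used by the latent-perturbation procedure.
    """

    sample_ids: list
    codes: np.ndarray  # samples x K

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2 or len(self.sample_ids) != self.codes.shape[0]:
            raise ValueError("codes must be samples x K aligned with sample_ids")
        if self.codes.shape[0] == 1:
            warnings.warn("single sample: component SDs are zero")
            self.component_sd = np.zeros(self.codes.shape[1])
        else:
            self.component_sd = self.codes.std(axis=0, ddof=1)
        self.component_mean = self.codes.mean(axis=0)

    @property
    def code_size(self) -> int:
        return self.codes.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.codes,
            index=self.sample_ids,
            columns=[f"CIC_{i + 1}" for i in range(self.code_size)],
        )


# -- architecture constructors ---------------------------------------------

def selected_architecture(
    n_genes: int,
    code_size: int = DEFAULT_CODE_SIZE,
    hidden: Optional[int] = None,
) -> NetworkSpec:
    """The architecture selected for whole-profile compression.

    Encoder: linear n_genes -> hidden, logsigmoid, linear hidden -> code;
    decoder mirrored.  At the reference scale of 20184 genes the hidden
    width is 2000; for other gene counts it defaults to a proportional
    n_genes / 10 (overridable).
    """
    if hidden is None:
        # 2000 at the reference 20184-gene scale; proportional otherwise
        hidden = 2000 if n_genes == 20184 else max(2, round(n_genes / HIDDEN_COMPRESSION))
    if n_genes <= code_size:
        raise ValueError("n_genes must exceed code_size")
    if code_size >= hidden:
        raise ValueError(
            f"code_size {code_size} must be smaller than hidden width {hidden}"
        )
    encoder = parse_arch(f"L{hidden}, G, L{code_size}", n_genes)
    return NetworkSpec.symmetric(encoder)


#: Roster of candidate encoder architectures compared on the
#: 1000-top-variance-gene problem, all with a 30-component bottleneck and
#: mirrored decoders.  Includes the winner family (single merged 300:30
#: linear stage after the nonlinearity), its two runner-up variants with the
#: extra 300:100:30 stages, and spans the remaining activation vocabulary.
CANDIDATE_ARCHES: tuple[tuple[str, str], ...] = (
    ("logsig-merged", "L300, G, L30"),
    ("softmax-merged", "L300, SM, L30"),
    ("logsig-deep", "L300, G, L100, L30"),
    ("softmax-deep", "L300, SM, L100, L30"),
    ("sigmoid", "L300, S, L30"),
    ("tanh", "L300, T, L30"),
    ("relu", "L300, R, L30"),
    ("softplus", "L300, SP, L30"),
    ("softshrink", "L300, SH0.5, L30"),
    ("logsig-2stage", "L500, G, L100, G, L30"),
)


def candidate_architectures(input_size: int) -> dict[str, NetworkSpec]:
    """The 10 candidate autoencoders compared during architecture selection."""
    return {
        name: NetworkSpec.symmetric(parse_arch(text, input_size))
        for name, text in CANDIDATE_ARCHES
    }


def classifier_autoencoder(
    n_genes: int,
    code_size: int = DEFAULT_CODE_SIZE,
    n_classes: int = 16,
    hidden_classifier: Optional[int] = None,
    hidden: Optional[int] = None,
) -> NetworkSpec:
    """Autoencoder whose code feeds both a decoder and a softmax classifier.

    The classifier branch contains at most one hidden (logsigmoid) layer
    before the linear-to-classes + softmax output.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    base = selected_architecture(n_genes, code_size, hidden)
    if hidden_classifier is None:
        cls = (
            LayerSpec("linear", in_size=code_size, out_size=n_classes),
            LayerSpec("softmax"),
        )
    else:
        cls = (
            LayerSpec("linear", in_size=code_size, out_size=hidden_classifier),
            LayerSpec("logsigmoid"),
            LayerSpec("linear", in_size=hidden_classifier, out_size=n_classes),
            LayerSpec("softmax"),
        )
    return NetworkSpec(
        encoder=base.encoder,
        decoder=base.decoder,
        code_size=code_size,
        classifier=cls,
    )


# -- encode / decode / classify -------------------------------------------

def _check_genes(model: TrainedModel, m: ExpressionMatrix) -> None:
    if m.n_genes != model.spec.input_size:
        raise ValueError(
            f"matrix has {m.n_genes} genes, model expects {model.spec.input_size}"
        )
    if model.gene_ids is not None and list(m.gene_ids) != list(model.gene_ids):
        missing = sorted(set(model.gene_ids) - set(m.gene_ids))
        if missing:
            raise ValueError(
                f"gene ids do not match the model; missing: {missing[:5]}"
            )
        raise ValueError("gene ids do not match the model (order differs)")


def encode(model: TrainedModel, m: ExpressionMatrix) -> CICMatrix:
    """Forward-pass every sample through the encoder to its CIC."""
    _check_genes(model, m)
    codes = model.encode_array(m.values.T)
    return CICMatrix(sample_ids=list(m.sample_ids), codes=codes)


def decode(model: TrainedModel, codes) -> ExpressionMatrix:
    """Decode CICs (CICMatrix or samples x K array) into REPs."""
    if isinstance(codes, CICMatrix):
        arr, sample_ids = codes.codes, codes.sample_ids
    else:
        arr = np.atleast_2d(np.asarray(codes, dtype=float))
        sample_ids = [f"rep{i}" for i in range(arr.shape[0])]
    values = model.decode_array(arr).T  # genes x samples
    gene_ids = (
        model.gene_ids
        if model.gene_ids is not None
        else [f"g{i}" for i in range(values.shape[0])]
    )
    return ExpressionMatrix(values, gene_ids, sample_ids)


def classify(
    model: TrainedModel, m: ExpressionMatrix
) -> tuple[pd.DataFrame, pd.Series]:
    """Class probabilities and argmax labels (ties -> lowest class index)."""
    if model.spec.classifier is None:
        raise ValueError("model has no classifier branch")
    _check_genes(model, m)
    codes = model.encode_array(m.values.T)
    logits = model.classifier_logits(codes)
    probs = softmax(logits)
    labels = (
        model.class_labels
        if model.class_labels is not None
        else [str(i) for i in range(probs.shape[1])]
    )
    prob_df = pd.DataFrame(probs, index=m.sample_ids, columns=labels)
    pred = pd.Series(
        [labels[i] for i in probs.argmax(axis=1)], index=m.sample_ids, name="predicted"
    )
    return prob_df, pred


def reconstruction_mse(model: TrainedModel, m: ExpressionMatrix) -> float:
    """Mean squared GEP-REP error over all genes and samples."""
    _check_genes(model, m)
    X = m.values.T
    recon = model.decode_array(model.encode_array(X))
    return float(np.mean((recon - X) ** 2))


# -- Model / Results -------------------------------------------------------

class CICAutoencoder:
    """Autoencoder model for a gene-expression matrix.

    Parameters
    ----------
    data : ExpressionMatrix
        Training profiles, genes x samples, log2 scale.
    arch : "selected", an architecture string ("L300, G, L30"), or a
        NetworkSpec.  Architecture strings describe the encoder; the
        decoder is mirrored.
    code_size : bottleneck width (ignored when `arch` is a NetworkSpec).
    hidden : first-stage width override for the selected architecture.
    """

    def __init__(
        self,
        data: ExpressionMatrix,
        arch="selected",
        code_size: int = DEFAULT_CODE_SIZE,
        hidden: Optional[int] = None,
    ) -> None:
        self.data = data
        if isinstance(arch, NetworkSpec):
            self.spec = arch
        elif arch == "selected":
            self.spec = selected_architecture(data.n_genes, code_size, hidden)
        else:
            self.spec = NetworkSpec.symmetric(parse_arch(arch, data.n_genes))
        self.arch_name = arch if isinstance(arch, str) else arch_string(
            self.spec.encoder
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CICAutoencoder":
        return cls(ExpressionMatrix.from_frame(df), **kwargs)

    def _labels(self):
        return None, None

    def fit(
        self,
        test_data: Optional[ExpressionMatrix] = None,
        cfg: Optional[TrainConfig] = None,
        center: bool = True,
        **cfg_kwargs,
    ):
        """Train by per-sample SGD and return a results object.

        Either pass a prebuilt :class:`TrainConfig` or its fields as
        keyword arguments (learning_rate, epochs, iterations_per_epoch,
        decay, loss_weights, input_noise_sd, l2, seed).  By default each
        gene is centered at its training mean before encoding (the mean is
        restored on decode).
        """
        if cfg is None:
            cfg = TrainConfig(**cfg_kwargs)
        elif cfg_kwargs:
            raise TypeError("pass either cfg or keyword fields, not both")
        labels, class_names = self._labels()
        test_labels = None
        if test_data is not None and labels is not None:
            test_labels = self._encode_labels(self._test_annotations(test_data))
        trained = train(
            self.spec,
            self.data.values.T,
            labels=labels,
            cfg=cfg,
            test_X=None if test_data is None else test_data.values.T,
            test_labels=test_labels,
            gene_ids=self.data.gene_ids,
            class_labels=class_names,
            center=center,
        )
        return self._results_cls()(self, trained, cfg)

    def _results_cls(self):
        return CICAutoencoderResults


class CICAutoencoderResults:
    """Fitted autoencoder: trained weights, loss history and transforms."""

    def __init__(self, model: CICAutoencoder, trained: TrainedModel, cfg: TrainConfig):
        self.model = model
        self.trained = trained
        self.cfg = cfg

    @property
    def training_log(self) -> pd.DataFrame:
        return pd.DataFrame(self.trained.training_log).set_index("epoch")

    @property
    def final_train_mse(self) -> float:
        return self.trained.training_log[-1]["train_mse"]

    def encode(self, data: Optional[ExpressionMatrix] = None) -> CICMatrix:
        return encode(self.trained, data if data is not None else self.model.data)

    def decode(self, codes) -> ExpressionMatrix:
        return decode(self.trained, codes)

    def reconstruct(self, data: Optional[ExpressionMatrix] = None) -> ExpressionMatrix:
        """Encode then decode: the REPs for the given (default: training) data."""
        data = data if data is not None else self.model.data
        rep = self.decode(self.encode(data))
        rep.sample_ids = list(data.sample_ids)
        return rep

    def mse(self, data: Optional[ExpressionMatrix] = None) -> float:
        return reconstruction_mse(
            self.trained, data if data is not None else self.model.data
        )

    def save(self, path) -> None:
        self.trained.save(path)

    def summary(self) -> str:
        spec = self.trained.spec
        log = self.trained.training_log
        n_params = 0
        for params in (
            self.trained.encoder_params,
            self.trained.decoder_params,
            self.trained.classifier_params or [],
        ):
            for p in params:
                if p is not None:
                    n_params += p[0].size + p[1].size
        lines = [
            f"{type(self).__name__}",
            "=" * 58,
            f"Encoder:            {arch_string(spec.encoder)}",
            f"Decoder:            {arch_string(spec.decoder)}",
        ]
        if spec.classifier is not None:
            lines.append(f"Classifier:         {arch_string(spec.classifier)}")
        lines += [
            f"Code size:          {spec.code_size}",
            f"Input genes:        {spec.input_size}",
            f"Trainable params:   {n_params}",
            f"Epochs trained:     {len(log)}",
            f"Learning rate:      {self.cfg.learning_rate:g} "
            f"(decay {self.cfg.decay:g}/step, restart each epoch)",
            f"Final train MSE:    {log[-1]['train_mse']:.6g}",
        ]
        if "test_mse" in log[-1]:
            lines.append(f"Final test MSE:     {log[-1]['test_mse']:.6g}")
        if "train_ce" in log[-1]:
            lines.append(f"Final train CE:     {log[-1]['train_ce']:.6g}")
        if "test_ce" in log[-1]:
            lines.append(f"Final test CE:      {log[-1]['test_ce']:.6g}")
        lines.append("=" * 58)
        return "\n".join(lines)


class ClassifierAutoencoder(CICAutoencoder):
    """Autoencoder with a classification branch on the code layer.

    Trained on ``loss = w_mse * MSE + w_ce * CE`` (default weights
    0.5/0.5).  `annotations` maps sample id -> cell-type label.
    """

    def __init__(
        self,
        data: ExpressionMatrix,
        annotations: pd.Series,
        code_size: int = DEFAULT_CODE_SIZE,
        hidden: Optional[int] = None,
        hidden_classifier: Optional[int] = None,
    ) -> None:
        ann = check_annotations(data, annotations)
        self.annotations = ann
        self.class_names = sorted(ann.unique())
        spec = classifier_autoencoder(
            data.n_genes,
            code_size,
            n_classes=len(self.class_names),
            hidden_classifier=hidden_classifier,
            hidden=hidden,
        )
        super().__init__(data, arch=spec)
        self._class_index = {c: i for i, c in enumerate(self.class_names)}

    def _labels(self):
        labels = np.array([self._class_index[t] for t in self.annotations])
        return labels, self.class_names

    def _encode_labels(self, ann: pd.Series) -> np.ndarray:
        unknown = sorted(set(ann.unique()) - set(self.class_names))
        if unknown:
            raise ValueError(f"labels absent from training classes: {unknown}")
        return np.array([self._class_index[t] for t in ann])

    def _test_annotations(self, test_data: ExpressionMatrix) -> pd.Series:
        return self._full_annotations.loc[test_data.sample_ids]

    def fit(self, test_data=None, test_annotations=None, cfg=None, **cfg_kwargs):
        self._full_annotations = (
            test_annotations if test_annotations is not None else self.annotations
        )
        if test_data is not None and test_annotations is None:
            raise ValueError("test_annotations required with test_data")
        return super().fit(test_data=test_data, cfg=cfg, **cfg_kwargs)

    def _results_cls(self):
        return ClassifierAutoencoderResults


class ClassifierAutoencoderResults(CICAutoencoderResults):
    def classify(self, data: Optional[ExpressionMatrix] = None):
        data = data if data is not None else self.model.data
        return classify(self.trained, data)

    def accuracy(self, data: ExpressionMatrix, annotations: pd.Series) -> float:
        _, pred = self.classify(data)
        truth = annotations.loc[data.sample_ids]
        return float((pred.to_numpy() == truth.to_numpy()).mean())
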