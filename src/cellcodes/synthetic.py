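"""Synthetic expression profiles with planted low-dimensional module structure.

Real tissue panels (the kind of compendium this package targets: hundreds of
log2 quantile-normalized profiles spanning over a dozen tissues, each tissue
sampled under many biological perturbations) owe their compressibility to
coexpressed gene modules.  The generator plants that structure explicitly:

* every gene belongs to exactly one of ``n_modules`` coexpression modules,
  loading 1.0 on it plus small cross-loadings on two other modules;
* every cell type has a base module-activity vector, and each of its
  ``n_conditions_per_type`` conditions shifts it slightly (emulating the
  requirement of at least 10 distinct biological perturbations per type);
* samples are loading @ activity plus additive Gaussian gene-level noise,
  produced directly on a log2-like scale and clipped to ``expression_scale``.

The noiseless matrix therefore has rank <= n_modules, and the planted
truth (module membership, loadings, activities, labels) is returned so that
downstream recovery claims can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = ["SyntheticDesign", "PlantedTruth", "generate"]


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of the planted-module generative model.

    Defaults scale down a 16-tissue x 65-sample compendium to 2000 genes
    while keeping the 30-module intrinsic dimensionality.
    """

    n_genes: int = 2000
    n_types: int = 16
    samples_per_type: int = 65
    n_modules: int = 30
    n_conditions_per_type: int = 10
    noise_sd: float = 0.2
    expression_scale: tuple[float, float] = (2.0, 14.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_types < 1 or self.samples_per_type < 1:
            raise ValueError("n_genes, n_types and samples_per_type must be >= 1")
        if self.n_modules < 1 or self.n_modules > self.n_genes:
            raise ValueError(
                f"n_modules={self.n_modules} must be in [1, n_genes={self.n_genes}]"
            )
        if self.n_conditions_per_type < 1:
            raise ValueError("n_conditions_per_type must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.expression_scale
        if not lo < hi:
            raise ValueError("expression_scale must be an increasing (lo, hi) pair")

    @property
    def n_samples(self) -> int:
        return self.n_types * self.samples_per_type


@dataclass
class PlantedTruth:
    """Ground truth behind a generated matrix.

    ``loading_matrix @ activity_matrix`` is the noiseless signal
    (rank <= n_modules).
    """

    module_of_gene: pd.Series  # gene id -> module index
    loading_matrix: np.ndarray  # genes x modules
    activity_matrix: np.ndarray  # modules x samples
    type_of_sample: pd.Series  # sample id -> type label
    condition_of_sample: pd.Series = field(default=None)  # sample id -> condition

    @property
    def noiseless(self) -> np.ndarray:
        return self.loading_matrix @ self.activity_matrix


# Effect sizes of the generative model.  Every module has one baseline
# activity shared by all types; each type deviates moderately around it and
# each condition adds a smaller shift.  This reproduces the variance scale
# of real log2 quantile-normalized tissue compendia, where most genes keep
# similar levels across tissues (per-gene variance well below 1) rather
# than every module swinging over the whole dynamic range.  The bounded
# draws keep noiseless values strictly inside the default expression scale
# so clipping never engages at noise_sd = 0.
_BASE_LO, _BASE_HI = 5.5, 10.5  # module baseline, log2 units
_TYPE_EFFECT_SD = 0.6  # per-type module deviation (truncated at +-1.5)
_TYPE_EFFECT_CLIP = 1.5
_CONDITION_HALF_WIDTH = 0.5  # uniform per-condition shift
_CROSS_SD = 0.02  # cross-loading scale (clipped at +-0.05)
_CROSS_CLIP = 0.05
_N_CROSS = 2


def generate(
    design: SyntheticDesign,
) -> tuple[ExpressionMatrix, pd.Series, PlantedTruth]:
    """Draw one synthetic compendium.

    Returns ``(matrix, annotations, truth)`` where `annotations` maps sample
    id to cell-type label.  The same design (including seed) reproduces the
    output bit for bit.
    """
    design.validate()
    root = np.random.SeedSequence(design.seed)
    rng_load, rng_act, rng_noise = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    G, M, T, S = (
        design.n_genes,
        design.n_modules,
        design.n_types,
        design.samples_per_type,
    )
    n = design.n_samples

    # module membership: round-robin so every module is populated
    module_of_gene = np.arange(G) % M
    loading = np.zeros((G, M))
    loading[np.arange(G), module_of_gene] = 1.0
    if M > 1:
        for g in range(G):
            others = np.delete(np.arange(M), module_of_gene[g])
            picks = rng_load.choice(others, size=min(_N_CROSS, M - 1), replace=False)
            cross = np.clip(
                rng_load.normal(0.0, _CROSS_SD, size=len(picks)),
                -_CROSS_CLIP,
                _CROSS_CLIP,
            )
            loading[g, picks] = cross

    # shared module baselines, per-type deviations, per-condition offsets
    baseline = rng_act.uniform(_BASE_LO, _BASE_HI, size=M)
    type_dev = np.clip(
        rng_act.normal(0.0, _TYPE_EFFECT_SD, size=(T, M)),
        -_TYPE_EFFECT_CLIP,
        _TYPE_EFFECT_CLIP,
    )
    offsets = rng_act.uniform(
        -_CONDITION_HALF_WIDTH,
        _CONDITION_HALF_WIDTH,
        size=(T, design.n_conditions_per_type, M),
    )
    activity = np.empty((M, n))
    type_labels = []
    condition_ids = []
    for t in range(T):
        for j in range(S):
            c = j % design.n_conditions_per_type
            activity[:, t * S + j] = baseline + type_dev[t] + offsets[t, c]
            type_labels.append(f"type{t:02d}")
            condition_ids.append(c)

    signal = loading @ activity
    if design.noise_sd > 0:
        values = signal + rng_noise.normal(0.0, design.noise_sd, size=signal.shape)
    else:
        values = signal.copy()
    lo, hi = design.expression_scale
    np.clip(values, lo, hi, out=values)

    gene_ids = [f"gene{g:05d}" for g in range(G)]
    sample_ids = [f"s{t:02d}_{j:03d}" for t in range(T) for j in range(S)]
    matrix = ExpressionMatrix(values, gene_ids, sample_ids)
    annotations = pd.Series(type_labels, index=sample_ids, name="type")
    truth = PlantedTruth(
        module_of_gene=pd.Series(module_of_gene, index=gene_ids, name="module"),
        loading_matrix=loading,
        activity_matrix=activity,
        type_of_sample=annotations.copy(),
        condition_of_sample=pd.Series(condition_ids, index=sample_ids, name="condition"),
    )
    return matrix, annotations, truth


def save_truth(truth: PlantedTruth, prefix) -> None:
    """Serialize planted truth to TSV sidecar files (``<prefix>.*.tsv``)."""
    prefix = str(prefix)
    truth.module_of_gene.to_frame().to_csv(f"{prefix}.modules.tsv", sep="\t")
    pd.DataFrame(
        truth.loading_matrix, index=truth.module_of_gene.index
    ).to_csv(f"{prefix}.loadings.tsv", sep="\t")
    pd.DataFrame(
        truth.activity_matrix, columns=truth.type_of_sample.index
    ).to_csv(f"{prefix}.activities.tsv", sep="\t")
    truth.type_of_sample.to_frame().to_csv(f"{prefix}.types.tsv", sep="\t")
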