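"""Attribute latent code components to genes, and screen REPs for identity.

The perturbation procedure asks what each code component controls: decode
the mean code C-bar to get a baseline REP, then bump one component i to
C-bar_i + 2*sigma_i and record which genes' reproduced expression changes
the most.  The top-k genes (default 100, equal k for every component so
downstream enrichment is unbiased) form that component's gene set; sets may
overlap across components.

A simple per-gene differential-expression screen (Welch's t with
Benjamini-Hochberg adjustment, log2FC > 1 and adjusted p <= 0.05) checks
whether reconstructed profiles carry the expected identity genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .models import CICMatrix
from .network import TrainedModel

__all__ = [
    "component_stats",
    "ComponentGeneSet",
    "perturb_components",
    "de_screen",
    "export_gene_sets",
    "read_gene_sets",
]


def component_stats(codes: CICMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sample SD (n-1 denominator) of each code component."""
    if codes.codes.shape[0] < 2:
        warnings.warn("single sample: component SDs are zero")
    return codes.component_mean.copy(), codes.component_sd.copy()


@dataclass
class ComponentGeneSet:
    """Genes most influenced by one code component.

    Ordered by descending |delta| (or signed delta in signed mode), ties
    broken by input gene order.  `delta` keeps the full change vector.
    """

    component: int  # 1-based index
    genes: list
    delta: np.ndarray

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene set contains duplicates")


def perturb_components(
    model: TrainedModel,
    component_mean: np.ndarray,
    component_sd: np.ndarray,
    k: int = 100,
    mode: str = "absolute",
) -> list[ComponentGeneSet]:
    """Per-component top-k genes by REP change under a +2 sigma bump.

    For component i, ``delta_i = decode(C-bar + 2 sigma_i e_i) - decode(C-bar)``.
    Components with sigma_i = 0 produce an empty set (with a warning) rather
    than arbitrary genes.  ``mode`` ranks by absolute change (default) or by
    signed increase.
    """
    cbar = np.asarray(component_mean, dtype=float)
    sigma = np.asarray(component_sd, dtype=float)
    K = model.spec.code_size
    if cbar.shape != (K,) or sigma.shape != (K,):
        raise ValueError(f"component stats must have length {K}")
    if not np.all(np.isfinite(sigma)):
        raise ValueError("sigma must be finite")
    if mode not in ("absolute", "signed"):
        raise ValueError("mode must be 'absolute' or 'signed'")
    gene_ids = (
        model.gene_ids
        if model.gene_ids is not None
        else [f"g{i}" for i in range(model.spec.output_size)]
    )
    baseline = model.decode_array(cbar)
    perturbed = np.tile(cbar, (K, 1))
    perturbed[np.arange(K), np.arange(K)] += 2.0 * sigma
    reps = model.decode_array(perturbed)  # K x genes
    deltas = reps - baseline[None, :]
    sets = []
    for i in range(K):
        if sigma[i] == 0:
            warnings.warn(f"component {i + 1} has zero SD; emitting an empty set")
            sets.append(
                ComponentGeneSet(component=i + 1, genes=[], delta=deltas[i].copy())
            )
            continue
        score = np.abs(deltas[i]) if mode == "absolute" else deltas[i]
        top = np.argsort(-score, kind="stable")[: min(k, len(gene_ids))]
        sets.append(
            ComponentGeneSet(
                component=i + 1,
                genes=[gene_ids[j] for j in top],
                delta=deltas[i].copy(),
            )
        )
    return sets


def de_screen(
    group_a: ExpressionMatrix,
    group_b: ExpressionMatrix,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes enriched in group A vs group B on log2-scale values.

    Per-gene Welch's t-test with Benjamini-Hochberg adjustment; keeps genes
    with mean difference > `lfc_threshold` AND adjusted p <= `alpha`, in
    ascending adjusted-p order.  Returns columns gene, log2fc, p, padj.
    """
    if list(group_a.gene_ids) != list(group_b.gene_ids):
        raise ValueError("groups must share the same genes in the same order")
    if group_a.n_samples < 2 or group_b.n_samples < 2:
        raise ValueError("each group needs at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = stats.ttest_ind(
            group_a.values, group_b.values, axis=1, equal_var=False
        )
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)  # constant genes -> no call
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    lfc = group_a.values.mean(axis=1) - group_b.values.mean(axis=1)
    table = pd.DataFrame(
        {"gene": group_a.gene_ids, "log2fc": lfc, "p": pvals, "padj": padj}
    )
    hits = table[(table["log2fc"] > lfc_threshold) & (table["padj"] <= alpha)]
    return hits.sort_values("padj", kind="stable").reset_index(drop=True)


# -- GMT export ------------------------------------------------------------

def export_gene_sets(sets: list[ComponentGeneSet], path) -> None:
    """Write component gene sets in GMT format.

    One line per set: ``CIC_<i> <tab> <i> <tab> gene1 <tab> gene2 ...``.
    Duplicate genes within a set are rejected; an all-empty collection
    produces a valid file with a warning.
    """
    if all(len(s.genes) == 0 for s in sets):
        warnings.warn("all gene sets are empty")
    with open(path, "wt", encoding="utf-8") as fh:
        for s in sets:
            if len(set(s.genes)) != len(s.genes):
                raise ValueError(f"set CIC_{s.component} contains duplicate genes")
            fields = [f"CIC_{s.component}", str(s.component), *s.genes]
            fh.write("\t".join(fields) + "\n")


def read_gene_sets(path) -> dict[str, list]:
    """Parse a GMT file into ``{set name: [genes]}`` (description dropped)."""
    out: dict[str, list] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line[:50]!r}")
            out[fields[0]] = fields[2:]
    return out
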