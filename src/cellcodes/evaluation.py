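"""Evaluation protocols for reproduced expression profiles.

* REP-GEP ranking: for each test profile, how many *other* test profiles
  are closer to it than its own reconstruction?  A faithful code puts the
  paired REP at rank 1 for nearly every sample.
* GEP-GEP vs GEP-REP paired comparison with a Wilcoxon signed-rank test.
* k-fold cross-validation orchestration with fresh weights per fold.
* Leave-one-type-out universality: train without one cell type, then test
  whether each held-out sample's REP beats every training profile.
* Downstream random-forest / SVM classification on code matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .expression import ExpressionMatrix, check_annotations
from .network import TrainConfig, train
from . import models as _models

__all__ = [
    "spearman",
    "RankingResult",
    "rank_reps",
    "reverse_rank_reps",
    "pairwise_comparison",
    "FoldPlan",
    "make_folds",
    "run_cv",
    "CVResult",
    "leave_one_type_out",
    "LOTOReport",
    "downstream_classify",
]


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (mid-rank ties); NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _similarity_matrix(A: np.ndarray, B: np.ndarray, metric: str) -> np.ndarray:
    """similarity[i, j] between column i of A and column j of B.

    Higher is more similar: Spearman correlation, or negated MSE.
    """
    if metric == "spearman":
        ra = np.apply_along_axis(stats.rankdata, 0, A)
        rb = np.apply_along_axis(stats.rankdata, 0, B)
        ra = ra - ra.mean(axis=0)
        rb = rb - rb.mean(axis=0)
        na = np.linalg.norm(ra, axis=0)
        nb = np.linalg.norm(rb, axis=0)
        na[na == 0] = np.nan
        nb[nb == 0] = np.nan
        return (ra.T @ rb) / np.outer(na, nb)
    if metric == "mse":
        a2 = (A**2).sum(axis=0)[:, None]
        b2 = (B**2).sum(axis=0)[None, :]
        mse = (a2 + b2 - 2.0 * (A.T @ B)) / A.shape[0]
        return -mse
    raise ValueError(f"metric must be 'spearman' or 'mse', got {metric!r}")


@dataclass
class RankingResult:
    """Per-sample rank of the paired REP among all test candidates."""

    ranks: pd.Series  # sample id -> rank in [1, n_test]
    metric: str

    @property
    def histogram(self) -> pd.Series:
        n = len(self.ranks)
        counts = self.ranks.value_counts().sort_index()
        counts.index.name = "rank"
        return counts

    def fraction_at_rank(self, r: int = 1) -> float:
        return float((self.ranks == r).mean())


def _check_matched(geps: ExpressionMatrix, reps: ExpressionMatrix) -> None:
    if list(geps.sample_ids) != list(reps.sample_ids):
        raise ValueError("GEP and REP sample ids must match one-to-one")
    if list(geps.gene_ids) != list(reps.gene_ids):
        raise ValueError("GEP and REP gene ids must match")


def rank_reps(
    geps: ExpressionMatrix, reps: ExpressionMatrix, metric: str = "spearman"
) -> RankingResult:
    """Rank each sample's REP against all other test GEPs.

    rank(s) = 1 + #{g != s : similarity(GEP_s, GEP_g) >= similarity(GEP_s,
    REP_s)} — a tie with a foreign profile counts against the REP.
    """
    _check_matched(geps, reps)
    sim_gg = _similarity_matrix(geps.values, geps.values, metric)
    sim_gr = _similarity_matrix(geps.values, reps.values, metric)
    n = geps.n_samples
    ranks = np.empty(n, dtype=int)
    for s in range(n):
        own = sim_gr[s, s]
        others = np.delete(sim_gg[s], s)
        ranks[s] = 1 + int(np.sum(others >= own))
    return RankingResult(
        ranks=pd.Series(ranks, index=geps.sample_ids, name="rank"), metric=metric
    )


def reverse_rank_reps(
    reps: ExpressionMatrix, geps: ExpressionMatrix, metric: str = "spearman"
) -> RankingResult:
    """Rank each REP's own GEP among all test GEPs (roles swapped).

    rank(s) = 1 + #{g != s : similarity(REP_s, GEP_g) >= similarity(REP_s,
    GEP_s)}.
    """
    _check_matched(geps, reps)
    sim_rg = _similarity_matrix(reps.values, geps.values, metric)
    n = geps.n_samples
    ranks = np.empty(n, dtype=int)
    for s in range(n):
        own = sim_rg[s, s]
        others = np.delete(sim_rg[s], s)
        ranks[s] = 1 + int(np.sum(others >= own))
    return RankingResult(
        ranks=pd.Series(ranks, index=geps.sample_ids, name="rank"), metric=metric
    )


def pairwise_comparison(
    geps: ExpressionMatrix, reps: ExpressionMatrix, metric: str = "spearman"
) -> tuple[pd.DataFrame, float]:
    """Closest-other-GEP score vs own-REP score, with a paired Wilcoxon test.

    Returns a per-sample table with columns ``gep_gep`` (the best similarity
    to any other test GEP) and ``gep_rep`` (similarity to the paired REP),
    plus the two-sided Wilcoxon signed-rank p-value over the paired columns
    (NaN when every pair is tied).
    """
    _check_matched(geps, reps)
    n = geps.n_samples
    if n < 6:
        warnings.warn("fewer than 6 samples: the Wilcoxon test has little power")
    sim_gg = _similarity_matrix(geps.values, geps.values, metric)
    sim_gr = _similarity_matrix(geps.values, reps.values, metric)
    np.fill_diagonal(sim_gg, -np.inf)
    table = pd.DataFrame(
        {
            "gep_gep": sim_gg.max(axis=1),
            "gep_rep": np.diag(sim_gr),
        },
        index=geps.sample_ids,
    )
    diffs = table["gep_rep"] - table["gep_gep"]
    if np.allclose(diffs, 0):
        return table, float("nan")
    method = "exact" if n <= 25 else "approx"
    res = stats.wilcoxon(
        table["gep_rep"], table["gep_gep"], alternative="two-sided", method=method
    )
    return table, float(res.pvalue)


# -- cross-validation ------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Partition of samples into folds; each sample tests exactly once."""

    n_folds: int = 10
    mode: str = "stratified-by-type"  # or "random"
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.mode not in ("random", "stratified-by-type"):
            raise ValueError("mode must be 'random' or 'stratified-by-type'")


def make_folds(
    sample_ids: Sequence[str],
    plan: FoldPlan,
    labels: Optional[pd.Series] = None,
) -> pd.Series:
    """Assign each sample id to a fold index [0, n_folds)."""
    ids = np.asarray(list(sample_ids))
    assign = np.empty(len(ids), dtype=int)
    if plan.mode == "stratified-by-type":
        if labels is None:
            raise ValueError("stratified folds need type labels")
        splitter = StratifiedKFold(
            n_splits=plan.n_folds, shuffle=True, random_state=plan.seed
        )
        split = splitter.split(ids, labels.loc[ids].to_numpy())
    else:
        splitter = KFold(n_splits=plan.n_folds, shuffle=True, random_state=plan.seed)
        split = splitter.split(ids)
    for fold, (_, test_idx) in enumerate(split):
        if len(test_idx) < 2:
            warnings.warn(f"fold {fold} has fewer than 2 test samples")
        assign[test_idx] = fold
    return pd.Series(assign, index=ids, name="fold")


@dataclass
class CVResult:
    """Aggregated cross-validation learning curves."""

    per_fold_logs: list  # list of per-epoch log dicts, one list per fold
    folds: pd.Series

    def _per_epoch(self, key: str) -> np.ndarray:
        return np.array([[e[key] for e in log] for log in self.per_fold_logs])

    def mean_test_mse(self) -> np.ndarray:
        return self._per_epoch("test_mse").mean(axis=0)

    def se_test_mse(self) -> np.ndarray:
        arr = self._per_epoch("test_mse")
        return arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_test_mse": self.mean_test_mse(),
                "se_test_mse": self.se_test_mse(),
            },
            index=pd.RangeIndex(1, len(self.per_fold_logs[0]) + 1, name="epoch"),
        )


def run_cv(
    matrix: ExpressionMatrix,
    annotations: Optional[pd.Series],
    model_builder: Callable[[ExpressionMatrix, Optional[pd.Series]], object],
    cfg: TrainConfig,
    plan: FoldPlan,
) -> CVResult:
    """k-fold cross-validation with fresh weights per fold.

    `model_builder(train_matrix, train_annotations)` must return an unfitted
    CICAutoencoder or ClassifierAutoencoder.  Each fold reseeds training with
    ``cfg.seed + fold`` so every round restarts from new random parameters,
    and the held-out fold's losses are logged per epoch.
    """
    if annotations is not None:
        annotations = check_annotations(matrix, annotations)
    folds = make_folds(matrix.sample_ids, plan, labels=annotations)
    logs = []
    results = []
    from dataclasses import replace

    for fold in range(plan.n_folds):
        test_ids = folds.index[folds == fold]
        train_ids = folds.index[folds != fold]
        train_m = matrix.subset_samples(train_ids)
        test_m = matrix.subset_samples(test_ids)
        model = model_builder(
            train_m, annotations.loc[train_ids] if annotations is not None else None
        )
        fold_cfg = replace(cfg, seed=cfg.seed + fold)
        if isinstance(model, _models.ClassifierAutoencoder):
            res = model.fit(
                test_data=test_m, test_annotations=annotations, cfg=fold_cfg
            )
        else:
            res = model.fit(test_data=test_m, cfg=fold_cfg)
        logs.append(res.trained.training_log)
        results.append(res)
    out = CVResult(per_fold_logs=logs, folds=folds)
    out.fold_results = results
    return out


# -- leave-one-type-out universality ---------------------------------------

@dataclass
class LOTOReport:
    """Universality check for one held-out cell type."""

    held_out_type: str
    per_sample: pd.DataFrame  # pass_spearman, pass_mse, mse, spearman
    median_mse: float
    median_spearman: float

    @property
    def pass_fraction(self) -> float:
        """Fraction of held-out samples whose REP beats every training GEP
        under both metrics."""
        both = self.per_sample["pass_spearman"] & self.per_sample["pass_mse"]
        return float(both.mean())


def leave_one_type_out(
    matrix: ExpressionMatrix,
    annotations: pd.Series,
    type_label: str,
    model_builder: Callable[[ExpressionMatrix], object],
    cfg: TrainConfig,
) -> LOTOReport:
    """Train without one cell type; test whether its REPs stay closest.

    A held-out sample passes when its REP is more similar to its own GEP
    than *every* training GEP is, under the given metric (ties fail).
    """
    annotations = check_annotations(matrix, annotations)
    if type_label not in set(annotations):
        raise ValueError(f"unknown type label {type_label!r}")
    if annotations.nunique() < 2:
        raise ValueError("need at least 2 types")
    test_ids = annotations.index[annotations == type_label]
    train_ids = annotations.index[annotations != type_label]
    train_m = matrix.subset_samples(train_ids)
    test_m = matrix.subset_samples(test_ids)
    model = model_builder(train_m)
    res = model.fit(cfg=cfg)
    rep = res.reconstruct(test_m)

    sim_sp_rep = np.diag(_similarity_matrix(test_m.values, rep.values, "spearman"))
    sim_sp_train = _similarity_matrix(test_m.values, train_m.values, "spearman")
    sim_mse_rep = np.diag(_similarity_matrix(test_m.values, rep.values, "mse"))
    sim_mse_train = _similarity_matrix(test_m.values, train_m.values, "mse")

    per_sample = pd.DataFrame(
        {
            "spearman": sim_sp_rep,
            "mse": -sim_mse_rep,
            "pass_spearman": sim_sp_rep > sim_sp_train.max(axis=1),
            "pass_mse": sim_mse_rep > sim_mse_train.max(axis=1),
        },
        index=test_m.sample_ids,
    )
    report = LOTOReport(
        held_out_type=type_label,
        per_sample=per_sample,
        median_mse=float(per_sample["mse"].median()),
        median_spearman=float(per_sample["spearman"].median()),
    )
    report.results = res
    return report


# -- downstream classification --------------------------------------------

def downstream_classify(
    train_codes: np.ndarray,
    train_labels: Sequence,
    test_codes: np.ndarray,
    method: str = "rf",
    test_labels: Optional[Sequence] = None,
    seed: int = 0,
):
    """Random-forest or SVM classification of code vectors.

    Returns ``(predictions, n_misclassified)``; the count is None when
    `test_labels` is not given.  RF uses 500 trees; SVM an RBF kernel with
    C=1 — fixed, documented defaults.
    """
    train_labels = np.asarray(train_labels)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training set contains a single class")
    if method == "rf":
        clf = RandomForestClassifier(n_estimators=500, random_state=seed)
    elif method == "svm":
        clf = SVC(kernel="rbf", C=1.0, random_state=seed)
    else:
        raise ValueError("method must be 'rf' or 'svm'")
    clf.fit(np.asarray(train_codes, dtype=float), train_labels)
    pred = clf.predict(np.asarray(test_codes, dtype=float))
    n_err = None
    if test_labels is not None:
        n_err = int(np.sum(pred != np.asarray(test_labels)))
    return pred, n_err
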