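"""Cross-validated evaluation: ROC/AUC, PR/AUPR, tissue stratification,
source-ablation grids, and feature-response correlation analysis.

The outer loop is stratified 10-fold cross-validation over labeled
(cell, drug) pairs by default; ``split_unit="cell"`` or ``"drug"`` instead
holds out whole cell lines or compounds, probing generalization to unseen
entities.  Penalty selection runs inside each training fold only, so no
test information leaks into model choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .containers import KronfuseError, ResponseMatrix, SimilarityMatrix
from .kernel import PairKernel
from .labels import LabelMatrix, list_pairs
from .model import PairSVM, SvmConfig


@dataclass
class EvalConfig:
    outer_folds: int = 10
    split_unit: str = "pair"  # pair | cell | drug
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.outer_folds < 2:
            raise KronfuseError("need at least 2 outer folds")
        if self.split_unit not in ("pair", "cell", "drug"):
            raise KronfuseError(f"unknown split unit {self.split_unit!r}")


def roc_auc(scores, labels):
    """Trapezoidal AUC (equals the normalized Mann-Whitney U statistic) plus
    the ROC curve points ``(fpr, tpr)``."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise KronfuseError("ROC needs both classes")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(roc_auc_score(labels, scores)), (fpr, tpr)


def pr_aupr(scores, labels):
    """Average precision (step-wise, no interpolation) plus the PR curve
    points ``(recall, precision)``."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise KronfuseError("PR needs both classes")
    precision, recall, _ = precision_recall_curve(labels, scores)
    return float(average_precision_score(labels, scores)), (recall, precision)


@dataclass
class CVResult:
    """Pooled out-of-fold scores plus per-fold metrics.

    ``scores`` are per-fold standardized decision values (used for pooled
    ranking metrics); ``raw_scores`` keep the signed decision values whose
    sign at 0 is the class prediction.
    """

    pairs: list[tuple[str, str]]
    labels: np.ndarray
    scores: np.ndarray
    raw_scores: np.ndarray
    fold_of_pair: np.ndarray
    fold_auc: list[float]
    fold_aupr: list[float]
    chosen_C: list[float]

    @property
    def predictions(self) -> np.ndarray:
        return np.where(self.raw_scores >= 0, 1, -1)

    @property
    def pooled_auc(self) -> float:
        return roc_auc(self.scores, self.labels)[0]

    @property
    def pooled_aupr(self) -> float:
        return pr_aupr(self.scores, self.labels)[0]

    def summary(self) -> str:
        return (
            f"{self.fold_of_pair.max() + 1}-fold CV over {len(self.pairs)} pairs: "
            f"AUC {self.pooled_auc:.3f} "
            f"(per-fold {np.mean(self.fold_auc):.3f} +/- {np.std(self.fold_auc):.3f}), "
            f"AUPR {self.pooled_aupr:.3f} "
            f"(per-fold {np.mean(self.fold_aupr):.3f} +/- {np.std(self.fold_aupr):.3f})"
        )


def _outer_folds(pairs, y, eval_config: EvalConfig):
    n = len(pairs)
    if eval_config.split_unit == "pair":
        cv = StratifiedKFold(n_splits=eval_config.outer_folds, shuffle=True,
                             random_state=eval_config.seed)
        return list(cv.split(np.zeros(n), y))
    unit = 0 if eval_config.split_unit == "cell" else 1
    uniq = sorted({p[unit] for p in pairs})
    gid = {g: i for i, g in enumerate(uniq)}
    groups = np.array([gid[p[unit]] for p in pairs])
    rng = np.random.default_rng(eval_config.seed)
    perm = rng.permutation(len(uniq))
    groups = perm[groups]
    cv = GroupKFold(n_splits=eval_config.outer_folds)
    return list(cv.split(np.zeros(n), y, groups))


def cross_validate(
    pk: PairKernel,
    label_matrix: LabelMatrix,
    svm_config: SvmConfig | None = None,
    eval_config: EvalConfig | None = None,
) -> CVResult:
    """Outer k-fold CV of the pair SVM; every labeled pair is scored exactly
    once, by a model that never saw it."""
    svm_config = svm_config or SvmConfig()
    eval_config = eval_config or EvalConfig()
    labeled = list_pairs(label_matrix, "labeled")
    if not labeled:
        raise KronfuseError("no labeled pairs")
    plist = [(c, d) for c, d, _ in labeled]
    y = np.array([lab for _, _, lab in labeled])
    folds = _outer_folds(plist, y, eval_config)
    scores = np.full(len(plist), np.nan)
    raw_scores = np.full(len(plist), np.nan)
    fold_of_pair = np.full(len(plist), -1, dtype=int)
    fold_auc, fold_aupr, chosen = [], [], []
    for k, (tr, te) in enumerate(folds):
        if set(tr) & set(te):
            raise KronfuseError("leakage: pair present in both train and test")
        train_pairs = [labeled[i] for i in tr]
        test_pairs = [plist[i] for i in te]
        if eval_config.split_unit == "cell":
            assert not ({plist[i][0] for i in tr} & {plist[i][0] for i in te})
        elif eval_config.split_unit == "drug":
            assert not ({plist[i][1] for i in tr} & {plist[i][1] for i in te})
        fold_cfg = replace(svm_config, seed=svm_config.seed + k)
        res = PairSVM(pk, train_pairs, fold_cfg).fit()
        s = res.decision_scores(test_pairs)
        # decision values from different folds live on different scales
        # (intercept and margin shrink with C); standardize within fold so
        # pooled rankings are comparable — per-fold metrics are unaffected
        raw_scores[te] = s
        sd = s.std()
        scores[te] = (s - s.mean()) / (sd if sd > 0 else 1.0)
        fold_of_pair[te] = k
        chosen.append(res.C)
        y_te = y[te]
        if len(set(y_te.tolist())) == 2:
            fold_auc.append(roc_auc(s, y_te)[0])
            fold_aupr.append(pr_aupr(s, y_te)[0])
        else:
            warnings.warn(f"fold {k} has a single class; fold metrics skipped")
    assert not np.isnan(scores).any() and (fold_of_pair >= 0).all()
    return CVResult(plist, y, scores, raw_scores, fold_of_pair,
                    fold_auc, fold_aupr, chosen)


def ablation_grid(
    cell_sources: dict[str, SimilarityMatrix],
    drug_sources: dict[str, SimilarityMatrix],
    label_matrix: LabelMatrix,
    svm_config: SvmConfig | None = None,
    eval_config: EvalConfig | None = None,
) -> dict[tuple[str, str], CVResult]:
    """Cross-validate every (cell source x drug source) combination.

    Pass the per-source matrices plus their max-combinations (e.g. keys
    ``Mut, CN, GE, Comb_c`` by ``Chem, Target, ATC, Comb_d``) to reproduce a
    full source-ablation table of AUCs.
    """
    out = {}
    for cname, s_cell in cell_sources.items():
        for dname, s_drug in drug_sources.items():
            pk = PairKernel(s_cell, s_drug)
            out[(cname, dname)] = cross_validate(pk, label_matrix, svm_config, eval_config)
    return out


def tissue_stratified(
    cv: CVResult, tissue_of_cell: dict[str, str], tissues: list[str] | None = None
) -> dict[str, dict[str, float]]:
    """Per-tissue AUC/AUPR over the pooled out-of-fold scores of test pairs
    whose cell belongs to each tissue."""
    if tissues is None:
        tissues = sorted({tissue_of_cell.get(c) for c, _ in cv.pairs} - {None})
    out = {}
    for tissue in tissues:
        idx = [i for i, (c, _) in enumerate(cv.pairs) if tissue_of_cell.get(c) == tissue]
        if not idx:
            warnings.warn(f"tissue {tissue!r}: no test pairs; skipped")
            continue
        y = cv.labels[idx]
        if len(set(y.tolist())) < 2:
            warnings.warn(f"tissue {tissue!r}: fewer than 2 classes; skipped")
            continue
        s = cv.scores[idx]
        out[tissue] = {
            "auc": roc_auc(s, y)[0],
            "aupr": pr_aupr(s, y)[0],
            "n_pairs": len(idx),
        }
    return out


@dataclass
class ResponseProfileSimilarityConfig:
    """Gaussian bandwidth for response-profile similarity; the mean-distance
    rule mirrors :class:`~kronfuse.cellsim.GaussianConfig`."""

    bandwidth_rule: str = "mean_squared_distance"
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.bandwidth_rule not in ("mean_squared_distance", "fixed"):
            raise KronfuseError(f"unknown bandwidth rule {self.bandwidth_rule!r}")
        if self.bandwidth_rule == "fixed" and (self.gamma is None or self.gamma <= 0):
            raise KronfuseError("fixed bandwidth requires gamma > 0")


def response_profile_similarity(
    responses: ResponseMatrix,
    axis: str = "cells",
    config: ResponseProfileSimilarityConfig | None = None,
) -> SimilarityMatrix:
    """Gaussian similarity between response profiles (rows for cells,
    columns for drugs), over pairwise-complete positions.

    Squared distances are per-shared-position means, so profiles observed on
    different numbers of drugs are comparable; pairs with fewer than 2 shared
    measurements get a 0 entry and are reported unavailable pairwise.
    """
    config = config or ResponseProfileSimilarityConfig()
    if axis not in ("cells", "drugs"):
        raise KronfuseError(f"unknown axis {axis!r}")
    x = responses.values if axis == "cells" else responses.values.T
    ids = responses.cell_ids if axis == "cells" else responses.drug_ids
    n = len(ids)
    if n < 2:
        raise KronfuseError("need at least 2 profiles")
    mask = ~np.isnan(x)
    d2 = np.full((n, n), np.nan)
    for i in range(n):
        d2[i, i] = 0.0
        for j in range(i + 1, n):
            common = mask[i] & mask[j]
            if common.sum() < 2:
                continue
            diff = x[i, common] - x[j, common]
            d2[i, j] = d2[j, i] = float((diff @ diff) / common.sum())
    off = d2[~np.eye(n, dtype=bool)]
    off = off[~np.isnan(off)]
    if config.bandwidth_rule == "fixed":
        gamma = float(config.gamma)
    else:
        if off.size == 0 or off.mean() == 0.0:
            raise KronfuseError("mean pairwise profile distance is 0 or undefined")
        gamma = 1.0 / float(off.mean())
    values = np.where(np.isnan(d2), 0.0, np.exp(-gamma * np.nan_to_num(d2)))
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(ids), np.clip(values, 0.0, 1.0), "response_profile")


def similarity_correlation(
    s_feature: SimilarityMatrix, s_response: SimilarityMatrix, bins: int = 3
) -> dict:
    """Correlate feature similarity with response-profile similarity.

    Uses strictly-upper-triangle entries present in both matrices; returns
    the Pearson correlation, per-bin (tertile by default) response-similarity
    summaries, and Welch t statistics between adjacent bins.
    """
    if s_feature.entity_ids != s_response.entity_ids:
        raise KronfuseError("matrices must share one id order")
    n = s_feature.n_entities
    iu = np.triu_indices(n, k=1)
    xf = s_feature.values[iu]
    xr = s_response.values[iu]
    if xf.size < 2:
        raise KronfuseError("need at least 2 entity pairs")
    pcc, pcc_p = stats.pearsonr(xf, xr)
    edges = np.quantile(xf, np.linspace(0, 1, bins + 1))
    edges[0] -= 1e-12
    which = np.clip(np.searchsorted(edges, xf, side="right") - 1, 0, bins - 1)
    names = (["low", "moderate", "high"] if bins == 3
             else [f"bin{i}" for i in range(bins)])
    bin_stats = {}
    for b in range(bins):
        vals = xr[which == b]
        bin_stats[names[b]] = {
            "n": int(vals.size),
            "mean": float(vals.mean()) if vals.size else float("nan"),
            "median": float(np.median(vals)) if vals.size else float("nan"),
        }
    ttests = {}
    for b in range(bins - 1):
        lo, hi = xr[which == b], xr[which == b + 1]
        if lo.size > 1 and hi.size > 1:
            t, p = stats.ttest_ind(hi, lo, equal_var=False)
            ttests[f"{names[b + 1]}_vs_{names[b]}"] = {"t": float(t), "p": float(p)}
    return {"pcc": float(pcc), "pcc_p": float(pcc_p), "bins": bin_stats, "ttests": ttests}
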