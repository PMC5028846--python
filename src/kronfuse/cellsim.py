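"""Cell-side similarity constructions and max-combination fusion.

Three views of a cell line enter the model: oncogene mutation status
(weighted cosine over binary profiles), gene-level copy number (Gaussian
kernel on the profile distance), and mRNA expression (absolute Pearson
correlation).  `combine_max` fuses any set of similarity matrices by the
element-wise maximum: two cells are considered similar if any single data
source says they are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform

from .containers import FeatureTable, KronfuseError, SimilarityMatrix


@dataclass
class MutationWeightConfig:
    """Oncogene weighting for the mutation-profile cosine.

    ``inverse_frequency_exp`` down-weights frequently mutated genes:
    w_k = exp(-f_k / (h * sigma_f)) where f_k is the mutation rate of gene k
    across the cells, sigma_f the standard deviation of the rates (replaced
    by 1 when zero), and h a damping constant, 10 by default.
    """

    h: float = 10.0
    weight_scheme: str = "inverse_frequency_exp"

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise KronfuseError("h must be positive")
        if self.weight_scheme not in ("inverse_frequency_exp", "uniform"):
            raise KronfuseError(f"unknown weight scheme {self.weight_scheme!r}")


@dataclass
class GaussianConfig:
    """Bandwidth policy for Gaussian similarities.

    ``mean_squared_distance`` sets gamma to the reciprocal of the mean
    squared Euclidean distance over all distinct entity pairs — a standard
    self-tuning heuristic; ``fixed`` uses the supplied gamma.
    """

    bandwidth_rule: str = "mean_squared_distance"
    gamma: float | None = None
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.bandwidth_rule not in ("mean_squared_distance", "fixed"):
            raise KronfuseError(f"unknown bandwidth rule {self.bandwidth_rule!r}")
        if self.bandwidth_rule == "fixed" and (self.gamma is None or self.gamma <= 0):
            raise KronfuseError("fixed bandwidth requires gamma > 0")


def mutation_weights(freqs: np.ndarray, config: MutationWeightConfig | None = None) -> np.ndarray:
    """Per-gene weights from mutation rates f_k in [0, 1]."""
    config = config or MutationWeightConfig()
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise KronfuseError("empty frequency vector")
    if (freqs < 0).any() or (freqs > 1).any():
        raise KronfuseError("mutation rates must lie in [0, 1]")
    if config.weight_scheme == "uniform":
        return np.ones_like(freqs)
    sigma = float(np.std(freqs))
    if sigma < 1e-12:  # effectively constant rates
        sigma = 1.0
    return np.exp(-freqs / (config.h * sigma))


def weighted_cosine(z: np.ndarray, zp: np.ndarray, w: np.ndarray) -> float:
    """Weighted cosine between binary profiles:
    sum(w^2 z z') / (||w z|| * ||w z'||); 0 if either profile is all zero."""
    z = np.asarray(z, dtype=float)
    zp = np.asarray(zp, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (z.shape == zp.shape == w.shape):
        raise KronfuseError("profile/weight length mismatch")
    if (w < 0).any():
        raise KronfuseError("weights must be non-negative")
    if not np.isin(z, (0.0, 1.0)).all() or not np.isin(zp, (0.0, 1.0)).all():
        raise KronfuseError("profiles must be binary")
    w2 = w * w
    na = np.sqrt(float(w2 @ z))
    nb = np.sqrt(float(w2 @ zp))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float((w2 * z) @ zp / (na * nb))


def mutation_similarity(table: FeatureTable, config: MutationWeightConfig | None = None) -> SimilarityMatrix:
    """Weighted-cosine similarity over the table's binary mutation profiles.

    Gene weights come from the table's own mutation rates.  All-zero profiles
    get similarity 0 with everything but themselves; the diagonal is 1.
    """
    if table.source_tag != "mutation":
        raise KronfuseError("mutation_similarity requires a mutation table")
    config = config or MutationWeightConfig()
    z = table.values
    if z.shape[1] == 0:
        values = np.eye(table.n_entities)
        return SimilarityMatrix(list(table.entity_ids), values, "mutation")
    w = mutation_weights(z.mean(axis=0), config)
    wz = z * w  # rows scaled by weights
    gram = wz @ wz.T
    norms = np.sqrt(np.diag(gram))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = gram / np.outer(norms, norms)
    values[~np.isfinite(values)] = 0.0
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(list(table.entity_ids), values, "mutation")


def _prepare_features(table: FeatureTable, standardize: bool) -> np.ndarray:
    x = table.values.copy()
    # mean imputation per feature for missing entries
    if np.isnan(x).any():
        col_means = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
        col_means = np.nan_to_num(col_means)
        idx = np.where(np.isnan(x))
        x[idx] = col_means[idx[1]]
    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    return x


def gaussian_similarity(table: FeatureTable, config: GaussianConfig | None = None) -> SimilarityMatrix:
    """Gaussian-kernel similarity exp(-gamma * ||x - x'||^2) between entities."""
    config = config or GaussianConfig()
    if table.n_entities < 2:
        raise KronfuseError("gaussian_similarity needs at least 2 entities")
    x = _prepare_features(table, config.standardize)
    sq = np.sum(x * x, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    if config.bandwidth_rule == "fixed":
        gamma = float(config.gamma)
    else:
        mean_d2 = float(squareform(d2, checks=False).mean())
        if mean_d2 == 0.0:
            raise KronfuseError(
                "all rows identical: mean pairwise distance is 0, supply a fixed gamma")
        gamma = 1.0 / mean_d2
    values = np.exp(-gamma * d2)
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(list(table.entity_ids), values, table.source_tag)


def abs_pearson_similarity(table: FeatureTable) -> SimilarityMatrix:
    """|Pearson correlation| between entity profiles over pairwise-complete
    features.  Zero-variance profiles and pairs with fewer than 2 overlapping
    features get similarity 0 (1 on the diagonal)."""
    x = table.values
    n = table.n_entities
    if x.shape[1] < 2:
        raise KronfuseError("abs_pearson_similarity needs at least 2 features")
    mask = ~np.isnan(x)
    values = np.zeros((n, n))
    if mask.all():
        xc = x - x.mean(axis=1, keepdims=True)
        norms = np.sqrt((xc * xc).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (xc @ xc.T) / np.outer(norms, norms)
        corr[~np.isfinite(corr)] = 0.0
        values = np.abs(corr)
    else:
        warned = False
        for i in range(n):
            for j in range(i + 1, n):
                common = mask[i] & mask[j]
                if common.sum() < 2:
                    if not warned:
                        warnings.warn("pair(s) with <2 overlapping features; similarity set to 0")
                        warned = True
                    continue
                xi, xj = x[i, common], x[j, common]
                xi = xi - xi.mean()
                xj = xj - xj.mean()
                denom = np.sqrt((xi @ xi) * (xj @ xj))
                if denom > 0:
                    values[i, j] = values[j, i] = abs(float(xi @ xj) / denom)
    np.fill_diagonal(values, 1.0)
    values = np.clip(values, 0.0, 1.0)
    return SimilarityMatrix(list(table.entity_ids), values, table.source_tag)


def combine_max(mats: list[SimilarityMatrix], source_tag: str = "combined") -> SimilarityMatrix:
    """Element-wise maximum over the sources available for both entities.

    Inputs must already share one id order (see ``align_entities`` union
    mode).  A pair with no shared available source gets 0 off-diagonal.
    """
    if not mats:
        raise KronfuseError("combine_max needs at least one matrix")
    ids = mats[0].entity_ids
    for m in mats[1:]:
        if m.entity_ids != ids:
            raise KronfuseError("combine_max inputs are not id-aligned")
    n = len(ids)
    out = np.zeros((n, n))
    any_shared = np.zeros((n, n), dtype=bool)
    avail = np.zeros(n, dtype=bool)
    for m in mats:
        a = np.asarray(m.available, dtype=bool)
        shared = np.outer(a, a)
        np.maximum(out, np.where(shared, m.values, 0.0), out=out)
        any_shared |= shared
        avail |= a
    out[~any_shared] = 0.0
    np.fill_diagonal(out, 1.0)
    if not any_shared[~np.eye(n, dtype=bool)].all():
        warnings.warn("some entity pairs share no available source; similarity set to 0")
    return SimilarityMatrix(list(ids), np.clip(out, 0.0, 1.0), source_tag, avail)
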