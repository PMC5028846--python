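"""Drug-side similarities: chemical descriptors, protein targets, ATC codes.

Chemical similarity reuses the Gaussian kernel on descriptor vectors.
Target similarity is the maximum normalized Smith-Waterman score across the
two drugs' target-protein sets.  ATC similarity scores the closest pair of
codes in the WHO hierarchy, discounted geometrically with tree distance and
weighted by the specificity (inverse corpus frequency) of the deepest shared
prefix, then normalized so self-similarity is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .containers import (
    ATC_LEVEL_LENGTHS,
    DrugAnnotation,
    FeatureTable,
    KronfuseError,
    SimilarityMatrix,
    check_sequence,
    parse_atc,
)
from .cellsim import GaussianConfig, gaussian_similarity


@dataclass
class AlignmentConfig:
    """Local-alignment scoring for target-protein similarity.

    Default BLOSUM62 with affine gaps 11/1 (the common modern choice); the
    ``matlab`` preset (BLOSUM50, linear gap 8) mimics older toolbox defaults.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise KronfuseError("require gap_open >= gap_extend > 0")

    @classmethod
    def matlab(cls) -> "AlignmentConfig":
        return cls(substitution_matrix="BLOSUM50", gap_open=8.0, gap_extend=8.0)


@dataclass
class AtcConfig:
    """ATC-code similarity parameters: per-edge decay rho (default 0.25)."""

    rho: float = 0.25
    weight_normalization: str = "max_one"

    def __post_init__(self) -> None:
        if not (0 < self.rho < 1):
            raise KronfuseError("rho must lie in (0, 1)")
        if self.weight_normalization != "max_one":
            raise KronfuseError("only max_one weight normalization is supported")


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman_score(a: str, b: str, config: AlignmentConfig | None = None) -> float:
    """Raw local-alignment (Smith-Waterman) score; 0 when no positive-scoring
    local alignment exists."""
    config = config or AlignmentConfig()
    a = check_sequence(a)
    b = check_sequence(b)
    aligner = _aligner(config.substitution_matrix, config.gap_open, config.gap_extend)
    return max(0.0, float(aligner.score(a, b)))


def normalized_sw(a: str, b: str, config: AlignmentConfig | None = None) -> float:
    """SW(a,b) / sqrt(SW(a,a) * SW(b,b)), clipped into [0, 1]."""
    config = config or AlignmentConfig()
    saa = smith_waterman_score(a, a, config)
    sbb = smith_waterman_score(b, b, config)
    if saa == 0.0 or sbb == 0.0:
        raise KronfuseError("zero self-alignment score; cannot normalize")
    sab = smith_waterman_score(a, b, config)
    return float(np.clip(sab / np.sqrt(saa * sbb), 0.0, 1.0))


def target_similarity(
    annotations: list[DrugAnnotation], config: AlignmentConfig | None = None
) -> SimilarityMatrix:
    """Max normalized SW score over the cross product of the two drugs'
    target sets.  Drugs sharing a target protein score 1; drugs with no
    targets score 0 with everything (flagged as unavailable)."""
    config = config or AlignmentConfig()
    ids = [a.drug_id for a in annotations]
    n = len(ids)
    avail = np.array([len(a.targets) > 0 for a in annotations])
    if not avail.any():
        raise KronfuseError("no drug has any target protein")
    # cache pairwise protein scores across drugs
    proteins: dict[str, str] = {}
    for a in annotations:
        for pid, seq in a.targets:
            proteins[pid] = seq
    pids = sorted(proteins)
    norm_cache: dict[tuple[str, str], float] = {}

    def _norm(p: str, q: str) -> float:
        key = (p, q) if p <= q else (q, p)
        if key not in norm_cache:
            norm_cache[key] = 1.0 if p == q else normalized_sw(proteins[p], proteins[q], config)
        return norm_cache[key]

    values = np.zeros((n, n))
    for i in range(n):
        ti = {pid for pid, _ in annotations[i].targets}
        for j in range(i, n):
            tj = {pid for pid, _ in annotations[j].targets}
            if not ti or not tj:
                continue
            if ti & tj:
                s = 1.0
            else:
                s = max(_norm(p, q) for p in ti for q in tj)
            values[i, j] = values[j, i] = s
    np.fill_diagonal(values, 1.0)
    if not avail.all():
        warnings.warn("drug(s) with no targets: similarity fixed to 0")
    _ = pids
    return SimilarityMatrix(ids, values, "target", avail)


def atc_tree_distance(t_i: str, t_j: str) -> int:
    """Shortest path length between two ATC codes in the classification tree.

    Codes whose anatomical (level-1) letters differ connect through a virtual
    root above level 1, adding 2 edges.
    """
    pi = parse_atc(t_i)
    pj = parse_atc(t_j)
    m = 0
    for a, b in zip(pi, pj):
        if a == b:
            m += 1
        else:
            break
    d = (len(pi) - m) + (len(pj) - m)
    if m == 0:
        d += 2
    return d


def atc_code_weights(all_codes: list[str]) -> dict[str, float]:
    """Inverse-frequency weights for every prefix observed in the corpus,
    normalized so the maximum weight is 1.

    freq(p) = (#codes carrying prefix p) / (#codes); rare, specific prefixes
    get the largest weights.
    """
    if not all_codes:
        raise KronfuseError("empty ATC corpus")
    n = len(all_codes)
    counts: dict[str, int] = {}
    for code in all_codes:
        for prefix in parse_atc(code):
            counts[prefix] = counts.get(prefix, 0) + 1
    raw = {p: n / c for p, c in counts.items()}
    top = max(raw.values())
    return {p: v / top for p, v in raw.items()}


def _code_pair_score(t_i: str, t_j: str, weights: dict[str, float], rho: float) -> float:
    """rho^distance, weighted by the specificity of the deepest shared prefix."""
    pi = parse_atc(t_i)
    pj = parse_atc(t_j)
    lca = None
    for a, b in zip(pi, pj):
        if a == b:
            lca = a
        else:
            break
    d = atc_tree_distance(t_i, t_j)
    if lca is None:
        w = min(weights.values())  # virtual root: least specific
    else:
        w = weights[lca]
    return (rho ** d) * w


def atc_similarity(
    annotations: list[DrugAnnotation], config: AtcConfig | None = None
) -> SimilarityMatrix:
    """Drug-level ATC similarity.

    The raw affinity R(d, d') is the best code-pair score over
    A(d) x A(d'); the final score is R(d, d') / sqrt(R(d, d) R(d', d')), so
    identical code sets score exactly 1.  Codeless drugs score 0 and are
    flagged unavailable.
    """
    config = config or AtcConfig()
    ids = [a.drug_id for a in annotations]
    n = len(ids)
    avail = np.array([len(a.atc_codes) > 0 for a in annotations])
    if not avail.any():
        raise KronfuseError("no drug has any ATC code")
    corpus = [code for a in annotations for code in sorted(a.atc_codes)]
    weights = atc_code_weights(corpus)

    def raw(ai: DrugAnnotation, aj: DrugAnnotation) -> float:
        return max(
            _code_pair_score(ti, tj, weights, config.rho)
            for ti in ai.atc_codes
            for tj in aj.atc_codes
        )

    self_raw = np.array([raw(a, a) if avail[k] else 1.0 for k, a in enumerate(annotations)])
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if avail[i] and avail[j]:
                values[i, j] = values[j, i] = raw(annotations[i], annotations[j]) / np.sqrt(
                    self_raw[i] * self_raw[j])
    np.fill_diagonal(values, 1.0)
    if not avail.all():
        warnings.warn("drug(s) with no ATC codes: similarity fixed to 0")
    return SimilarityMatrix(ids, np.clip(values, 0.0, 1.0), "atc", avail)


def chemical_similarity(
    table: FeatureTable, config: GaussianConfig | None = None
) -> SimilarityMatrix:
    """Gaussian kernel on molecular-descriptor vectors (features z-scored
    by default so heterogeneous descriptor scales contribute evenly)."""
    if table.source_tag != "descriptor":
        raise KronfuseError("chemical_similarity requires a descriptor table")
    sm = gaussian_similarity(table, config or GaussianConfig(standardize=True))
    sm.source_tag = "chemical"
    return sm


def annotations_descriptor_table(annotations: list[DrugAnnotation]) -> FeatureTable:
    """Collect per-drug descriptor vectors into a FeatureTable (drugs lacking
    descriptors are omitted)."""
    rows = [(a.drug_id, a.descriptors) for a in annotations if a.descriptors is not None]
    if not rows:
        raise KronfuseError("no drug has descriptors")
    width = len(rows[0][1])
    for d, v in rows:
        if len(v) != width:
            raise KronfuseError(f"descriptor length mismatch for drug {d!r}")
    values = np.vstack([v for _, v in rows])
    return FeatureTable([d for d, _ in rows], [f"desc{i}" for i in range(width)],
                        values, "descriptor")
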