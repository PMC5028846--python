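"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — explicit loops, textbook dynamic
programming — and shares no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import substitution_matrices


def cosine_weighted(z, zp, w):
    num = sum(wi * wi * a * b for wi, a, b in zip(w, z, zp))
    na = math.sqrt(sum((wi * a) ** 2 for wi, a in zip(w, z)))
    nb = math.sqrt(sum((wi * b) ** 2 for wi, b in zip(w, zp)))
    if na == 0 or nb == 0:
        return 0.0
    return num / (na * nb)


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    if vx == 0 or vy == 0:
        return 0.0
    return cov / math.sqrt(vx * vy)


def gaussian_matrix(x, gamma):
    n = len(x)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            d2 = sum((a - b) ** 2 for a, b in zip(x[i], x[j]))
            out[i, j] = math.exp(-gamma * d2)
    return out


def smith_waterman(a: str, b: str, matrix_name="BLOSUM62", gap_open=11.0, gap_extend=1.0):
    """Gotoh affine-gap local alignment, explicit O(nm) tables.

    ``gap_open`` is the cost of the first residue of a gap, ``gap_extend``
    of each further residue.
    """
    sub = substitution_matrices.load(matrix_name)
    n, m = len(a), len(b)
    neg = -1e18
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i][j] = s + max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def normalized_sw(a, b, **kw):
    saa = smith_waterman(a, a, **kw)
    sbb = smith_waterman(b, b, **kw)
    return smith_waterman(a, b, **kw) / math.sqrt(saa * sbb)


def atc_levels(code):
    cuts = [1, 3, 4, 5, 7]
    return [code[:c] for c in cuts if len(code) >= c]


def atc_distance(ti, tj):
    pi, pj = atc_levels(ti), atc_levels(tj)
    m = 0
    for x, y in zip(pi, pj):
        if x != y:
            break
        m += 1
    d = (len(pi) - m) + (len(pj) - m)
    return d + 2 if m == 0 else d


def atc_pair_score(ti, tj, weights, rho):
    pi, pj = atc_levels(ti), atc_levels(tj)
    lca = None
    for x, y in zip(pi, pj):
        if x != y:
            break
        lca = x
    w = weights[lca] if lca is not None else min(weights.values())
    return rho ** atc_distance(ti, tj) * w


def atc_drug_similarity(codes_a, codes_b, weights, rho):
    raw = lambda A, B: max(atc_pair_score(x, y, weights, rho) for x in A for y in B)
    return raw(codes_a, codes_b) / math.sqrt(raw(codes_a, codes_a) * raw(codes_b, codes_b))


def auc_concordance(scores, labels):
    """Mann-Whitney: fraction of (pos, neg) pairs ranked concordantly,
    ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l != 1]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                conc += 1
            elif p == q:
                conc += 0.5
    return conc / total


def average_precision(scores, labels):
    """Step-wise AP: sum over distinct descending thresholds of
    (delta recall) * precision, ties handled jointly."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    scores = [scores[i] for i in order]
    labels = [labels[i] for i in order]
    n_pos = sum(1 for l in labels if l == 1)
    ap = 0.0
    tp = fp = 0
    i = 0
    prev_recall = 0.0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        tp += sum(1 for k in range(i, j) if labels[k] == 1)
        fp += (j - i) - sum(1 for k in range(i, j) if labels[k] == 1)
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def kron_gram(s_cell, s_drug, cell_ids, drug_ids, pairs_a, pairs_b):
    """Explicit Kronecker product, then index the requested pair block."""
    full = np.kron(s_cell, s_drug)
    def pos(pair):
        c, d = pair
        return cell_ids.index(c) * len(drug_ids) + drug_ids.index(d)
    return np.array([[full[pos(p), pos(q)] for q in pairs_b] for p in pairs_a])
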