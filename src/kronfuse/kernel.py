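"""The Kronecker-product pairwise kernel over (cell, drug) pairs.

K((c, d), (c', d')) = S_cell(c, c') * S_drug(d, d'): two pairs are similar
only when the cells and the drugs are simultaneously similar.  The kernel
is kept factorized — Gram blocks are assembled on demand from the two
entity-level similarity matrices, never by materializing the full Kronecker
product.  Max-combined and |PCC| similarities need not be positive
semidefinite, so each factor can be repaired by eigenvalue clipping first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import KronfuseError, SimilarityMatrix

Pair = tuple[str, str]


def psd_clip(sm: SimilarityMatrix, tol: float = 1e-8) -> SimilarityMatrix:
    """Project a similarity matrix onto the PSD cone.

    Negative eigenvalues are zeroed and the matrix reconstructed; the
    diagonal is then rescaled back to 1 (correlation-style normalization) so
    the result is still a similarity matrix.  Idempotent up to ``tol``.
    """
    v = sm.values
    if not np.allclose(v, v.T, atol=1e-9, rtol=0):
        raise KronfuseError("psd_clip requires a symmetric matrix")
    evals, evecs = np.linalg.eigh(v)
    if evals.min() >= -tol:
        return sm
    evals = np.clip(evals, 0.0, None)
    rec = (evecs * evals) @ evecs.T
    d = np.sqrt(np.clip(np.diag(rec), tol, None))
    rec = rec / np.outer(d, d)
    rec = np.clip((rec + rec.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(rec, 1.0)
    return SimilarityMatrix(list(sm.entity_ids), rec, sm.source_tag,
                            np.asarray(sm.available).copy())


@dataclass
class PairKernel:
    """Factorized kernel over (cell, drug) pairs.

    ``psd_mode="clip"`` (the default) applies ``psd_clip`` to each factor
    once at construction, which keeps the pair Gram PSD (the Kronecker
    product of PSD factors is PSD) and the SVM solver stable.
    """

    s_cell: SimilarityMatrix
    s_drug: SimilarityMatrix
    psd_mode: str = "clip"
    _cell_pos: dict = field(init=False, repr=False)
    _drug_pos: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.psd_mode not in ("none", "clip"):
            raise KronfuseError(f"unknown psd mode {self.psd_mode!r}")
        if self.psd_mode == "clip":
            self.s_cell = psd_clip(self.s_cell)
            self.s_drug = psd_clip(self.s_drug)
        self._cell_pos = {c: i for i, c in enumerate(self.s_cell.entity_ids)}
        self._drug_pos = {d: i for i, d in enumerate(self.s_drug.entity_ids)}

    def _index(self, pair: Pair) -> tuple[int, int]:
        c, d = pair
        try:
            return self._cell_pos[c], self._drug_pos[d]
        except KeyError as e:
            raise KronfuseError(f"unknown id in pair {pair!r}") from e

    def kernel_value(self, p1: Pair, p2: Pair) -> float:
        i1, j1 = self._index(p1)
        i2, j2 = self._index(p2)
        return float(self.s_cell.values[i1, i2] * self.s_drug.values[j1, j2])

    def kernel_submatrix(self, pairs_a: list[Pair], pairs_b: list[Pair]) -> np.ndarray:
        """|A| x |B| Gram block, computed from the factors."""
        ia = np.array([self._index(p) for p in pairs_a], dtype=int).reshape(-1, 2)
        ib = np.array([self._index(p) for p in pairs_b], dtype=int).reshape(-1, 2)
        if ia.size == 0 or ib.size == 0:
            return np.zeros((len(pairs_a), len(pairs_b)))
        cell_block = self.s_cell.values[np.ix_(ia[:, 0], ib[:, 0])]
        drug_block = self.s_drug.values[np.ix_(ia[:, 1], ib[:, 1])]
        return cell_block * drug_block
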