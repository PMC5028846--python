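"""Class-weighted SVM on the precomputed pair kernel.

`PairSVM` is a model object in the statsmodels mould: constructed from a
:class:`~kronfuse.kernel.PairKernel` plus labeled (cell, drug) pairs,
``fit()`` selects the soft-margin penalty C by inner cross-validated AUC
(when a grid is given) and returns a :class:`PairSVMResults` carrying the
support pairs, dual coefficients, intercept, and a ``summary()`` table.

Class weighting follows the balanced rule weight(class) =
n_total / (2 * n_class), which compensates the roughly 3:1 excess of
resistant over sensitive associations seen in drug-response panels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import KronfuseError
from .kernel import Pair, PairKernel

LabeledPair = tuple[str, str, int]


@dataclass
class SvmConfig:
    C_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    inner_folds: int = 3
    class_weighting: str = "balanced"  # or "none"
    seed: int = 0
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if not self.C_grid:
            raise KronfuseError("C grid must be non-empty")
        if any(c <= 0 for c in self.C_grid):
            raise KronfuseError("C values must be positive")
        if self.class_weighting not in ("balanced", "none"):
            raise KronfuseError(f"unknown class weighting {self.class_weighting!r}")


def class_weights(labels: np.ndarray, scheme: str = "balanced") -> dict[int, float]:
    """weight(class) = n_total / (2 * n_class) under ``balanced``; all 1 otherwise."""
    labels = np.asarray(labels)
    out = {}
    for cls in (-1, 1):
        n_cls = int((labels == cls).sum())
        if n_cls == 0:
            raise KronfuseError("both classes must be present")
        out[cls] = labels.size / (2.0 * n_cls) if scheme == "balanced" else 1.0
    return out


def _fit_svc(gram: np.ndarray, y: np.ndarray, C: float, config: SvmConfig) -> SVC:
    weights = class_weights(y, config.class_weighting)
    svc = SVC(kernel="precomputed", C=C, class_weight=weights, tol=config.tol,
              cache_size=500, random_state=config.seed)
    svc.fit(gram, y)
    return svc


def select_C(pk: PairKernel, pairs: list[LabeledPair], config: SvmConfig):
    """Grid-search C by mean inner-fold AUC; ties break toward smaller C.

    Returns ``(best_C, table)`` where table maps C -> mean AUC.  A grid of
    one skips the search.
    """
    grid = sorted(config.C_grid)
    if len(grid) == 1:
        return grid[0], {grid[0]: float("nan")}
    plist = [(c, d) for c, d, _ in pairs]
    y = np.array([lab for _, _, lab in pairs])
    gram = pk.kernel_submatrix(plist, plist)
    cv = StratifiedKFold(n_splits=config.inner_folds, shuffle=True,
                         random_state=config.seed)
    table: dict[float, float] = {}
    for C in grid:
        aucs = []
        for tr, te in cv.split(gram, y):
            svc = _fit_svc(gram[np.ix_(tr, tr)], y[tr], C, config)
            scores = svc.decision_function(gram[np.ix_(te, tr)])
            aucs.append(roc_auc_score(y[te], scores))
        table[C] = float(np.mean(aucs))
    best = max(grid, key=lambda C: (table[C], -C))
    return best, table


@dataclass
class PairSVM:
    """SVM over (cell, drug) pairs with a precomputed Kronecker kernel."""

    kernel: PairKernel
    pairs: list[LabeledPair]
    config: SvmConfig = field(default_factory=SvmConfig)

    def __post_init__(self) -> None:
        labs = {lab for _, _, lab in self.pairs}
        if not {-1, 1} <= labs:
            raise KronfuseError("training pairs must contain both classes")
        if not labs <= {-1, 1}:
            raise KronfuseError("training labels must be +1/-1")

    @classmethod
    def from_matrices(cls, s_cell, s_drug, label_matrix, config=None, psd_mode="clip"):
        """Build from the two similarity factors and a LabelMatrix."""
        from .labels import list_pairs

        pk = PairKernel(s_cell, s_drug, psd_mode=psd_mode)
        return cls(pk, list_pairs(label_matrix, "labeled"), config or SvmConfig())

    def fit(self, C: float | None = None) -> "PairSVMResults":
        """Select C (unless given) and solve the weighted soft-margin SVM."""
        cfg = self.config
        if C is None:
            C, c_table = select_C(self.kernel, self.pairs, cfg)
        else:
            c_table = {C: float("nan")}
        plist = [(c, d) for c, d, _ in self.pairs]
        y = np.array([lab for _, _, lab in self.pairs])
        gram = self.kernel.kernel_submatrix(plist, plist)
        if not np.isfinite(gram).all():
            raise KronfuseError("non-finite kernel entries")
        svc = _fit_svc(gram, y, C, cfg)
        support = [plist[i] for i in svc.support_]
        return PairSVMResults(
            model=self,
            C=C,
            c_table=c_table,
            class_weights_=class_weights(y, cfg.class_weighting),
            support_pairs=support,
            dual_coef=np.asarray(svc.dual_coef_[0], dtype=float),
            intercept=float(svc.intercept_[0]),
        )


@dataclass
class PairSVMResults:
    """Fitted pair-SVM: everything needed to reproduce decision values."""

    model: PairSVM | None
    C: float
    c_table: dict[float, float]
    class_weights_: dict[int, float]
    support_pairs: list[Pair]
    dual_coef: np.ndarray
    intercept: float
    _kernel: PairKernel | None = None

    @property
    def kernel(self) -> PairKernel:
        if self._kernel is not None:
            return self._kernel
        if self.model is None:
            raise KronfuseError("results detached from a kernel; call attach_kernel")
        return self.model.kernel

    def attach_kernel(self, pk: PairKernel) -> None:
        self._kernel = pk

    def decision_scores(self, pairs: list[Pair]) -> np.ndarray:
        """Signed decision values f(p) = sum_i alpha_i K(p, sv_i) + b."""
        if not pairs:
            return np.zeros(0)
        block = self.kernel.kernel_submatrix(pairs, self.support_pairs)
        return block @ self.dual_coef + self.intercept

    def predict(self, pairs: list[Pair]) -> np.ndarray:
        return np.where(self.decision_scores(pairs) >= 0, 1, -1)

    def rank_unknown(self, unknown_pairs: list[Pair], top_k: int | None = None):
        """Rank unlabeled pairs by decision score, descending; ties break by
        (cell_id, drug_id).  Returns a list of ((cell, drug), score)."""
        scores = self.decision_scores(unknown_pairs)
        order = sorted(range(len(unknown_pairs)),
                       key=lambda i: (-scores[i], unknown_pairs[i]))
        if top_k is not None:
            order = order[: max(0, top_k)]
        return [(unknown_pairs[i], float(scores[i])) for i in order]

    def summary(self) -> str:
        lines = [
            "Pairwise-kernel SVM results",
            "=" * 42,
            f"training pairs      {len(self.model.pairs) if self.model else 'n/a'}",
            f"support pairs       {len(self.support_pairs)}",
            f"penalty C           {self.C:g}",
            f"class weights       -1: {self.class_weights_[-1]:.4g}, "
            f"+1: {self.class_weights_[1]:.4g}",
            f"intercept           {self.intercept:.6g}",
        ]
        if any(np.isfinite(v) for v in self.c_table.values()):
            lines.append("inner-CV AUC by C:")
            for C, auc in sorted(self.c_table.items()):
                lines.append(f"    C={C:<8g} AUC={auc:.4f}")
        return "\n".join(lines)

    # -- serialization (text JSON) -------------------------------------
    def save(self, path) -> None:
        payload = {
            "C": self.C,
            "c_table": {str(k): v for k, v in self.c_table.items()},
            "class_weights": {str(k): v for k, v in self.class_weights_.items()},
            "support_pairs": [list(p) for p in self.support_pairs],
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path, kernel: PairKernel) -> "PairSVMResults":
        with open(path) as fh:
            payload = json.load(fh)
        res = cls(
            model=None,
            C=float(payload["C"]),
            c_table={float(k): float(v) for k, v in payload["c_table"].items()},
            class_weights_={int(k): float(v) for k, v in payload["class_weights"].items()},
            support_pairs=[tuple(p) for p in payload["support_pairs"]],
            dual_coef=np.array(payload["dual_coef"], dtype=float),
            intercept=float(payload["intercept"]),
        )
        res.attach_kernel(kernel)
        return res
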