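"""Categorize continuous drug responses into sensitive / resistant / unknown.

For IC50 the defaults follow the bimodal shape of 8-point dose-response
summaries truncated to [0, 8]: values <= 0.5 are sensitive (+1), values
>= 7.5 resistant (-1), the band in between unknown (0).  For Amax and
ActArea no fixed cuts are published, so either explicit thresholds or
quantile cuts must be chosen; for ActArea larger values mean more sensitive,
so the direction flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import KronfuseError, LabelMatrix, ResponseMatrix


@dataclass
class CategorizationConfig:
    measure: str = "IC50"
    mode: str = "fixed_thresholds"
    sensitive_cut: float | None = None
    resistant_cut: float | None = None
    quantile_low: float = 0.25
    quantile_high: float = 0.75
    # True when larger values mean more sensitive (ActArea)
    larger_is_sensitive: bool | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_thresholds", "quantile"):
            raise KronfuseError(f"unknown categorization mode {self.mode!r}")
        if self.larger_is_sensitive is None:
            self.larger_is_sensitive = self.measure == "ActArea"
        if self.measure == "IC50" and self.mode == "fixed_thresholds":
            if self.sensitive_cut is None:
                self.sensitive_cut = 0.5
            if self.resistant_cut is None:
                self.resistant_cut = 7.5
        if self.mode == "fixed_thresholds":
            if self.sensitive_cut is None or self.resistant_cut is None:
                raise KronfuseError(
                    f"fixed thresholds for measure {self.measure!r} must be supplied")
            lo, hi = sorted((self.sensitive_cut, self.resistant_cut))
            if lo >= hi:
                raise KronfuseError("sensitive and resistant regions overlap")
        else:
            if not (0 < self.quantile_low < self.quantile_high < 1):
                raise KronfuseError("require 0 < quantile_low < quantile_high < 1")


def _fixed_cuts(config: CategorizationConfig) -> tuple[float, float]:
    s, r = config.sensitive_cut, config.resistant_cut
    if config.larger_is_sensitive and s < r:
        raise KronfuseError(
            "larger_is_sensitive requires sensitive_cut above resistant_cut")
    if not config.larger_is_sensitive and s > r:
        raise KronfuseError(
            "smaller-is-sensitive requires sensitive_cut below resistant_cut")
    return s, r


def categorize(responses: ResponseMatrix, config: CategorizationConfig | None = None) -> LabelMatrix:
    """Map a ResponseMatrix onto {+1, 0, -1}; measured-but-in-between pairs
    become unknown (0), unmeasured pairs stay missing."""
    config = config or CategorizationConfig()
    if config.measure != responses.measure:
        raise KronfuseError(
            f"config measure {config.measure!r} != matrix measure {responses.measure!r}")
    vals = responses.values
    missing = np.isnan(vals)
    if config.mode == "quantile":
        known = np.sort(vals[~missing])
        m = known.size
        if m == 0:
            raise KronfuseError("cannot take quantiles of an all-missing matrix")
        # symmetric nearest-rank cuts: the lower tail keeps ceil(q_low*m)
        # values, the upper tail keeps m - floor(q_high*m) values
        k_lo = int(np.ceil(config.quantile_low * m))
        k_hi = int(np.floor(config.quantile_high * m))
        if k_lo < 1 or k_hi >= m:
            raise KronfuseError("quantile cuts leave an empty tail")
        lo = float(known[k_lo - 1])
        hi = float(known[k_hi])
        if config.larger_is_sensitive:
            s_cut, r_cut = hi, lo
        else:
            s_cut, r_cut = lo, hi
    else:
        s_cut, r_cut = _fixed_cuts(config)
    labels = np.zeros(vals.shape, dtype=int)
    with np.errstate(invalid="ignore"):
        if config.larger_is_sensitive:
            labels[vals >= s_cut] = 1
            labels[vals <= r_cut] = -1
        else:
            labels[vals <= s_cut] = 1
            labels[vals >= r_cut] = -1
    labels[missing] = 0
    lm = LabelMatrix(list(responses.cell_ids), list(responses.drug_ids), labels, missing)
    if not (lm.labels != 0).any():
        warnings.warn("no pair was labeled sensitive or resistant")
    return lm


def label_counts(labels: LabelMatrix) -> dict[str, int]:
    """Tallies; n_sensitive + n_resistant + n_unknown + n_missing equals the
    number of matrix entries."""
    lab, miss = labels.labels, labels.missing
    return {
        "n_sensitive": int(((lab == 1) & ~miss).sum()),
        "n_resistant": int(((lab == -1) & ~miss).sum()),
        "n_unknown": int(((lab == 0) & ~miss).sum()),
        "n_missing": int(miss.sum()),
    }


def list_pairs(labels: LabelMatrix, which: str = "labeled") -> list[tuple[str, str, int]]:
    """Enumerate pairs in row-major (cell, then drug) order.

    ``labeled`` -> pairs with label +1/-1; ``unknown`` -> measured pairs with
    label 0.  Missing pairs appear in neither list.
    """
    if which not in ("labeled", "unknown"):
        raise KronfuseError(f"unknown selection {which!r}")
    out = []
    for i, c in enumerate(labels.cell_ids):
        for j, d in enumerate(labels.drug_ids):
            if labels.missing[i, j]:
                continue
            lab = int(labels.labels[i, j])
            if which == "labeled" and lab != 0:
                out.append((c, d, lab))
            elif which == "unknown" and lab == 0:
                out.append((c, d, 0))
    return out
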