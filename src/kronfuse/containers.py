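"""Core in-memory containers shared by every stage of the pipeline.

All containers are thin wrappers around numpy arrays plus ordered id lists.
Entity order is always explicit; alignment across heterogeneous sources is
done by :func:`kronfuse.io.align_entities`, never implicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

SOURCE_TAGS = ("mutation", "copy_number", "expression", "descriptor")
MEASURES = ("IC50", "Amax", "ActArea")

# 5-level ATC pattern; prefixes at levels 1..5 are all accepted.
_ATC_LEVEL_RE = (
    re.compile(r"^[A-Z]$"),
    re.compile(r"^[A-Z]\d{2}$"),
    re.compile(r"^[A-Z]\d{2}[A-Z]$"),
    re.compile(r"^[A-Z]\d{2}[A-Z]{2}$"),
    re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$"),
)
# prefix lengths of levels 1..5
ATC_LEVEL_LENGTHS = (1, 3, 4, 5, 7)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class KronfuseError(ValueError):
    """Base class for input-contract violations."""


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise KronfuseError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class FeatureTable:
    """Entities x features numeric matrix with a source tag.

    ``values`` is float64 with NaN for missing entries.  Mutation tables must
    be strictly binary (0/1, no missing).
    """

    entity_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    source_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise KronfuseError("feature table values must be 2-D")
        if self.values.shape != (len(self.entity_ids), len(self.feature_ids)):
            raise KronfuseError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.entity_ids)} entities x {len(self.feature_ids)} features"
            )
        if self.source_tag not in SOURCE_TAGS:
            raise KronfuseError(f"unknown source tag {self.source_tag!r}")
        _check_unique(self.entity_ids, "entity")
        if self.source_tag == "mutation":
            vals = self.values
            if np.isnan(vals).any() or not np.isin(vals, (0.0, 1.0)).all():
                bad = vals[~np.isin(vals, (0.0, 1.0))]
                raise KronfuseError(
                    f"mutation table must be binary; found value {bad.flat[0]!r}"
                )

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    def reindex(self, ids: list[str]) -> "FeatureTable":
        """Return a copy over ``ids``; entities absent from the table get NaN
        rows (all-zero for mutation tables)."""
        pos = {e: i for i, e in enumerate(self.entity_ids)}
        fill = 0.0 if self.source_tag == "mutation" else np.nan
        out = np.full((len(ids), len(self.feature_ids)), fill)
        for r, e in enumerate(ids):
            if e in pos:
                out[r] = self.values[pos[e]]
        return FeatureTable(list(ids), list(self.feature_ids), out, self.source_tag)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over one entity set, values in [0, 1].

    ``available`` flags entities actually observed in the underlying source;
    rows/columns of unavailable entities carry 0 off-diagonal and 1 on the
    diagonal and are ignored by max-combination.
    """

    entity_ids: list[str]
    values: np.ndarray
    source_tag: str = "similarity"
    available: np.ndarray | None = None

    SYM_TOL = 1e-9

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise KronfuseError("similarity matrix must be square over entity_ids")
        _check_unique(self.entity_ids, "entity")
        if self.available is None:
            self.available = np.ones(n, dtype=bool)
        else:
            self.available = np.asarray(self.available, dtype=bool)
            if self.available.shape != (n,):
                raise KronfuseError("availability mask length mismatch")
        self.validate()

    def validate(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=self.SYM_TOL, rtol=0):
            raise KronfuseError("similarity matrix is not symmetric")
        if (v < -self.SYM_TOL).any() or (v > 1 + 1e-9 + self.SYM_TOL).any():
            raise KronfuseError("similarity values outside [0, 1]")
        diag = np.diag(v)[self.available]
        if diag.size and not np.allclose(diag, 1.0, atol=1e-9):
            raise KronfuseError("diagonal must be 1 for available entities")

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    def loc(self, a: str, b: str) -> float:
        pos = {e: i for i, e in enumerate(self.entity_ids)}
        return float(self.values[pos[a], pos[b]])

    def reindex(self, ids: list[str]) -> "SimilarityMatrix":
        pos = {e: i for i, e in enumerate(self.entity_ids)}
        n = len(ids)
        out = np.zeros((n, n))
        avail = np.zeros(n, dtype=bool)
        for r, e in enumerate(ids):
            out[r, r] = 1.0
            if e in pos:
                avail[r] = bool(self.available[pos[e]])
        for r, e in enumerate(ids):
            if e not in pos:
                continue
            for c, f in enumerate(ids):
                if f in pos:
                    out[r, c] = self.values[pos[e], pos[f]]
        return SimilarityMatrix(list(ids), out, self.source_tag, avail)


def parse_atc(code: str) -> list[str]:
    """Split an ATC code (possibly a prefix) into its level prefixes.

    ``"L01XE08" -> ["L", "L01", "L01X", "L01XE", "L01XE08"]``.
    """
    code = code.strip().upper()
    for lvl, (length, pat) in enumerate(zip(ATC_LEVEL_LENGTHS, _ATC_LEVEL_RE)):
        if len(code) == length:
            if not pat.match(code):
                raise KronfuseError(f"malformed ATC code {code!r}")
            return [code[:l] for l in ATC_LEVEL_LENGTHS[: lvl + 1]]
    raise KronfuseError(f"malformed ATC code {code!r}")


def check_sequence(seq: str, pid: str = "?") -> str:
    seq = seq.strip().upper()
    if not seq:
        raise KronfuseError(f"empty sequence for protein {pid!r}")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise KronfuseError(
            f"invalid residue(s) {sorted(bad)} in sequence for protein {pid!r}"
        )
    return seq


@dataclass
class DrugAnnotation:
    """Per-drug side information: descriptors, protein targets, ATC codes."""

    drug_id: str
    descriptors: np.ndarray | None = None
    targets: set[tuple[str, str]] = field(default_factory=set)
    atc_codes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for code in self.atc_codes:
            parse_atc(code)
        self.targets = {(pid, check_sequence(seq, pid)) for pid, seq in self.targets}


@dataclass
class ResponseMatrix:
    """Cells x drugs continuous response values; NaN marks unmeasured pairs."""

    cell_ids: list[str]
    drug_ids: list[str]
    values: np.ndarray
    measure: str = "IC50"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.drug_ids)):
            raise KronfuseError("response matrix shape inconsistent with id lists")
        if self.measure not in MEASURES:
            raise KronfuseError(f"unknown measure {self.measure!r}")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.drug_ids, "drug")


@dataclass
class LabelMatrix:
    """Cells x drugs relationship matrix over {+1, 0, -1}.

    +1 sensitive, -1 resistant, 0 unknown (measured but between thresholds).
    ``missing`` marks pairs with no measurement at all — distinct from 0.
    """

    cell_ids: list[str]
    drug_ids: list[str]
    labels: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.missing = np.asarray(self.missing, dtype=bool)
        shape = (len(self.cell_ids), len(self.drug_ids))
        if self.labels.shape != shape or self.missing.shape != shape:
            raise KronfuseError("label matrix shape inconsistent with id lists")
        if not np.isin(self.labels, (-1, 0, 1)).all():
            raise KronfuseError("labels must be in {+1, 0, -1}")
        if (self.labels[self.missing] != 0).any():
            raise KronfuseError("missing entries cannot carry a label")
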