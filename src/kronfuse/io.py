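"""Readers, writers and entity alignment for the delimited-text inputs.

Conventions: tab-separated UTF-8 with one header row of ids and one id
column; comma-separated files are accepted by sniffing the delimiter.
Missing values are the empty cell or the literal ``NA``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import (
    DrugAnnotation,
    FeatureTable,
    KronfuseError,
    LabelMatrix,
    ResponseMatrix,
    SimilarityMatrix,
    check_sequence,
    parse_atc,
)

_NA_VALUES = ["", "NA", "NaN", "nan"]


def _sniff_sep(path) -> str:
    with open(path, newline="") as fh:
        sample = fh.readline()
    if not sample.strip():
        raise KronfuseError(f"empty table: {path}")
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=_sniff_sep(path),
        index_col=0,
        na_values=_NA_VALUES,
        keep_default_na=False,
    )
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise KronfuseError(f"empty table: {path}")
    return df


def read_feature_matrix(path, source_tag: str, orientation: str = "entities_in_rows") -> FeatureTable:
    """Parse a delimited matrix into a :class:`FeatureTable`.

    ``orientation`` says whether entities (cells or drugs) are the rows or the
    columns of the file; the result is always entities-in-rows.  Non-numeric
    cells become missing values.
    """
    if orientation not in ("entities_in_rows", "entities_in_columns"):
        raise KronfuseError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    if orientation == "entities_in_columns":
        df = df.T
    entity_ids = [str(e) for e in df.index]
    dupes = pd.Index(entity_ids).duplicated()
    if dupes.any():
        raise KronfuseError(f"duplicate entity id: {entity_ids[int(np.argmax(dupes))]!r}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return FeatureTable(entity_ids, [str(f) for f in df.columns], values, source_tag)


def write_feature_matrix(table: FeatureTable, path) -> None:
    df = pd.DataFrame(table.values, index=table.entity_ids, columns=table.feature_ids)
    df.to_csv(path, sep="\t", na_rep="NA")


def read_mutation_calls(path, cell_universe: list[str], strict: bool = False) -> FeatureTable:
    """Build the binary gene-by-cell presence matrix.

    Accepts either an already-binary matrix (cells in rows) or a call list:
    a MAF file (``Hugo_Symbol``/``Tumor_Sample_Barcode`` columns) or a plain
    two-column (gene, cell) table.  Cells with no calls get all-zero rows.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False, comment="#")
    cols = list(df.columns)
    if "Hugo_Symbol" in cols and "Tumor_Sample_Barcode" in cols:
        calls = df[["Hugo_Symbol", "Tumor_Sample_Barcode"]]
    elif len(cols) == 2:
        # headerless (gene, cell) pair list
        calls = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#",
                            na_values=_NA_VALUES, keep_default_na=False)
    else:
        # matrix form: first column is the cell id
        table = read_feature_matrix(path, "copy_number")  # parse numerically first
        if not np.isin(table.values[~np.isnan(table.values)], (0.0, 1.0)).all():
            bad = table.values[~np.isin(table.values, (0.0, 1.0))]
            raise KronfuseError(f"mutation matrix is not binary (found {bad.flat[0]})")
        t = FeatureTable(table.entity_ids, table.feature_ids,
                         np.nan_to_num(table.values), "mutation")
        return t.reindex(sorted(cell_universe))

    universe = sorted(set(cell_universe))
    uni_pos = {c: i for i, c in enumerate(universe)}
    pairs = []
    dropped = set()
    for gene, cell in calls.itertuples(index=False):
        gene, cell = str(gene), str(cell)
        if cell not in uni_pos:
            if strict:
                raise KronfuseError(f"cell {cell!r} in call list absent from cell universe")
            dropped.add(cell)
            continue
        pairs.append((gene, cell))
    if dropped:
        warnings.warn(f"dropped calls for {len(dropped)} cell(s) outside the universe")
    genes = sorted({g for g, _ in pairs})
    values = np.zeros((len(universe), len(genes)))
    gene_pos = {g: j for j, g in enumerate(genes)}
    for gene, cell in pairs:
        values[uni_pos[cell], gene_pos[gene]] = 1.0
    if not genes:
        warnings.warn("mutation call list is empty; returning all-zero table")
    return FeatureTable(universe, genes, values, "mutation")


def _read_pair_file(path) -> list[tuple[str, str]]:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#",
                     na_values=_NA_VALUES, keep_default_na=False)
    if df.shape[1] < 2:
        raise KronfuseError(f"expected a two-column file: {path}")
    return [(str(a), str(b)) for a, b in df.iloc[:, :2].itertuples(index=False)]


def read_drug_annotations(
    descriptor_path=None, target_map_path=None, fasta_path=None, atc_path=None
) -> list[DrugAnnotation]:
    """Assemble one :class:`DrugAnnotation` per drug seen in any input file.

    Missing components (no descriptors, no targets, no codes) are recorded as
    absent, not an error; a target map naming a protein with no FASTA record
    is an error.
    """
    descriptors: dict[str, np.ndarray] = {}
    if descriptor_path is not None:
        table = read_feature_matrix(descriptor_path, "descriptor")
        for i, d in enumerate(table.entity_ids):
            descriptors[d] = table.values[i]

    targets: dict[str, set[tuple[str, str]]] = {}
    if target_map_path is not None:
        seqs: dict[str, str] = {}
        if fasta_path is not None:
            for rec in SeqIO.parse(str(fasta_path), "fasta"):
                seqs[rec.id] = check_sequence(str(rec.seq), rec.id)
        for drug, prot in _read_pair_file(target_map_path):
            if prot not in seqs:
                raise KronfuseError(f"protein {prot!r} in target map has no FASTA record")
            targets.setdefault(drug, set()).add((prot, seqs[prot]))

    atc: dict[str, set[str]] = {}
    if atc_path is not None:
        for drug, code in _read_pair_file(atc_path):
            parse_atc(code)
            atc.setdefault(drug, set()).add(code)

    drug_ids = sorted(set(descriptors) | set(targets) | set(atc))
    return [
        DrugAnnotation(
            d,
            descriptors=descriptors.get(d),
            targets=targets.get(d, set()),
            atc_codes=atc.get(d, set()),
        )
        for d in drug_ids
    ]


def read_response_matrix(path, measure: str = "IC50") -> ResponseMatrix:
    df = _read_table(path)
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return ResponseMatrix([str(c) for c in df.index], [str(d) for d in df.columns],
                          values, measure)


def write_response_matrix(rm: ResponseMatrix, path) -> None:
    pd.DataFrame(rm.values, index=rm.cell_ids, columns=rm.drug_ids).to_csv(
        path, sep="\t", na_rep="NA")


def read_similarity_matrix(path, source_tag: str = "similarity") -> SimilarityMatrix:
    df = _read_table(path)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise KronfuseError("similarity matrix row and column ids differ")
    return SimilarityMatrix(ids, df.to_numpy(dtype=float), source_tag)


def write_similarity_matrix(sm: SimilarityMatrix, path) -> None:
    pd.DataFrame(sm.values, index=sm.entity_ids, columns=sm.entity_ids).to_csv(
        path, sep="\t")


def read_label_matrix(path) -> LabelMatrix:
    df = _read_table(path)
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    missing = np.isnan(vals)
    labels = np.nan_to_num(vals).astype(int)
    return LabelMatrix([str(c) for c in df.index], [str(d) for d in df.columns],
                       labels, missing)


def write_label_matrix(lm: LabelMatrix, path) -> None:
    vals = lm.labels.astype(float)
    vals[lm.missing] = np.nan
    pd.DataFrame(vals, index=lm.cell_ids, columns=lm.drug_ids).to_csv(
        path, sep="\t", na_rep="NA", float_format="%.0f")


def read_cell_metadata(path) -> dict[str, str]:
    """Two-column (cell_id, tissue) file -> mapping."""
    return dict(_read_pair_file(path))


@dataclass
class AlignmentReport:
    ids: list[str]
    availability: np.ndarray  # tables x entities boolean

    @property
    def fully_covered(self) -> np.ndarray:
        return self.availability.all(axis=0)


def align_entities(tables: list, mode: str = "intersection"):
    """Reindex FeatureTables / SimilarityMatrices onto one sorted id list.

    ``intersection`` keeps ids present in every input (error if empty);
    ``union`` keeps all ids and records per-table availability, which
    max-combination consumes downstream.  Returns ``(aligned, report)``.
    """
    if not tables:
        raise KronfuseError("align_entities needs at least one input")
    if mode not in ("intersection", "union"):
        raise KronfuseError(f"unknown mode {mode!r}")
    id_sets = [set(t.entity_ids) for t in tables]
    if mode == "intersection":
        common = set.intersection(*id_sets)
        if not common:
            raise KronfuseError("no entities shared by all inputs (empty intersection)")
        ids = sorted(common)
    else:
        ids = sorted(set.union(*id_sets))
    availability = np.array([[i in s for i in ids] for s in id_sets], dtype=bool)
    aligned = [t.reindex(ids) for t in tables]
    return aligned, AlignmentReport(ids, availability)
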