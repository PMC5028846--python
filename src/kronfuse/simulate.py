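"""Synthetic pharmacogenomic bundle with planted cluster structure.

The generator emulates the shape of a cell-line drug-screening release:
cells fall into latent clusters visible, noisily, in each genomic source
(binary oncogene mutations, gene-level copy number, expression); drugs fall
into clusters visible in molecular descriptors, target-protein sequences
(within-cluster sequences descend from one ancestor), and ATC codes (one
level-4 prefix per cluster).  Sensitivity is block-structured: the
probability that a (cell, drug) pair is sensitive depends only on the two
cluster memberships, by default an anti-diagonal block matrix so neither
side alone separates the classes — fusing both sides must genuinely help.
IC50-like responses place sensitive pairs near 0.2 and resistant pairs near
7.8 on the truncated [0, 8] scale, with a configurable fraction pushed into
the uncertain middle band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import DrugAnnotation, FeatureTable, KronfuseError, ResponseMatrix
from . import io as kio

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_TISSUES = ("LUNG", "HAEMATOPOIETIC_AND_LYMPHOID_TISSUE", "SKIN",
            "BREAST", "PANCREAS", "ENDOMETRIUM")


def _anti_diagonal(n_cell: int, n_drug: int, hi: float = 0.9, lo: float = 0.1) -> np.ndarray:
    p = np.full((n_cell, n_drug), lo)
    for i in range(n_cell):
        p[i, (n_drug - 1 - i) % n_drug] = hi
    return p


@dataclass
class GeneratorConfig:
    n_cells: int = 120
    n_drugs: int = 20
    n_cell_clusters: int = 4
    n_drug_clusters: int = 4
    n_mut_genes: int = 25
    n_cn_genes: int = 200
    n_expr_genes: int = 300
    n_descriptors: int = 50
    block_sensitive_prob: np.ndarray | None = None
    feature_noise_sd: float = 1.0
    response_noise_sd: float = 0.15
    frac_unknown: float = 0.2
    frac_missing_response: float = 0.0
    frac_missing_source: dict = field(default_factory=dict)  # per-source cell dropout
    # per-source signal scale; set to 0 to make a source uninformative
    source_signal: dict = field(default_factory=dict)
    protein_length: int = 300
    protein_mut_rate: float = 0.05
    n_tissues: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_sensitive_prob is None:
            self.block_sensitive_prob = _anti_diagonal(
                self.n_cell_clusters, self.n_drug_clusters)
        self.block_sensitive_prob = np.asarray(self.block_sensitive_prob, dtype=float)
        if self.block_sensitive_prob.shape != (self.n_cell_clusters, self.n_drug_clusters):
            raise KronfuseError("block_sensitive_prob shape must be clusters x clusters")
        if ((self.block_sensitive_prob < 0) | (self.block_sensitive_prob > 1)).any():
            raise KronfuseError("block probabilities must lie in [0, 1]")
        if self.n_cells < self.n_cell_clusters or self.n_drugs < self.n_drug_clusters:
            raise KronfuseError("need at least one entity per cluster")
        if not (0 <= self.frac_unknown < 1):
            raise KronfuseError("frac_unknown must lie in [0, 1)")

    def signal(self, source: str) -> float:
        return float(self.source_signal.get(source, 1.0))


@dataclass
class SyntheticBundle:
    mutation: FeatureTable
    copy_number: FeatureTable
    expression: FeatureTable
    descriptors: FeatureTable
    annotations: list[DrugAnnotation]
    tissue_of_cell: dict[str, str]
    responses: ResponseMatrix
    cell_cluster: dict[str, int]
    drug_cluster: dict[str, int]
    config: GeneratorConfig


def _assign_clusters(n: int, k: int) -> np.ndarray:
    """Contiguous blocks of floor(n/k), remainder to the last cluster."""
    base = n // k
    out = np.repeat(np.arange(k), base)
    return np.concatenate([out, np.full(n - out.size, k - 1)])


def generate(config: GeneratorConfig | None = None) -> SyntheticBundle:
    """Draw one complete input bundle from a single seeded generator.

    Child generators are derived per component, so e.g. changing the number
    of drugs leaves the cell-side draw untouched.
    """
    cfg = config or GeneratorConfig()
    root = np.random.SeedSequence(cfg.seed)
    seeds = {name: np.random.default_rng(s) for name, s in zip(
        ("cells", "mut", "cn", "expr", "drugs", "desc", "prot", "resp", "tissue"),
        root.spawn(9))}

    cell_ids = [f"CELL{i:03d}" for i in range(cfg.n_cells)]
    drug_ids = [f"DRUG{j:02d}" for j in range(cfg.n_drugs)]
    cell_cluster = _assign_clusters(cfg.n_cells, cfg.n_cell_clusters)
    drug_cluster = _assign_clusters(cfg.n_drugs, cfg.n_drug_clusters)

    # --- mutation: cluster-specific signature genes, Bernoulli flips -----
    rng = seeds["mut"]
    sig_strength = cfg.signal("mutation")
    p_on = 0.5 + 0.4 * sig_strength  # within-signature mutation probability
    p_bg = 0.05
    sig_genes = np.array_split(np.arange(cfg.n_mut_genes), cfg.n_cell_clusters)
    mut = (rng.random((cfg.n_cells, cfg.n_mut_genes)) < p_bg).astype(float)
    for k, genes in enumerate(sig_genes):
        rows = cell_cluster == k
        mut[np.ix_(rows, genes)] = (
            rng.random((rows.sum(), genes.size)) < p_on).astype(float)
    mutation = FeatureTable(cell_ids, [f"GENE{g:03d}" for g in range(cfg.n_mut_genes)],
                            mut, "mutation")

    # --- continuous genomic views: cluster means + Gaussian noise --------
    def _gaussian_view(rng, n_feat, clusters, n_clusters, signal):
        means = rng.normal(0.0, 1.0, size=(n_clusters, n_feat)) * signal
        x = means[clusters] + rng.normal(0.0, cfg.feature_noise_sd, size=(len(clusters), n_feat))
        return x

    cn = _gaussian_view(seeds["cn"], cfg.n_cn_genes, cell_cluster,
                        cfg.n_cell_clusters, cfg.signal("copy_number"))
    copy_number = FeatureTable(cell_ids, [f"GENE{g:04d}" for g in range(cfg.n_cn_genes)],
                               cn, "copy_number")
    expr = _gaussian_view(seeds["expr"], cfg.n_expr_genes, cell_cluster,
                          cfg.n_cell_clusters, cfg.signal("expression"))
    expression = FeatureTable(cell_ids, [f"PROBE{g:04d}" for g in range(cfg.n_expr_genes)],
                              expr, "expression")
    desc = _gaussian_view(seeds["desc"], cfg.n_descriptors, drug_cluster,
                          cfg.n_drug_clusters, cfg.signal("descriptor"))
    descriptors = FeatureTable(drug_ids, [f"DESC{g:03d}" for g in range(cfg.n_descriptors)],
                               desc, "descriptor")

    # --- target proteins: one ancestor per drug cluster, 5% point mutations
    rng = seeds["prot"]
    ancestors = ["".join(rng.choice(_AA, size=cfg.protein_length))
                 for _ in range(cfg.n_drug_clusters)]
    annotations = []
    atc_letters = "LNCAJ"
    for j, d in enumerate(drug_ids):
        k = drug_cluster[j]
        seq = np.array(list(ancestors[k]))
        flips = rng.random(cfg.protein_length) < cfg.protein_mut_rate
        seq[flips] = rng.choice(_AA, size=int(flips.sum()))
        # one level-4 ATC prefix per drug cluster; distinct level-5 leaves
        prefix = f"{atc_letters[k % len(atc_letters)]}{k + 1:02d}X{'ABCDE'[k % 5]}"
        code = f"{prefix}{j + 1:02d}"
        annotations.append(DrugAnnotation(
            d,
            descriptors=desc[j],
            targets={(f"PROT_{d}", "".join(seq))},
            atc_codes={code},
        ))

    # --- tissues: random assignment, independent of clusters -------------
    rng = seeds["tissue"]
    tissues = list(_TISSUES[: cfg.n_tissues])
    tissue_of_cell = {c: tissues[rng.integers(len(tissues))] for c in cell_ids}

    # --- responses: block-structured IC50-like values ---------------------
    rng = seeds["resp"]
    p_sens = cfg.block_sensitive_prob[np.ix_(cell_cluster, drug_cluster)]
    sensitive = rng.random((cfg.n_cells, cfg.n_drugs)) < p_sens
    values = np.where(sensitive,
                      rng.normal(0.2, cfg.response_noise_sd, sensitive.shape),
                      rng.normal(7.8, cfg.response_noise_sd, sensitive.shape))
    values = np.clip(values, 0.0, 8.0)
    # shift a fraction into the unknown middle band
    unk = rng.random(values.shape) < cfg.frac_unknown
    values[unk] = rng.uniform(1.5, 6.5, size=int(unk.sum()))
    if cfg.frac_missing_response > 0:
        miss = rng.random(values.shape) < cfg.frac_missing_response
        values[miss] = np.nan
    responses = ResponseMatrix(cell_ids, drug_ids, values, "IC50")

    # --- per-source cell dropout ------------------------------------------
    rng = seeds["cells"]
    def _drop(table: FeatureTable, source: str) -> FeatureTable:
        frac = float(cfg.frac_missing_source.get(source, 0.0))
        if frac <= 0:
            return table
        keep = rng.random(table.n_entities) >= frac
        if not keep.any():
            raise KronfuseError(f"all cells dropped from source {source!r}")
        return FeatureTable([e for e, k in zip(table.entity_ids, keep) if k],
                            table.feature_ids, table.values[keep], table.source_tag)

    mutation = _drop(mutation, "mutation")
    copy_number = _drop(copy_number, "copy_number")
    expression = _drop(expression, "expression")

    return SyntheticBundle(
        mutation=mutation,
        copy_number=copy_number,
        expression=expression,
        descriptors=descriptors,
        annotations=annotations,
        tissue_of_cell=tissue_of_cell,
        responses=responses,
        cell_cluster={c: int(k) for c, k in zip(cell_ids, cell_cluster)},
        drug_cluster={d: int(k) for d, k in zip(drug_ids, drug_cluster)},
        config=cfg,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write the bundle in exactly the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutation": outdir / "mutation.tsv",
        "copy_number": outdir / "copy_number.tsv",
        "expression": outdir / "expression.tsv",
        "descriptors": outdir / "descriptors.tsv",
        "targets_map": outdir / "drug_targets.tsv",
        "targets_fasta": outdir / "targets.fasta",
        "atc": outdir / "drug_atc.tsv",
        "tissue": outdir / "cell_tissue.tsv",
        "responses": outdir / "responses.tsv",
        "clusters": outdir / "true_clusters.tsv",
    }
    kio.write_feature_matrix(bundle.mutation, paths["mutation"])
    kio.write_feature_matrix(bundle.copy_number, paths["copy_number"])
    kio.write_feature_matrix(bundle.expression, paths["expression"])
    kio.write_feature_matrix(bundle.descriptors, paths["descriptors"])
    kio.write_response_matrix(bundle.responses, paths["responses"])
    with open(paths["targets_map"], "w") as fh_map, open(paths["targets_fasta"], "w") as fh_fa:
        for a in bundle.annotations:
            for pid, seq in sorted(a.targets):
                fh_map.write(f"{a.drug_id}\t{pid}\n")
                fh_fa.write(f">{pid}\n{seq}\n")
    with open(paths["atc"], "w") as fh:
        for a in bundle.annotations:
            for code in sorted(a.atc_codes):
                fh.write(f"{a.drug_id}\t{code}\n")
    with open(paths["tissue"], "w") as fh:
        for c, t in bundle.tissue_of_cell.items():
            fh.write(f"{c}\t{t}\n")
    with open(paths["clusters"], "w") as fh:
        for c, k in bundle.cell_cluster.items():
            fh.write(f"cell\t{c}\t{k}\n")
        for d, k in bundle.drug_cluster.items():
            fh.write(f"drug\t{d}\t{k}\n")
    return paths
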