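"""High-level assembly: from raw tables to aligned similarity factors.

These helpers glue the per-source similarity constructions to entity
alignment and max-combination, producing the ``{source name: matrix}``
dictionaries the evaluation and CLI layers consume.  Cell-side sources are
named ``Mut``, ``CN``, ``GE`` and their fusion ``Comb_c``; drug-side sources
``Chem``, ``Target``, ``ATC`` and ``Comb_d``.
"""

from __future__ import annotations

import numpy as np

from .cellsim import (
    GaussianConfig,
    MutationWeightConfig,
    abs_pearson_similarity,
    combine_max,
    gaussian_similarity,
    mutation_similarity,
)
from .containers import DrugAnnotation, FeatureTable, KronfuseError, SimilarityMatrix
from .drugsim import (
    AlignmentConfig,
    AtcConfig,
    atc_similarity,
    chemical_similarity,
    target_similarity,
)
from .io import align_entities
from .labels import CategorizationConfig, categorize

CELL_SOURCES = ("Mut", "CN", "GE")
DRUG_SOURCES = ("Chem", "Target", "ATC")


def cell_similarities(
    mutation: FeatureTable | None = None,
    copy_number: FeatureTable | None = None,
    expression: FeatureTable | None = None,
    cell_ids: list[str] | None = None,
    mutation_config: MutationWeightConfig | None = None,
    gaussian_config: GaussianConfig | None = None,
) -> dict[str, SimilarityMatrix]:
    """Build S_Mut / S_CN / S_GE plus their max-combination ``Comb_c``.

    Sources may cover different cell sets; matrices are aligned onto the
    union (or onto ``cell_ids`` when given) with per-cell availability
    tracked, exactly what max-combination expects.
    """
    mats: dict[str, SimilarityMatrix] = {}
    if mutation is not None:
        mats["Mut"] = mutation_similarity(mutation, mutation_config)
    if copy_number is not None:
        mats["CN"] = gaussian_similarity(copy_number, gaussian_config)
    if expression is not None:
        mats["GE"] = abs_pearson_similarity(expression)
    if not mats:
        raise KronfuseError("at least one cell-side source is required")
    names = list(mats)
    aligned, report = align_entities(list(mats.values()), mode="union")
    if cell_ids is not None:
        aligned = [m.reindex(sorted(cell_ids)) for m in aligned]
    mats = dict(zip(names, aligned))
    mats["Comb_c"] = combine_max(list(mats.values()), "comb_c")
    _ = report
    return mats


def drug_similarities(
    annotations: list[DrugAnnotation],
    gaussian_config: GaussianConfig | None = None,
    alignment_config: AlignmentConfig | None = None,
    atc_config: AtcConfig | None = None,
) -> dict[str, SimilarityMatrix]:
    """Build S_Chem / S_Target / S_ATC plus ``Comb_d`` over one drug order."""
    from .drugsim import annotations_descriptor_table

    drug_ids = sorted(a.drug_id for a in annotations)
    order = {d: i for i, d in enumerate(drug_ids)}
    annotations = sorted(annotations, key=lambda a: order[a.drug_id])
    mats: dict[str, SimilarityMatrix] = {}
    if any(a.descriptors is not None for a in annotations):
        table = annotations_descriptor_table(annotations)
        mats["Chem"] = chemical_similarity(table, gaussian_config).reindex(drug_ids)
    if any(a.targets for a in annotations):
        mats["Target"] = target_similarity(annotations, alignment_config)
    if any(a.atc_codes for a in annotations):
        mats["ATC"] = atc_similarity(annotations, atc_config)
    if not mats:
        raise KronfuseError("at least one drug-side source is required")
    mats = {k: m.reindex(drug_ids) for k, m in mats.items()}
    mats["Comb_d"] = combine_max(list(mats.values()), "comb_d")
    return mats


def bundle_similarities(bundle, **kwargs):
    """Cell- and drug-side similarity dictionaries for a synthetic bundle,
    aligned to the response matrix's cell and drug order."""
    cells = cell_similarities(
        mutation=bundle.mutation,
        copy_number=bundle.copy_number,
        expression=bundle.expression,
        cell_ids=bundle.responses.cell_ids,
        **{k: v for k, v in kwargs.items() if k in ("mutation_config", "gaussian_config")},
    )
    drugs = drug_similarities(bundle.annotations)
    return cells, drugs


def bundle_labels(bundle, config: CategorizationConfig | None = None):
    return categorize(bundle.responses, config)


def source_selection(
    mats: dict[str, SimilarityMatrix], sources: list[str], combined_name: str
) -> SimilarityMatrix:
    """Pick one factor: a single named source, or the max-combination of a
    subset (recomputed when the subset is proper)."""
    missing = [s for s in sources if s not in mats]
    if missing:
        raise KronfuseError(f"unknown or unavailable source(s): {missing}")
    if len(sources) == 1:
        return mats[sources[0]]
    from .cellsim import combine_max

    return combine_max([mats[s] for s in sources], combined_name)


def prevalence(labels: np.ndarray) -> float:
    labels = np.asarray(labels)
    return float((labels == 1).mean())
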