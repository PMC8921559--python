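"""End-to-end discovery pipeline over a simulated (or equivalently shaped) study.

Chains the stages the way the emulated study ran them: build the merged
enhancer catalog from the ChIP samples, call DEGs and intergenic DEEs on the
paired count matrices, link DEEs to DEGs, call DMLs/DMRs and genic DMEs, and
hand the results to replication/topology scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import catalog as cat
from . import differential as diff
from . import linking
from .intervals import GeneModel, GenomicInterval
from .simulate import SimulatedStudy

__all__ = ["build_catalog_from_chip", "match_catalog_to_templates", "DiscoveryResult", "run_discovery"]


def build_catalog_from_chip(
    chip_samples: dict,
    genes: Sequence[GeneModel],
    state_samples: Sequence[str] = (),
) -> list[cat.CatalogEnhancer]:
    """Classify each sample's enhancers and union-merge them into a catalog.

    Samples listed in ``state_samples`` are ingested from their
    chromatin-state segmentation; the rest from H3K4me1/H3K27ac peak overlap.
    """
    per_sample = []
    state_set = set(state_samples)
    for sid, marks in chip_samples.items():
        if sid in state_set:
            per_sample.append(cat.ingest_state_bed(marks["states"], sid))
        else:
            per_sample.append(
                cat.classify_sample_enhancers(marks["H3K4me1"], marks["H3K27ac"], sid)
            )
    return cat.merge_catalog(per_sample, genes)


def match_catalog_to_templates(
    catalog_df: pd.DataFrame, templates: pd.DataFrame
) -> dict[str, str]:
    """Map catalog enhancer ids to generator template ids by best overlap."""
    mapping: dict[str, str] = {}
    for row in catalog_df.itertuples():
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        best = None
        sub = templates[templates["chrom"] == row.chrom]
        for t in sub.itertuples():
            ov = max(0, min(iv.end, t.end) - max(iv.start, t.start))
            if ov > 0 and (best is None or ov > best[0]):
                best = (ov, t.template_id)
        if best is not None:
            mapping[row.enhancer_id] = best[1]
    return mapping


@dataclass
class DiscoveryResult:
    """Everything the discovery stage produced, keyed by template/gene ids."""

    catalog: pd.DataFrame
    erna_results: diff.DifferentialResults
    gene_results: diff.DifferentialResults
    dees: pd.DataFrame
    degs: pd.DataFrame
    links: pd.DataFrame
    erna_log: pd.DataFrame
    gene_log: pd.DataFrame
    dml: pd.DataFrame | None = None
    dmrs: list = field(default_factory=list)
    dmes: list = field(default_factory=list)


def run_discovery(
    study: SimulatedStudy,
    use_template_ids: bool = True,
    with_methylation: bool = True,
    state_sample_tail: int = 5,
) -> DiscoveryResult:
    """Run catalog + differential + linking (+ methylation) on a simulated study.

    With ``use_template_ids`` the catalog rows are re-keyed to the
    generator's template ids (by best overlap) so results join directly onto
    the eRNA count matrix and the planted truth. The last
    ``state_sample_tail`` ChIP samples are ingested from their state
    segmentations, the rest from peak files, mirroring a mixed-source
    catalog.
    """
    sample_ids = list(study.chip_samples)
    state_samples = sample_ids[len(sample_ids) - state_sample_tail :] if state_sample_tail else []
    enhancers = build_catalog_from_chip(study.chip_samples, study.genes, state_samples)
    catalog_df = cat.catalog_to_frame(enhancers)
    if use_template_ids:
        mapping = match_catalog_to_templates(catalog_df, study.templates)
        catalog_df = catalog_df.assign(
            enhancer_id=[mapping.get(e, e) for e in catalog_df["enhancer_id"]]
        )
        catalog_df = catalog_df.drop_duplicates(subset="enhancer_id", keep="first")

    erna_model = diff.PairedDifferenceModel.from_counts(
        study.erna_counts, study.patients, study.conditions, study.library_sizes,
        kind="eRNA",
    )
    erna_results = erna_model.fit()
    gene_model = diff.PairedDifferenceModel.from_counts(
        study.gene_counts, study.patients, study.conditions, study.library_sizes,
        kind="gene",
    )
    gene_results = gene_model.fit()
    dees = diff.call_dee(erna_results)
    degs = diff.call_deg(gene_results)

    # restrict DEEs to intergenic catalog enhancers, as the study design does
    intergenic = set(catalog_df.loc[catalog_df["class"] == "intergenic", "enhancer_id"])
    dees = dees[dees.index.isin(intergenic)]

    erna_log = diff.log2_fpm(study.erna_counts, study.library_sizes)
    gene_log = diff.log2_fpm(study.gene_counts, study.library_sizes)
    links = linking.link_intergenic(
        dees, degs, erna_log, gene_log, study.genes, catalog_df
    )

    dml = None
    dmrs: list = []
    dmes: list = []
    if with_methylation:
        beta_matrix = diff.PairedMatrix(study.beta, study.patients, study.conditions)
        dml, dmrs = diff.call_dml_dmr(beta_matrix, study.cpg_positions)
        dmes = linking.link_genic_dme(
            catalog_df,
            dmrs,
            study.cpg_positions,
            degs,
            study.beta,
            gene_log,
            study.genes,
        )
    return DiscoveryResult(
        catalog=catalog_df,
        erna_results=erna_results,
        gene_results=gene_results,
        dees=dees,
        degs=degs,
        links=links,
        erna_log=erna_log,
        gene_log=gene_log,
        dml=dml,
        dmrs=dmrs,
        dmes=dmes,
    )
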