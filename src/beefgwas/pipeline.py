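"""End-to-end orchestration: genotypes + phenotypes to enrichment and network.

Convenience layer used by the command-line interface and by whole-pipeline
analyses; each stage simply calls the corresponding module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import enrichment as enr
from . import gene_trait_network as gtn
from . import multiple_testing as mt
from . import snp_gene_map as sgm
from .formats_io import GeneModel, GenotypeMatrix, GoAnnotationMap
from .gwa import AssocResult, scan

__all__ = ["PipelineResult", "run_pipeline", "assoc_to_frame"]


@dataclass
class PipelineResult:
    assoc: dict[str, list[AssocResult]]
    meff: mt.MeffResult
    thresholds: mt.ThresholdSet
    hits: dict[str, list[tuple[AssocResult, str]]]
    gene_sets: list[sgm.GeneSnpSet]
    gene_lists: dict[str, enr.GeneListEntry] = field(default_factory=dict)
    enrichment: dict[str, list[enr.EnrichmentRecord]] = field(default_factory=dict)
    network: gtn.GeneTraitNetwork | None = None


def run_pipeline(
    g: GenotypeMatrix,
    pheno: pd.DataFrame,
    genes: list[GeneModel],
    go: GoAnnotationMap | None = None,
    background: set[str] | None = None,
    traits: list[str] | None = None,
    covariates: tuple[str, ...] = ("year",),
    flank: int = 3000,
    raw_alpha: float = 0.05,
    r2_max: float = 0.3,
    min_background: int = 2,
) -> PipelineResult:
    """Scan, threshold, map, prune, enrich and build the network.

    ``g`` must already be quality controlled.  Enrichment runs only when
    both a GO annotation and a tissue background list are supplied.
    """
    if traits is None:
        traits = [
            c for c in pheno.columns if c not in ("sample_id", "year", "breed_group")
        ]
    assoc = {t: scan(g, pheno, t, covariates=covariates) for t in traits}
    meff = mt.compute_meff(g)
    thresholds = mt.ThresholdSet.from_meff(meff, raw=raw_alpha)
    hits = {t: mt.classify_hits(assoc[t], thresholds) for t in traits}
    gene_sets = sgm.build_gene_snp_sets(
        g, assoc, genes, flank=flank, alpha=raw_alpha, r2_max=r2_max
    )
    result = PipelineResult(
        assoc=assoc,
        meff=meff,
        thresholds=thresholds,
        hits=hits,
        gene_sets=gene_sets,
    )
    if go is not None and background is not None:
        filtered = enr.restrict_to_tissue(gene_sets, background)
        for t in traits:
            gene_list = enr.build_gene_list(filtered, t)
            result.gene_lists[t] = gene_list
            if gene_list.n_list:
                result.enrichment[t] = enr.enrich_all(
                    gene_list, go, background, min_background=min_background
                )
            else:
                result.enrichment[t] = []
    result.network = gtn.build_network(gene_sets, pheno)
    return result


def assoc_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [r.variant.id for r in results],
            "chrom": [r.variant.chrom for r in results],
            "pos": [r.variant.pos for r in results],
            "trait": [r.trait for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "wald": [r.wald for r in results],
            "p": [r.p for r in results],
        }
    )
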