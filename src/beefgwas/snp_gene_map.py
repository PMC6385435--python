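"""Assignment of associated SNPs to genes and LD pruning.

A SNP is assigned to a gene when it lies inside the gene span or within a
3 kb flank on either side (strand-agnostic; a SNP inside two overlapping
genes counts for both).  Per trait, "raw" associated SNPs are those with
single-marker p <= 0.05.  Within each gene the raw SNPs are pruned
greedily to a mutually uncorrelated subset: walking the SNPs in order of
increasing p, a SNP is retained only if its squared Pearson dosage
correlation with every already-retained SNP is at most 0.3.  The retained
count becomes the gene's multiplicity in the enrichment gene list and its
weight in the gene-trait network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import GeneModel, GenotypeMatrix, Variant
from .gwa import AssocResult

__all__ = [
    "GeneSnpSet",
    "assign_snps",
    "raw_filter",
    "prune_uncorrelated",
    "build_gene_snp_sets",
]


@dataclass
class GeneSnpSet:
    """Raw and pruned associated SNPs for one gene and one trait.

    Both lists are ordered by ascending p (ties broken by genomic position,
    then variant ID); ``kept`` is always a subset of ``raw`` and the most
    significant raw SNP is always kept.
    """

    gene_id: str
    trait: str
    raw: list[str] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)

    @property
    def multiplicity(self) -> int:
        return len(self.kept)


def assign_snps(
    variants: list[Variant],
    genes: list[GeneModel],
    flank: int = 3000,
) -> dict[str, list[Variant]]:
    """Map each gene to the variants within ``flank`` bp of its span.

    Boundaries are inclusive: a variant at exactly ``start1 - flank`` or
    ``end1 + flank`` is assigned.  A variant may be assigned to any number
    of genes; genes with no variants map to an empty list.
    """
    by_chrom: dict[str, tuple[np.ndarray, list[Variant]]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, ([], []))[1].append(v)  # type: ignore[arg-type]
    prepared: dict[str, tuple[np.ndarray, list[Variant]]] = {}
    for chrom, (_, vs) in by_chrom.items():
        vs_sorted = sorted(vs, key=lambda v: v.pos)
        prepared[chrom] = (np.array([v.pos for v in vs_sorted]), vs_sorted)

    out: dict[str, list[Variant]] = {}
    for gene in genes:
        out[gene.gene_id] = []
        if gene.chrom not in prepared:
            continue
        pos, vs = prepared[gene.chrom]
        lo = np.searchsorted(pos, gene.start1 - flank, side="left")
        hi = np.searchsorted(pos, gene.end1 + flank, side="right")
        out[gene.gene_id] = vs[lo:hi]
    return out


def raw_filter(
    assoc: list[AssocResult], alpha: float = 0.05
) -> dict[str, list[AssocResult]]:
    """Per-trait raw associated SNPs: p <= alpha, inclusive."""
    out: dict[str, list[AssocResult]] = {}
    for r in assoc:
        if r.ok and r.p <= alpha:
            out.setdefault(r.trait, []).append(r)
    return out


def _order_by_p(results: list[AssocResult]) -> list[AssocResult]:
    return sorted(results, key=lambda r: (r.p, r.variant.pos, r.variant.id))


def prune_uncorrelated(
    g: GenotypeMatrix,
    raw_snps: list[AssocResult],
    r2_max: float = 0.3,
) -> list[str]:
    """Greedy LD pruning of one gene's raw SNPs.

    SNPs are visited by ascending p (ties by position then ID); the best
    SNP is always kept and a subsequent SNP is kept iff its dosage
    r-squared with every kept SNP is <= ``r2_max``.  r-squared is the
    squared Pearson correlation of mean-imputed dosages.
    """
    ordered = _order_by_p(raw_snps)
    kept: list[str] = []
    kept_cols: list[np.ndarray] = []
    for r in ordered:
        col = g.column(r.variant.id)  # raises KeyError if absent
        col = np.where(np.isnan(col), np.nanmean(col), col)
        if not kept:
            kept.append(r.variant.id)
            kept_cols.append(col)
            continue
        ok = True
        for kc in kept_cols:
            if col.std() == 0 or kc.std() == 0:
                r2 = 1.0  # a monomorphic column carries no extra signal
            else:
                r2 = float(np.corrcoef(col, kc)[0, 1]) ** 2
            if r2 > r2_max:
                ok = False
                break
        if ok:
            kept.append(r.variant.id)
            kept_cols.append(col)
    return kept


def build_gene_snp_sets(
    g: GenotypeMatrix,
    assoc_by_trait: dict[str, list[AssocResult]],
    genes: list[GeneModel],
    flank: int = 3000,
    alpha: float = 0.05,
    r2_max: float = 0.3,
) -> list[GeneSnpSet]:
    """Full mapping stage: raw filter, gene assignment, per-gene pruning.

    ``assoc_by_trait`` maps trait name to that trait's complete scan; the
    result contains one :class:`GeneSnpSet` per (gene, trait) with at least
    one raw associated SNP.
    """
    all_variants = {v.id: v for v in g.variants}
    gene_variants = assign_snps(list(all_variants.values()), genes, flank=flank)
    sets: list[GeneSnpSet] = []
    for trait, assoc in assoc_by_trait.items():
        raw = raw_filter(assoc, alpha=alpha).get(trait, [])
        raw_by_id = {r.variant.id: r for r in raw}
        for gene in genes:
            hits = [
                raw_by_id[v.id] for v in gene_variants[gene.gene_id] if v.id in raw_by_id
            ]
            if not hits:
                continue
            ordered = _order_by_p(hits)
            kept = prune_uncorrelated(g, ordered, r2_max=r2_max)
            sets.append(
                GeneSnpSet(
                    gene_id=gene.gene_id,
                    trait=trait,
                    raw=[r.variant.id for r in ordered],
                    kept=kept,
                )
            )
    return sets
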