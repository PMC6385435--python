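"""Bipartite gene-trait network weighted by uncorrelated-SNP counts.

Rows are genes, columns are traits; the weight w[g, t] is the number of
retained uncorrelated SNPs of gene g for trait t.  A gene's connectivity
is the sum of its weights across traits (a trait-count alternative is
available), and the most connected genes are candidate loci carrying
multiple QTLs: several independent association signals, possibly for
several traits.  Trait-trait edges carry the phenotypic correlation of the
analysis-ready (transformed) trait values.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .formats_io import TRAITS
from .gwa import preprocess_trait
from .snp_gene_map import GeneSnpSet

__all__ = [
    "GeneTraitNetwork",
    "build_network",
    "top_genes",
    "select_multi_qtl_candidates",
    "export_network",
]


@dataclass
class GeneTraitNetwork:
    weights: pd.DataFrame
    """genes x traits, non-negative integer kept-SNP counts."""
    trait_corr: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if (w < 0).any() or not np.allclose(w, np.round(w)):
            raise ValueError("weights must be non-negative integers")
        c = self.trait_corr.to_numpy()
        if not np.allclose(c, c.T, atol=1e-8, equal_nan=True):
            raise ValueError("trait_corr must be symmetric")

    def gene_connectivity(self, mode: str = "weight") -> pd.Series:
        """Per-gene connectivity: total kept SNPs ('weight', default) or
        the number of traits touched ('traits')."""
        if mode == "weight":
            return self.weights.sum(axis=1)
        if mode == "traits":
            return (self.weights > 0).sum(axis=1)
        raise ValueError("mode must be 'weight' or 'traits'")

    def trait_connectivity(self) -> pd.Series:
        return self.weights.sum(axis=0)


def build_network(
    gene_sets: list[GeneSnpSet],
    pheno: pd.DataFrame,
    transform: bool = True,
) -> GeneTraitNetwork:
    """Assemble the weight matrix and trait correlations.

    Only genes with at least one kept SNP for some trait appear.  Trait
    correlations are pairwise-complete Pearson on the transformed values
    (sensory traits are recorded on fewer animals than carcass traits).
    """
    traits = [t for t in TRAITS if t in pheno.columns]
    genes = sorted({s.gene_id for s in gene_sets if s.multiplicity > 0})
    w = pd.DataFrame(0, index=genes, columns=traits, dtype=int)
    for s in gene_sets:
        if s.multiplicity > 0:
            if s.trait not in w.columns:
                w[s.trait] = 0
            w.loc[s.gene_id, s.trait] = s.multiplicity

    values = {}
    for t in w.columns:
        if t not in pheno.columns:
            raise KeyError(f"trait {t!r} missing from phenotype table")
        v = pheno[t].to_numpy(float)
        values[t] = preprocess_trait(v, t) if transform else v
        if np.nanstd(values[t]) == 0:
            raise ValueError(f"trait {t!r} has zero variance")
    corr = pd.DataFrame(values).corr(method="pearson")  # pairwise-complete
    return GeneTraitNetwork(weights=w, trait_corr=corr)


def top_genes(net: GeneTraitNetwork, k: int = 30, mode: str = "weight") -> pd.DataFrame:
    """Genes ranked by connectivity.

    Ties are broken by the number of traits touched (descending: the gene
    spread over more traits ranks first), then by gene ID for determinism.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    conn = net.gene_connectivity(mode=mode)
    spread = net.gene_connectivity(mode="traits")
    df = (
        pd.DataFrame({"connectivity": conn, "n_traits": spread})
        .rename_axis("gene_id")
        .reset_index()
        .sort_values(
            by=["connectivity", "n_traits", "gene_id"],
            ascending=[False, False, True],
            kind="stable",
        )
        .set_index("gene_id")
    )
    return df.head(k)


@dataclass
class MultiQtlSelection:
    genes: list[str]
    traits_by_gene: dict[str, list[str]]
    """Per selected gene, the traits with >= 2 kept SNPs (joint-model input)."""
    gap_ratio: float
    """Connectivity of the m-th gene over the (m+1)-th; descriptive only."""


def select_multi_qtl_candidates(net: GeneTraitNetwork, m: int = 5) -> MultiQtlSelection:
    """Top-m connected genes, forwarded to the joint multi-SNP model.

    For each selected gene the traits with at least two retained SNPs are
    listed (a single SNP needs no joint model).  The gap ratio compares the
    last selected connectivity with the first excluded one as a descriptive
    check that the selected genes stand out.
    """
    if m <= 0:
        return MultiQtlSelection(genes=[], traits_by_gene={}, gap_ratio=float("nan"))
    ranked = top_genes(net, k=max(m + 1, 1))
    genes = list(ranked.index[:m])
    conn = net.gene_connectivity()
    if len(ranked) > m and conn[genes[-1]] > 0:
        gap = float(conn[genes[-1]]) / float(max(conn[ranked.index[m]], 1))
    else:
        gap = float("nan") if len(ranked) <= m else 1.0
    traits_by_gene = {
        g: [t for t in net.weights.columns if net.weights.loc[g, t] >= 2]
        for g in genes
    }
    return MultiQtlSelection(genes=genes, traits_by_gene=traits_by_gene, gap_ratio=gap)


def export_network(
    net: GeneTraitNetwork,
    edges_path: str,
    graphml_path: str | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Write the network as a TSV edge list and optionally GraphML.

    Gene-trait edges carry the SNP-count weight; trait-trait edges carry
    the signed phenotypic correlation.  Node sizes (connectivity) are
    stored as node attributes in the GraphML output.
    """
    w = net.weights
    if top_k is not None:
        keep = top_genes(net, k=top_k).index
        w = w.loc[[g for g in w.index if g in set(keep)]]
    rows = []
    for gene in w.index:
        for trait in w.columns:
            if w.loc[gene, trait] > 0:
                rows.append(("gene_trait", gene, trait, int(w.loc[gene, trait])))
    traits = list(net.trait_corr.columns)
    for i, t1 in enumerate(traits):
        for t2 in traits[i + 1 :]:
            r = net.trait_corr.loc[t1, t2]
            if np.isfinite(r):
                rows.append(("trait_trait", t1, t2, float(r)))
    edges = pd.DataFrame(rows, columns=["edge_type", "source", "target", "weight"])
    edges.to_csv(edges_path, sep="\t", index=False)

    if graphml_path is not None:
        gr = nx.Graph()
        conn = net.gene_connectivity()
        for gene in w.index:
            gr.add_node(gene, kind="gene", connectivity=int(conn[gene]))
        tconn = net.trait_connectivity()
        for trait in traits:
            gr.add_node(trait, kind="trait", connectivity=int(tconn.get(trait, 0)))
        for _, r in edges.iterrows():
            gr.add_edge(r["source"], r["target"], weight=float(r["weight"]),
                        edge_type=r["edge_type"])
        nx.write_graphml(gr, graphml_path)
    return edges
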