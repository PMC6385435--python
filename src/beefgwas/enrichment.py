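"""Tissue-restricted hypergeometric gene-set enrichment.

The enrichment population is the set of genes expressed in the target
tissue (the background list); genes absent from it never enter a trait's
gene list.  A trait's gene list is a multiset: a gene appears once per
retained uncorrelated SNP, so a gene with three independent association
signals carries three entries.  For every GO term annotated to at least
``min_background`` background genes, a hypergeometric test compares the
term's entries in the list (k, counted with multiplicity) against the
term's background genes (K) given the list size (n, with multiplicity) and
the background size (N).  Benjamini-Hochberg adjustment is applied per
trait over the tested terms.

Multiplicity enters n and k only; K and N remain plain gene counts because
the background and the GO universe are sets, not multisets.  Both
over-representation (P[X >= k]) and under-representation (P[X <= k])
tails are computed; over-representation is the default reading.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .formats_io import GoAnnotationMap
from .multiple_testing import bh_adjust
from .snp_gene_map import GeneSnpSet

__all__ = [
    "GeneListEntry",
    "EnrichmentRecord",
    "restrict_to_tissue",
    "build_gene_list",
    "hypergeom_test",
    "enrich_all",
    "overlap_summary",
]


@dataclass
class GeneListEntry:
    """Multiplicity-expanded gene list for one trait."""

    trait: str
    entries: Counter
    """gene_id -> number of retained uncorrelated SNPs."""

    @property
    def n_list(self) -> int:
        return int(sum(self.entries.values()))

    @property
    def genes(self) -> set[str]:
        return set(self.entries)


@dataclass
class EnrichmentRecord:
    trait: str
    go_term: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p_over: float
    p_under: float
    direction: str = "over"
    p_adj: float = float("nan")

    @property
    def p_raw(self) -> float:
        return self.p_over if self.direction == "over" else self.p_under


def restrict_to_tissue(
    gene_sets: list[GeneSnpSet], background: set[str]
) -> list[GeneSnpSet]:
    """Drop gene/trait sets whose gene is not expressed in the tissue.

    The same background set must then be used as the enrichment population.
    """
    if not background:
        raise ValueError("background list is empty")
    kept = [s for s in gene_sets if s.gene_id in background]
    if gene_sets and not kept:
        raise ValueError(
            "no overlap between associated genes and the tissue background "
            f"(background size {len(background)}, "
            f"{len({s.gene_id for s in gene_sets})} associated genes)"
        )
    return kept


def build_gene_list(gene_sets: list[GeneSnpSet], trait: str) -> GeneListEntry:
    """Multiset of genes for one trait, one entry per kept uncorrelated SNP."""
    entries: Counter = Counter()
    for s in gene_sets:
        if s.trait == trait and s.multiplicity > 0:
            entries[s.gene_id] += s.multiplicity
    return GeneListEntry(trait=trait, entries=entries)


def hypergeom_test(k: int, K: int, n: int, N: int, tail: str = "over") -> float:
    """Hypergeometric tail probability.

    Draw ``n`` from a population of ``N`` containing ``K`` successes;
    ``tail='over'`` returns P(X >= k), ``tail='under'`` returns P(X <= k).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if tail == "over":
        return float(hypergeom.sf(k - 1, N, K, n))
    if tail == "under":
        return float(hypergeom.cdf(k, N, K, n))
    raise ValueError("tail must be 'over' or 'under'")


def enrich_all(
    gene_list: GeneListEntry,
    go: GoAnnotationMap,
    background: set[str],
    min_background: int = 2,
    direction: str = "over",
    unique: bool = False,
) -> list[EnrichmentRecord]:
    """Test every eligible GO term against one trait's gene list.

    Terms annotated to fewer than ``min_background`` background genes are
    not tested (singleton terms only inflate the adjustment denominator).
    ``unique=True`` collapses multiplicity, making n and k plain gene
    counts.  Records come back sorted by raw p in the chosen direction,
    with BH adjustment over exactly the tested terms.
    """
    N = len(background)
    if N == 0:
        raise ValueError("background list is empty")
    entries = (
        Counter({g: 1 for g in gene_list.entries}) if unique else gene_list.entries
    )
    for gene in entries:
        if gene not in background:
            raise ValueError(
                f"gene {gene} in gene list but not in background; apply "
                "restrict_to_tissue before enrichment"
            )
    n = int(sum(entries.values()))
    if n == 0:
        return []
    if n > N:
        # multiplicity can push the list size past the number of distinct
        # background genes; the hypergeometric draw is then ill-defined
        raise ValueError(
            f"list size with multiplicity ({n}) exceeds background size ({N})"
        )

    term_bg: dict[str, set[str]] = {}
    for gene in background:
        for term in go.gene_terms.get(gene, ()):
            term_bg.setdefault(term, set()).add(gene)

    records: list[EnrichmentRecord] = []
    for term, bg_genes in sorted(term_bg.items()):
        K = len(bg_genes)
        if K < min_background:
            continue
        k = int(sum(cnt for gene, cnt in entries.items() if gene in bg_genes))
        # multiplicity can push k past the term's gene count; cap at the
        # hypergeometric support so the tail probability stays in (0, 1]
        k = min(k, n, K)
        records.append(
            EnrichmentRecord(
                trait=gene_list.trait,
                go_term=term,
                name=go.term_names.get(term, ""),
                k=k,
                K=K,
                n=n,
                N=N,
                p_over=float(hypergeom.sf(k - 1, N, K, n)),
                p_under=float(hypergeom.cdf(k, N, K, n)),
                direction=direction,
            )
        )
    if not records:
        return []
    p_raw = np.array([r.p_raw for r in records])
    p_adj = bh_adjust(p_raw, m_override=len(records))
    for r, adj in zip(records, p_adj):
        r.p_adj = float(adj)
    records.sort(key=lambda r: (r.p_raw, r.go_term))
    return records


def overlap_summary(
    records_by_trait: dict[str, list[EnrichmentRecord]],
    gene_lists_by_trait: dict[str, GeneListEntry],
    go: GoAnnotationMap,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> dict[str, dict[str, set[str]]]:
    """Cross-trait overlap of enriched terms.

    For each term passing the reporting threshold (raw p by default) in at
    least two traits, returns the per-trait annotated gene sets (unique
    genes, multiplicity ignored) plus their intersection under the key
    ``"__shared__"``.
    """
    if len(records_by_trait) < 2:
        raise ValueError("overlap_summary needs enrichment for >= 2 traits")
    passing: dict[str, list[str]] = {}
    for trait, records in records_by_trait.items():
        for r in records:
            p = r.p_adj if use_adjusted else r.p_raw
            if p <= alpha:
                passing.setdefault(r.go_term, []).append(trait)
    out: dict[str, dict[str, set[str]]] = {}
    for term, traits in passing.items():
        if len(traits) < 2:
            continue
        term_genes = go.genes_for_term(term)
        per_trait = {
            t: gene_lists_by_trait[t].genes & term_genes for t in sorted(traits)
        }
        shared: set[str] = set.intersection(*per_trait.values())
        per_trait["__shared__"] = shared
        out[term] = per_trait
    return out
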