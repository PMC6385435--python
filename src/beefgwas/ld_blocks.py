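"""Haplotype-block prediction from unphased genotypes.

The block definition is the Gabriel confidence-interval rule as
implemented in Haploview: for every variant pair, two-locus haplotype
frequencies are estimated by EM over the double-heterozygote phase
ambiguity, a likelihood-based confidence interval is placed on |D'|, and
pairs are classified as "strong LD" (CI bottom >= 0.70 and CI top >= 0.98)
or as showing "strong evidence of historical recombination" (CI top
< 0.90).  A run of variants whose outermost pair is in strong LD is
accepted as a block when at least 95% of its informative pairs are strong;
overlapping candidates are resolved longest-first.  All four cut-offs are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import GenotypeMatrix

__all__ = [
    "PairLd",
    "LdBlock",
    "em_haplotype_freqs",
    "dprime_ci",
    "gabriel_blocks",
]


@dataclass
class PairLd:
    v1: str
    v2: str
    p_ab: np.ndarray
    """2x2 haplotype frequencies: p_ab[i, j] = freq of (allele i at v1, allele j at v2),
    with index 0 = REF, 1 = ALT."""
    D: float
    dprime: float
    r2: float
    n_informative: int
    """Chromosomes from samples genotyped at both sites."""
    converged: bool = True
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    loglik_trace: list[float] | None = None

    @property
    def p_a(self) -> float:
        """ALT frequency at the first locus."""
        return float(self.p_ab[1, 0] + self.p_ab[1, 1])

    @property
    def p_b(self) -> float:
        return float(self.p_ab[0, 1] + self.p_ab[1, 1])


def _genotype_class_counts(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """3x3 table of joint genotype counts over pairwise-complete samples."""
    ok = ~(np.isnan(x1) | np.isnan(x2))
    a = x1[ok].astype(int)
    b = x2[ok].astype(int)
    counts = np.zeros((3, 3))
    for i, j in zip(a, b):
        counts[i, j] += 1
    return counts


def _class_probs(p: np.ndarray) -> np.ndarray:
    """3x3 genotype-class probabilities under HWE from haplotype freqs."""
    # haplotypes: 00, 01, 10, 11 with freqs p[0,0], p[0,1], p[1,0], p[1,1]
    probs = np.zeros((3, 3))
    hap = [(0, 0), (0, 1), (1, 0), (1, 1)]
    for (a1, b1) in hap:
        for (a2, b2) in hap:
            probs[a1 + a2, b1 + b2] += p[a1, b1] * p[a2, b2]
    return probs


def em_haplotype_freqs(
    g: GenotypeMatrix,
    v1: str,
    v2: str,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> PairLd:
    """Two-locus haplotype frequencies by EM on unphased genotypes.

    Every genotype class except the double heterozygote contributes known
    haplotype counts; the double-het count is split between the cis
    (REF-REF / ALT-ALT) and trans phases in proportion to their current
    expected frequency products.  Convergence is declared when the largest
    frequency change falls below ``tol``; a non-converged pair is returned
    with ``converged=False`` rather than raised.
    """
    x1, x2 = g.column(v1), g.column(v2)
    counts = _genotype_class_counts(x1, x2)
    n_chrom = int(2 * counts.sum())
    if n_chrom == 0:
        raise ValueError(f"no pairwise-complete samples for {v1}, {v2}")
    for x, name in ((x1, v1), (x2, v2)):
        col = x[~np.isnan(x)]
        freq = col.sum() / (2 * col.size) if col.size else 0.0
        if not 0.0 < freq < 1.0:
            raise ValueError(f"variant {name} is monomorphic; LD undefined")

    # fixed haplotype contributions from unambiguous genotype classes:
    # genotype (i, j) carries known haplotypes unless i == j == 1
    fixed = np.zeros((2, 2))
    for i in range(3):
        for j in range(3):
            c = counts[i, j]
            if c == 0 or (i == 1 and j == 1):
                continue
            # each sample contributes 2 haplotypes, split by genotype
            a_alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[i]
            b_alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[j]
            if i == 1:  # het at locus 1, hom at locus 2
                fixed[0, b_alleles[0]] += c
                fixed[1, b_alleles[0]] += c
            elif j == 1:  # hom at locus 1, het at locus 2
                fixed[a_alleles[0], 0] += c
                fixed[a_alleles[0], 1] += c
            else:
                fixed[a_alleles[0], b_alleles[0]] += 2 * c
    n_dh = counts[1, 1]

    p = np.full((2, 2), 0.25)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        cis = p[0, 0] * p[1, 1]
        trans = p[0, 1] * p[1, 0]
        denom = cis + trans
        w_cis = 0.5 if denom == 0 else cis / denom
        new = fixed.copy()
        new[0, 0] += n_dh * w_cis
        new[1, 1] += n_dh * w_cis
        new[0, 1] += n_dh * (1 - w_cis)
        new[1, 0] += n_dh * (1 - w_cis)
        new /= n_chrom
        trace.append(_pair_loglik(counts, new))
        if np.max(np.abs(new - p)) < tol:
            p = new
            converged = True
            break
        p = new

    p_a = p[1, 0] + p[1, 1]
    p_b = p[0, 1] + p[1, 1]
    D = p[1, 1] - p_a * p_b
    if D >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = 0.0 if dmax == 0 else D / dmax
    denom_r = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = 0.0 if denom_r == 0 else D**2 / denom_r
    return PairLd(
        v1=v1,
        v2=v2,
        p_ab=p,
        D=float(D),
        dprime=float(dprime),
        r2=float(r2),
        n_informative=n_chrom,
        converged=converged,
        loglik_trace=trace,
    )


def _pair_loglik(counts: np.ndarray, p: np.ndarray) -> float:
    probs = np.clip(_class_probs(p), 1e-300, None)
    return float(np.sum(counts * np.log(probs)))


def dprime_ci(
    pair: PairLd,
    g: GenotypeMatrix,
    conf: float = 0.90,
    grid_size: int = 101,
) -> tuple[float, float]:
    """Likelihood-based confidence bounds on |D'| (Wall-Pritchard style).

    With the allele frequencies fixed at their EM estimates, the genotype
    data's likelihood is evaluated over a grid of |D'| in [0, 1] (signed by
    the EM point estimate); the bounds are the grid values where the
    normalized likelihood mass crosses (1-conf)/2 and 1-(1-conf)/2.
    """
    counts = _genotype_class_counts(g.column(pair.v1), g.column(pair.v2))
    p_a, p_b = pair.p_a, pair.p_b
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic margin: D' confidence interval undefined")
    sign = 1.0 if pair.D >= 0 else -1.0
    if sign > 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    grid = np.linspace(0.0, 1.0, grid_size)
    logls = np.empty(grid_size)
    for i, t in enumerate(grid):
        D = sign * t * dmax
        p = np.array(
            [
                [(1 - p_a) * (1 - p_b) + D, (1 - p_a) * p_b - D],
                [p_a * (1 - p_b) - D, p_a * p_b + D],
            ]
        )
        p = np.clip(p, 1e-12, None)
        p /= p.sum()
        logls[i] = _pair_loglik(counts, p)
    w = np.exp(logls - logls.max())
    w /= w.sum()
    cum = np.cumsum(w)
    lo_q, hi_q = (1 - conf) / 2, 1 - (1 - conf) / 2
    ci_low = float(grid[int(np.searchsorted(cum, lo_q))])
    ci_high = float(grid[min(int(np.searchsorted(cum, hi_q)), grid_size - 1)])
    return ci_low, ci_high


@dataclass
class LdBlock:
    chrom: str
    first_idx: int
    last_idx: int
    start_pos: int
    end_pos: int
    variant_ids: list[str]

    @property
    def n_variants(self) -> int:
        return self.last_idx - self.first_idx + 1


def gabriel_blocks(
    g: GenotypeMatrix,
    region: tuple[str, int, int] | None = None,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
    frac_strong: float = 0.95,
    conf: float = 0.90,
) -> list[LdBlock]:
    """Partition a region into Gabriel confidence-interval LD blocks.

    ``region`` is (chrom, start1, end1); None processes the whole panel
    chromosome by chromosome.  A pair is strong when ci_low >= strong_low
    and ci_high >= strong_high, and recombinant when ci_high < recomb_high;
    candidate spans need a strong outermost pair and at least
    ``frac_strong`` strong among their informative (strong or recombinant)
    pairs.  Longer candidates win conflicts.
    """
    if region is None:
        blocks: list[LdBlock] = []
        for chrom in dict.fromkeys(v.chrom for v in g.variants):
            pos = [v.pos for v in g.variants if v.chrom == chrom]
            blocks.extend(
                gabriel_blocks(
                    g, (chrom, min(pos), max(pos)), strong_low, strong_high,
                    recomb_high, frac_strong, conf,
                )
            )
        return blocks

    chrom, start1, end1 = region
    idx = [
        j
        for j, v in enumerate(g.variants)
        if v.chrom == chrom and start1 <= v.pos <= end1
    ]
    idx.sort(key=lambda j: g.variants[j].pos)
    m = len(idx)
    if m < 2:
        return []

    # pairwise classification: 1 strong, -1 recombination, 0 uninformative
    cls = np.zeros((m, m), dtype=int)
    for a in range(m):
        for b in range(a + 1, m):
            v1, v2 = g.variants[idx[a]].id, g.variants[idx[b]].id
            try:
                pair = em_haplotype_freqs(g, v1, v2)
                lo, hi = dprime_ci(pair, g, conf=conf)
            except ValueError:
                continue
            if lo >= strong_low and hi >= strong_high:
                cls[a, b] = 1
            elif hi < recomb_high:
                cls[a, b] = -1

    candidates: list[tuple[int, int]] = []
    for a in range(m):
        for b in range(a + 1, m):
            if cls[a, b] != 1:  # outermost pair must be strong
                continue
            sub = cls[a : b + 1, a : b + 1]
            strong = int((sub == 1).sum())
            recomb = int((sub == -1).sum())
            if strong + recomb == 0:
                continue
            if strong / (strong + recomb) >= frac_strong:
                candidates.append((a, b))

    # longest first (bp length, then SNP count), accept non-overlapping
    def length_bp(c: tuple[int, int]) -> int:
        return g.variants[idx[c[1]]].pos - g.variants[idx[c[0]]].pos

    candidates.sort(key=lambda c: (-length_bp(c), -(c[1] - c[0]), c[0]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for a, b in candidates:
        if taken[a : b + 1].any():
            continue
        taken[a : b + 1] = True
        members = [g.variants[idx[j]].id for j in range(a, b + 1)]
        blocks.append(
            LdBlock(
                chrom=chrom,
                first_idx=idx[a],
                last_idx=idx[b],
                start_pos=g.variants[idx[a]].pos,
                end_pos=g.variants[idx[b]].pos,
                variant_ids=members,
            )
        )
    blocks.sort(key=lambda blk: blk.start_pos)
    return blocks
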