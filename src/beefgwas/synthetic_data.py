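"""Synthetic Angus-Brahman-like dataset generator.

Every stage of the association pipeline can be exercised without any
download: this module emits genotypes, phenotypes, gene models, GO
annotation and a tissue background list with the statistical structure the
analysis assumes, together with the ground truth needed by tests.

Genotypes
    Chromosomes are tiled with LD blocks.  Within each block, haplotypes
    are drawn from a small founder-haplotype pool per ancestral population
    (pool size controls within-block r-squared); between blocks the draws
    are independent, so recombination happens only at block boundaries.
    Two ancestral populations with Balding-Nichols-diverged allele
    frequencies are mixed according to six breed-composition groups with
    Angus proportions 0.9, 0.72, 0.625, 0.5, 0.3 and 0.1, reproducing the
    admixture confounding a kinship matrix must absorb.

Phenotypes
    Seven correlated meat-quality traits.  On a unit-variance latent scale,
    each trait is the sum of a year effect, planted QTL effects, a
    polygenic term drawn from the realized genomic relationship matrix
    (so cross-trait genetic correlations are exact in distribution) and
    residual noise.  Traits are then emitted the way they are measured:
    shear force as the average peak load (kg) of six cores, sensory traits
    as averaged 8-point integer panel scores, cooking loss as a percentage
    from thaw/cooked weights, marbling as a skewed integer score on the
    100-999 scale.

Annotation
    Genes tile the simulated chromosomes without overlap; QTL-carrying
    genes span one LD block per causal SNP so their causal variants stay
    mutually uncorrelated.  GO terms are assigned at random except for one
    planted term that is enriched among the causal genes; the background
    list contains every causal gene plus a configurable fraction of the
    rest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats_io as fio
from .formats_io import GeneModel, GenotypeMatrix, GoAnnotationMap, Variant, TRAITS
from .gwa import compute_grm, _eigh_psd

__all__ = [
    "QtlEffect",
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_annotation",
    "simulate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class QtlEffect:
    """One planted QTL: a gene, a trait, the fraction of phenotypic variance
    explained by the gene (split equally over its causal SNPs), and the
    number of causal SNPs (each placed in a distinct LD block)."""

    gene_id: str
    trait: str
    frac: float
    n_causal_snps: int


def _default_h2() -> dict[str, float]:
    # marbling, tenderness and WBSF at the published estimates for this
    # population; remaining traits at values typical for sensory/carcass
    # traits in beef cattle.
    return {
        "wbsf": 0.17,
        "marbling": 0.50,
        "cooking_loss": 0.30,
        "tenderness": 0.47,
        "juiciness": 0.25,
        "connective_tissue": 0.30,
        "flavor": 0.15,
    }


def _default_rg() -> np.ndarray:
    rg = np.eye(len(TRAITS))
    i, j = TRAITS.index("wbsf"), TRAITS.index("tenderness")
    rg[i, j] = rg[j, i] = -0.97
    return rg


def _default_qtls() -> list[QtlEffect]:
    # Three multi-QTL genes; each affects two traits through the same three
    # causal SNPs.  None touches WBSF or tenderness, whose genetic
    # covariance is governed purely by the polygenic correlation.
    return [
        QtlEffect("GENE010", "cooking_loss", 0.06, 3),
        QtlEffect("GENE010", "marbling", 0.06, 3),
        QtlEffect("GENE045", "cooking_loss", 0.06, 3),
        QtlEffect("GENE045", "juiciness", 0.06, 3),
        QtlEffect("GENE080", "cooking_loss", 0.06, 3),
        QtlEffect("GENE080", "flavor", 0.045, 3),
    ]


#: Raw-scale (mean, SD) for each trait, matching the descriptive statistics
#: of the motivating population.
TRAIT_SCALES: dict[str, tuple[float, float]] = {
    "wbsf": (4.30, 1.15),
    "marbling": (425.57, 90.03),
    "cooking_loss": (23.25, 5.74),
    "tenderness": (5.28, 0.84),
    "juiciness": (5.01, 0.76),
    "connective_tissue": (5.81, 0.83),
    "flavor": (5.56, 0.46),
}

#: Expected Angus proportion for breed-composition groups 1..6.
ADMIXTURE_GROUPS = (0.9, 0.72, 0.625, 0.5, 0.3, 0.1)


@dataclass
class SimConfig:
    n_samples: int = 672
    n_sensory: int = 495
    n_variants: int = 3000
    n_chromosomes: int = 3
    block_length_mean: int = 10
    block_length_jitter: bool = True
    """Poisson-vary block lengths; False gives exact ``block_length_mean``."""
    within_block_r2: float = 0.5
    fst: float = 0.1
    admixture: tuple[float, ...] = ADMIXTURE_GROUPS
    n_genes: int = 100
    gene_block_gap: int = 1
    n_go_terms: int = 150
    planted_term: str = "GO:0005789"
    planted_term_name: str = "endoplasmic reticulum membrane"
    planted_extra_genes: int = 12
    terms_per_gene: float = 3.0
    background_fraction: float = 0.9
    qtl_spec: list[QtlEffect] = field(default_factory=_default_qtls)
    h2: dict[str, float] = field(default_factory=_default_h2)
    rg: np.ndarray = field(default_factory=_default_rg)
    panel_size: int = 9
    n_cores: int = 6
    core_noise_var: float = 0.1
    panelist_score_sd: float = 0.7
    year_effect_sd: float = 0.1
    years: tuple[int, ...] = tuple(range(2007, 2015))
    missing_rate: float = 0.0
    seed: int = 0

    @property
    def founder_pool_size(self) -> int:
        """Haplotypes per population per block; ~1/within_block_r2."""
        return max(2, int(round(1.0 / self.within_block_r2)))

    def qtl_frac_total(self, trait: str) -> float:
        return sum(q.frac for q in self.qtl_spec if q.trait == trait)

    def validate(self) -> None:
        for t in TRAITS:
            if t not in self.h2:
                raise ValueError(f"h2 missing for trait {t!r}")
            if not 0.0 <= self.h2[t] <= 1.0:
                raise ValueError(f"h2[{t}]={self.h2[t]} outside [0, 1]")
        rg = np.asarray(self.rg, dtype=float)
        if rg.shape != (len(TRAITS), len(TRAITS)):
            raise ValueError("rg must be a 7x7 matrix over the trait order")
        if not np.allclose(rg, rg.T) or not np.allclose(np.diag(rg), 1.0):
            raise ValueError("rg must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(rg).min() < -1e-8:
            raise ValueError("rg is not positive semi-definite")
        for q in self.qtl_spec:
            if q.trait not in TRAITS:
                raise ValueError(f"unknown trait {q.trait!r} in qtl_spec")
            if q.n_causal_snps < 1:
                raise ValueError("n_causal_snps must be >= 1")
        for t in TRAITS:
            tot = self.qtl_frac_total(t)
            if tot >= 1.0:
                raise ValueError(f"QTL fractions for {t} sum to {tot} >= 1")
            if tot > self.h2[t] + 1e-12:
                raise ValueError(
                    f"QTL fractions for {t} ({tot}) exceed its heritability "
                    f"({self.h2[t]}); QTL variance counts toward h2"
                )
        if not 0 < self.n_sensory <= self.n_samples:
            raise ValueError("n_sensory must be in (0, n_samples]")
        if len(self.admixture) != 6:
            raise ValueError("admixture must give 6 breed-group proportions")


@dataclass
class SimTruth:
    """Ground truth carried alongside the emitted dataset."""

    blocks: list[tuple[str, int, int]] = field(default_factory=list)
    """(chrom, first column, last column) of each LD block, inclusive."""
    gene_blocks: dict[str, list[int]] = field(default_factory=dict)
    gene_models: list[GeneModel] = field(default_factory=list)
    causal_snps: dict[str, list[str]] = field(default_factory=dict)
    """trait -> causal variant IDs."""
    causal_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    """trait -> {variant_id: latent-scale effect on the standardized dosage}."""
    causal_genes: list[str] = field(default_factory=list)
    breeding_values: pd.DataFrame | None = None
    planted_term: str = ""
    sensory_samples: list[str] = field(default_factory=list)
    panel_scores: dict[str, np.ndarray] = field(default_factory=dict)
    core_loads: np.ndarray | None = None


@dataclass
class SimDataset:
    config: SimConfig
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    genes: list[GeneModel]
    go: GoAnnotationMap
    background: set[str]
    truth: SimTruth


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _plan_blocks(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[str, int, int]]:
    """Partition columns into per-chromosome LD blocks."""
    blocks: list[tuple[str, int, int]] = []
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_variants // cfg.n_chromosomes)
    per_chrom[: cfg.n_variants % cfg.n_chromosomes] += 1
    col = 0
    for c in range(cfg.n_chromosomes):
        chrom = str(c + 1)
        end_chrom = col + int(per_chrom[c])
        while col < end_chrom:
            if cfg.block_length_jitter:
                length = max(2, int(rng.poisson(cfg.block_length_mean)))
            else:
                length = cfg.block_length_mean
            length = min(length, end_chrom - col)
            if end_chrom - (col + length) == 1:  # avoid a trailing singleton
                length += 1
            blocks.append((chrom, col, col + length - 1))
            col += length
    return blocks


def _plan_genes(
    cfg: SimConfig, blocks: list[tuple[str, int, int]]
) -> dict[str, list[int]]:
    """Assign each gene a run of whole LD blocks, QTL genes first-class.

    Genes are laid out in ID order with ``gene_block_gap`` intergenic blocks
    between consecutive genes; a gene named in the QTL spec spans one block
    per causal SNP so its causal variants fall in distinct blocks.
    """
    spans: dict[str, int] = {}
    for i in range(cfg.n_genes):
        spans[f"GENE{i + 1:03d}"] = 1
    for q in cfg.qtl_spec:
        if q.gene_id not in spans:
            raise ValueError(
                f"qtl_spec names {q.gene_id!r} but only GENE001..GENE{cfg.n_genes:03d} exist"
            )
        spans[q.gene_id] = max(spans[q.gene_id], q.n_causal_snps)

    gene_blocks: dict[str, list[int]] = {}
    b = 0
    for gene_id, span in spans.items():
        # keep a gene on one chromosome
        while b + span <= len(blocks) and len({blocks[k][0] for k in range(b, b + span)}) > 1:
            b += 1
        if b + span > len(blocks):
            raise ValueError(
                "infeasible config: not enough LD blocks to tile "
                f"{cfg.n_genes} genes (ran out at {gene_id})"
            )
        gene_blocks[gene_id] = list(range(b, b + span))
        b += span + cfg.gene_block_gap
    return gene_blocks


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw the genotype panel; deterministic under ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    blocks = _plan_blocks(cfg, rng)
    gene_blocks = _plan_genes(cfg, blocks)

    n = cfg.n_samples
    pool = cfg.founder_pool_size
    # breed groups: near-equal contiguous groups 1..6
    group = np.array([(i * 6) // n for i in range(n)]) + 1
    theta = np.array([cfg.admixture[gp - 1] for gp in group])  # P(Angus)

    dosages = np.empty((n, cfg.n_variants))
    spacing = 10_000  # ~chip density of a 250k bovine array
    variants: list[Variant] = []
    for chrom, c0, c1 in blocks:
        L = c1 - c0 + 1
        # ancestral frequencies and Balding-Nichols divergence
        p_anc = rng.uniform(0.1, 0.9, size=L)
        a = p_anc * (1 - cfg.fst) / cfg.fst
        b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
        p_pop = np.stack([rng.beta(a, b), rng.beta(a, b)])  # (2 pops, L)
        p_pop = np.clip(p_pop, 0.02, 0.98)
        # founder haplotype pools, redrawing columns monomorphic across the
        # pools that admixture can actually reach
        used = np.array([theta.max() > 0, theta.min() < 1])
        n_used = int(used.sum())
        haps = (rng.random((2, pool, L)) < p_pop[:, None, :]).astype(np.int8)
        for _ in range(10):
            tot = haps[used].sum(axis=(0, 1))
            bad = (tot == 0) | (tot == n_used * pool)
            if not bad.any():
                break
            haps[:, :, bad] = (
                rng.random((2, pool, int(bad.sum()))) < p_pop[:, None, bad]
            ).astype(np.int8)
        else:
            # stubbornly monomorphic columns: flip one founder allele in a
            # reachable pool so every emitted SNP segregates
            tot = haps[used].sum(axis=(0, 1))
            for col in np.where((tot == 0) | (tot == n_used * pool))[0]:
                pop_i = int(np.where(used)[0][rng.integers(n_used)])
                f_i = int(rng.integers(pool))
                haps[pop_i, f_i, col] = 1 - haps[pop_i, f_i, col]

        # per-haplotype population of origin, then a founder from that pool
        origin = (rng.random((n, 2)) >= theta[:, None]).astype(int)  # 0=Angus
        founder = rng.integers(0, pool, size=(n, 2))
        h0 = haps[origin[:, 0], founder[:, 0], :]
        h1 = haps[origin[:, 1], founder[:, 1], :]
        dosages[:, c0 : c1 + 1] = h0 + h1

    # sequential positions: spacing bp apart within each chromosome
    counters: dict[str, int] = {}
    for j in range(cfg.n_variants):
        chrom = next(c for (c, c0, c1) in blocks if c0 <= j <= c1)
        k = counters.get(chrom, 0)
        counters[chrom] = k + 1
        variants.append(
            Variant(id=f"snp{j + 1:05d}", chrom=chrom, pos=10_000 + k * spacing)
        )

    if cfg.missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.missing_rate
        dosages[miss] = np.nan

    samples = [f"steer{i + 1:04d}" for i in range(n)]
    g = GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)

    truth = SimTruth(blocks=blocks, gene_blocks=gene_blocks)
    truth.gene_models = _gene_models_from_blocks(g, blocks, gene_blocks)
    return g, truth


def _gene_models_from_blocks(
    g: GenotypeMatrix,
    blocks: list[tuple[str, int, int]],
    gene_blocks: dict[str, list[int]],
) -> list[GeneModel]:
    genes = []
    for gene_id, bidx in gene_blocks.items():
        chrom = blocks[bidx[0]][0]
        first = blocks[bidx[0]][1]
        last = blocks[bidx[-1]][2]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                start1=g.variants[first].pos - 500,
                end1=g.variants[last].pos + 500,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def _pick_causal_columns(
    g: GenotypeMatrix, truth: SimTruth, gene_id: str, n_causal: int
) -> list[int]:
    """One causal SNP per block of the gene: the most polymorphic column."""
    cols: list[int] = []
    maf = g.maf()
    for bidx in truth.gene_blocks[gene_id][:n_causal]:
        _, c0, c1 = truth.blocks[bidx]
        c = int(c0 + np.argmax(maf[c0 : c1 + 1]))
        if maf[c] <= 0:
            raise ValueError(
                f"gene {gene_id}: block {bidx} has no polymorphic SNP for a QTL"
            )
        cols.append(c)
    return cols


def simulate_phenotypes(
    g: GenotypeMatrix, cfg: SimConfig, truth: SimTruth
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate the seven traits on top of a simulated genotype panel.

    The polygenic terms across traits are drawn from N(0, S (x) G) where G
    is the realized relationship matrix (normalized to unit mean diagonal)
    and S carries the per-trait polygenic variances and the genetic
    correlation matrix, so the cross-trait correlation of breeding values
    matches the configured rg in distribution.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    n = g.n_samples
    T = len(TRAITS)

    maf = g.maf()
    poly_cols = np.where(maf > 0)[0]
    grm = compute_grm(g.subset(variant_idx=poly_cols))
    gmat = grm.matrix / np.mean(np.diag(grm.matrix))
    d, u = _eigh_psd(gmat)
    L = u * np.sqrt(d)

    h2_poly = np.array([cfg.h2[t] - cfg.qtl_frac_total(t) for t in TRAITS])
    s = np.sqrt(h2_poly)
    sigma_poly = (s[:, None] * np.asarray(cfg.rg, float)) * s[None, :]
    dd, uu = np.linalg.eigh(sigma_poly)
    C = uu * np.sqrt(np.clip(dd, 0.0, None))
    upoly = L @ rng.standard_normal((n, T)) @ C.T  # n x T

    # planted QTL effects on standardized dosages
    x = g.imputed()
    xs = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    bv = upoly.copy()
    causal_cols: dict[str, list[int]] = {}
    truth.causal_snps = {t: [] for t in TRAITS}
    truth.causal_effects = {t: {} for t in TRAITS}
    qtl_genes: list[str] = []
    for q in cfg.qtl_spec:
        if q.gene_id not in causal_cols:
            n_causal = max(
                qq.n_causal_snps for qq in cfg.qtl_spec if qq.gene_id == q.gene_id
            )
            causal_cols[q.gene_id] = _pick_causal_columns(g, truth, q.gene_id, n_causal)
            qtl_genes.append(q.gene_id)
        cols = causal_cols[q.gene_id][: q.n_causal_snps]
        beta = np.sqrt(q.frac / q.n_causal_snps)
        ti = TRAITS.index(q.trait)
        for c in cols:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            bv[:, ti] += sign * beta * xs[:, c]
            vid = g.variants[c].id
            truth.causal_snps[q.trait].append(vid)
            truth.causal_effects[q.trait][vid] = sign * beta
    truth.causal_genes = qtl_genes

    # year assignment and year effects (shared covariate, per-trait effects)
    years = rng.choice(cfg.years, size=n)
    year_eff = {
        (yr, t): rng.normal(0.0, cfg.year_effect_sd)
        for yr in cfg.years
        for t in range(T)
    }
    year_term = np.array([[year_eff[(years[i], t)] for t in range(T)] for i in range(n)])

    group = np.array([(i * 6) // n for i in range(n)]) + 1
    sensory_idx = np.sort(rng.choice(n, size=cfg.n_sensory, replace=False))
    truth.sensory_samples = [g.samples[i] for i in sensory_idx]

    pheno = pd.DataFrame(
        {
            "sample_id": g.samples,
            "year": years,
            "breed_group": group,
        }
    )

    for ti, t in enumerate(TRAITS):
        mean, sd = TRAIT_SCALES[t]
        h2 = cfg.h2[t]
        signal = bv[:, ti] + year_term[:, ti]
        if t == "wbsf":
            # six core peak loads on a log-normal scale, then averaged
            core_var = cfg.core_noise_var
            e_common_var = max(1.0 - h2 - core_var / cfg.n_cores, 0.0)
            e = rng.normal(0.0, np.sqrt(e_common_var), size=n)
            eps = rng.normal(0.0, np.sqrt(core_var), size=(n, cfg.n_cores))
            sigma_log = sd / mean
            mu_log = np.log(mean) - 0.5 * sigma_log**2
            cores = np.exp(
                mu_log + sigma_log * (signal[:, None] + e[:, None] + eps)
            )
            truth.core_loads = cores
            pheno[t] = np.round(cores.mean(axis=1), 3)
        elif t == "cooking_loss":
            e = rng.normal(0.0, np.sqrt(1.0 - h2), size=n)
            loss = np.clip(mean + sd * (signal + e), 2.0, 48.0)
            thaw = rng.normal(320.0, 25.0, size=n)
            cooked = thaw * (1.0 - loss / 100.0)
            pheno[t] = np.round(100.0 * (thaw - cooked) / thaw, 2)
        elif t == "marbling":
            e = rng.normal(0.0, np.sqrt(1.0 - h2), size=n)
            a, b = 0.45, 0.25  # mild right skew on the visual scale
            latent = signal + e
            f = np.sinh(a * latent + b)
            ef = np.sinh(b) * np.exp(a**2 / 2)
            vf = 0.5 * (np.cosh(2 * b) * np.exp(2 * a**2) - 1.0) - ef**2
            score = mean + sd * (f - ef) / np.sqrt(vf)
            pheno[t] = np.clip(np.round(score), 100, 999)
        else:
            # sensory trait: averaged integer panel scores on the 8-point scale
            panelist_lat_sd = cfg.panelist_score_sd / sd
            var_mean_eps = panelist_lat_sd**2 / cfg.panel_size
            e_common_var = max(1.0 - h2 - var_mean_eps, 0.0)
            e = rng.normal(0.0, np.sqrt(e_common_var), size=n)
            eps = rng.normal(0.0, panelist_lat_sd, size=(n, cfg.panel_size))
            scores = np.clip(
                np.round(mean + sd * (signal[:, None] + e[:, None] + eps)), 1, 8
            )
            truth.panel_scores[t] = scores
            col = np.full(n, np.nan)
            col[sensory_idx] = scores[sensory_idx].mean(axis=1)
            pheno[t] = col

    truth.breeding_values = pd.DataFrame(bv, columns=list(TRAITS), index=g.samples)
    return pheno, truth


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def simulate_annotation(
    cfg: SimConfig, truth: SimTruth
) -> tuple[list[GeneModel], GoAnnotationMap, set[str]]:
    """Emit gene models, a GO vocabulary with one planted enriched term,
    and a tissue background list."""
    rng = np.random.default_rng([cfg.seed, 2])
    genes = truth.gene_models
    gene_ids = [g.gene_id for g in genes]

    other_terms = [f"GO:{8000000 + k:07d}" for k in range(cfg.n_go_terms - 1)]
    go = GoAnnotationMap()
    go.term_names[cfg.planted_term] = cfg.planted_term_name
    for k, term in enumerate(other_terms):
        go.term_names[term] = f"synthetic pathway {k + 1}"

    for gid in gene_ids:
        k = min(int(rng.poisson(cfg.terms_per_gene)), len(other_terms))
        if k:
            chosen = rng.choice(len(other_terms), size=k, replace=False)
            go.gene_terms[gid] = {other_terms[int(c)] for c in chosen}

    causal = list(truth.causal_genes)
    non_causal = [gid for gid in gene_ids if gid not in causal]
    planted_members = causal + [
        non_causal[int(i)]
        for i in rng.choice(
            len(non_causal), size=min(cfg.planted_extra_genes, len(non_causal)),
            replace=False,
        )
    ]
    for gid in planted_members:
        go.gene_terms.setdefault(gid, set()).add(cfg.planted_term)

    background = set(causal)
    for gid in non_causal:
        if rng.random() < cfg.background_fraction:
            background.add(gid)
    truth.planted_term = cfg.planted_term
    return genes, go, background


# ---------------------------------------------------------------------------
# One-call orchestration and file output
# ---------------------------------------------------------------------------


def simulate_dataset(cfg: SimConfig | None = None, seed: int | None = None) -> SimDataset:
    """Generate a complete dataset (genotypes, phenotypes, annotation)."""
    if cfg is None:
        cfg = SimConfig()
    if seed is not None:
        cfg = replace_seed(cfg, seed)
    g, truth = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(g, cfg, truth)
    genes, go, background = simulate_annotation(cfg, truth)
    return SimDataset(
        config=cfg,
        genotypes=g,
        phenotypes=pheno,
        genes=genes,
        go=go,
        background=background,
        truth=truth,
    )


def replace_seed(cfg: SimConfig, seed: int) -> SimConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed)


def write_dataset(ds: SimDataset, outdir: str, vcf: bool = True) -> None:
    """Write the dataset in the exact formats the readers accept."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if vcf:
        fio.write_vcf(ds.genotypes, str(out / "genotypes.vcf"))
    fio.write_dosage_tsv(ds.genotypes, str(out / "genotypes.tsv"))
    fio.write_phenotypes(ds.phenotypes, str(out / "phenotypes.tsv"))
    fio.write_bed_genes(ds.genes, str(out / "genes.bed"))
    fio.write_go_annotation(ds.go, str(out / "go_annotation.tsv"))
    fio.write_background(ds.background, str(out / "background.txt"))
    truth = {
        "planted_term": ds.truth.planted_term,
        "causal_genes": ds.truth.causal_genes,
        "causal_snps": ds.truth.causal_snps,
        "blocks": ds.truth.blocks,
        "sensory_samples": ds.truth.sensory_samples,
        "config": {
            k: v
            for k, v in asdict(ds.config).items()
            if not isinstance(v, np.ndarray)
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
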