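"""Readers, writers and genotype quality control.

The pipeline works from a small set of plain-text formats:

* VCF v4.x (GT field only) or an internal dosage TSV for genotypes;
* BED4 for gene coordinates;
* a TSV phenotype/covariate table (``sample_id``, ``year``, ``breed_group``,
  then one column per trait);
* a two/three-column TSV mapping genes to GO terms;
* a one-gene-per-line background list of genes expressed in the target
  tissue (bovine skeletal muscle for the motivating application).

Coordinates are 1-based inclusive everywhere inside the package; the only
conversion happens at the BED boundary (half-open, 0-based).

Dosages are stored as a float matrix with ``numpy.nan`` marking missing
genotypes; every non-missing entry is 0, 1 or 2 copies of the ALT allele.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "GenotypeMatrix",
    "GeneModel",
    "GoAnnotationMap",
    "QcReport",
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_bed_genes",
    "write_bed_genes",
    "read_phenotypes",
    "write_phenotypes",
    "read_go_annotation",
    "write_go_annotation",
    "read_background",
    "write_background",
    "qc_filter",
]

#: Meat-quality trait names used throughout the package.
TRAITS = (
    "wbsf",
    "marbling",
    "cooking_loss",
    "tenderness",
    "juiciness",
    "connective_tissue",
    "flavor",
)

#: Sensory-panel traits, recorded on a subset of animals only.
SENSORY_TRAITS = ("tenderness", "juiciness", "connective_tissue", "flavor")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP. ``pos`` is 1-based."""

    id: str
    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "G"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")


@dataclass
class GenotypeMatrix:
    """Samples x variants allele-dosage matrix.

    ``dosages`` has shape ``(n_samples, n_variants)``; entries are 0/1/2
    ALT-allele counts or NaN for missing calls.
    """

    samples: list[str]
    variants: list[Variant]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"dosage at sample {self.samples[bad[0]]}, variant "
                f"{self.variants[bad[1]].id} is not in {{0,1,2,NaN}}"
            )
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant IDs are not unique")
        self._index = {vid: j for j, vid in enumerate(ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def column(self, variant_id: str) -> np.ndarray:
        """Dosage vector for one variant."""
        try:
            j = self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in genotype matrix") from None
        return self.dosages[:, j]

    def column_index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in genotype matrix") from None

    # -- per-variant / per-sample statistics -----------------------------
    def allele_freq(self) -> np.ndarray:
        """ALT allele frequency per variant, over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-variant mean."""
        x = self.dosages.copy()
        if np.isnan(x).any():
            with np.errstate(invalid="ignore"):
                mu = np.nanmean(x, axis=0)
            mu = np.where(np.isnan(mu), 0.0, mu)
            idx = np.where(np.isnan(x))
            x[idx] = mu[idx[1]]
        return x

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        variant_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            variants=[self.variants[j] for j in vi],
            dosages=self.dosages[np.ix_(si, vi)],
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene span; ``start1``/``end1`` are 1-based inclusive."""

    gene_id: str
    chrom: str
    start1: int
    end1: int

    def __post_init__(self) -> None:
        if self.start1 > self.end1:
            raise ValueError(
                f"gene {self.gene_id}: start1 {self.start1} > end1 {self.end1}"
            )


@dataclass
class GoAnnotationMap:
    """Gene -> set of GO terms, plus term descriptions."""

    gene_terms: dict[str, set[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    def genes_for_term(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_terms.values():
            out |= ts
        return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_MAP = {
    (0, 0): 0.0,
    (0, 1): 1.0,
    (1, 0): 1.0,
    (1, 1): 2.0,
}


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    GT codes map as 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing;
    both ``/`` and ``|`` separators are accepted.  Multiallelic records are
    rejected with the (1-based) record number in the message.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    for rec_no, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise FormatError(
                f"record {rec_no} ({rec.CHROM}:{rec.POS}): non-biallelic site "
                f"(ALT={rec.ALT}); only biallelic SNPs are supported"
            )
        col = np.full(len(samples), np.nan)
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            try:
                col[i] = _GT_MAP[(a, b)]
            except KeyError:
                raise FormatError(
                    f"record {rec_no}: unexpected allele index in GT {a}/{b}"
                ) from None
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(
            Variant(id=vid, chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0])
        )
        columns.append(col)
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF v4.2 with GT-only FORMAT."""
    dose_to_gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for v in g.variants:
            if v.chrom not in chroms:
                chroms.append(v.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        order = sorted(
            range(g.n_variants),
            key=lambda j: (chroms.index(g.variants[j].chrom), g.variants[j].pos),
        )
        for j in order:
            v = g.variants[j]
            gts = [
                dose_to_gt.get(d, "./.") if not np.isnan(d) else "./."
                for d in g.dosages[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Dosage TSV (internal interchange format)
# ---------------------------------------------------------------------------


def write_dosage_tsv(g: GenotypeMatrix, path: str) -> None:
    """Variants as rows: variant_id, chrom, pos, ref, alt, then samples."""
    meta = pd.DataFrame(
        {
            "variant_id": g.variant_ids,
            "chrom": [v.chrom for v in g.variants],
            "pos": [v.pos for v in g.variants],
            "ref": [v.ref for v in g.variants],
            "alt": [v.alt for v in g.variants],
        }
    )
    dose = pd.DataFrame(g.dosages.T, columns=g.samples)
    pd.concat([meta, dose], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta_cols = ["variant_id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise FormatError(f"dosage TSV missing columns: {missing}")
    samples = [c for c in df.columns if c not in meta_cols]
    variants = [
        Variant(
            id=str(r.variant_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
        )
        for r in df.itertuples()
    ]
    return GenotypeMatrix(
        samples=samples, variants=variants, dosages=df[samples].to_numpy(float).T
    )


def read_genotypes(path: str) -> GenotypeMatrix:
    """Dispatch on extension: ``.vcf`` -> VCF, otherwise dosage TSV."""
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return read_vcf(p)
    return read_dosage_tsv(p)


# ---------------------------------------------------------------------------
# BED genes
# ---------------------------------------------------------------------------


def read_bed_genes(path: str) -> list[GeneModel]:
    """Read BED4+ gene records, converting to 1-based inclusive spans."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise FormatError(f"line {line_no}: BED4 needs >= 4 columns")
            chrom, s0, e0, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if s0 >= e0:
                raise FormatError(
                    f"line {line_no}: start {s0} >= end {e0} for gene {name}"
                )
            if name in seen:
                raise FormatError(f"line {line_no}: duplicate gene_id {name}")
            seen.add(name)
            genes.append(GeneModel(gene_id=name, chrom=chrom, start1=s0 + 1, end1=e0))
    return genes


def write_bed_genes(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start1 - 1}\t{g.end1}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(path: str) -> pd.DataFrame:
    """Phenotype/covariate table with one row per sample.

    Required columns: ``sample_id``, ``year``, ``breed_group``; all other
    columns are treated as traits.  ``breed_group`` must be in 1..6.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("sample_id", "year", "breed_group"):
        if col not in df.columns:
            raise FormatError(f"phenotype table missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r} in phenotype table")
    bg = df["breed_group"].dropna()
    if not bg.isin(range(1, 7)).all():
        raise FormatError("breed_group values must be integers in 1..6")
    return df


def write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# GO annotation and background list
# ---------------------------------------------------------------------------


def read_go_annotation(path: str) -> GoAnnotationMap:
    """TSV with columns gene_id, go_term and an optional description."""
    go = GoAnnotationMap()
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "go_term" not in df.columns:
        raise FormatError("GO annotation TSV needs columns gene_id, go_term")
    for r in df.itertuples():
        go.gene_terms.setdefault(str(r.gene_id), set()).add(str(r.go_term))
        if hasattr(r, "description") and isinstance(r.description, str):
            go.term_names[str(r.go_term)] = r.description
    return go


def write_go_annotation(go: GoAnnotationMap, path: str) -> None:
    rows = []
    for gene in sorted(go.gene_terms):
        for term in sorted(go.gene_terms[gene]):
            rows.append((gene, term, go.term_names.get(term, "")))
    pd.DataFrame(rows, columns=["gene_id", "go_term", "description"]).to_csv(
        path, sep="\t", index=False
    )


def read_background(path: str) -> set[str]:
    """One gene ID per line; genes expressed in the target tissue.

    The set need not be a subset of the gene models in use: the expression
    atlas and the annotation can legitimately disagree.
    """
    with open(path) as fh:
        genes = {line.strip() for line in fh if line.strip()}
    if not genes:
        raise FormatError(f"background list {path} is empty")
    return genes


def write_background(genes: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


@dataclass
class QcReport:
    """Counts of samples/variants dropped by each criterion."""

    n_samples_in: int
    n_variants_in: int
    n_samples_dropped_call_rate: int
    n_variants_dropped_maf: int
    n_variants_dropped_call_rate: int
    n_samples_out: int
    n_variants_out: int
    dropped_samples: list[str]
    dropped_variants_maf: list[str]
    dropped_variants_call_rate: list[str]

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "n_samples_in": self.n_samples_in,
            "n_variants_in": self.n_variants_in,
            "n_samples_dropped_call_rate": self.n_samples_dropped_call_rate,
            "n_variants_dropped_maf": self.n_variants_dropped_maf,
            "n_variants_dropped_call_rate": self.n_variants_dropped_call_rate,
            "n_samples_out": self.n_samples_out,
            "n_variants_out": self.n_variants_out,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_tsv(self, path: str) -> None:
        rows = (
            [("sample", s, "call_rate") for s in self.dropped_samples]
            + [("variant", v, "maf") for v in self.dropped_variants_maf]
            + [("variant", v, "call_rate") for v in self.dropped_variants_call_rate]
        )
        pd.DataFrame(rows, columns=["kind", "id", "criterion"]).to_csv(
            path, sep="\t", index=False
        )


class EmptyPanelError(ValueError):
    """QC removed every variant (or every sample)."""


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    var_call_min: float = 0.9,
    sample_call_min: float = 0.85,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply chip-style genotype QC.

    Samples with call rate below ``sample_call_min`` are dropped first;
    variant MAF and call rate are then recomputed on the retained samples,
    and variants with MAF strictly below ``maf_min`` (so MAF == maf_min is
    kept) or call rate strictly below ``var_call_min`` are dropped.
    """
    if g.n_samples == 0 or g.n_variants == 0:
        raise EmptyPanelError("empty genotype matrix")

    keep_s = g.sample_call_rate() >= sample_call_min
    dropped_samples = [s for s, k in zip(g.samples, keep_s) if not k]
    if not keep_s.any():
        raise EmptyPanelError("all samples dropped by call-rate filter")
    g1 = g.subset(sample_idx=np.where(keep_s)[0])

    maf = g1.maf()
    cr = g1.variant_call_rate()
    with np.errstate(invalid="ignore"):
        low_maf = ~(maf >= maf_min)  # NaN MAF (all-missing variant) also drops
        low_cr = cr < var_call_min
    keep_v = ~(low_maf | low_cr)
    if not keep_v.any():
        raise EmptyPanelError("empty panel: all variants dropped by QC")
    ids = g1.variant_ids
    report = QcReport(
        n_samples_in=g.n_samples,
        n_variants_in=g.n_variants,
        n_samples_dropped_call_rate=len(dropped_samples),
        n_variants_dropped_maf=int(low_maf.sum()),
        n_variants_dropped_call_rate=int(low_cr.sum()),
        n_samples_out=int(keep_s.sum()),
        n_variants_out=int(keep_v.sum()),
        dropped_samples=dropped_samples,
        dropped_variants_maf=[ids[j] for j in np.where(low_maf)[0]],
        dropped_variants_call_rate=[ids[j] for j in np.where(low_cr)[0]],
    )
    return g1.subset(variant_idx=np.where(keep_v)[0]), report
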