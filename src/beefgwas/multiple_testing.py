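"""Effective number of independent tests and significance thresholds.

SNPs in LD do not contribute independent tests, so a Bonferroni-style
genome-wide threshold of 0.05 / n_SNPs is too strict.  The effective
number of tests M_eff is computed simpleM-style: chromosomes are processed
in windows of consecutive SNPs, the eigenvalue spectrum of each window's
genotype correlation matrix is taken, and M_eff for the window is the
smallest number of leading eigenvalues whose cumulative share of the total
variance reaches the cutoff C (default 0.995).  The genome-wide threshold
is then 0.05 / sum-of-window-M_eff.

Benjamini-Hochberg adjustment is provided with an ``m_override`` so the
step-up denominator can be M_eff (for GWA p-values) or the number of
tested pathways (for enrichment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import GenotypeMatrix
from .gwa import AssocResult

__all__ = [
    "MeffResult",
    "ThresholdSet",
    "compute_meff",
    "bh_adjust",
    "classify_hits",
]


@dataclass
class MeffResult:
    window_meff: list[int]
    window_spectra: list[np.ndarray]
    total_meff: int
    C: float
    n_variants: int

    @property
    def threshold(self) -> float:
        return 0.05 / self.total_meff


@dataclass(frozen=True)
class ThresholdSet:
    """Per-trait significance tiers.

    ``genome_wide`` defaults to 0.05/M_eff when built from a
    :class:`MeffResult`; ``secondary`` is the fallback tier used only for
    traits where nothing reaches genome-wide significance; ``raw`` is the
    inclusion threshold feeding the enrichment gene lists.
    """

    genome_wide: float = 0.6e-6
    secondary: float = 0.1e-3
    raw: float = 0.05

    def __post_init__(self) -> None:
        if not self.raw >= self.secondary >= self.genome_wide > 0:
            raise ValueError("need raw >= secondary >= genome_wide > 0")

    @classmethod
    def from_meff(
        cls, meff: "MeffResult", secondary: float = 0.1e-3, raw: float = 0.05
    ) -> "ThresholdSet":
        # on small panels 0.05/M_eff can exceed the secondary tier; collapse
        # the two rather than violate the ordering
        gw = meff.threshold
        return cls(genome_wide=gw, secondary=max(secondary, gw), raw=raw)


def _window_meff(x: np.ndarray, C: float) -> tuple[int, np.ndarray]:
    """M_eff of one window of mean-imputed dosage columns."""
    if x.shape[1] == 1:
        return 1, np.array([1.0])
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic variant in window; apply QC first")
    corr = np.corrcoef(x, rowvar=False)
    ev = np.linalg.eigvalsh(corr)[::-1]
    ev = np.clip(ev, 0.0, None)
    total = ev.sum()
    cum = np.cumsum(ev) / total
    k = int(np.searchsorted(cum, C - 1e-12) + 1)
    return min(k, x.shape[1]), ev


def compute_meff(g: GenotypeMatrix, C: float = 0.995, window: int = 133) -> MeffResult:
    """simpleM-style effective number of independent tests.

    Each chromosome is partitioned, in SNP order, into windows of at most
    ``window`` variants; correlations are Pearson on mean-imputed dosages
    (the composite-LD correlation for unphased genotypes).  Negative
    eigenvalues from near-singular windows are clipped at zero before the
    cumulative-variance ratio is formed.
    """
    if not 0 < C <= 1.0:
        raise ValueError("C must be in (0, 1]")
    x = g.imputed()
    chroms = [v.chrom for v in g.variants]
    window_meff: list[int] = []
    spectra: list[np.ndarray] = []
    j = 0
    while j < g.n_variants:
        chrom = chroms[j]
        k = j
        while k < g.n_variants and chroms[k] == chrom and k - j < window:
            k += 1
        m, ev = _window_meff(x[:, j:k], C)
        window_meff.append(m)
        spectra.append(ev)
        j = k
    return MeffResult(
        window_meff=window_meff,
        window_spectra=spectra,
        total_meff=int(sum(window_meff)),
        C=C,
        n_variants=g.n_variants,
    )


def bh_adjust(pvalues: np.ndarray, m_override: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adjusted[i] = min_{j: p_j >= p_i} (m * p_j / rank_j)`` clipped at 1.
    ``m_override`` replaces the number of tests in the numerator (e.g. the
    effective number of independent tests); it must be at least the number
    of p-values supplied.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    m = k if m_override is None else int(m_override)
    if m < k:
        raise ValueError(f"m_override {m} smaller than number of p-values {k}")
    if k == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(k)
    out[order] = adj
    return out


def classify_hits(
    results: list[AssocResult], t: ThresholdSet
) -> list[tuple[AssocResult, str]]:
    """Label each SNP genome_wide / secondary / raw / none for one trait.

    The secondary tier is a per-trait fallback: it is only reported when no
    SNP of the trait reaches the genome-wide threshold.  All comparisons
    are inclusive (p equal to a threshold passes it).
    """
    traits = {r.trait for r in results}
    if len(traits) > 1:
        raise ValueError("classify_hits operates per trait; got several traits")
    any_gw = any(r.ok and r.p <= t.genome_wide for r in results)
    labelled: list[tuple[AssocResult, str]] = []
    for r in results:
        if not r.ok:
            labelled.append((r, "none"))
        elif r.p <= t.genome_wide:
            labelled.append((r, "genome_wide"))
        elif r.p <= t.secondary and not any_gw:
            labelled.append((r, "secondary"))
        elif r.p <= t.raw:
            labelled.append((r, "raw"))
        else:
            labelled.append((r, "none"))
    return labelled
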