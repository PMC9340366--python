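"""Post-genotyping validation: call rates, conversion categories,
Hardy-Weinberg exact testing, QC filtering and MAF spectra.

Genotypes are handled as a dosage matrix (samples x SNPs, alt-allele count
in {0,1,2} with -1 for missing).  Conversion categories approximate
array cluster QC at genotype level: cluster geometry is not available from
dosages, so "Failed" collapses every non-call-rate cluster failure, and the
remaining three categories follow the standard four-way reporting used for
Axiom-style arrays:

* ``PolyHighResolution`` — polymorphic with the minor-allele homozygote
  class observed (all three genotype clusters in the typical case);
* ``MonoHighResolution`` — at most one allele observed (monomorphic);
* ``NoMinorHom`` — polymorphic but no minor-allele homozygote called;
* ``Failed`` — SNP call rate below threshold.

The HWE test is the exact conditional test: given the allele counts, the
probability of each attainable heterozygote count (same parity as the
observed one) is computed and the p-value sums those configurations no
more probable than the observed one.  No mid-p correction; ties (equal
probability) are included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import lgamma, log
from typing import Mapping, Sequence

import numpy as np

from .variantstore import CallSet

__all__ = [
    "GenotypeMatrix",
    "ConversionReport",
    "CATEGORIES",
    "call_rates",
    "classify_conversion",
    "hwe_exact_test",
    "qc_filter",
    "maf_spectrum",
]

MISSING = -1
CATEGORIES = (
    "PolyHighResolution", "MonoHighResolution", "NoMinorHom", "Failed",
)


@dataclass
class GenotypeMatrix:
    """samples x SNPs dosage matrix; entries in {0,1,2} or -1 (missing)."""

    dosages: np.ndarray
    samples: list[str]
    snp_keys: list[tuple]
    population: str = ""

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.snp_keys)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snp_keys)} SNPs"
            )
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1")

    @classmethod
    def from_callset(cls, callset: CallSet, population: str = "",
                     samples: Sequence[str] | None = None) -> "GenotypeMatrix":
        sample_list = list(samples) if samples else list(callset.samples)
        idx = [callset.sample_index(s) for s in sample_list]
        n, m = len(sample_list), len(callset.records)
        d = np.full((n, m), MISSING, dtype=np.int8)
        keys = []
        for j, r in enumerate(callset.records):
            keys.append((r.chrom, r.pos, r.ref, r.alts))
            for i, si in enumerate(idx):
                a, b = r.genotypes[si]
                if a is not None and b is not None:
                    d[i, j] = (a != 0) + (b != 0)
        return cls(dosages=d, samples=sample_list, snp_keys=keys,
                   population=population)

    @property
    def n_snps(self) -> int:
        return len(self.snp_keys)

    def genotype_counts(self) -> np.ndarray:
        """per-SNP (n_hom_ref, n_het, n_hom_alt) counts, missing excluded."""
        out = np.zeros((self.n_snps, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = (self.dosages == g).sum(axis=0)
        return out

    def maf(self) -> np.ndarray:
        """per-SNP minor allele frequency over called alleles (NaN when
        nothing is called)."""
        counts = self.genotype_counts()
        called = counts.sum(axis=1)
        alt = counts[:, 1] + 2 * counts[:, 2]
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called > 0, alt / (2 * called), np.nan)
        return np.minimum(p, 1 - p)


@dataclass
class ConversionReport:
    categories: np.ndarray  # per-SNP category strings
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"category fractions sum to {total}, not 1")


def call_rates(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(per-SNP, per-sample) non-missing fractions."""
    if matrix.dosages.size == 0:
        raise ValueError("empty genotype matrix")
    called = matrix.dosages != MISSING
    return called.mean(axis=0), called.mean(axis=1)


def classify_conversion(matrix: GenotypeMatrix,
                        snp_cr_min: float = 0.97) -> ConversionReport:
    """Classify each SNP into the four conversion categories (see module
    docstring); categories are mutually exclusive and exhaustive."""
    snp_cr, _ = call_rates(matrix)
    counts = matrix.genotype_counts()
    cats = np.empty(matrix.n_snps, dtype=object)
    for j in range(matrix.n_snps):
        n0, n1, n2 = counts[j]
        if snp_cr[j] < snp_cr_min or (n0 + n1 + n2) == 0:
            cats[j] = "Failed"
            continue
        ref_alleles = 2 * n0 + n1
        alt_alleles = 2 * n2 + n1
        if ref_alleles == 0 or alt_alleles == 0:
            cats[j] = "MonoHighResolution"
            continue
        minor_hom = n2 if alt_alleles <= ref_alleles else n0
        cats[j] = "NoMinorHom" if minor_hom == 0 else "PolyHighResolution"
    fractions = {
        c: float((cats == c).sum()) / matrix.n_snps for c in CATEGORIES
    } if matrix.n_snps else {}
    return ConversionReport(categories=cats, fractions=fractions)


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=100_000)
def _hwe_log_probs(n: int, n_a: int) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """log-probabilities of every attainable heterozygote count given n
    genotypes and n_a copies of the minor allele (parity fixed)."""
    hets = tuple(range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2))
    # log P(n_het | n, n_a) up to a constant:
    #   n! / (n_hom_a! n_het! n_hom_A!) * 2^n_het  /  C(2n, n_a)
    base = lgamma(n + 1) - (lgamma(2 * n + 1) - lgamma(n_a + 1)
                            - lgamma(2 * n - n_a + 1))
    lps = []
    for h in hets:
        homa = (n_a - h) // 2
        homA = n - h - homa
        lps.append(base + h * log(2) - lgamma(homa + 1) - lgamma(h + 1)
                   - lgamma(homA + 1))
    return hets, tuple(lps)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    p = sum of the conditional probabilities (heterozygote count given
    allele counts) of every configuration no more probable than the
    observed one.  Monomorphic sites return 1.  Plain exact p, no mid-p;
    equal-probability ties included.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # minor allele copies
    if n_a == 0:
        return 1.0
    hets, lps = _hwe_log_probs(n, n_a)
    probs = np.exp(np.array(lps))
    probs /= probs.sum()  # guard against rounding drift
    obs = hets.index(n_Aa)
    # include ties up to floating error
    p = float(probs[probs <= probs[obs] * (1 + 1e-12)].sum())
    return min(p, 1.0)


def qc_filter(matrix: GenotypeMatrix, cr_min: float = 0.95,
              hwe_alpha: float = 1e-7,
              polymorphic_maf: float = 0.001,
              ) -> tuple[list[tuple], dict[str, int]]:
    """Post-genotyping QC within one population.

    SNPs are removed for call rate < ``cr_min`` or HWE exact p <
    ``hwe_alpha``; a SNP failing both is counted once, under call rate
    (precedence keeps ledger categories disjoint).  Returns the kept SNP
    keys and a ledger with the two-way removal accounting plus the number
    of kept SNPs that are polymorphic (MAF > ``polymorphic_maf``).
    """
    snp_cr, _ = call_rates(matrix)
    counts = matrix.genotype_counts()
    maf = matrix.maf()
    kept: list[tuple] = []
    removed_cr = removed_hwe = 0
    poly = 0
    for j, key in enumerate(matrix.snp_keys):
        if snp_cr[j] < cr_min:
            removed_cr += 1
            continue
        if hwe_exact_test(*counts[j]) < hwe_alpha:
            removed_hwe += 1
            continue
        kept.append(key)
        if not np.isnan(maf[j]) and maf[j] > polymorphic_maf:
            poly += 1
    ledger = {
        "removed_call_rate": removed_cr,
        "removed_hwe": removed_hwe,
        "kept": len(kept),
        "kept_polymorphic": poly,
        "total": matrix.n_snps,
    }
    assert removed_cr + removed_hwe + len(kept) == matrix.n_snps
    return kept, ledger


def maf_spectrum(frequencies: Sequence[float],
                 bin_edges: Sequence[float]) -> np.ndarray:
    """Histogram of MAF values over half-open bins [lo, hi), last bin
    closed at the upper edge; total count conserved."""
    f = np.asarray(list(frequencies), dtype=float)
    if f.size and (f.min() < 0 or f.max() > 0.5):
        raise ValueError("MAF values must lie in [0, 0.5]")
    edges = np.asarray(bin_edges, dtype=float)
    counts, _ = np.histogram(f, bins=edges)
    return counts
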