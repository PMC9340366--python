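"""Relatedness pruning and linkage-disequilibrium decay.

LD is measured as r², the squared Pearson correlation of unphased allele
dosages at two loci, over pairwise-complete samples — the statistic
standard genotype-based LD tooling reports for diploid data.  Close
relatives inflate r², so samples are first pruned on the genomic
relationship matrix (allele-frequency-standardised dosage covariance).
Pairs are binned by physical distance (2 kb units by default, right-closed
bins) and per-bin averages summarise the decay, whose expectation declines
with distance as a function of 4·Ne·c.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genoqc import GenotypeMatrix, MISSING

__all__ = [
    "genomic_relatedness",
    "prune_related",
    "pairwise_r2",
    "bin_ld",
    "ld_decay_summary",
]


def _dosage_float(matrix: GenotypeMatrix) -> np.ndarray:
    d = matrix.dosages.astype(float)
    d[matrix.dosages == MISSING] = np.nan
    return d


def genomic_relatedness(matrix: GenotypeMatrix,
                        maf_min: float = 0.05,
                        freqs: np.ndarray | None = None) -> np.ndarray:
    """Allele-frequency-standardised genomic relationship matrix.

    entry(j,k) = mean over SNPs of (x_j - 2p)(x_k - 2p) / (2p(1-p)),
    with p the alt-allele frequency; monomorphic SNPs and SNPs with
    MAF < ``maf_min`` are skipped, missing genotypes handled
    pairwise-complete.  Diagonal ≈ 1 + inbreeding.

    ``freqs`` supplies external per-SNP alt frequencies; by default p is
    estimated from the matrix itself, which carries the usual ~ -1/(n-1)
    off-diagonal bias in small cohorts.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least two samples")
    d = _dosage_float(matrix)
    called = ~np.isnan(d)
    p = (np.asarray(freqs, dtype=float) if freqs is not None
         else np.nanmean(d, axis=0) / 2.0)
    maf = np.minimum(p, 1 - p)
    use = (maf >= maf_min) & (p > 0) & (p < 1)
    if not use.any():
        raise ValueError("no SNPs usable for relatedness after MAF filter")
    d = d[:, use]
    called = called[:, use]
    p = p[use]
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    z0 = np.where(np.isnan(z), 0.0, z)
    num = z0 @ z0.T
    den = called.astype(float) @ called.astype(float).T
    if (den == 0).any():
        i, j = np.argwhere(den == 0)[0]
        raise ValueError(
            f"samples {matrix.samples[i]!r} and {matrix.samples[j]!r} share "
            "no called SNPs"
        )
    return num / den


def prune_related(relmatrix: np.ndarray, sample_ids: Sequence[str],
                  cutoff: float = 0.12) -> list[str]:
    """Greedy pruning so no retained pair exceeds ``cutoff`` relatedness.

    While any off-diagonal pair exceeds the cutoff, the sample in the most
    above-cutoff pairs is removed (ties broken by removing the
    lexicographically larger id) — a deterministic stand-in for the
    unstated internal order of common rel-cutoff implementations.
    """
    R = np.asarray(relmatrix, dtype=float)
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("relatedness matrix must be symmetric")
    ids = list(sample_ids)
    active = set(range(len(ids)))
    while True:
        viol = {
            i: sum(
                1 for j in active
                if j != i and R[i, j] > cutoff
            )
            for i in active
        }
        worst = max(viol.values(), default=0)
        if worst == 0:
            break
        cands = [i for i, v in viol.items() if v == worst]
        drop = max(cands, key=lambda i: ids[i])
        active.discard(drop)
    return [ids[i] for i in sorted(active)]


def pairwise_r2(matrix: GenotypeMatrix,
                positions: Mapping[tuple, tuple[str, int]] | None = None,
                max_dist: int = 1_001_000,
                max_pairs_window: int = 50_000,
                maf_min: float = 0.05) -> pd.DataFrame:
    """r² for all same-chromosome SNP pairs within ``max_dist`` bp and at
    most ``max_pairs_window`` intervening-SNP separation.

    SNPs are first filtered to MAF >= ``maf_min``.  r² is the squared
    Pearson correlation of dosage vectors over pairwise-complete samples;
    zero-variance pairs are skipped.  ``positions`` maps SNP key ->
    (chrom, pos); by default keys of the form (chrom, pos, ...) are used
    directly.  Returns columns snp_a, snp_b, dist, r2.
    """
    if positions is None:
        positions = {k: (k[0], k[1]) for k in matrix.snp_keys}
    d = _dosage_float(matrix)
    maf = matrix.maf()
    keep = np.nonzero(~np.isnan(maf) & (maf >= maf_min))[0]

    by_chrom: dict[str, list[int]] = {}
    for j in keep:
        chrom, pos = positions[matrix.snp_keys[j]]
        by_chrom.setdefault(chrom, []).append(j)

    rows = []
    for chrom, idx in by_chrom.items():
        idx = sorted(idx, key=lambda j: positions[matrix.snp_keys[j]][1])
        pos = np.array([positions[matrix.snp_keys[j]][1] for j in idx])
        sub = d[:, idx]
        complete = not np.isnan(sub).any()
        if complete:
            # standardise once; per-anchor vectorised dot products
            sd = sub.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                Z = (sub - sub.mean(axis=0)) / sd
        n_samp = sub.shape[0]
        for a in range(len(idx)):
            b_hi = min(len(idx), a + 1 + max_pairs_window)
            b_hi = min(b_hi, int(np.searchsorted(pos, pos[a] + max_dist,
                                                 side="right")))
            if b_hi <= a + 1:
                continue
            if complete:
                if sd[a] == 0:
                    continue
                r_vec = Z[:, a] @ Z[:, a + 1:b_hi] / n_samp
                for boff, r in enumerate(r_vec):
                    b = a + 1 + boff
                    if np.isnan(r):
                        continue  # zero-variance partner skipped
                    rows.append((matrix.snp_keys[idx[a]],
                                 matrix.snp_keys[idx[b]],
                                 int(pos[b] - pos[a]), float(r * r)))
            else:
                for b in range(a + 1, b_hi):
                    r = _pairwise_corr(sub[:, a], sub[:, b])
                    if np.isnan(r):
                        continue
                    rows.append((matrix.snp_keys[idx[a]],
                                 matrix.snp_keys[idx[b]],
                                 int(pos[b] - pos[a]), float(r * r)))
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "dist", "r2"])


def _pairwise_corr(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def bin_ld(pairs: pd.DataFrame, bin_width: int = 2000) -> pd.DataFrame:
    """Average r² in right-closed distance bins (0, w], (w, 2w], ...

    A pair at exactly a bin edge falls in the lower bin (closed right
    edge).  Pair counts are conserved across bins.
    """
    if len(pairs) == 0:
        return pd.DataFrame(columns=["lo", "hi", "n_pairs", "mean_r2"])
    if (pairs["dist"] < 1).any():
        raise ValueError("pair distances must be >= 1")
    idx = (np.ceil(pairs["dist"] / bin_width) - 1).astype(int)
    grouped = pairs.assign(_bin=idx).groupby("_bin")["r2"]
    out = pd.DataFrame({
        "lo": grouped.size().index * bin_width,
        "hi": (grouped.size().index + 1) * bin_width,
        "n_pairs": grouped.size().values,
        "mean_r2": grouped.mean().values,
    }).reset_index(drop=True)
    return out


def ld_decay_summary(bins: pd.DataFrame,
                     query_distances: Sequence[int]) -> dict[int, float]:
    """Mean r² at named distances: the value at distance d is the mean of
    the bin containing d under the right-closed convention (lo < d <= hi).

    Raises when a query lies beyond the covered range.
    """
    if len(bins) == 0:
        raise ValueError("no bins")
    out: dict[int, float] = {}
    for q in query_distances:
        sel = bins[(bins["lo"] < q) & (q <= bins["hi"])]
        if len(sel) == 0:
            lo_cov, hi_cov = bins["lo"].min(), bins["hi"].max()
            if q <= lo_cov or q > hi_cov:
                raise ValueError(
                    f"query distance {q} outside covered range "
                    f"({lo_cov}, {hi_cov}]"
                )
            raise ValueError(f"no pairs observed in the bin containing {q}")
        out[int(q)] = float(sel["mean_r2"].iloc[0])
    return out
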