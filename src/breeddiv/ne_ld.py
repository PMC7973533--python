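"""LD-based effective population size (Waples & Do style).

The estimator uses the mean squared composite (genotype-dosage) correlation
r^2 over pairs of approximately unlinked SNPs. After subtracting the
finite-sample expectation for S >= 30 individuals under random mating,

    r2_drift = mean(r2) - (1/S + 3.19/S^2),

Ne is solved from the drift relation E(r2_drift) = 1/(3 Ne) + 0.69/Ne^2:

    Ne = (1/3 + sqrt(1/9 - 2.76 r2_drift)) / (2 r2_drift).

A parametric 95% confidence interval treats n' * mean(r2)/E(r2) as
chi-square with n' degrees of freedom, n' being the number of SNP pairs
used. Pairs on the same chromosome closer than a configurable separation are
excluded to guard against physical-linkage inflation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from breeddiv.genotypes import GenotypeMatrix


@dataclass(frozen=True)
class NeEstimate:
    ne: float  # may be math.inf when corrected r2 <= 0
    ci95: tuple[float, float]
    maf_cutoff: float
    n_snps: int
    n_pairs: int
    mean_r2: float
    r2_drift: float

    @property
    def ne_rounded(self) -> float:
        return round(self.ne, 1) if math.isfinite(self.ne) else math.inf


def _ne_from_r2_drift(r2d: float) -> float:
    if r2d <= 0:
        return math.inf
    disc = 1.0 / 9.0 - 2.76 * r2d
    if disc < 0:
        # very strong LD: fall back to the first-order relation
        return 1.0 / (3.0 * r2d)
    return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2d)


def ne_from_ld(
    G: GenotypeMatrix,
    markers: pd.DataFrame,
    snp_ids: list[str] | None = None,
    maf_cutoff: float = 0.05,
    min_separation_bp: float = 5e6,
    min_pairs: int = 100,
) -> NeEstimate:
    """Estimate Ne from LD among a thinned SNP subset.

    ``snp_ids`` restricts the computation to a pre-thinned panel (see
    ``genotypes.thin_markers``); SNPs with minor allele frequency below
    ``maf_cutoff`` are excluded, as are same-chromosome pairs closer than
    ``min_separation_bp``.
    """
    id_to_col = {sid: j for j, sid in enumerate(markers["id"])}
    if snp_ids is None:
        cols = np.arange(len(markers))
    else:
        cols = np.array([id_to_col[s] for s in snp_ids])
        cols.sort()
    calls = G.calls[:, cols].astype(np.float64)
    calls[G.calls[:, cols] < 0] = np.nan
    freqs = np.nanmean(calls, axis=0) / 2.0
    mafs = np.minimum(freqs, 1.0 - freqs)
    usable = mafs >= maf_cutoff
    cols = cols[usable]
    calls = calls[:, usable]
    m = len(cols)
    chrom = markers["chrom"].to_numpy()[cols]
    bp = markers["bp"].to_numpy()[cols]

    n = calls.shape[0]
    # standardize; missing entries handled by mean imputation (rare after QC)
    mean = np.nanmean(calls, axis=0)
    inds = np.where(np.isnan(calls))
    calls[inds] = np.take(mean, inds[1])
    X = calls - calls.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 0
    X, chrom, bp = X[:, ok], chrom[ok], bp[ok]
    sd = sd[ok]
    m = X.shape[1]
    X = X / sd

    # accumulate sum of r^2 over admissible pairs in blocks
    total_r2 = 0.0
    n_pairs = 0
    block = 1024
    for lo in range(0, m, block):
        hi = min(lo + block, m)
        C = (X[:, lo:hi].T @ X) / n  # (b, m) correlations
        r2 = C * C
        # mask: upper-triangle pairs (global index j > i), excluding close pairs
        gi = np.arange(lo, hi)[:, None]
        gj = np.arange(m)[None, :]
        mask = gj > gi
        same = chrom[lo:hi][:, None] == chrom[None, :]
        close = same & (np.abs(bp[lo:hi][:, None] - bp[None, :]) < min_separation_bp)
        mask &= ~close
        total_r2 += float(r2[mask].sum())
        n_pairs += int(mask.sum())
    if n_pairs < min_pairs:
        raise ValueError(f"only {n_pairs} usable SNP pairs (< {min_pairs})")

    mean_r2 = total_r2 / n_pairs
    sample_term = 1.0 / n + 3.19 / n**2
    r2_drift = mean_r2 - sample_term
    ne = _ne_from_r2_drift(r2_drift)

    # parametric chi-square CI on mean r2, propagated through the solver
    lo_r2 = n_pairs * mean_r2 / stats.chi2.ppf(0.975, n_pairs)
    hi_r2 = n_pairs * mean_r2 / stats.chi2.ppf(0.025, n_pairs)
    ci = (
        _ne_from_r2_drift(hi_r2 - sample_term),
        _ne_from_r2_drift(lo_r2 - sample_term),
    )
    return NeEstimate(ne, ci, maf_cutoff, m, n_pairs, mean_r2, r2_drift)
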