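"""Runs-of-homozygosity detection with the scanning-window algorithm.

Two phases per individual and chromosome:

1. slide a window of ``window_snps`` consecutive SNPs; a window *passes* if
   it contains at most ``window_het`` heterozygous and at most
   ``window_missing`` missing calls; a SNP is ROH-eligible if the fraction of
   passing windows among the complete windows covering it is at least
   ``window_threshold`` (windows are never truncated or extended at
   chromosome ends, so terminal SNPs are covered by fewer windows);
2. maximal stretches of eligible SNPs become segments if they are first split
   at inter-SNP gaps above ``max_gap_kb`` and then satisfy ``min_snps``,
   ``min_length_kb`` and a density of at least one SNP per
   ``density_kb_per_snp``.

Coordinates are 1-based inclusive bp; segment length is end - start + 1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from breeddiv.genotypes import GenotypeMatrix


@dataclass(frozen=True)
class ROHParams:
    min_length_kb: float = 1000.0
    min_snps: int = 50
    density_kb_per_snp: float = 50.0
    max_gap_kb: float = 100.0
    window_snps: int = 50
    window_het: int = 1
    window_missing: int = 5
    window_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "min_length_kb",
            "min_snps",
            "density_kb_per_snp",
            "max_gap_kb",
            "window_snps",
            "window_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ROHSegment:
    individual: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return round(self.length_bp / 1000.0, 2)


def _eligible_snps(
    het: np.ndarray, miss: np.ndarray, params: ROHParams
) -> np.ndarray:
    """Phase 1: per-SNP eligibility from passing-window hit rates."""
    L = len(het)
    w = params.window_snps
    if L < w:
        return np.zeros(L, dtype=bool)
    het_c = np.concatenate(([0], np.cumsum(het)))
    mis_c = np.concatenate(([0], np.cumsum(miss)))
    het_in = het_c[w:] - het_c[:-w]  # per window start 0..L-w
    mis_in = mis_c[w:] - mis_c[:-w]
    passing = (het_in <= params.window_het) & (mis_in <= params.window_missing)
    pass_c = np.concatenate(([0], np.cumsum(passing)))
    idx = np.arange(L)
    lo = np.maximum(0, idx - w + 1)  # first window start covering SNP
    hi = np.minimum(idx, L - w)  # last window start covering SNP
    covering = hi - lo + 1
    hits = pass_c[hi + 1] - pass_c[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(covering > 0, hits / covering, 0.0)
    return rate >= params.window_threshold


def _stretch_to_segments(
    bp: np.ndarray, idx: np.ndarray, params: ROHParams
) -> list[tuple[int, int, int]]:
    """Phase 2: split an eligible stretch at large gaps and apply thresholds."""
    out = []
    if len(idx) == 0:
        return out
    gaps = np.diff(bp[idx])
    cut = np.flatnonzero(gaps > params.max_gap_kb * 1000.0)
    pieces = np.split(idx, cut + 1)
    for piece in pieces:
        n = len(piece)
        if n < params.min_snps:
            continue
        start, end = int(bp[piece[0]]), int(bp[piece[-1]])
        length = end - start + 1
        if length < params.min_length_kb * 1000.0:
            continue
        if length / n > params.density_kb_per_snp * 1000.0:
            continue
        out.append((start, end, n))
    return out


def detect_roh(
    G: GenotypeMatrix, markers: pd.DataFrame, params: ROHParams | None = None
) -> list[ROHSegment]:
    """Detect ROH segments for every individual across all chromosomes."""
    params = params or ROHParams()
    key = markers[["chrom", "bp"]].apply(tuple, axis=1)
    if not key.is_monotonic_increasing:
        raise ValueError("marker map must be sorted by (chromosome, bp)")
    chroms = markers["chrom"].to_numpy()
    bps = markers["bp"].to_numpy()
    segments: list[ROHSegment] = []
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        bp = bps[cols]
        calls = G.calls[:, cols]
        for i, iid in enumerate(G.ids):
            row = calls[i]
            het = row == 1
            miss = row < 0
            eligible = _eligible_snps(het, miss, params)
            # maximal runs of eligible SNPs
            edges = np.diff(eligible.astype(np.int8))
            starts = list(np.flatnonzero(edges == 1) + 1)
            ends = list(np.flatnonzero(edges == -1) + 1)
            if eligible.size and eligible[0]:
                starts = [0] + starts
            if eligible.size and eligible[-1]:
                ends = ends + [eligible.size]
            for s, e in zip(starts, ends):
                for start, end, n in _stretch_to_segments(
                    bp, np.arange(s, e), params
                ):
                    segments.append(ROHSegment(iid, int(chrom), start, end, n))
    return segments


def covered_genome_length(markers: pd.DataFrame) -> int:
    """Autosomal genome length covered by the array: sum of per-chromosome spans."""
    spans = markers.groupby("chrom")["bp"].agg(["min", "max"])
    return int((spans["max"] - spans["min"]).sum())


def froh(
    segments: list[ROHSegment],
    markers: pd.DataFrame,
    n_individuals: int | None = None,
    scope: str = "population",
) -> float | pd.Series:
    """F_ROH: genome fraction in runs, over the array-covered genome length.

    ``scope='individual'`` returns a per-individual Series (only individuals
    with at least one segment appear); ``scope='population'`` sums run
    lengths across all individuals and divides by covered length times
    ``n_individuals``.
    """
    covered = covered_genome_length(markers)
    if covered <= 0:
        raise ValueError("zero covered genome length")
    if scope == "individual":
        acc: dict[str, int] = {}
        for seg in segments:
            acc[seg.individual] = acc.get(seg.individual, 0) + seg.length_bp
        return pd.Series(
            {k: v / covered for k, v in sorted(acc.items())}, name="F_ROH", dtype=float
        )
    if scope == "population":
        if n_individuals is None:
            raise ValueError("population scope needs n_individuals")
        total = sum(seg.length_bp for seg in segments)
        return total / (covered * n_individuals)
    raise ValueError("scope must be 'population' or 'individual'")


def snp_roh_frequency(
    segments: list[ROHSegment], markers: pd.DataFrame, n_individuals: int
) -> pd.Series:
    """Per-SNP fraction of individuals whose ROH set covers its position."""
    chroms = markers["chrom"].to_numpy()
    bps = markers["bp"].to_numpy()
    counts = np.zeros(len(markers), dtype=np.int64)
    order: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in np.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        order[int(chrom)] = (cols, bps[cols])
    for seg in segments:
        cols, bp = order[seg.chrom]
        lo = np.searchsorted(bp, seg.start_bp, side="left")
        hi = np.searchsorted(bp, seg.end_bp, side="right")
        counts[cols[lo:hi]] += 1
    return pd.Series(counts / n_individuals, index=markers["id"], name="roh_freq")


def roh_summary(
    G: GenotypeMatrix,
    markers: pd.DataFrame,
    length_classes_kb: tuple[float, ...] = (1000.0, 2000.0, 4000.0, 8000.0),
    params: ROHParams | None = None,
) -> pd.DataFrame:
    """Length-class ROH summary table.

    Each class is re-detected with its own ``min_length_kb`` (the SNP-count
    and density constraints interact with minimum length, so filtering the
    shortest-class segments would not be equivalent).
    """
    params = params or ROHParams()
    covered = covered_genome_length(markers)
    n_ind = G.n_individuals
    rows = []
    for min_kb in length_classes_kb:
        segs = detect_roh(G, markers, replace(params, min_length_kb=min_kb))
        total_runs = len(segs)
        per_ind_len = {iid: 0 for iid in G.ids}
        for s in segs:
            per_ind_len[s.individual] += s.length_bp
        pct_genome = float(
            np.mean([v / covered for v in per_ind_len.values()]) * 100.0
        )
        rows.append(
            {
                "min_length_mb": min_kb / 1000.0,
                "pct_genome_in_runs": pct_genome,
                "mean_runs_per_individual": total_runs / n_ind,
                "mean_snps_per_run": (
                    float(np.mean([s.n_snps for s in segs])) if segs else 0.0
                ),
                "mean_froh": pct_genome / 100.0,
                "total_runs": total_runs,
            }
        )
    return pd.DataFrame(rows)


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """Segment list as a TSV-ready table."""
    return pd.DataFrame(
        [
            {
                "individual": s.individual,
                "chrom": s.chrom,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "n_snps": s.n_snps,
                "length_kb": s.length_kb,
            }
            for s in segments
        ],
        columns=["individual", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"],
    )
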