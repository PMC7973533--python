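"""Genotype container, QC filters and marker statistics.

Genotypes live in a :class:`GenotypeMatrix`: individuals x SNPs, int8 dosage
of the A1 allele (0/1/2), -1 for missing. A1 is the minor allele by sample
frequency at read time (ties broken lexically) and stays frozen through all
downstream filtering so allele-frequency shifts keep a well-defined sign.
The on-disk format is text PED/MAP (whitespace separated, alleles A/C/G/T,
0 = missing; MAP columns: chromosome, id, cM (ignored), bp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_FLOOR, ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from breeddiv.pedigree import Pedigree

VALID_ALLELES = frozenset("ACGT0")
MISSING = np.int8(-1)


@dataclass
class GenotypeMatrix:
    """Biallelic genotype calls: A1-dosage matrix with row ids."""

    ids: list[str]
    calls: np.ndarray  # (n_individuals, n_snps) int8; -1 missing

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[0] != len(self.ids):
            raise ValueError("calls must be (n_individuals, n_snps)")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def subset(self, rows: np.ndarray | list[int] | None = None,
               cols: np.ndarray | list[int] | None = None) -> "GenotypeMatrix":
        calls = self.calls
        ids = self.ids
        if rows is not None:
            rows = np.asarray(rows)
            calls = calls[rows]
            ids = [self.ids[i] for i in rows]
        if cols is not None:
            calls = calls[:, np.asarray(cols)]
        return GenotypeMatrix(ids, calls.copy())


def _validate_map(markers: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "id", "bp"}
    if not required <= set(markers.columns):
        raise ValueError(f"marker map needs columns {sorted(required)}")
    key = markers[["chrom", "bp"]].apply(tuple, axis=1)
    if not key.is_monotonic_increasing:
        raise ValueError("marker map must be sorted by (chromosome, bp)")
    if key.duplicated().any():
        raise ValueError("duplicate (chromosome, bp) positions in marker map")
    return markers.reset_index(drop=True)


def read_genotypes(
    ped_path: str | Path, map_path: str | Path
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read text PED/MAP files; returns (genotypes, marker map).

    A1 per SNP is the minor allele by frequency (tie -> lexically smaller);
    half-missing calls are set fully missing with a warning. Monomorphic SNPs
    keep their single observed allele as A2 and are flagged in the map.
    """
    markers = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "bp"],
        dtype={"chrom": int, "id": str, "cm": float, "bp": int},
    )
    markers = _validate_map(markers[["chrom", "id", "cm", "bp"]])
    m = len(markers)

    ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with Path(ped_path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"PED line {lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            ids.append(parts[1])
            row = parts[6:]
            bad = set(row) - VALID_ALLELES
            if bad:
                raise ValueError(
                    f"PED line {lineno}: invalid allele symbol(s) {sorted(bad)}"
                )
            allele_rows.append(
                np.frombuffer("".join(row).encode(), dtype=np.uint8)
            )
    if not ids:
        raise ValueError(f"{ped_path}: no individuals")
    alleles = np.vstack(allele_rows).reshape(len(ids), m, 2)  # byte codes

    zero = ord("0")
    a_missing = alleles == zero
    half = a_missing[:, :, 0] != a_missing[:, :, 1]
    if half.any():
        warnings.warn(f"{int(half.sum())} half-missing call(s) set to missing")
        alleles[half] = zero
        a_missing = alleles == zero

    calls = np.full((len(ids), m), MISSING, dtype=np.int8)
    a1_list, a2_list, mono = [], [], []
    for j in range(m):
        col = alleles[:, j, :].ravel()
        col = col[col != zero]
        symbols, counts = np.unique(col, return_counts=True)
        if len(symbols) > 2:
            raise ValueError(f"SNP {markers['id'][j]!r} has >2 alleles")
        if len(symbols) == 0:
            a1_list.append("0")
            a2_list.append("0")
            mono.append(True)
            continue
        if len(symbols) == 1:
            a1, a2 = "0", chr(symbols[0])
            mono.append(True)
        else:
            order = np.lexsort((symbols, counts))  # ascending count, tie: lexical
            a1, a2 = chr(symbols[order[0]]), chr(symbols[order[1]])
            mono.append(False)
        a1_list.append(a1)
        a2_list.append(a2)
        snp = alleles[:, j, :]
        nonmiss = ~a_missing[:, j, 0] & ~a_missing[:, j, 1]
        if a1 != "0":
            calls[nonmiss, j] = (snp[nonmiss] == ord(a1)).sum(axis=1)
        else:
            calls[nonmiss, j] = 0
    markers = markers.assign(a1=a1_list, a2=a2_list, monomorphic=mono)
    return GenotypeMatrix(ids, calls), markers


def write_genotypes(
    G: GenotypeMatrix, markers: pd.DataFrame, ped_path: str | Path,
    map_path: str | Path
) -> None:
    """Write PED/MAP text files round-tripping with :func:`read_genotypes`."""
    map_out = pd.DataFrame(
        {
            "chrom": markers["chrom"],
            "id": markers["id"],
            "cm": markers["cm"] if "cm" in markers else 0.0,
            "bp": markers["bp"],
        }
    )
    map_out.to_csv(map_path, sep="\t", header=False, index=False)
    a1 = markers["a1"].to_numpy()
    a2 = markers["a2"].to_numpy()
    with Path(ped_path).open("w") as fh:
        for i, iid in enumerate(G.ids):
            row = G.calls[i]
            fields = ["FAM", iid, "0", "0", "0", "-9"]
            for j, g in enumerate(row):
                if g < 0:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [a2[j], a2[j]]
                elif g == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a1[j], a1[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Frequencies, heterozygosity, inbreeding
# ---------------------------------------------------------------------------

def allele_frequencies(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP A1 frequency and call counts among non-missing genotypes."""
    calls = G.calls
    nonmiss = calls >= 0
    n = nonmiss.sum(axis=0)
    dosage = np.where(nonmiss, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, dosage / (2.0 * n), np.nan)
    return pd.DataFrame({"freq_a1": freq, "n_called": n, "all_missing": n == 0})


def qc_filter(
    G: GenotypeMatrix,
    markers: pd.DataFrame,
    mind: float = 0.2,
    geno: float = 0.25,
    maf: float = 0.02,
) -> tuple[GenotypeMatrix, pd.DataFrame, dict[str, int]]:
    """Quality-control filtering in the conventional order.

    1. drop individuals with genotype missingness > ``mind``
    2. drop SNPs with missingness > ``geno`` (computed on kept individuals)
    3. drop SNPs with minor allele frequency < ``maf``

    Returns filtered (genotypes, markers) and a log of counts removed at each
    step. Raises if nothing survives.
    """
    for name, val in (("mind", mind), ("geno", geno), ("maf", maf)):
        if not 0 <= val <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    calls = G.calls
    miss_ind = (calls < 0).mean(axis=1)
    keep_rows = np.flatnonzero(miss_ind <= mind)
    log = {"individuals_removed_mind": G.n_individuals - len(keep_rows)}
    calls = calls[keep_rows]
    if calls.size == 0:
        raise ValueError("all individuals removed by missingness filter")
    miss_snp = (calls < 0).mean(axis=0)
    keep_geno = miss_snp <= geno
    log["snps_removed_geno"] = int((~keep_geno).sum())
    nonmiss = calls >= 0
    n = nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, np.where(nonmiss, calls, 0).sum(axis=0) / (2.0 * n), 0.0)
    mafs = np.minimum(freq, 1.0 - freq)
    keep_maf = keep_geno & (mafs >= maf)
    log["snps_removed_maf"] = int((keep_geno & ~keep_maf).sum())
    keep_cols = np.flatnonzero(keep_maf)
    if keep_cols.size == 0:
        raise ValueError("all SNPs removed by QC filters")
    out = GenotypeMatrix([G.ids[i] for i in keep_rows], calls[:, keep_cols].copy())
    log["individuals_kept"] = out.n_individuals
    log["snps_kept"] = out.n_snps
    return out, markers.iloc[keep_cols].reset_index(drop=True), log


def het_stats(
    G: GenotypeMatrix, small_sample_correction: bool = False
) -> pd.DataFrame:
    """Per-SNP observed (Ho) and expected (He = 2p(1-p)) heterozygosity.

    ``small_sample_correction`` multiplies He by 2n/(2n-1). Monomorphic SNPs
    get Ho = He = 0.
    """
    calls = G.calls
    nonmiss = calls >= 0
    n = nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, ((calls == 1) & nonmiss).sum(axis=0) / n, 0.0)
        p = np.where(n > 0, np.where(nonmiss, calls, 0).sum(axis=0) / (2.0 * n), 0.0)
    he = 2.0 * p * (1.0 - p)
    if small_sample_correction:
        with np.errstate(invalid="ignore", divide="ignore"):
            he = np.where(n > 0, he * (2.0 * n) / (2.0 * n - 1.0), 0.0)
    return pd.DataFrame({"Ho": ho, "He": he, "n_called": n})


def mlh(G: GenotypeMatrix) -> pd.Series:
    """Per-individual multi-locus heterozygosity (N - O)/N.

    N = non-missing genotypes, O = homozygous genotypes for the individual.
    """
    calls = G.calls
    n = (calls >= 0).sum(axis=1)
    het = (calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(n > 0, het / n, np.nan)
    return pd.Series(vals, index=G.ids, name="MLH")


def f_geno(G: GenotypeMatrix) -> pd.Series:
    """Method-of-moments inbreeding F = (O_hom - E_hom)/(N - E_hom) per individual.

    E_hom sums, over the individual's non-missing SNPs, the expected
    homozygosity 1 - 2 p (1-p) 2n/(2n-1) at sample allele frequencies with the
    finite-sample correction (the convention of the usual ``--het`` output).
    """
    calls = G.calls
    nonmiss = calls >= 0
    n_snp = nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_snp > 0, np.where(nonmiss, calls, 0).sum(axis=0) / (2.0 * n_snp), 0.0)
        corr = np.where(n_snp > 0, (2.0 * n_snp) / (2.0 * n_snp - 1.0), 0.0)
    exp_hom_snp = 1.0 - 2.0 * p * (1.0 - p) * corr
    # per-individual sums over that individual's non-missing SNPs
    n_i = nonmiss.sum(axis=1).astype(float)
    o_hom = ((calls == 0) | (calls == 2)).sum(axis=1).astype(float)
    e_hom = nonmiss @ exp_hom_snp
    denom = n_i - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(np.abs(denom) > 1e-12, (o_hom - e_hom) / denom, np.nan)
    return pd.Series(f, index=G.ids, name="F_geno")


# ---------------------------------------------------------------------------
# Disease-variant arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiseaseCounts:
    affected: int
    carrier: int
    normal: int

    def __post_init__(self) -> None:
        if min(self.affected, self.carrier, self.normal) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.affected + self.carrier + self.normal


def genotype_counts_to_allele_freq(c: DiseaseCounts, decimals: int | None = 3) -> float:
    """Mutant (recessive) allele frequency q = (2 affected + carrier) / (2 total)."""
    if c.total == 0:
        raise ValueError("no tested animals")
    q = (2 * c.affected + c.carrier) / (2 * c.total)
    return _round_half_up(q, decimals) if decimals is not None else q


def status_proportions_pct(c: DiseaseCounts) -> tuple[float, float, float]:
    """Observed (affected, carrier, normal) percentages, 2-decimal half-up."""
    if c.total == 0:
        raise ValueError("no tested animals")
    return tuple(
        _round_half_up(100.0 * x / c.total, 2)
        for x in (c.affected, c.carrier, c.normal)
    )  # type: ignore[return-value]


def hwe_expectations(
    q: float, reconcile: bool = False
) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype-class percentages (affected, carrier, normal).

    Returns (q^2, 2q(1-q), (1-q)^2) x 100, each rounded half-up to 2 decimals.
    With ``reconcile=True`` the rounded components are adjusted by largest
    remainder so they sum to exactly 100.00; the default reports each class
    independently rounded.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    # decimal arithmetic: printed frequencies like 0.035 are exact decimals,
    # and binary-float rounding of e.g. 6.755 would otherwise go the wrong way
    qd = Decimal(repr(q))
    raw = (
        qd * qd * 100,
        2 * qd * (1 - qd) * 100,
        (1 - qd) ** 2 * 100,
    )
    cents = Decimal("0.01")
    if not reconcile:
        return tuple(
            float(v.quantize(cents, rounding=ROUND_HALF_UP)) for v in raw
        )  # type: ignore[return-value]
    floors = [v.quantize(cents, rounding=ROUND_FLOOR) for v in raw]
    remainders = [v - f for v, f in zip(raw, floors)]
    short = int((100 - sum(floors)) / cents)
    order = sorted(range(3), key=lambda i: -remainders[i])
    out = floors[:]
    for i in range(short):
        out[order[i % 3]] += cents
    return tuple(float(v) for v in out)  # type: ignore[return-value]


def per_year_status_proportions(
    ped: Pedigree, disease: str, min_tested: int = 10
) -> pd.DataFrame:
    """Per-birth-year proportions of affected/carrier/normal among tested animals.

    Years with fewer than ``min_tested`` tested animals are excluded, as are
    animals with missing or placeholder birth years.
    """
    if disease not in ("tns", "ncl"):
        raise ValueError("disease must be 'tns' or 'ncl'")
    attr = f"{disease}_status"
    rows = []
    for rec in ped:
        status = getattr(rec, attr)
        if status == "untested":
            continue
        if rec.birth_year is None or rec.year_is_placeholder:
            continue
        rows.append((rec.birth_year, status))
    if not rows:
        return pd.DataFrame(
            columns=["affected", "carrier", "normal", "n_tested"]
        ).rename_axis("year")
    df = pd.DataFrame(rows, columns=["year", "status"])
    counts = df.groupby(["year", "status"]).size().unstack(fill_value=0)
    for col in ("affected", "carrier", "normal"):
        if col not in counts:
            counts[col] = 0
    counts["n_tested"] = counts[["affected", "carrier", "normal"]].sum(axis=1)
    counts = counts[counts["n_tested"] >= min_tested]
    out = counts[["affected", "carrier", "normal"]].div(counts["n_tested"], axis=0)
    out["n_tested"] = counts["n_tested"]
    return out


# ---------------------------------------------------------------------------
# Thinning, relationship matrices, pruning
# ---------------------------------------------------------------------------

def thin_markers(
    markers: pd.DataFrame,
    n_segments: int = 12_001,
    n_sample: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Thin to ~independent SNPs: cut the genome into ``n_segments``
    contiguous equal-SNP-count segments, sample ``n_sample`` of them without
    replacement, and take one uniformly random SNP from each.
    """
    m = len(markers)
    if m < n_segments:
        raise ValueError(
            f"{m} SNPs cannot form {n_segments} segments; "
            "reduce n_segments/n_sample for small panels"
        )
    if n_sample > n_segments:
        raise ValueError("n_sample must not exceed n_segments")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bounds = np.linspace(0, m, n_segments + 1).astype(int)
    chosen_segments = rng.choice(n_segments, size=n_sample, replace=False)
    chosen_segments.sort()
    picks = [
        int(rng.integers(bounds[s], bounds[s + 1])) for s in chosen_segments
    ]
    return [markers["id"].iloc[i] for i in picks]


def ibs_distance_matrix(G: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise IBS distance: 1 - mean shared-allele proportion over overlap.

    Per SNP the shared proportion is (2 - |g_i - g_j|)/2. Pairs with no
    overlapping non-missing SNPs get NaN with a warning.
    """
    if G.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    calls = G.calls
    onehot = [np.asarray((calls == k), dtype=np.float64) for k in (0, 1, 2)]
    nonmiss = np.asarray(calls >= 0, dtype=np.float64)
    overlap = nonmiss @ nonmiss.T
    absdiff = np.zeros_like(overlap)
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            absdiff += abs(a - b) * (onehot[a] @ onehot[b].T)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(overlap > 0, absdiff / (2.0 * overlap), np.nan)
    if np.isnan(dist).any():
        warnings.warn("some pairs share no non-missing SNPs; distance undefined")
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=G.ids, columns=G.ids)


def grm(G: GenotypeMatrix) -> pd.DataFrame:
    """VanRaden/GCTA genetic relationship matrix from standardized dosages.

    Per pair, the cross-product of (g - 2p)/sqrt(2p(1-p)) is averaged over
    SNPs non-missing in both individuals. Monomorphic SNPs contribute nothing.
    """
    calls = G.calls
    nonmiss = calls >= 0
    n = nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(nonmiss, calls, 0).sum(axis=0) / (2.0 * n), 0.0)
    sd = np.sqrt(2.0 * p * (1.0 - p))
    poly = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(nonmiss & poly, (calls - 2.0 * p) / np.where(poly, sd, 1.0), 0.0)
    counts = (nonmiss & poly).astype(np.float64)
    pair_n = counts @ counts.T
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(pair_n > 0, (z @ z.T) / pair_n, np.nan)
    return pd.DataFrame(g, index=G.ids, columns=G.ids)


def prune_by_relationship(
    G: GenotypeMatrix, cutoff: float, relmat: pd.DataFrame | None = None
) -> list[str]:
    """Greedy pruning so no retained pair exceeds ``cutoff`` relatedness.

    While any off-diagonal GRM entry exceeds the cutoff, drop from the worst
    pair the member with the higher mean relatedness (ties: higher
    missingness, then later input order). Deterministic.
    """
    if relmat is None:
        relmat = grm(G)
    rel = relmat.to_numpy(dtype=float).copy()
    np.fill_diagonal(rel, 0.0)
    missingness = (G.calls < 0).mean(axis=1)
    active = np.ones(len(rel), dtype=bool)
    while True:
        sub = np.where(np.outer(active, active), rel, -np.inf)
        i, j = np.unravel_index(np.nanargmax(sub), sub.shape)
        if sub[i, j] <= cutoff:
            break
        cand = []
        for k in (i, j):
            mean_rel = rel[k, active].mean()
            cand.append((mean_rel, missingness[k], k))
        cand.sort()
        drop = cand[-1][2]
        active[drop] = False
    return [G.ids[k] for k in np.flatnonzero(active)]


def _round_half_up(x: float, decimals: int) -> float:
    return float(
        Decimal(repr(x)).quantize(Decimal(f"1e-{decimals}"), rounding=ROUND_HALF_UP)
    )
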