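"""Synthetic closed-breed generator: pedigree, gene-dropped SNP genotypes,
planted recessive disease loci, and fixture emission.

The simulator emulates the structure the analyses assume: a multi-decade
closed studbook with popular-sire skew (sires drawn proportionally to
per-male Gamma-distributed "popularity" weights, small shape = strong skew),
founder haplotypes with independently drawn allele frequencies, Mendelian
gene dropping with Poisson recombination along 38 autosomes, and one or two
recessive disease loci each descending from a single founder haplotype.

Haplotypes are stored as founder-origin labels; observable alleles are a
lookup through the founder haplotype table. That makes identity-by-descent
(true inbreeding, allele conservation, disease-status truth) exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from breeddiv.genotypes import GenotypeMatrix, write_genotypes
from breeddiv.pedigree import AnimalRecord, Pedigree, write_pedigree


@dataclass(frozen=True)
class DiseaseLocusSpec:
    """A recessive disease locus to plant in the simulated breed."""

    name: str  # becomes the SNP id of the perfectly tagging marker
    chrom: int
    bp: int
    target_freq: float  # realized cohort allele frequency aimed for
    band: float = 0.03  # acceptable absolute deviation from target
    founder_id: str | None = None  # restrict origin to this founder

    def __post_init__(self) -> None:
        if not 0.0 < self.target_freq < 0.5:
            raise ValueError("target allele frequency must be in (0, 0.5)")


@dataclass(frozen=True)
class BreedSimConfig:
    """Study conditions for the synthetic breed.

    Defaults are a desk-scale closed breed: ~3,000 animals over 1950-2015
    with moderate popular-sire skew, 10,000 SNPs on 38 autosomes of ~5.26 Mb
    at ~20 kb spacing (a compressed genome keeping array-like marker
    density), and the two recessive disease loci at the carrier-frequency
    regimes of the motivating diseases (high ~6.5% and low ~3.5% allele
    frequency, each from a single founder haplotype).
    """

    n_founders: int = 60
    years: tuple[int, int] = (1950, 2015)
    founder_years: int = 8  # founders appear over the first N years
    litters_per_year: int = 10
    litter_size_mean: float = 4.5
    popular_sire_alpha: float = 0.7  # Gamma shape of sire usage weights
    min_breeding_age: int = 2
    max_breeding_age: int = 8
    refpop_window: tuple[int, int] = (2005, 2015)
    n_snps: int = 10_000
    n_chromosomes: int = 38
    chromosome_length_bp: int = 5_263_000
    founder_maf: tuple[float, float] = (0.02, 0.5)
    recomb_rate_cm_per_mb: float = 1.0
    missing_rate: float = 0.0
    genotyping_error_rate: float = 0.0
    n_genotyped: int = 250
    disease_loci: tuple[DiseaseLocusSpec, ...] = (
        DiseaseLocusSpec("tns_like", chrom=4, bp=2_630_000, target_freq=0.065),
        DiseaseLocusSpec("ncl_like", chrom=22, bp=2_630_000, target_freq=0.035,
                         band=0.02),
    )
    test_prob: float = 0.5  # probability a dog has a disease-test record
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 4 or self.litters_per_year < 1:
            raise ValueError("need at least 4 founders and 1 litter per year")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("need at least one SNP per chromosome")


@dataclass
class SimOutput:
    """Simulated breed: pedigree, genotyped subset, marker map and truth."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix  # genotyped subset only
    markers: pd.DataFrame
    truth: pd.DataFrame  # per animal: true IBD inbreeding, disease dosages
    config: BreedSimConfig
    origins: np.ndarray  # (n_animals, 2, n_snps) founder-haplotype labels
    founder_haplotypes: np.ndarray  # (2*n_founders, n_snps) alleles 0/1


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(cfg: BreedSimConfig, rng: np.random.Generator | None = None
                      ) -> Pedigree:
    """Simulate the closed studbook: founders, yearly litters, sire skew."""
    rng = rng or np.random.default_rng(cfg.seed)
    start, end = cfg.years
    records: list[AnimalRecord] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"dog_{counter}"

    birth_year: dict[str, int] = {}
    sex_of: dict[str, str] = {}
    males: list[str] = []
    females: list[str] = []

    founder_years = np.sort(
        rng.integers(start, start + cfg.founder_years, size=cfg.n_founders)
    )
    for i, fy in enumerate(founder_years):
        sex = "male" if i % 2 == 0 else "female"
        aid = new_id()
        records.append(AnimalRecord(id=aid, sex=sex, birth_year=int(fy)))
        birth_year[aid] = int(fy)
        sex_of[aid] = sex
        (males if sex == "male" else females).append(aid)

    popularity: dict[str, float] = {
        m: float(rng.gamma(cfg.popular_sire_alpha, 1.0)) for m in males
    }

    for year in range(start + 1, end + 1):
        sires = [
            m
            for m in males
            if cfg.min_breeding_age <= year - birth_year[m] <= cfg.max_breeding_age
        ]
        dams = [
            f
            for f in females
            if cfg.min_breeding_age <= year - birth_year[f] <= cfg.max_breeding_age
        ]
        if not sires or not dams:
            if year > start + cfg.founder_years + cfg.min_breeding_age:
                raise RuntimeError(
                    f"breed extinct in {year}: no breedable sires or dams; "
                    "increase founders or litters_per_year"
                )
            continue
        n_litters = min(cfg.litters_per_year, len(dams))
        litter_dams = rng.choice(dams, size=n_litters, replace=False)
        weights = np.array([popularity[m] for m in sires])
        weights = weights / weights.sum()
        for dam in litter_dams:
            sire = str(rng.choice(sires, p=weights))
            size = max(1, int(rng.poisson(cfg.litter_size_mean)))
            for _ in range(size):
                sex = "male" if rng.random() < 0.5 else "female"
                aid = new_id()
                records.append(
                    AnimalRecord(
                        id=aid, sire=sire, dam=str(dam), sex=sex, birth_year=year
                    )
                )
                birth_year[aid] = year
                sex_of[aid] = sex
                if sex == "male":
                    males.append(aid)
                    popularity[aid] = float(rng.gamma(cfg.popular_sire_alpha, 1.0))
                else:
                    females.append(aid)
    return Pedigree(records)


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------

def _marker_map(cfg: BreedSimConfig) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    rows = []
    for c in range(cfg.n_chromosomes):
        k = per_chrom[c]
        pos = np.linspace(1, cfg.chromosome_length_bp, k + 1)[:-1].astype(int) + 1
        pos = np.unique(pos)
        for j, bp in enumerate(pos):
            rows.append((c + 1, f"snp_{c + 1}_{j + 1}", 0.0, int(bp)))
    return pd.DataFrame(rows, columns=["chrom", "id", "cm", "bp"])


def _meiosis(
    origins: np.ndarray,
    parent_row: int,
    chrom_slices: list[slice],
    bp_by_chrom: list[np.ndarray],
    morgans: float,
    rng: np.random.Generator,
    out: np.ndarray,
) -> None:
    """One gamete: per chromosome, Poisson crossovers between the two parental
    haplotypes, uniform crossover positions, random starting haplotype."""
    for sl, bp in zip(chrom_slices, bp_by_chrom):
        n_x = rng.poisson(morgans)
        hap = int(rng.integers(0, 2))
        if n_x == 0:
            out[sl] = origins[parent_row, hap, sl]
            continue
        cuts = np.sort(rng.uniform(bp[0], bp[-1], size=n_x))
        switch = np.searchsorted(cuts, bp, side="left")  # crossovers passed
        choose = (hap + switch) % 2
        seg = origins[parent_row, :, sl]
        out[sl] = np.take_along_axis(seg, choose[None, :], axis=0)[0]


def simulate_genotypes(
    ped: Pedigree, cfg: BreedSimConfig, rng: np.random.Generator | None = None
) -> SimOutput:
    """Gene-drop founder haplotypes down the pedigree with recombination."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    markers = _marker_map(cfg)
    m = len(markers)
    chroms = markers["chrom"].to_numpy()
    chrom_slices = []
    bp_by_chrom = []
    for c in range(1, cfg.n_chromosomes + 1):
        idx = np.flatnonzero(chroms == c)
        chrom_slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
        bp_by_chrom.append(markers["bp"].to_numpy()[idx])
    morgans = cfg.chromosome_length_bp / 1e6 * cfg.recomb_rate_cm_per_mb / 100.0

    founder_ids = sorted(ped.founders(), key=ped.index_of)
    n_f = len(founder_ids)
    freqs = rng.uniform(cfg.founder_maf[0], cfg.founder_maf[1], size=m)
    founder_haps = (rng.random((2 * n_f, m)) < freqs).astype(np.int8)

    sire_idx, dam_idx = ped.parent_indices()
    n = len(ped)
    origins = np.zeros((n, 2, m), dtype=np.int16)
    founder_label = {ped.index_of(fid): 2 * k for k, fid in enumerate(founder_ids)}
    gamete = np.empty(m, dtype=np.int16)
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        if s < 0 and d < 0:
            base = founder_label[i]
            origins[i, 0, :] = base
            origins[i, 1, :] = base + 1
            continue
        for slot, p in enumerate((s, d)):
            # closed breed: simulated pedigrees have both parents known
            _meiosis(origins, p, chrom_slices, bp_by_chrom, morgans, rng, gamete)
            origins[i, slot, :] = gamete

    truth = _truth_table(ped, origins)
    genotyped_ids = _pick_genotyped(ped, cfg, rng)
    G = _genotypes_for(ped, origins, founder_haps, genotyped_ids, cfg, rng)
    return SimOutput(ped, G, markers, truth, cfg, origins, founder_haps)


def _truth_table(ped: Pedigree, origins: np.ndarray) -> pd.DataFrame:
    ibd_f = (origins[:, 0, :] == origins[:, 1, :]).mean(axis=1)
    return pd.DataFrame({"id": ped.ids, "true_F_ibd": ibd_f}).set_index("id")


def _pick_genotyped(
    ped: Pedigree, cfg: BreedSimConfig, rng: np.random.Generator
) -> list[str]:
    lo, hi = cfg.refpop_window
    pool = [
        r.id for r in ped if r.birth_year is not None and lo <= r.birth_year <= hi
    ]
    if len(pool) <= cfg.n_genotyped:
        return pool
    pick = rng.choice(len(pool), size=cfg.n_genotyped, replace=False)
    return [pool[i] for i in np.sort(pick)]


def _genotypes_for(
    ped: Pedigree,
    origins: np.ndarray,
    founder_haps: np.ndarray,
    ids: list[str],
    cfg: BreedSimConfig,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    rows = [ped.index_of(i) for i in ids]
    sub = origins[rows]  # (k, 2, m)
    alleles = founder_haps[sub, np.arange(founder_haps.shape[1])[None, None, :]]
    calls = alleles.sum(axis=1).astype(np.int8)
    if cfg.genotyping_error_rate > 0:
        err = rng.random(calls.shape) < cfg.genotyping_error_rate
        calls = np.where(err, rng.integers(0, 3, size=calls.shape, dtype=np.int8), calls)
    if cfg.missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < cfg.missing_rate, -1, calls)
    return GenotypeMatrix(ids, calls)


# ---------------------------------------------------------------------------
# Disease loci
# ---------------------------------------------------------------------------

def plant_disease_locus(
    sim: SimOutput,
    spec: DiseaseLocusSpec,
    rng: np.random.Generator | None = None,
    cohort: list[str] | None = None,
) -> tuple[SimOutput, pd.Series]:
    """Plant a recessive mutation on one founder haplotype.

    The mutation is identified with a single founder haplotype at the marker
    nearest ``spec``'s position; the marker's alleles are rewritten so dosage
    equals mutant-copy count (a perfect tag). The founder haplotype is chosen
    among those whose realized identity-by-descent frequency in the cohort
    falls inside the target band; raises if none qualifies. Returns the
    updated simulation and per-animal statuses, with testing ascertainment
    applied (untested animals keep their truth in the truth table).
    """
    rng = rng or np.random.default_rng(sim.config.seed + 2)
    markers = sim.markers
    sel = markers.index[markers["chrom"] == spec.chrom]
    if len(sel) == 0:
        raise ValueError(f"no markers on chromosome {spec.chrom}")
    j = int(sel[np.argmin(np.abs(markers.loc[sel, "bp"] - spec.bp))])

    cohort = cohort or sim.genotypes.ids
    rows = [sim.pedigree.index_of(i) for i in cohort]
    labels = sim.origins[rows, :, j].ravel()
    counts = np.bincount(labels, minlength=sim.founder_haplotypes.shape[0])
    freqs = counts / labels.size

    candidates = np.flatnonzero(np.abs(freqs - spec.target_freq) <= spec.band)
    if spec.founder_id is not None:
        base = 2 * sorted(sim.pedigree.founders(), key=sim.pedigree.index_of).index(
            spec.founder_id
        )
        candidates = candidates[np.isin(candidates, [base, base + 1])]
    if candidates.size == 0:
        raise RuntimeError(
            f"no founder haplotype reaches {spec.target_freq}+-{spec.band} "
            f"at {spec.name}; widen the band or adjust the simulation"
        )
    mutant = int(rng.choice(candidates))

    founder_haps = sim.founder_haplotypes.copy()
    founder_haps[:, j] = 0
    founder_haps[mutant, j] = 1
    markers = markers.copy()
    markers.loc[j, "id"] = spec.name

    dosage = (sim.origins[:, :, j] == mutant).sum(axis=1)
    status_names = np.array(["normal", "carrier", "affected"])
    true_status = pd.Series(
        status_names[dosage], index=sim.pedigree.ids, name=spec.name
    )
    tested = rng.random(len(true_status)) < sim.config.test_prob
    observed = true_status.where(tested, "untested")

    truth = sim.truth.copy()
    truth[f"{spec.name}_dosage"] = dosage
    truth[f"{spec.name}_tested"] = tested

    geno_rows = [sim.pedigree.index_of(i) for i in sim.genotypes.ids]
    calls = sim.genotypes.calls.copy()
    calls[:, j] = dosage[geno_rows]
    new_G = GenotypeMatrix(sim.genotypes.ids, calls)

    out = SimOutput(
        sim.pedigree, new_G, markers, truth, sim.config, sim.origins, founder_haps
    )
    return out, observed


def apply_statuses(ped: Pedigree, tns: pd.Series | None = None,
                   ncl: pd.Series | None = None) -> Pedigree:
    """Rebuild the pedigree with observed disease-test statuses attached."""
    records = []
    for rec in ped:
        records.append(
            dc_replace(
                rec,
                tns_status=str(tns[rec.id]) if tns is not None else rec.tns_status,
                ncl_status=str(ncl[rec.id]) if ncl is not None else rec.ncl_status,
            )
        )
    return Pedigree(records)


def simulate_breed(
    cfg: BreedSimConfig | None = None,
) -> tuple[SimOutput, dict[str, pd.Series]]:
    """End-to-end simulation: pedigree, genotypes, planted disease loci.

    Returns the simulation output (pedigree carrying observed statuses) and
    the per-disease observed status series.
    """
    cfg = cfg or BreedSimConfig()
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    sim = simulate_genotypes(ped, cfg, rng)
    statuses: dict[str, pd.Series] = {}
    for spec in cfg.disease_loci:
        sim, observed = plant_disease_locus(sim, spec, rng)
        statuses[spec.name] = observed
    if statuses:
        ped = apply_statuses(
            ped,
            tns=statuses.get("tns_like"),
            ncl=statuses.get("ncl_like"),
        )
        sim = SimOutput(
            ped, sim.genotypes, sim.markers, sim.truth, cfg, sim.origins,
            sim.founder_haplotypes,
        )
    return sim, statuses


def emit_fixtures(sim: SimOutput, outdir: str | Path) -> dict[str, Path]:
    """Write pedigree CSV, PED/MAP and truth TSV; deterministic given the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "ped": outdir / "genotypes.ped",
        "map": outdir / "genotypes.map",
        "truth": outdir / "truth.tsv",
    }
    write_pedigree(sim.pedigree, paths["pedigree"])
    markers = sim.markers.copy()
    if "a1" not in markers:
        # allele labels for on-disk representation: A = allele 1 (the founder
        # haplotype "1" allele), G = allele 0
        markers["a1"] = "A"
        markers["a2"] = "G"
    write_genotypes(sim.genotypes, markers, paths["ped"], paths["map"])
    sim.truth.to_csv(paths["truth"], sep="\t")
    return paths
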