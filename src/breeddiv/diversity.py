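"""Genealogical diversity metrics.

Inbreeding coefficients are computed with the Meuwissen & Luo tabular
recursion (diagonal of the additive relationship matrix via per-animal
ancestor tracing), which scales to registry-sized pedigrees in O(n x
ancestors). Kinship (coancestry) between explicit pairs or subsets uses the
standard recursive tabular rules with memoization; a full-database kinship
matrix is refused by design.

Rate-of-inbreeding conventions:

* population rate        dF   = 1 / (2 Ne)
* individual rate        dF_i = 1 - (1 - F)^(1/(EqG - 1))
* depth-adjusted F       F_EqG = 1 - (1 - dF_i)^(mean_EqG - 1)

The realized pedigree effective population size is Ne = 1/(2 mean dF_i) over
a reference cohort, the Gutierrez-style estimator built on individual
increases in inbreeding.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from breeddiv.pedigree import Pedigree, ReferencePopulation

#: animals whose F is considered undefined: neither parent known is a founder
#: (F = 0 by convention); "shallow" flags F values resting on < 1 complete
#: generation so cohort statistics can exclude them.


def inbreeding_coefficients(ped: Pedigree) -> pd.Series:
    """Inbreeding coefficient F for every animal (Meuwissen & Luo recursion).

    Founders and single-parent animals get F = 0. Returns a float Series
    indexed by animal id, in pedigree (topological) order.
    """
    sire, dam = ped.parent_indices()
    n = len(ped)
    F = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        F[i] = _kinship_from_arrays(s, d, sire, dam, F)
    return pd.Series(F, index=ped.ids, name="F")


def _within_family_variance(idx: int, sire: list[int], dam: list[int], F: np.ndarray) -> float:
    s, d = sire[idx], dam[idx]
    if s >= 0 and d >= 0:
        return 0.5 - 0.25 * (F[s] + F[d])
    if s >= 0 or d >= 0:
        return 0.75 - 0.25 * F[max(s, d)]
    return 1.0


def _kinship_from_arrays(
    a: int, b: int, sire: list[int], dam: list[int], F: np.ndarray
) -> float:
    """Coancestry of animals at positions a and b given F of all their ancestors.

    Computes A(a,b)/2 by tracing the combined ancestor contributions L of a
    fictitious offspring of a x b: A_off,off = 1 + F_off = sum_j L_j^2 d_j,
    hence kinship(a, b) = F_off = sum_j L_j^2 d_j - 1 (Meuwissen & Luo 1992).
    """
    # L coefficients accumulated by processing animals in decreasing topological
    # index with a max-heap so each ancestor is visited once.
    contrib: dict[int, float] = {}
    heap: list[int] = []

    def push(idx: int, c: float) -> None:
        if idx in contrib:
            contrib[idx] += c
        else:
            contrib[idx] = c
            heapq.heappush(heap, -idx)

    push(a, 0.5)
    push(b, 0.5)
    total = 0.0
    while heap:
        idx = -heapq.heappop(heap)
        c = contrib.pop(idx)
        total += c * c * _within_family_variance(idx, sire, dam, F)
        for parent in (sire[idx], dam[idx]):
            if parent >= 0:
                push(parent, c / 2.0)
    # offspring own Mendelian term: d_off = 0.5 - 0.25 (F_a + F_b), L_off = 1
    f_off = total + (0.5 - 0.25 * (F[a] + F[b])) - 1.0
    # guard tiny negative rounding noise
    return 0.0 if -1e-14 < f_off < 0 else f_off


class _KinshipTable:
    """Memoized recursive coancestry over a pedigree (iterative, stack-based)."""

    def __init__(self, ped: Pedigree):
        self.sire, self.dam = ped.parent_indices()
        self.cache: dict[tuple[int, int], float] = {}

    def phi(self, a: int, b: int) -> float:
        pending = [(a, b)]
        while pending:
            i, j = pending[-1]
            key = (i, j) if i >= j else (j, i)
            if key in self.cache:
                pending.pop()
                continue
            i, j = key
            if i == j:
                s, d = self.sire[i], self.dam[i]
                if s >= 0 and d >= 0:
                    sub = (min(s, d), max(s, d))[::-1]
                    if sub not in self.cache:
                        pending.append(sub)
                        continue
                    self.cache[key] = 0.5 * (1.0 + self.cache[sub])
                else:
                    self.cache[key] = 0.5
                pending.pop()
                continue
            # i is topologically later than or equal to j; recurse through i's parents
            s, d = self.sire[i], self.dam[i]
            need = []
            for p in (s, d):
                if p >= 0:
                    sub = (max(p, j), min(p, j))
                    if sub not in self.cache:
                        need.append(sub)
            if need:
                pending.extend(need)
                continue
            val = 0.0
            for p in (s, d):
                if p >= 0:
                    val += 0.5 * self.cache[(max(p, j), min(p, j))]
            self.cache[key] = val
            pending.pop()
        a, b = max(a, b), min(a, b)
        return self.cache[(a, b)]


def kinship(ped: Pedigree, a: str, b: str) -> float:
    """Coancestry phi(a, b): probability two randomly drawn alleles are IBD."""
    table = _KinshipTable(ped)
    return table.phi(ped.index_of(a), ped.index_of(b))


MAX_KINSHIP_MATRIX = 20_000


def kinship_matrix(ped: Pedigree, ids: list[str]) -> pd.DataFrame:
    """Symmetric kinship matrix for an explicit id subset.

    Refuses requests beyond ``MAX_KINSHIP_MATRIX`` animals: a full
    registry-scale matrix does not fit in memory; compute mean kinship on
    samples or use :func:`kinship` pairwise instead.
    """
    if len(ids) > MAX_KINSHIP_MATRIX:
        raise ValueError(
            f"kinship matrix for {len(ids)} animals refused "
            f"(limit {MAX_KINSHIP_MATRIX}); subsample or use pairwise kinship()"
        )
    table = _KinshipTable(ped)
    idx = [ped.index_of(i) for i in ids]
    n = len(idx)
    out = np.empty((n, n))
    for r in range(n):
        for c in range(r, n):
            out[r, c] = out[c, r] = table.phi(idx[r], idx[c])
    return pd.DataFrame(out, index=ids, columns=ids)


def equivalent_generations(ped: Pedigree) -> pd.Series:
    """EqG per animal: sum over known ancestors (per path) of (1/2)^generation."""
    sire, dam = ped.parent_indices()
    n = len(ped)
    eqg = np.zeros(n)
    for i in range(n):
        t = 0.0
        for p in (sire[i], dam[i]):
            if p >= 0:
                t += 0.5 * (1.0 + eqg[p])
        eqg[i] = t
    return pd.Series(eqg, index=ped.ids, name="EqG")


def completeness_index(ped: Pedigree, depth: int = 5) -> pd.Series:
    """Pedigree completeness index over ``depth`` ascending generations.

    Per parental side, completeness is the mean over generations 1..depth of
    the filled fraction of that generation's ancestor slots; the index is the
    harmonic mean of the two sides (MacCluer-style), 0 for founders.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    sire, dam = ped.parent_indices()
    n = len(ped)
    # known[i, k] = number of known ancestors of i at generation k+1, counted by path
    known = np.zeros((n, depth), dtype=np.int64)
    for i in range(n):
        row = known[i]
        for p in (sire[i], dam[i]):
            if p >= 0:
                row[0] += 1
                row[1:] += known[p, : depth - 1]
    slots = 2.0 ** np.arange(1, depth + 1)
    pci = np.zeros(n)
    for i in range(n):
        sides = []
        for p in (sire[i], dam[i]):
            if p < 0:
                sides.append(0.0)
            else:
                filled = np.empty(depth)
                filled[0] = 1.0
                filled[1:] = known[p, : depth - 1] / slots[: depth - 1]
                sides.append(filled.mean())
        cs, cd = sides
        pci[i] = 0.0 if cs + cd == 0 else 2.0 * cs * cd / (cs + cd)
    return pd.Series(pci, index=ped.ids, name="PCI")


@dataclass(frozen=True)
class GenerationInterval:
    mean: float | None
    by_pathway: dict[str, float]
    n_pairs: int
    n_skipped: int


def generation_interval(ped: Pedigree) -> GenerationInterval:
    """Mean parental age at offspring birth over the four gametic pathways.

    Pairs with missing or placeholder-flagged birth years on either side are
    skipped and counted.
    """
    diffs: dict[str, list[int]] = {
        "sire-son": [],
        "sire-daughter": [],
        "dam-son": [],
        "dam-daughter": [],
    }
    skipped = 0
    for rec in ped:
        if rec.birth_year is None or rec.year_is_placeholder:
            skipped += sum(p is not None for p in (rec.sire, rec.dam))
            continue
        child_side = {"male": "son", "female": "daughter"}.get(rec.sex, "son")
        for role, parent in (("sire", rec.sire), ("dam", rec.dam)):
            if parent is None:
                continue
            prec = ped[parent]
            if prec.birth_year is None or prec.year_is_placeholder:
                skipped += 1
                continue
            diffs[f"{role}-{child_side}"].append(rec.birth_year - prec.birth_year)
    pooled = [d for v in diffs.values() for d in v]
    if not pooled:
        warnings.warn("no parent-offspring pairs with usable birth years")
        return GenerationInterval(None, {}, 0, skipped)
    by_path = {k: float(np.mean(v)) for k, v in diffs.items() if v}
    return GenerationInterval(float(np.mean(pooled)), by_path, len(pooled), skipped)


def delta_f_overall(ne: float, decimals: int | None = 3) -> float:
    """Population rate of inbreeding dF = 1/(2 Ne), reported to 3 decimals."""
    if ne <= 0:
        raise ValueError("effective population size must be positive")
    val = 1.0 / (2.0 * ne)
    return _round_half_up(val, decimals) if decimals is not None else val


def delta_f_individual(F: float, eqg: float) -> float:
    """Individual rate dF_i = 1 - (1 - F)^(1/(EqG - 1)); undefined for EqG <= 1."""
    if eqg <= 1.0:
        return math.nan
    return 1.0 - (1.0 - F) ** (1.0 / (eqg - 1.0))


def f_adjusted(dfi: float, mean_eqg: float) -> float:
    """Depth-adjusted inbreeding F_EqG = 1 - (1 - dF_i)^(mean_EqG - 1)."""
    if mean_eqg <= 1.0:
        return math.nan
    return 1.0 - (1.0 - dfi) ** (mean_eqg - 1.0)


@dataclass(frozen=True)
class NeEstimateFromPedigree:
    ne: float | None
    mean_dfi: float | None
    n_used: int


def realized_ne_pedigree(
    ped: Pedigree,
    refpop: ReferencePopulation,
    F: pd.Series | None = None,
    eqg: pd.Series | None = None,
) -> NeEstimateFromPedigree:
    """Realized Ne = 1/(2 mean dF_i) over cohort members with defined dF_i.

    Members with EqG <= 1 or with no known parent are excluded.
    """
    if F is None:
        F = inbreeding_coefficients(ped)
    if eqg is None:
        eqg = equivalent_generations(ped)
    dfis = []
    for aid in refpop.members:
        rec = ped[aid]
        if rec.sire is None and rec.dam is None:
            continue
        d = delta_f_individual(float(F[aid]), float(eqg[aid]))
        if not math.isnan(d):
            dfis.append(d)
    if not dfis:
        warnings.warn("no cohort members with defined individual rate of inbreeding")
        return NeEstimateFromPedigree(None, None, 0)
    mean_dfi = float(np.mean(dfis))
    ne = math.inf if mean_dfi <= 0 else 1.0 / (2.0 * mean_dfi)
    return NeEstimateFromPedigree(ne, mean_dfi, len(dfis))


def inbreeding_trend(
    ped: Pedigree,
    mean_eqg: float | None = None,
    F: pd.Series | None = None,
    eqg: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-birth-year means of F, dF_i and F_EqG.

    Excludes animals with undefined F (no known parent), animals with only one
    fully traceable generation (EqG <= 1), placeholder years, and years with a
    single eligible animal. ``mean_eqg`` defaults to the mean EqG of eligible
    animals (held fixed across years).
    """
    if F is None:
        F = inbreeding_coefficients(ped)
    if eqg is None:
        eqg = equivalent_generations(ped)
    rows = []
    for rec in ped:
        if rec.birth_year is None or rec.year_is_placeholder:
            continue
        if rec.sire is None and rec.dam is None:
            continue
        e = float(eqg[rec.id])
        if e <= 1.0:
            continue
        rows.append((rec.birth_year, float(F[rec.id]), e))
    if not rows:
        return pd.DataFrame(
            columns=["mean_F", "mean_dFi", "mean_F_eqg", "n"]
        ).rename_axis("year")
    df = pd.DataFrame(rows, columns=["year", "F", "EqG"])
    if mean_eqg is None:
        mean_eqg = float(df["EqG"].mean())
    df["dFi"] = [delta_f_individual(f, e) for f, e in zip(df["F"], df["EqG"])]
    df["F_eqg"] = [f_adjusted(d, mean_eqg) for d in df["dFi"]]
    g = df.groupby("year")
    out = pd.DataFrame(
        {
            "mean_F": g["F"].mean(),
            "mean_dFi": g["dFi"].mean(),
            "mean_F_eqg": g["F_eqg"].mean(),
            "n": g.size(),
        }
    )
    return out[out["n"] >= 2]


def correlate_inbreeding_estimates(
    x: pd.Series, y: pd.Series, alpha: float = 0.05
) -> tuple[float, tuple[float, float], float]:
    """Pearson r between two per-animal inbreeding estimates on shared ids.

    Returns (r, (ci_lo, ci_hi), p) with a Fisher-z confidence interval.
    """
    shared = x.index.intersection(y.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared animals to correlate")
    xv = np.asarray(x.loc[shared], dtype=float)
    yv = np.asarray(y.loc[shared], dtype=float)
    ok = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[ok], yv[ok]
    if len(xv) < 3:
        raise ValueError("need at least 3 shared non-missing values")
    r, p = stats.pearsonr(xv, yv)
    n = len(xv)
    if abs(r) >= 1.0:
        ci = (r, r)
    else:
        z = np.arctanh(r)
        se = 1.0 / math.sqrt(n - 3)
        crit = stats.norm.ppf(1 - alpha / 2)
        ci = (float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se)))
    return float(r), ci, float(p)


def _round_half_up(x: float, decimals: int) -> float:
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor
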