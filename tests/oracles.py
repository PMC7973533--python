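"""Independent brute-force oracles used by the test suite.

These implementations favour literal enumeration over efficiency and share no
code with the package internals they check.
"""

from __future__ import annotations

import numpy as np

from breeddiv.pedigree import AnimalRecord, Pedigree


# ---------------------------------------------------------------------------
# Random small pedigrees
# ---------------------------------------------------------------------------

def random_small_pedigree(
    rng: np.random.Generator,
    n_founders: int = 4,
    n_offspring: int = 8,
    p_unknown: float = 0.15,
) -> Pedigree:
    """Random pedigree of at most 12 animals; parent slots may be unknown."""
    records = [
        AnimalRecord(id=f"a{i}", birth_year=2000 + i) for i in range(n_founders)
    ]
    for k in range(n_offspring):
        i = n_founders + k
        sire = dam = None
        if rng.random() > p_unknown:
            sire = f"a{rng.integers(0, i)}"
        if rng.random() > p_unknown:
            dam = f"a{rng.integers(0, i)}"
            if dam == sire:
                dam = None
        records.append(
            AnimalRecord(id=f"a{i}", sire=sire, dam=dam, birth_year=2000 + i)
        )
    return Pedigree(records)


# ---------------------------------------------------------------------------
# Exhaustive allele-transmission enumeration: exact F and kinship
# ---------------------------------------------------------------------------

def enumerate_identity(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Exact F and kinship by enumerating every Mendelian transmission.

    Each founder (or unknown-parent slot) contributes unique allele labels;
    every known-parent meiosis is a binary choice. All 2^k inheritance
    configurations are enumerated with equal weight, so the returned
    probabilities are exact up to float summation.

    Returns (F vector, kinship matrix) in pedigree order.
    """
    sire, dam = ped.parent_indices()
    n = len(ped)
    slots = []  # (animal, slot, parent) needing a transmission bit
    for i in range(n):
        for slot, p in enumerate((sire[i], dam[i])):
            if p >= 0:
                slots.append((i, slot, p))
    k = len(slots)
    if k > 22:
        raise ValueError("pedigree too large for exhaustive enumeration")
    nconf = 1 << k
    cfg = np.arange(nconf, dtype=np.int64)
    alleles = np.empty((nconf, n, 2), dtype=np.int16)
    label = 0
    bit = {}
    for b, (i, slot, p) in enumerate(slots):
        bit[(i, slot)] = b
    for i in range(n):
        for slot, p in enumerate((sire[i], dam[i])):
            if p < 0:
                alleles[:, i, slot] = label
                label += 1
            else:
                choice = (cfg >> bit[(i, slot)]) & 1
                alleles[:, i, slot] = alleles[cfg, p, choice]
    F = (alleles[:, :, 0] == alleles[:, :, 1]).mean(axis=0)
    phi = np.empty((n, n))
    for a in range(n):
        for b in range(a, n):
            same = 0.0
            for x in range(2):
                for y in range(2):
                    same += (alleles[:, a, x] == alleles[:, b, y]).mean()
            phi[a, b] = phi[b, a] = same / 4.0
    return F, phi


# ---------------------------------------------------------------------------
# Breadth-first ancestor closure
# ---------------------------------------------------------------------------

def bfs_ancestors(ped: Pedigree, ids: set[str]) -> set[str]:
    out: set[str] = set()
    frontier = set(ids)
    while frontier:
        nxt = set()
        for aid in frontier:
            for p in ped.parents(aid):
                if p is not None and p not in out:
                    out.add(p)
                    nxt.add(p)
        frontier = nxt
    return out


# ---------------------------------------------------------------------------
# Literal scanning-window ROH implementation
# ---------------------------------------------------------------------------

def brute_force_roh(
    genotypes_row: np.ndarray,
    bp: np.ndarray,
    min_length_kb: float,
    min_snps: int,
    density_kb_per_snp: float,
    max_gap_kb: float,
    window_snps: int,
    window_het: int,
    window_missing: int,
    window_threshold: float,
) -> list[tuple[int, int, int]]:
    """Enumerate all windows and stretches literally for one chromosome.

    Returns (start_bp, end_bp, n_snps) tuples.
    """
    L = len(genotypes_row)
    passing = []
    for s in range(0, L - window_snps + 1):
        win = genotypes_row[s : s + window_snps]
        het = int((win == 1).sum())
        mis = int((win < 0).sum())
        passing.append(het <= window_het and mis <= window_missing)
    eligible = []
    for j in range(L):
        covering = [
            s for s in range(max(0, j - window_snps + 1), min(j, L - window_snps) + 1)
        ]
        if not covering:
            eligible.append(False)
            continue
        hit = sum(passing[s] for s in covering) / len(covering)
        eligible.append(hit >= window_threshold)
    segments = []
    j = 0
    while j < L:
        if not eligible[j]:
            j += 1
            continue
        start = j
        while j + 1 < L and eligible[j + 1]:
            j += 1
        stretch = list(range(start, j + 1))
        j += 1
        # split at large gaps
        pieces = [[stretch[0]]]
        for idx in stretch[1:]:
            if bp[idx] - bp[pieces[-1][-1]] > max_gap_kb * 1000:
                pieces.append([idx])
            else:
                pieces[-1].append(idx)
        for piece in pieces:
            nsnp = len(piece)
            length = int(bp[piece[-1]]) - int(bp[piece[0]]) + 1
            if nsnp < min_snps:
                continue
            if length < min_length_kb * 1000:
                continue
            if length / nsnp > density_kb_per_snp * 1000:
                continue
            segments.append((int(bp[piece[0]]), int(bp[piece[-1]]), nsnp))
    return segments
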