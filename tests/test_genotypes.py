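import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breeddiv import genotypes as gt
from breeddiv.genotypes import DiseaseCounts, GenotypeMatrix
from breeddiv.pedigree import AnimalRecord, Pedigree


def small_map(m, chrom=1, spacing=1000):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "id": [f"s{j}" for j in range(m)],
            "cm": 0.0,
            "bp": np.arange(1, m + 1) * spacing,
        }
    )


def random_matrix(rng, n=30, m=60, miss=0.05):
    p = rng.uniform(0.05, 0.95, m)
    calls = ((rng.random((n, m)) < p) * 1 + (rng.random((n, m)) < p) * 1).astype(
        np.int8
    )
    calls[rng.random((n, m)) < miss] = -1
    return GenotypeMatrix([f"i{k}" for k in range(n)], calls)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_read_hand_coded(tmp_path):
    (tmp_path / "x.map").write_text(
        "1 s1 0 100\n1 s2 0 200\n1 s3 0 300\n"
    )
    # s1: i1 AA, i2 AG -> A freq 3/4 -> A1=G; s2: both GG (monomorphic)
    # s3: i1 missing, i2 AA
    (tmp_path / "x.ped").write_text(
        "F i1 0 0 1 0 A A G G 0 0\n"
        "F i2 0 0 2 0 A G G G A A\n"
    )
    G, M = gt.read_genotypes(tmp_path / "x.ped", tmp_path / "x.map")
    assert G.ids == ["i1", "i2"]
    np.testing.assert_array_equal(G.calls[:, 0], [0, 1])  # G-dosage
    assert M["a1"].tolist() == ["G", "0", "0"]
    assert M["monomorphic"].tolist() == [False, True, True]
    np.testing.assert_array_equal(G.calls[:, 2], [-1, 0])


def test_read_rejects_bad_symbol(tmp_path):
    (tmp_path / "x.map").write_text("1 s1 0 100\n")
    (tmp_path / "x.ped").write_text("F i1 0 0 1 0 A X\n")
    with pytest.raises(ValueError, match="invalid allele"):
        gt.read_genotypes(tmp_path / "x.ped", tmp_path / "x.map")


def test_read_rejects_row_length_mismatch(tmp_path):
    (tmp_path / "x.map").write_text("1 s1 0 100\n1 s2 0 200\n")
    (tmp_path / "x.ped").write_text("F i1 0 0 1 0 A A\n")
    with pytest.raises(ValueError, match="expected"):
        gt.read_genotypes(tmp_path / "x.ped", tmp_path / "x.map")


def test_write_read_write_roundtrip(tmp_path, rng):
    G = random_matrix(rng)
    M = small_map(G.n_snps).assign(a1="A", a2="G")
    gt.write_genotypes(G, M, tmp_path / "a.ped", tmp_path / "a.map")
    G1, M1 = gt.read_genotypes(tmp_path / "a.ped", tmp_path / "a.map")
    gt.write_genotypes(G1, M1, tmp_path / "b.ped", tmp_path / "b.map")
    G2, M2 = gt.read_genotypes(tmp_path / "b.ped", tmp_path / "b.map")
    np.testing.assert_array_equal(G1.calls, G2.calls)
    assert G1.ids == G2.ids
    pd.testing.assert_frame_equal(M1, M2)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_drops_expected(rng):
    calls = np.ones((4, 10), dtype=np.int8)
    calls[:, ::2] = 2  # keep variation trivially out of scope; set freqs below
    calls[0, :3] = -1  # individual 0: 30% missing
    G = GenotypeMatrix(["a", "b", "c", "d"], calls)
    # SNP 0: make polymorphic enough for everyone else
    G.calls[1:, 0] = [0, 1, 2]
    G2, M2, log = gt.qc_filter(G, small_map(10), mind=0.2, geno=0.25, maf=0.0)
    assert log["individuals_removed_mind"] == 1
    assert "a" not in G2.ids


def test_qc_maf_filter_and_idempotence(rng):
    G = random_matrix(rng, n=50, m=80, miss=0.02)
    M = small_map(80)
    G1, M1, log1 = gt.qc_filter(G, M, 0.2, 0.25, 0.1)
    mafs = gt.allele_frequencies(G1)["freq_a1"]
    mafs = np.minimum(mafs, 1 - mafs)
    assert (mafs >= 0.1).all()
    G2, M2, log2 = gt.qc_filter(G1, M1, 0.2, 0.25, 0.1)
    np.testing.assert_array_equal(G1.calls, G2.calls)
    assert log2["snps_removed_maf"] == 0 and log2["individuals_removed_mind"] == 0


def test_qc_survivor_counts_match_recount(rng):
    G = random_matrix(rng, n=40, m=100, miss=0.1)
    mind, geno, maf = 0.15, 0.1, 0.05
    G2, M2, log = gt.qc_filter(G, small_map(100), mind, geno, maf)
    # brute-force recount
    keep_ind = [(row < 0).mean() <= mind for row in G.calls]
    sub = G.calls[np.array(keep_ind)]
    n_keep_snps = 0
    for j in range(sub.shape[1]):
        col = sub[:, j]
        if (col < 0).mean() > geno:
            continue
        ok = col[col >= 0]
        f = ok.sum() / (2 * len(ok)) if len(ok) else 0.0
        if min(f, 1 - f) < maf:
            continue
        n_keep_snps += 1
    assert G2.n_individuals == sum(keep_ind)
    assert G2.n_snps == n_keep_snps


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def test_allele_frequency_hand_tally():
    G = GenotypeMatrix(["a", "b", "c"], np.array([[0], [1], [2]], dtype=np.int8))
    out = gt.allele_frequencies(G)
    assert out["freq_a1"].iloc[0] == pytest.approx(0.5)
    G2 = GenotypeMatrix(["a", "b"], np.array([[-1], [-1]], dtype=np.int8))
    out2 = gt.allele_frequencies(G2)
    assert out2["all_missing"].iloc[0]
    assert np.isnan(out2["freq_a1"].iloc[0])


def test_het_stats_extremes():
    G = GenotypeMatrix(["a", "b"], np.array([[1, 0], [1, 0]], dtype=np.int8))
    hs = gt.het_stats(G)
    assert hs["Ho"].iloc[0] == 1.0 and hs["He"].iloc[0] == pytest.approx(0.5)
    assert hs["Ho"].iloc[1] == 0.0 and hs["He"].iloc[1] == 0.0


def test_ho_complement_identity(rng):
    G = random_matrix(rng)
    hs = gt.het_stats(G)
    calls = G.calls
    for j in range(G.n_snps):
        col = calls[:, j][calls[:, j] >= 0]
        hom = ((col == 0) | (col == 2)).mean() if len(col) else 0
        if len(col):
            assert hs["Ho"].iloc[j] + hom == pytest.approx(1.0)


def test_mlh_extremes_and_mean_identity(rng):
    hom = GenotypeMatrix(["a"], np.array([[0, 2, 2]], dtype=np.int8))
    assert gt.mlh(hom)["a"] == 0.0
    het = GenotypeMatrix(["a"], np.array([[1, 1, 1]], dtype=np.int8))
    assert gt.mlh(het)["a"] == 1.0
    G = random_matrix(rng, miss=0.0)
    per_ind_hom = (((G.calls == 0) | (G.calls == 2)).mean(axis=1)).mean()
    assert gt.mlh(G).mean() == pytest.approx(1.0 - per_ind_hom)


def test_f_geno_null_and_selfed(rng):
    # HWE population: mean F close to 0 (within 3 SE)
    n, m = 200, 500
    p = rng.uniform(0.1, 0.9, m)
    calls = ((rng.random((n, m)) < p) * 1 + (rng.random((n, m)) < p) * 1).astype(np.int8)
    F = gt.f_geno(GenotypeMatrix([f"i{k}" for k in range(n)], calls))
    se = F.std() / np.sqrt(n)
    assert abs(F.mean()) < 3 * max(se, 1e-3)
    # fully homozygous individual at 50/50 SNPs -> F -> 1
    half = GenotypeMatrix(
        ["x", "y", "z", "w"],
        np.array(
            [[0, 2] * 20, [2, 0] * 20, [0, 2] * 20, [2, 0] * 20], dtype=np.int8
        ),
    )
    assert gt.f_geno(half).mean() == pytest.approx(1.0)


def test_f_geno_one_generation_selfing(rng):
    """Selfed offspring of HWE parents have expected F near 1/2."""
    n, m = 300, 400
    p = rng.uniform(0.2, 0.8, m)
    parent_h1 = (rng.random((n, m)) < p).astype(np.int8)
    parent_h2 = (rng.random((n, m)) < p).astype(np.int8)
    pick1 = rng.integers(0, 2, (n, m)).astype(bool)
    pick2 = rng.integers(0, 2, (n, m)).astype(bool)
    g1 = np.where(pick1, parent_h1, parent_h2)
    g2 = np.where(pick2, parent_h1, parent_h2)
    calls = (g1 + g2).astype(np.int8)
    F = gt.f_geno(GenotypeMatrix([f"i{k}" for k in range(n)], calls))
    se = F.std() / np.sqrt(n)
    assert abs(F.mean() - 0.5) < 3 * max(se, 5e-3)


# ---------------------------------------------------------------------------
# Disease arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts,expected",
    [
        ((58, 1448, 4933), 0.121),
        ((22, 614, 1395), 0.162),
        ((44, 257, 5655), 0.029),
        ((0, 0, 10), 0.0),
    ],
)
def test_counts_to_allele_freq(counts, expected):
    assert gt.genotype_counts_to_allele_freq(DiseaseCounts(*counts)) == expected


def test_counts_to_allele_freq_zero_total():
    with pytest.raises(ValueError):
        gt.genotype_counts_to_allele_freq(DiseaseCounts(0, 0, 0))


@pytest.mark.parametrize(
    "q,expected",
    [
        (0.077, (0.59, 14.21, 85.19)),
        (0.035, (0.12, 6.76, 93.12)),
        (0.0, (0.0, 0.0, 100.0)),
    ],
)
def test_hwe_expectations(q, expected):
    assert gt.hwe_expectations(q) == expected


@settings(max_examples=50, derandomize=True)
@given(q=st.floats(0.0, 1.0))
def test_hwe_reconciled_sums_to_100(q):
    a, c, n = gt.hwe_expectations(q, reconcile=True)
    assert round(a + c + n, 2) == 100.0


def test_per_year_status_proportions():
    recs = []
    # 2005: 10 tested, 4 carriers; 2006: 9 tested -> excluded
    for i in range(10):
        recs.append(
            AnimalRecord(
                id=f"a{i}",
                birth_year=2005,
                tns_status="carrier" if i < 4 else "normal",
            )
        )
    for i in range(9):
        recs.append(AnimalRecord(id=f"b{i}", birth_year=2006, tns_status="normal"))
    recs.append(AnimalRecord(id="untested", birth_year=2005))
    ped = Pedigree(recs)
    out = gt.per_year_status_proportions(ped, "tns")
    assert list(out.index) == [2005]
    assert out.loc[2005, "carrier"] == pytest.approx(0.4)
    assert out.loc[2005, "n_tested"] == 10


# ---------------------------------------------------------------------------
# Thinning / GRM / pruning
# ---------------------------------------------------------------------------

def test_thin_markers_segments_and_determinism():
    M = small_map(24_002)
    subset = gt.thin_markers(M, n_segments=12_001, n_sample=10_000, seed=42)
    assert len(subset) == 10_000
    assert len(set(subset)) == 10_000
    subset2 = gt.thin_markers(M, n_segments=12_001, n_sample=10_000, seed=42)
    assert subset == subset2
    with pytest.raises(ValueError, match="segments"):
        gt.thin_markers(small_map(100), 12_001, 10_000, 1)


def test_ibs_identical_and_opposite():
    G = GenotypeMatrix(
        ["a", "b", "c"],
        np.array([[0, 2, 1], [0, 2, 1], [2, 0, 1]], dtype=np.int8),
    )
    D = gt.ibs_distance_matrix(G)
    assert D.loc["a", "b"] == 0.0
    assert D.loc["a", "a"] == 0.0
    assert D.loc["a", "c"] == pytest.approx(2 / 3)  # two opposite + one equal het
    opp = GenotypeMatrix(["a", "b"], np.array([[0, 0], [2, 2]], dtype=np.int8))
    assert gt.ibs_distance_matrix(opp).loc["a", "b"] == 1.0
    assert np.allclose(D.to_numpy(), D.to_numpy().T)


def test_grm_diagonal_and_parent_offspring(rng):
    n, m = 100, 800
    p = rng.uniform(0.1, 0.9, m)
    h = lambda: (rng.random((n, m)) < p).astype(np.int8)  # noqa: E731
    # explicit haplotypes for parents A and B; offspring get one from each
    a1, a2, b1, b2 = h(), h(), h(), h()
    A = a1 + a2
    B = b1 + b2
    off = np.where(rng.integers(0, 2, (n, m)) == 0, a1, a2) + np.where(
        rng.integers(0, 2, (n, m)) == 0, b1, b2
    )
    ids = (
        [f"A{k}" for k in range(n)]
        + [f"B{k}" for k in range(n)]
        + [f"O{k}" for k in range(n)]
    )
    G = GenotypeMatrix(ids, np.vstack([A, B, off]).astype(np.int8))
    K = gt.grm(G).to_numpy()
    # diagonal ~ 1 for non-inbred; parent-offspring ~ 0.5
    assert abs(np.diag(K).mean() - 1.0) < 0.05
    po = np.array([K[k, 2 * n + k] for k in range(n)])
    assert abs(po.mean() - 0.5) < 3 * po.std() / np.sqrt(n) + 0.02


def test_prune_identity_and_duplicate(rng):
    n, m = 20, 400
    p = rng.uniform(0.2, 0.8, m)
    calls = ((rng.random((n, m)) < p) * 1 + (rng.random((n, m)) < p) * 1).astype(np.int8)
    calls[1] = calls[0]  # duplicate pair
    G = GenotypeMatrix([f"i{k}" for k in range(n)], calls)
    kept = gt.prune_by_relationship(G, cutoff=0.45)
    assert len(kept) == n - 1
    assert ("i0" in kept) != ("i1" in kept)
    # unrelated individuals: nothing removed
    calls2 = ((rng.random((n, m)) < p) * 1 + (rng.random((n, m)) < p) * 1).astype(np.int8)
    G2 = GenotypeMatrix([f"j{k}" for k in range(n)], calls2)
    assert gt.prune_by_relationship(G2, cutoff=0.45) == G2.ids


def test_prune_postcondition(breed_sim):
    sim, _ = breed_sim
    sub = sim.genotypes.subset(rows=np.arange(60))
    relmat = gt.grm(sub)
    kept = gt.prune_by_relationship(sub, cutoff=0.45, relmat=relmat)
    vals = relmat.loc[kept, kept].to_numpy().copy()
    np.fill_diagonal(vals, 0.0)
    assert vals.max() <= 0.45 + 1e-12
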