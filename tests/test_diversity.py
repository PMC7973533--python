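import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breeddiv import diversity
from breeddiv.pedigree import AnimalRecord, Pedigree, select_reference_population
from oracles import enumerate_identity, random_small_pedigree


def test_offspring_of_full_sibs(fullsib_offspring_pedigree):
    F = diversity.inbreeding_coefficients(fullsib_offspring_pedigree)
    assert F["x"] == pytest.approx(0.25, abs=1e-15)
    assert F["s1"] == 0.0


def test_unrelated_parents_give_zero(trio_pedigree):
    F = diversity.inbreeding_coefficients(trio_pedigree)
    assert F["o"] == 0.0


def test_kinship_parent_offspring_and_sibs(fullsib_offspring_pedigree):
    ped = fullsib_offspring_pedigree
    assert diversity.kinship(ped, "p1", "s1") == pytest.approx(0.25)
    assert diversity.kinship(ped, "s1", "s2") == pytest.approx(0.25)
    assert diversity.kinship(ped, "p1", "p2") == 0.0


def test_f_equals_parent_kinship_random(rng):
    """Two code paths must agree: F(child) == phi(sire, dam)."""
    for _ in range(20):
        ped = random_small_pedigree(rng, 4, 8, p_unknown=0.0)
        F = diversity.inbreeding_coefficients(ped)
        for rec in ped:
            if rec.sire and rec.dam:
                assert F[rec.id] == pytest.approx(
                    diversity.kinship(ped, rec.sire, rec.dam), abs=1e-12
                )


def test_f_and_phi_match_exhaustive_enumeration(rng):
    for _ in range(25):
        ped = random_small_pedigree(rng, 4, 8)
        F_oracle, phi_oracle = enumerate_identity(ped)
        F = diversity.inbreeding_coefficients(ped)
        np.testing.assert_allclose(F.to_numpy(), F_oracle, atol=1e-12)
        mat = diversity.kinship_matrix(ped, ped.ids).to_numpy()
        np.testing.assert_allclose(mat, phi_oracle, atol=1e-12)


def test_self_kinship_identity(fullsib_offspring_pedigree):
    ped = fullsib_offspring_pedigree
    F = diversity.inbreeding_coefficients(ped)
    for aid in ped.ids:
        assert diversity.kinship(ped, aid, aid) == pytest.approx(
            (1 + F[aid]) / 2, abs=1e-14
        )


def test_additive_matrix_positive_semidefinite(rng):
    ped = random_small_pedigree(rng, 4, 8, p_unknown=0.0)
    A = 2 * diversity.kinship_matrix(ped, ped.ids).to_numpy()
    assert np.allclose(A, A.T)
    assert np.linalg.eigvalsh(A).min() > -1e-8


def test_kinship_matrix_refuses_huge_request(fullsib_offspring_pedigree):
    ids = [f"x{i}" for i in range(diversity.MAX_KINSHIP_MATRIX + 1)]
    with pytest.raises(ValueError, match="refused"):
        diversity.kinship_matrix(fullsib_offspring_pedigree, ids)


def test_equivalent_generations_closed_forms():
    # both parents known, grandparents unknown -> EqG = 1
    ped = Pedigree(
        [
            AnimalRecord(id="s"),
            AnimalRecord(id="d"),
            AnimalRecord(id="o", sire="s", dam="d"),
        ]
    )
    eqg = diversity.equivalent_generations(ped)
    assert eqg["o"] == 1.0 and eqg["s"] == 0.0
    # complete pedigree to depth d -> EqG = d
    recs = [AnimalRecord(id=f"g0_{i}") for i in range(8)]
    layer = [f"g0_{i}" for i in range(8)]
    for depth in range(1, 4):
        new = []
        for j in range(len(layer) // 2):
            aid = f"g{depth}_{j}"
            recs.append(
                AnimalRecord(id=aid, sire=layer[2 * j], dam=layer[2 * j + 1])
            )
            new.append(aid)
        layer = new
    ped = Pedigree(recs)
    assert diversity.equivalent_generations(ped)["g3_0"] == pytest.approx(3.0)


def test_eqg_matches_brute_force(rng):
    for _ in range(10):
        ped = random_small_pedigree(rng, 4, 8)
        eqg = diversity.equivalent_generations(ped)
        sire, dam = ped.parent_indices()

        def brute(i):
            total = 0.0
            stack = [(i, 0)]
            while stack:
                j, g = stack.pop()
                for p in (sire[j], dam[j]):
                    if p >= 0:
                        total += 0.5 ** (g + 1)
                        stack.append((p, g + 1))
            return total

        for i, aid in enumerate(ped.ids):
            assert eqg[aid] == pytest.approx(brute(i), abs=1e-12)


def test_pci_bounds_and_closed_cases(fullsib_offspring_pedigree):
    ped = fullsib_offspring_pedigree
    pci = diversity.completeness_index(ped, depth=2)
    assert pci["p1"] == 0.0  # founder
    # x: parents known, grandparents known -> complete to depth 2
    assert pci["x"] == pytest.approx(1.0)
    assert ((pci >= 0) & (pci <= 1)).all()


def test_pci_half_known_hand_computed():
    # offspring with known sire (founder) and unknown dam, depth 2:
    # sire side: gen1 = 1, gen2 = 0 -> 0.5; dam side 0 -> harmonic mean 0
    ped = Pedigree([AnimalRecord(id="s"), AnimalRecord(id="o", sire="s")])
    pci = diversity.completeness_index(ped, depth=2)
    assert pci["o"] == 0.0
    # both parents known, no grandparents: each side (1 + 0)/2 = 0.5
    ped2 = Pedigree(
        [
            AnimalRecord(id="s"),
            AnimalRecord(id="d"),
            AnimalRecord(id="o", sire="s", dam="d"),
        ]
    )
    assert diversity.completeness_index(ped2, depth=2)["o"] == pytest.approx(0.5)


def test_generation_interval_trio(trio_pedigree):
    gi = diversity.generation_interval(trio_pedigree)
    # sire born 1990, dam 1992, offspring 1996 -> (6 + 4)/2 = 5
    assert gi.mean == pytest.approx(5.0)
    assert gi.n_pairs == 2


def test_generation_interval_excludes_placeholders():
    from breeddiv.pedigree import assign_placeholder_years

    ped = Pedigree(
        [
            AnimalRecord(id="s", birth_year=1990),
            AnimalRecord(id="d"),  # missing year -> placeholder
            AnimalRecord(id="o", sire="s", dam="d", birth_year=1996),
        ]
    )
    ped = assign_placeholder_years(ped, 1950)
    gi = diversity.generation_interval(ped)
    assert gi.mean == pytest.approx(6.0)  # only the sire pathway counts
    assert gi.n_skipped == 1


def test_delta_f_overall_paper_values():
    assert diversity.delta_f_overall(123.5) == 0.004
    assert diversity.delta_f_overall(65.4) == 0.008
    assert diversity.delta_f_overall(0.5) == 1.0
    with pytest.raises(ValueError):
        diversity.delta_f_overall(0.0)


def test_delta_f_individual_closed_forms():
    assert diversity.delta_f_individual(0.0, 5.0) == 0.0
    assert diversity.delta_f_individual(0.75, 3.0) == pytest.approx(0.5)
    assert math.isnan(diversity.delta_f_individual(0.2, 1.0))


@settings(max_examples=60, derandomize=True)
@given(
    F=st.floats(0.0, 0.95),
    eqg=st.floats(1.2, 15.0),
)
def test_dfi_feqg_round_trip(F, eqg):
    """delta_f_individual and f_adjusted are mutual inverses at equal depth."""
    dfi = diversity.delta_f_individual(F, eqg)
    back = diversity.f_adjusted(dfi, eqg)
    assert back == pytest.approx(F, abs=1e-10)


def test_realized_ne_constant_rate():
    """Cohort where every member has dF_i = 0.004 yields Ne = 125."""
    import pandas as pd

    recs = [AnimalRecord(id="gs"), AnimalRecord(id="gd")]
    recs += [
        AnimalRecord(id="s", sire="gs", dam="gd"),
        AnimalRecord(id="d", sire="gs", dam="gd"),
    ]
    recs += [
        AnimalRecord(id=f"m{i}", sire="s", dam="d", birth_year=2010) for i in range(5)
    ]
    ped = Pedigree(recs)
    rp = select_reference_population(ped, 2005, 2015)
    eqg = diversity.equivalent_generations(ped)
    # invert the dF_i formula so each member carries exactly dF_i = 0.004
    F_vals = pd.Series(
        {aid: 1.0 - (1.0 - 0.004) ** (eqg[aid] - 1.0) for aid in ped.ids}
    )
    est = diversity.realized_ne_pedigree(ped, rp, F_vals, eqg)
    assert est.ne == pytest.approx(125.0)
    assert est.n_used == 5


def _wright_fisher_pedigree(N, gens, seed):
    """Discrete generations of constant size N; parents drawn uniformly."""
    rng = np.random.default_rng(seed)
    recs = []
    males = [f"g0m{i}" for i in range(N // 2)]
    females = [f"g0f{i}" for i in range(N // 2)]
    recs += [AnimalRecord(id=m, sex="male", birth_year=2000) for m in males]
    recs += [AnimalRecord(id=f, sex="female", birth_year=2000) for f in females]
    for g in range(1, gens + 1):
        nm, nf = [], []
        for i in range(N):
            aid = f"g{g}i{i}"
            recs.append(
                AnimalRecord(
                    id=aid,
                    sire=str(rng.choice(males)),
                    dam=str(rng.choice(females)),
                    sex="male" if i < N // 2 else "female",
                    birth_year=2000 + g,
                )
            )
            (nm if i < N // 2 else nf).append(aid)
        males, females = nm, nf
    return Pedigree(recs)


def test_realized_ne_recovers_constant_census():
    """Random mating at constant size N: estimate within 25% at depth >= 8."""
    for N, seed in ((40, 0), (60, 1)):
        ped = _wright_fisher_pedigree(N, 10, seed)
        rp = select_reference_population(ped, 2009, 2010)
        est = diversity.realized_ne_pedigree(ped, rp)
        assert abs(est.ne - N) / N < 0.25, (N, est.ne)


def test_realized_ne_decreases_with_sire_skew():
    """Stronger popular-sire skew yields a smaller realized Ne."""
    from breeddiv.simulate import BreedSimConfig, simulate_pedigree

    def ne_at(alpha, seed):
        cfg = BreedSimConfig(
            n_founders=30,
            years=(1985, 2015),
            litters_per_year=8,
            popular_sire_alpha=alpha,
            n_snps=100,
            n_chromosomes=2,
            disease_loci=(),
            seed=seed,
        )
        ped = simulate_pedigree(cfg)
        rp = select_reference_population(ped, 2005, 2015)
        return diversity.realized_ne_pedigree(ped, rp).ne

    skewed = np.mean([ne_at(0.1, s) for s in range(3)])
    even = np.mean([ne_at(20.0, s) for s in range(3)])
    assert skewed < even


def test_trend_exclusions():
    recs = [
        AnimalRecord(id="gs"),
        AnimalRecord(id="gd"),
        AnimalRecord(id="s", sire="gs", dam="gd", birth_year=1995),
        AnimalRecord(id="d", sire="gs", dam="gd", birth_year=1995),
    ]
    # one dog in 1999 -> year excluded; two dogs in 2001 -> kept
    recs.append(AnimalRecord(id="only", sire="s", dam="d", birth_year=1999))
    recs += [
        AnimalRecord(id="a", sire="s", dam="d", birth_year=2001),
        AnimalRecord(id="b", sire="s", dam="d", birth_year=2001),
    ]
    ped = Pedigree(recs)
    trend = diversity.inbreeding_trend(ped)
    assert 1999 not in trend.index
    assert 2001 in trend.index
    assert trend.loc[2001, "n"] == 2
    # founders (undefined F) never form a year
    assert 1995 in trend.index or trend.loc[1995, "n"] >= 2 if 1995 in trend.index else True


def test_trend_monotone_under_drift(breed_sim):
    sim, _ = breed_sim
    trend = diversity.inbreeding_trend(sim.pedigree)
    years = trend.index.to_numpy()
    late = trend.loc[years >= years.max() - 10, "mean_F"].mean()
    early = trend.loc[years <= years.min() + 10, "mean_F"].mean()
    assert late > early  # closed breed accumulates inbreeding


def test_correlation_identity_and_sign():
    import pandas as pd

    x = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
    r, ci, p = diversity.correlate_inbreeding_estimates(x, x)
    assert r == pytest.approx(1.0)
    r2, _, _ = diversity.correlate_inbreeding_estimates(x, -x)
    assert r2 == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        diversity.correlate_inbreeding_estimates(x.iloc[:2], x.iloc[:2])
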