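"""Generators: pedigree structure, gene-dropped genotypes, phenotypes,
and fixture round-trips."""

import numpy as np
import pytest

from lassogwas.genio import AA, BB, MISSING, read_plink_text, read_phenotypes
from lassogwas.kinship import build_A
from lassogwas.pedigree import Pedigree, UNKNOWN, parent_indices, sort_pedigree
from lassogwas.synthetic import (
    SimulationTruth,
    generate_pedigree,
    simulate_genotypes,
    simulate_phenotype,
    write_fixture,
)


# ---------------------------------------------------------------------------
# generate_pedigree
# ---------------------------------------------------------------------------

def test_founders_only():
    ped = generate_pedigree(2, 0, 0, seed=1)
    assert len(ped) == 2
    assert all(s == UNKNOWN for s in ped.sires)


def test_single_pair_three_offspring():
    ped = generate_pedigree(2, 1, 3, seed=1)
    assert len(ped) == 5
    kids = [(s, d) for s, d in zip(ped.sires[2:], ped.dams[2:])]
    assert len(set(kids)) == 1  # all three share both parents
    assert kids[0][0] != UNKNOWN


def test_generation_sizes_match_mating_scheme():
    # 10 founders, 2 per pair: every generation has 5 pairs * 2 = 10
    ped = generate_pedigree(10, 3, 2, seed=7)
    assert len(ped) == 10 + 3 * 10
    gens = np.array(ped.generation)
    for g, expect in [(0, 10), (1, 10), (2, 10), (3, 10)]:
        assert (gens == g).sum() == expect
    # each non-founder has both parents in the previous generation
    gen_of = dict(zip(ped.ids, ped.generation))
    for i, s, d, g in zip(ped.ids, ped.sires, ped.dams, ped.generation):
        if g > 0:
            assert gen_of[s] == g - 1 and gen_of[d] == g - 1


def test_odd_founders_rejected():
    with pytest.raises(ValueError):
        generate_pedigree(3, 1, 2, seed=0)


def test_pedigree_deterministic_given_seed():
    a = generate_pedigree(8, 2, 2, seed=5)
    b = generate_pedigree(8, 2, 2, seed=5)
    assert a.ids == b.ids and a.sires == b.sires and a.dams == b.dams


# ---------------------------------------------------------------------------
# simulate_genotypes
# ---------------------------------------------------------------------------

def test_founder_allele_frequency_within_binomial_bound():
    ped = generate_pedigree(500, 0, 0, seed=2)
    G = simulate_genotypes(ped, 200, 0.5, 0.5, seed=3)
    freq = (G.calls.mean(axis=0)) / 2.0
    se = np.sqrt(0.5 * 0.5 / (2 * 500))
    # orientation folds frequencies to <= 0.5, so compare the folded value
    assert np.all(freq >= 0.5 - 3 * se)


def test_monomorphic_maf_rejected():
    ped = generate_pedigree(4, 0, 0, seed=1)
    with pytest.raises(ValueError):
        simulate_genotypes(ped, 10, 0.0, 0.0, seed=1)


def test_mendelian_transmission_conserves_alleles():
    """Offspring calls are consistent with one allele from each parent;
    in particular two AA parents can only produce AA."""
    ped = generate_pedigree(40, 2, 2, seed=11)
    G = simulate_genotypes(ped, 50, 0.2, 0.5, seed=12)
    sped = sort_pedigree(ped)
    index = {i: k for k, i in enumerate(G.individual_ids)}
    sire, dam = parent_indices(sped)
    order = np.array([index[i] for i in sped.ids])
    calls = G.calls[order]
    for i in range(len(sped)):
        s, d = sire[i], dam[i]
        if s < 0:
            continue
        # impossible offspring given parents: AA x AA -> must be AA, etc.
        both_aa = (calls[s] == AA) & (calls[d] == AA)
        assert np.all(calls[i][both_aa] == AA)
        both_bb = (calls[s] == BB) & (calls[d] == BB)
        assert np.all(calls[i][both_bb] == BB)
        # offspring homozygote requires each parent to carry that allele
        assert not np.any((calls[i] == BB) & (calls[s] == AA))
        assert not np.any((calls[i] == BB) & (calls[d] == AA))
        assert not np.any((calls[i] == AA) & (calls[s] == BB))
        assert not np.any((calls[i] == AA) & (calls[d] == BB))


def test_map_positions_strictly_increase_within_chromosome():
    ped = generate_pedigree(10, 0, 0, seed=4)
    G = simulate_genotypes(
        ped, 300, 0.1, 0.5, {"1": 1_000_000, "2": 500_000}, seed=5
    )
    for _, grp in G.snps.groupby("chrom"):
        assert np.all(np.diff(grp["bp"].to_numpy()) > 0)


def test_genotypes_reproducible_given_seed():
    ped = generate_pedigree(20, 1, 2, seed=6)
    a = simulate_genotypes(ped, 30, 0.1, 0.5, seed=9)
    b = simulate_genotypes(ped, 30, 0.1, 0.5, seed=9)
    np.testing.assert_array_equal(a.calls, b.calls)


# ---------------------------------------------------------------------------
# simulate_phenotype
# ---------------------------------------------------------------------------

def test_noiseless_null_phenotype_is_constant():
    ped = generate_pedigree(6, 0, 0, seed=1)
    G = simulate_genotypes(ped, 5, 0.3, 0.5, seed=2)
    y, g = simulate_phenotype(G, ped, SimulationTruth([], [], 0.0, 0.0, seed=3, mu=2.5))
    np.testing.assert_allclose(y, 2.5)
    np.testing.assert_allclose(g, 0.0)


def test_single_causal_snp_maps_identity():
    ped = generate_pedigree(10, 0, 0, seed=1)
    G = simulate_genotypes(ped, 5, 0.3, 0.5, seed=2)
    y, _ = simulate_phenotype(G, ped, SimulationTruth([2], [1.0], 0.0, 0.0, seed=3))
    np.testing.assert_allclose(y, G.calls[:, 2].astype(float) - 1.0)


def test_variance_components_add():
    ped = generate_pedigree(2000, 0, 0, seed=1)
    G = simulate_genotypes(ped, 1, 0.3, 0.5, seed=2)
    y, g = simulate_phenotype(G, ped, SimulationTruth([], [], 1.0, 1.0, seed=3))
    assert np.var(y) == pytest.approx(2.0, rel=0.10)
    assert np.var(g) == pytest.approx(1.0, rel=0.15)


def test_polygenic_covariance_tracks_A():
    """Across replicates, cov(g_i, g_j) regressed on A_ij has slope
    sigma_g2 (within 10%)."""
    ped = generate_pedigree(16, 2, 2, seed=21)
    G = simulate_genotypes(ped, 1, 0.3, 0.5, seed=22)
    A = build_A(ped).subset(list(G.individual_ids)).A
    sigma_g2 = 1.7
    reps = 4000
    gs = np.empty((reps, len(ped)))
    for r in range(reps):
        _, g = simulate_phenotype(
            G, ped, SimulationTruth([], [], sigma_g2, 0.0, seed=1000 + r)
        )
        gs[r] = g
    C = np.cov(gs, rowvar=False)
    x = A.ravel()
    slope = float(x @ C.ravel() / (x @ x))
    assert slope == pytest.approx(sigma_g2, rel=0.10)


def test_causal_index_out_of_range():
    ped = generate_pedigree(4, 0, 0, seed=1)
    G = simulate_genotypes(ped, 3, 0.3, 0.5, seed=2)
    with pytest.raises(IndexError):
        simulate_phenotype(G, ped, SimulationTruth([5], [1.0], 0.0, 0.0, seed=3))


# ---------------------------------------------------------------------------
# write_fixture
# ---------------------------------------------------------------------------

def test_fixture_round_trip(tmp_path):
    ped = generate_pedigree(10, 1, 2, seed=31)
    G = simulate_genotypes(ped, 12, 0.2, 0.5, seed=32, missing_rate=0.1)
    y, _ = simulate_phenotype(G, ped, SimulationTruth([0], [0.5], 0.5, 0.5, seed=33))
    paths = write_fixture(G, ped, y, tmp_path / "fx")
    assert len(paths) == 4
    G2 = read_plink_text(paths["ped"], paths["map"])
    np.testing.assert_array_equal(G.calls, G2.calls)
    assert G2.individual_ids == G.individual_ids
    ped2 = Pedigree.from_tsv(paths["pedigree"])
    assert ped2.ids == ped.ids and ped2.sires == ped.sires
    pheno = read_phenotypes(paths["phenotypes"])
    np.testing.assert_allclose(pheno["trait"].to_numpy(), y)
    with pytest.raises(FileExistsError):
        write_fixture(G, ped, y, tmp_path / "fx")


def test_fixture_line_counts(tmp_path):
    ped = generate_pedigree(100, 0, 0, seed=41)
    G = simulate_genotypes(ped, 500, 0.1, 0.5, seed=42)
    y = np.zeros(100)
    paths = write_fixture(G, ped, y, tmp_path / "fx2")
    assert len(paths["map"].read_text().splitlines()) == 500
    assert len(paths["ped"].read_text().splitlines()) == 100
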