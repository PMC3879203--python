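import numpy as np
import pandas as pd
import pytest

from lassogwas.genio import GenotypeMatrix
from lassogwas.kinship import RelationshipMatrix, build_A
from lassogwas.pedigree import Pedigree
from lassogwas.synthetic import (
    SimulationTruth,
    half_sib_pedigree,
    simulate_genotypes,
    simulate_phenotype,
)


def make_genotypes(calls, chrom=None, bp=None, ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a 2-D list of calls (-1/0/1/2)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, p = calls.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(p)],
            "chrom": chrom if chrom is not None else ["1"] * p,
            "bp": bp if bp is not None else list(range(1, p + 1)),
            "allele_a": ["A"] * p,
            "allele_b": ["B"] * p,
        }
    )
    return GenotypeMatrix(ids or [f"ind{i}" for i in range(n)], snps, calls)


def random_pedigree(rng: np.random.Generator, n_max: int = 50) -> Pedigree:
    """Random valid pedigree: each individual draws parents (or unknown)
    among earlier individuals."""
    n = int(rng.integers(2, n_max + 1))
    ids = [f"i{k}" for k in range(n)]
    sires, dams = [], []
    for k in range(n):
        if k < 2 or rng.random() < 0.3:
            sires.append("0")
            dams.append("0")
        else:
            s, d = rng.integers(0, k, size=2)
            sires.append(ids[int(s)])
            dams.append(ids[int(d)] if d != s else "0")
    return Pedigree(ids, sires, dams)


def half_sib_cohort(
    n_sires: int,
    daughters_per_sire: int,
    n_snps: int,
    causal: list[int],
    qtl_share: float,
    sigma_g2: float,
    sigma_e2: float,
    seed: int,
):
    """Paternal half-sib cohort of phenotyped daughters — the progeny-test
    family structure the pipeline targets.  Plants ``causal`` SNPs with
    effects sized so each explains ``qtl_share`` of total variance.

    Returns (y, X, R, effects) for the daughters only.
    """
    ped = half_sib_pedigree(n_sires, daughters_per_sire, seed)
    G = simulate_genotypes(ped, n_snps, 0.05, 0.5, seed=seed + 1)
    daughters = [i for i in ped.ids if i.startswith("C")]
    pos = {i: k for k, i in enumerate(G.individual_ids)}
    idx = [pos[i] for i in daughters]
    calls = G.calls[idx]
    X = calls.astype(float) - 1.0
    p = (X.mean(axis=0) + 1.0) / 2.0
    signs = np.resize([1.0, -1.0], len(causal))
    effects = signs * np.sqrt(qtl_share / (2 * p[causal] * (1 - p[causal]))) if causal else []
    Gd = GenotypeMatrix(daughters, G.snps, calls)
    y, _ = simulate_phenotype(
        Gd, ped,
        SimulationTruth(list(causal), list(effects), sigma_g2, sigma_e2, seed=seed + 2),
    )
    R = build_A(ped).subset(daughters)
    return y, X, R, effects


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
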