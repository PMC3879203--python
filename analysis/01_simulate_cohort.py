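"""Simulate the study cohort: a paternal half-sib pedigree (the
progeny-test family structure of a dairy population), gene-dropped
50K-style genotypes and an EBV-like phenotype with five planted QTLs for
the phenotyped daughters.

Writes the PLINK-text fixture to scratch/cohort/ (regenerable, large) and
the truth record plus cohort summaries to results/.
"""

import json
from pathlib import Path

import numpy as np

from lassogwas.genio import GenotypeMatrix
from lassogwas.lasso import allele_freq_from_coded
from lassogwas.synthetic import (
    SimulationTruth,
    half_sib_pedigree,
    simulate_genotypes,
    simulate_phenotype,
    write_fixture,
)

SEED = 2024
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

# study conditions: 1000 phenotyped daughters of 50 sires, 1500 SNPs over
# 5 chromosomes, MAF spectrum U(0.05, 0.5), 5 QTLs each explaining ~3% of
# variance, polygenic 30% and residual 50%
N_SIRES, DAUGHTERS_PER_SIRE = 50, 20
N_SNPS = 1500
CHROMS = {str(c): 60_000_000 for c in range(1, 6)}
QTL_SHARE, SIGMA_G2, SIGMA_E2 = 0.03, 0.30, 0.50


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ped = half_sib_pedigree(N_SIRES, DAUGHTERS_PER_SIRE, seed=SEED)
    G_all = simulate_genotypes(ped, N_SNPS, 0.05, 0.5, CHROMS, seed=SEED + 1,
                               missing_rate=0.01)
    # genotypes and phenotypes exist only for the daughters (the cows);
    # sires and dams stay pedigree-only, as in a real progeny-test cohort
    daughters = [i for i in ped.ids if i.startswith("C")]
    pos = {i: k for k, i in enumerate(G_all.individual_ids)}
    G = GenotypeMatrix(daughters, G_all.snps,
                       G_all.calls[[pos[i] for i in daughters]])
    X = G.calls.astype(float) - 1.0
    X[G.calls == -1] = 0.0  # missing -> mid code, only for effect sizing
    rng = np.random.default_rng(SEED + 2)
    causal = np.sort(rng.choice(N_SNPS, size=5, replace=False))
    p = allele_freq_from_coded(X)[causal]
    effects = rng.choice([-1.0, 1.0], 5) * np.sqrt(QTL_SHARE / (2 * p * (1 - p)))
    truth = SimulationTruth(causal.tolist(), effects.tolist(),
                            SIGMA_G2, SIGMA_E2, seed=SEED + 3)
    y, g = simulate_phenotype(G, ped, truth)
    paths = write_fixture(G, ped, y, OUT, force=True)
    (RESULTS / "truth.json").write_text(json.dumps({
        "causal_snp_ids": G.snps["snp_id"].iloc[causal].tolist(),
        "causal_snp_indices": causal.tolist(),
        "causal_effects": effects.tolist(),
        "sigma_g2": SIGMA_G2, "sigma_e2": SIGMA_E2, "seed": SEED,
        "n_individuals": G.n, "n_snps": G.p,
    }, indent=2))
    print(f"cohort: {G.n} phenotyped daughters of {N_SIRES} sires, "
          f"{G.p} SNPs on {len(CHROMS)} chromosomes")
    print(f"phenotype sd {y.std():.3f} (polygenic {SIGMA_G2}, residual {SIGMA_E2}, "
          f"5 QTLs x {QTL_SHARE} of variance)")
    print("fixture:", {k: str(v) for k, v in paths.items()})


if __name__ == "__main__":
    main()
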