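"""Synthetic pedigrees, gene-dropped genotypes and EBV-like phenotypes.

Everything downstream (QC, kinship, the mixed-model scan, the multi-SNP
LASSO, permutation thresholds) is exercised on data from this module, so the
generators carry a known truth record for parameter-recovery tests.

The phenotype is an additive-genetic surrogate: a handful of causal SNP
effects on the -1/0/+1 coded genotypes, plus a polygenic deviate with
covariance A*sigma_g2 drawn through the Cholesky factor of the pedigree
relationship matrix, plus i.i.d. Gaussian noise.  SNPs are transmitted
independently down the pedigree (no linkage disequilibrium beyond what
co-transmission induces), which is all the exchangeable-covariate model
needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import genio
from .genio import MISSING, GenotypeMatrix
from .kinship import build_A
from .pedigree import UNKNOWN, Pedigree


@dataclass
class SimulationTruth:
    """What was planted: causal SNP columns, their effects on the coded
    genotypes (trait units per code unit), and the variance components."""

    causal_snp_indices: list[int]
    causal_effects: list[float]
    sigma_g2: float
    sigma_e2: float
    seed: int
    mu: float = 0.0

    def __post_init__(self) -> None:
        if len(self.causal_snp_indices) != len(self.causal_effects):
            raise ValueError("causal index and effect lists must have equal length")
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")


def generate_pedigree(
    n_founders: int, n_generations: int, offspring_per_pair: int, seed: int
) -> Pedigree:
    """Discrete-generation random-mating pedigree.

    Founders (generation 0) have unknown parents.  Each later generation is
    produced by randomly pairing the previous generation's individuals
    (an odd individual is left unmated) and giving every pair
    ``offspring_per_pair`` offspring, both of whose parents are the pair.
    Deterministic given ``seed``.
    """
    if n_founders < 2 or n_founders % 2 != 0:
        raise ValueError("n_founders must be an even number >= 2 (founders are paired)")
    if n_generations < 0:
        raise ValueError("n_generations must be non-negative")
    rng = np.random.default_rng(seed)
    ids = [f"G0_{k}" for k in range(n_founders)]
    sires = [UNKNOWN] * n_founders
    dams = [UNKNOWN] * n_founders
    gens = [0] * n_founders
    prev = list(ids)
    for g in range(1, n_generations + 1):
        perm = rng.permutation(len(prev))
        n_pairs = len(prev) // 2
        child = 0
        cur: list[str] = []
        for k in range(n_pairs):
            pa, pb = prev[perm[2 * k]], prev[perm[2 * k + 1]]
            for _ in range(offspring_per_pair):
                cid = f"G{g}_{child}"
                child += 1
                ids.append(cid)
                sires.append(pa)
                dams.append(pb)
                gens.append(g)
                cur.append(cid)
        prev = cur
        if not prev:
            break
    return Pedigree(ids, sires, dams, gens)


def half_sib_pedigree(n_sires: int, daughters_per_sire: int, seed: int) -> Pedigree:
    """Paternal half-sib design: unrelated sires and dams, each sire mated to
    ``daughters_per_sire`` distinct dams, one daughter each — the family
    structure of a progeny-tested dairy cattle cohort."""
    ids, sires, dams, gens = [], [], [], []
    for s in range(n_sires):
        sid = f"S{s}"
        ids.append(sid)
        sires.append(UNKNOWN)
        dams.append(UNKNOWN)
        gens.append(0)
    k = 0
    for s in range(n_sires):
        for _ in range(daughters_per_sire):
            did = f"D{k}"
            ids.append(did)
            sires.append(UNKNOWN)
            dams.append(UNKNOWN)
            gens.append(0)
            ids.append(f"C{k}")
            sires.append(f"S{s}")
            dams.append(did)
            gens.append(1)
            k += 1
    return Pedigree(ids, sires, dams, gens)


def _allocate_positions(
    n_snps: int, chrom_sizes: dict[str, int], rng: np.random.Generator
) -> pd.DataFrame:
    """Distribute SNPs over chromosomes proportionally to size, with strictly
    increasing positions within each chromosome."""
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    counts = np.floor(n_snps * sizes / sizes.sum()).astype(int)
    while counts.sum() < n_snps:
        counts[int(np.argmax(sizes / np.maximum(counts, 1)))] += 1
    rows = []
    for c, m in zip(chroms, counts):
        if m == 0:
            continue
        pos = np.sort(rng.integers(1, max(int(chrom_sizes[c]), m + 1), size=m))
        pos = pos + np.arange(m)  # enforce strict increase
        for k, bp in enumerate(pos):
            rows.append((f"snp_{c}_{k}", str(c), int(bp)))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "bp"])


def simulate_genotypes(
    ped: Pedigree,
    n_snps: int,
    maf_low: float,
    maf_high: float,
    chrom_sizes: dict[str, int] | None = None,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """HWE founder genotypes at per-SNP MAF ~ Uniform(maf_low, maf_high),
    transmitted by gene dropping: each offspring receives one uniformly
    chosen allele from each parent, independently per SNP.

    After simulation each SNP is re-oriented so allele B is the empirically
    rarer allele (ties keep B the later letter), matching what
    :func:`genio.read_plink_text` reconstructs from files.
    """
    if len(ped) == 0:
        raise ValueError("empty pedigree")
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if chrom_sizes is None:
        chrom_sizes = {"1": 100_000_000}
    rng = np.random.default_rng(seed)
    from .pedigree import parent_indices, sort_pedigree

    sped = sort_pedigree(ped)
    sire, dam = parent_indices(sped)
    n = len(sped)
    maf = rng.uniform(maf_low, maf_high, size=n_snps)
    # haplotypes: 1 = B allele
    hap = np.zeros((n, n_snps, 2), dtype=np.int8)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0:
            hap[i, :, 0] = rng.random(n_snps) < maf
        else:
            pick = rng.integers(0, 2, size=n_snps)
            hap[i, :, 0] = hap[s, np.arange(n_snps), pick]
        if d < 0:
            hap[i, :, 1] = rng.random(n_snps) < maf
        else:
            pick = rng.integers(0, 2, size=n_snps)
            hap[i, :, 1] = hap[d, np.arange(n_snps), pick]
    calls = hap.sum(axis=2).astype(np.int8)

    # orient: B = rarer allele empirically; tie keeps current labels
    freq = calls.mean(axis=0) / 2.0
    flip = freq > 0.5
    calls[:, flip] = 2 - calls[:, flip]

    if missing_rate > 0:
        miss = rng.random(calls.shape) < missing_rate
        calls[miss] = MISSING

    snps = _allocate_positions(n_snps, chrom_sizes, rng)
    snps["allele_a"] = "A"
    snps["allele_b"] = "B"
    # realign ids to the caller's pedigree order
    G = GenotypeMatrix(list(sped.ids), snps, calls)
    if list(sped.ids) != list(ped.ids):
        index = {i: k for k, i in enumerate(sped.ids)}
        order = np.array([index[i] for i in ped.ids])
        G = GenotypeMatrix(list(ped.ids), snps, calls[order])
    return G


def simulate_phenotype(
    G: GenotypeMatrix, ped: Pedigree, truth: SimulationTruth
) -> tuple[np.ndarray, np.ndarray]:
    """y = mu + X_causal @ effects + g + e, with g ~ N(0, A*sigma_g2) drawn
    via the Cholesky factor of A and e ~ N(0, I*sigma_e2).

    Returns ``(y, g)`` aligned to ``G.individual_ids`` so tests can check the
    realised polygenic values.  Raises if A is not positive semidefinite.
    """
    idx = np.asarray(truth.causal_snp_indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= G.p):
        raise IndexError("causal SNP index out of range")
    rng = np.random.default_rng(truth.seed)
    n = G.n
    y = np.full(n, truth.mu, dtype=float)
    if idx.size:
        X = G.calls[:, idx].astype(float) - 1.0
        X[G.calls[:, idx] == MISSING] = 0.0  # missing -> mean code
        y += X @ np.asarray(truth.causal_effects, dtype=float)
    if truth.sigma_g2 > 0:
        R = build_A(ped).subset(list(G.individual_ids))
        L = R.cholesky()
        g = np.sqrt(truth.sigma_g2) * (L @ rng.standard_normal(n))
    else:
        g = np.zeros(n)
    y += g
    if truth.sigma_e2 > 0:
        y += np.sqrt(truth.sigma_e2) * rng.standard_normal(n)
    return y, g


def write_fixture(
    G: GenotypeMatrix,
    ped: Pedigree,
    y: np.ndarray | pd.DataFrame,
    out_dir: str | Path,
    force: bool = False,
) -> dict[str, Path]:
    """Emit a complete text fixture: PED/MAP genotypes, pedigree TSV and
    phenotype TSV.  Round-trips bit-identically through :mod:`genio` and
    :mod:`pedigree` readers.  Refuses to overwrite unless ``force``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": out / "genotypes.ped",
        "map": out / "genotypes.map",
        "pedigree": out / "pedigree.tsv",
        "phenotypes": out / "phenotypes.tsv",
    }
    for p in paths.values():
        if p.exists() and not force:
            raise FileExistsError(f"{p} exists (pass force=True to overwrite)")
    genio.write_plink_text(G, paths["ped"], paths["map"], ped=ped, force=force)
    ped.to_tsv(paths["pedigree"])
    if isinstance(y, pd.DataFrame):
        df = y.copy()
        df.insert(0, "id", G.individual_ids)
    else:
        df = pd.DataFrame({"id": G.individual_ids, "trait": np.asarray(y, dtype=float)})
    df.to_csv(paths["phenotypes"], sep="\t", index=False)
    return paths
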