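"""Genotype I/O, per-SNP statistics, quality control, and design-matrix coding.

Genotypes live in a :class:`GenotypeMatrix`: integer calls per individual x
SNP with codes AA=0, AB=1, BB=2, missing=-1, where allele B is the *minor*
allele as observed in the data (ties broken lexicographically: B is the
later-sorting allele).  The analysis design matrix codes AA/AB/BB as
-1/0/+1, so the coded column mean relates to the B-allele frequency by
p_B = (mean + 1) / 2.

QC mirrors standard 50K-array practice: a SNP is dropped when its minor
allele frequency is below 1%, its call rate below 90%, or its Hardy-Weinberg
chi-square P-value below 1e-6 — all strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1
AA = 0
AB = 1
BB = 2

SNP_COLUMNS = ["snp_id", "chrom", "bp", "allele_a", "allele_b"]


@dataclass
class GenotypeMatrix:
    """n individuals x p SNPs of genotype calls plus per-SNP map metadata.

    ``snps`` is a DataFrame with columns snp_id, chrom, bp, allele_a,
    allele_b; ``calls`` is an (n, p) int8 array in {-1, 0, 1, 2}.
    """

    individual_ids: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        n, p = self.calls.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual count does not match call matrix rows")
        if len(self.snps) != p:
            raise ValueError("SNP table length does not match call matrix columns")
        if n < 1 or p < 1:
            raise ValueError("need at least one individual and one SNP")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("snp_ids are not unique")
        if (self.snps["bp"].to_numpy() <= 0).any():
            raise ValueError("bp positions must be positive")

    @property
    def n(self) -> int:
        return self.calls.shape[0]

    @property
    def p(self) -> int:
        return self.calls.shape[1]

    def subset_snps(self, indices: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individual_ids),
            self.snps.iloc[indices].reset_index(drop=True),
            self.calls[:, indices],
        )


@dataclass
class SnpStats:
    """Per-SNP call rate, allele-B frequency, MAF and HWE test."""

    call_rate: np.ndarray
    p_b: np.ndarray  # frequency of the +1-coded (B) allele among observed calls
    maf: np.ndarray
    hwe_chi2: np.ndarray
    hwe_p: np.ndarray

    def to_frame(self, snps: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": snps["snp_id"].to_numpy(),
                "call_rate": self.call_rate,
                "p_b": self.p_b,
                "maf": self.maf,
                "hwe_chi2": self.hwe_chi2,
                "hwe_p": self.hwe_p,
            }
        )


@dataclass
class QCReport:
    n_input: int
    n_removed_maf: int
    n_removed_callrate: int
    n_removed_hwe: int
    n_retained: int
    reasons: pd.DataFrame  # snp_id, status, reason

    def __post_init__(self) -> None:
        total = self.n_removed_maf + self.n_removed_callrate + self.n_removed_hwe
        assert self.n_retained + total == self.n_input


def hwe_chi_square(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """Pearson 1-df chi-square against Hardy-Weinberg expectations.

    Expected genotype counts come from the observed allele frequency.  A
    monomorphic SNP carries no information and returns (0, 1) by convention.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    p = (2 * n_bb + n_ab) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return 0.0, 1.0
    q = 1.0 - p
    exp = np.array([q * q, 2 * p * q, p * p]) * n
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test P-value: the summed probability of all
    heterozygote counts no more probable than the observed one, conditional
    on the allele counts (computed with log-gamma for stability).
    Monomorphic SNPs return 1."""
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    nb = 2 * n_bb + n_ab
    if nb == 0 or nb == 2 * n:
        return 1.0
    from scipy.special import gammaln

    hs = np.arange(nb % 2, min(nb, 2 * n - nb) + 1, 2)
    nbb = (nb - hs) // 2
    naa = n - hs - nbb
    logp = (
        gammaln(n + 1) - gammaln(naa + 1) - gammaln(hs + 1) - gammaln(nbb + 1)
        + hs * np.log(2.0)
        + gammaln(nb + 1) + gammaln(2 * n - nb + 1) - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hs == n_ab][0]
    return float(min(prob[prob <= p_obs * (1 + 1e-12)].sum(), 1.0))


def snp_stats(G: GenotypeMatrix) -> SnpStats:
    """Vectorised per-SNP statistics on observed (non-missing) calls only."""
    calls = G.calls
    n = G.n
    n_aa = (calls == AA).sum(axis=0)
    n_ab = (calls == AB).sum(axis=0)
    n_bb = (calls == BB).sum(axis=0)
    obs = n_aa + n_ab + n_bb
    call_rate = obs / n
    with np.errstate(invalid="ignore", divide="ignore"):
        p_b = np.where(obs > 0, (2 * n_bb + n_ab) / (2 * np.maximum(obs, 1)), np.nan)
    maf = np.minimum(p_b, 1.0 - p_b)
    chi2 = np.zeros(G.p)
    hwe_p = np.ones(G.p)
    poly = (obs > 0) & (p_b > 0) & (p_b < 1)
    if poly.any():
        p = p_b[poly]
        q = 1.0 - p
        m = obs[poly]
        eaa = q * q * m
        eab = 2 * p * q * m
        ebb = p * p * m
        c = (
            (n_aa[poly] - eaa) ** 2 / eaa
            + (n_ab[poly] - eab) ** 2 / eab
            + (n_bb[poly] - ebb) ** 2 / ebb
        )
        chi2[poly] = c
        hwe_p[poly] = stats.chi2.sf(c, df=1)
    return SnpStats(call_rate, p_b, maf, chi2, hwe_p)


def apply_qc(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.90,
    hwe_p_min: float = 1e-6,
    hwe_test: str = "chi2",
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs failing MAF < maf_min OR call rate < call_rate_min OR
    HWE P < hwe_p_min (all strict).  Retained SNP order is preserved.

    The per-SNP removal *reason* follows the precedence MAF -> call rate ->
    HWE (each removed SNP is counted once); removal itself is the OR of the
    three rules.  ``hwe_test`` selects the Pearson chi-square (default) or
    the exact conditional test.
    """
    if not (0 <= maf_min <= 0.5 and 0 <= call_rate_min <= 1 and 0 <= hwe_p_min <= 1):
        raise ValueError("QC thresholds out of range")
    if hwe_test not in ("chi2", "exact"):
        raise ValueError("hwe_test must be 'chi2' or 'exact'")
    st = snp_stats(G)
    if hwe_test == "exact":
        calls = G.calls
        st.hwe_p = np.array([
            hwe_exact(
                int((calls[:, j] == AA).sum()),
                int((calls[:, j] == AB).sum()),
                int((calls[:, j] == BB).sum()),
            )
            for j in range(G.p)
        ])
    fail_maf = st.maf < maf_min  # NaN maf (no observed calls) compares False
    fail_cr = st.call_rate < call_rate_min
    fail_hwe = st.hwe_p < hwe_p_min
    removed = fail_maf | fail_cr | fail_hwe
    reason = np.full(G.p, "", dtype=object)
    reason[fail_hwe] = "hwe"
    reason[fail_cr] = "call_rate"
    reason[fail_maf] = "maf"
    status = np.where(removed, "removed", "retained")
    report = QCReport(
        n_input=G.p,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_callrate=int((fail_cr & ~fail_maf).sum()),
        n_removed_hwe=int((fail_hwe & ~fail_cr & ~fail_maf).sum()),
        n_retained=int((~removed).sum()),
        reasons=pd.DataFrame(
            {
                "snp_id": G.snps["snp_id"].to_numpy(),
                "maf": st.maf,
                "call_rate": st.call_rate,
                "hwe_p": st.hwe_p,
                "status": status,
                "reason": reason,
            }
        ),
    )
    if report.n_retained == 0:
        raise ValueError("QC removed every SNP — empty design matrix")
    keep = np.flatnonzero(~removed)
    return G.subset_snps(keep), report


def code_genotypes(G: GenotypeMatrix) -> np.ndarray:
    """Code AA/AB/BB as -1/0/+1; missing calls get the per-SNP mean of the
    observed codes (keeps the design dense without external imputation)."""
    codes = G.calls.astype(float) - 1.0
    miss = G.calls == MISSING
    if miss.any():
        obs = ~miss
        n_obs = obs.sum(axis=0)
        if (n_obs == 0).any():
            bad = G.snps["snp_id"].iloc[int(np.argmin(n_obs))]
            raise ValueError(f"SNP {bad!r} has no observed calls (should fail call-rate QC)")
        col_mean = np.where(obs, codes, 0.0).sum(axis=0) / n_obs
        codes = np.where(miss, col_mean[None, :], codes)
    return codes


def spacing_summary(G: GenotypeMatrix) -> tuple[float, float]:
    """Mean and median bp distance between adjacent SNPs, within chromosome,
    pooled across chromosomes.  Single-SNP chromosomes contribute no gaps."""
    gaps: list[np.ndarray] = []
    for _, grp in G.snps.groupby("chrom", sort=False):
        bp = grp["bp"].to_numpy()
        bp = np.sort(bp)
        if len(bp) >= 2:
            gaps.append(np.diff(bp))
    if not gaps:
        raise ValueError("no chromosome has two or more SNPs; spacing undefined")
    all_gaps = np.concatenate(gaps).astype(float)
    return float(all_gaps.mean()), float(np.median(all_gaps))


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into a GenotypeMatrix.

    Allele B (coded +1 downstream) is assigned per SNP as the rarer observed
    allele; a frequency tie makes B the lexicographically later allele.
    An allele string "0" marks a missing call (both alleles of the call).
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{map_path}:{ln}: expected 4 MAP columns, got {len(parts)}")
            chrom, snp_id, _cm, bp = parts
            map_rows.append((snp_id, chrom, int(bp)))
    p = len(map_rows)
    if p == 0:
        raise ValueError(f"{map_path}: no SNPs")

    ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * p:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * p} columns (6 + 2x{p} SNPs), "
                    f"got {len(parts)}"
                )
            ids.append(parts[1])
            allele_rows.append(parts[6:])
    if not ids:
        raise ValueError(f"{ped_path}: no individuals")

    n = len(ids)
    al = np.array(allele_rows, dtype=object).reshape(n, p, 2)
    calls = np.full((n, p), MISSING, dtype=np.int8)
    allele_a = []
    allele_b = []
    for j in range(p):
        a1 = al[:, j, 0]
        a2 = al[:, j, 1]
        ok = (a1 != "0") & (a2 != "0")
        observed = np.concatenate([a1[ok], a2[ok]])
        labels, counts = np.unique(observed, return_counts=True)
        if len(labels) > 2:
            raise ValueError(f"SNP {map_rows[j][0]!r} has more than two alleles: {list(labels)}")
        if len(labels) == 0:
            allele_a.append("")
            allele_b.append("")
            continue
        if len(labels) == 1:
            a_lab, b_lab = str(labels[0]), ""
        else:
            # B = rarer; tie -> lexicographically later allele is B
            order = np.lexsort((labels, -counts))
            a_lab, b_lab = str(labels[order[0]]), str(labels[order[1]])
        allele_a.append(a_lab)
        allele_b.append(b_lab)
        nb = (a1[ok] == b_lab).astype(np.int8) + (a2[ok] == b_lab).astype(np.int8)
        calls[ok, j] = nb
    snps = pd.DataFrame(
        {
            "snp_id": [r[0] for r in map_rows],
            "chrom": [r[1] for r in map_rows],
            "bp": [r[2] for r in map_rows],
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    return GenotypeMatrix(ids, snps, calls)


def write_plink_text(
    G: GenotypeMatrix,
    ped_path: str | Path,
    map_path: str | Path,
    ped: "object | None" = None,
    force: bool = False,
) -> None:
    """Write PED/MAP text.  Missing calls are written as "0 0"; PAT/MAT come
    from the pedigree when given, else "0"."""
    for path in (ped_path, map_path):
        if Path(path).exists() and not force:
            raise FileExistsError(f"{path} exists (pass force=True to overwrite)")
    with open(map_path, "w") as fh:
        for _, row in G.snps.iterrows():
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.bp}\n")
    parent = {}
    if ped is not None:
        parent = {i: (s, d) for i, s, d in zip(ped.ids, ped.sires, ped.dams)}
    with open(ped_path, "w") as fh:
        a_lab = G.snps["allele_a"].to_numpy()
        b_lab = G.snps["allele_b"].to_numpy()
        for i, iid in enumerate(G.individual_ids):
            pat, mat = parent.get(iid, ("0", "0"))
            fields = [iid, iid, pat, mat, "0", "-9"]
            row = G.calls[i]
            for j in range(G.p):
                c = row[j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == AA:
                    fields += [a_lab[j], a_lab[j]]
                elif c == AB:
                    fields += [a_lab[j], b_lab[j]]
                else:
                    fields += [b_lab[j], b_lab[j]]
            fh.write(" ".join(fields) + "\n")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV: first column ``id``, one column per trait."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "id":
        raise ValueError("phenotype file must start with an 'id' column")
    return df.set_index("id")
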