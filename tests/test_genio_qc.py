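"""Genotype file round-trips, per-SNP statistics, QC filtering and coding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lassogwas.genio import (
    hwe_exact,
    AA, AB, BB, MISSING,
    apply_qc,
    code_genotypes,
    hwe_chi_square,
    read_plink_text,
    snp_stats,
    spacing_summary,
    write_plink_text,
)

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# HWE chi-square
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts, chi2, p",
    [
        ((25, 50, 25), 0.0, 1.0),        # exact HWE proportions
        ((50, 0, 50), 100.0, None),      # all-homozygote: (25+50+25) by hand
        ((100, 0, 0), 0.0, 1.0),         # monomorphic convention
    ],
)
def test_hwe_chi_square_known_values(counts, chi2, p):
    c, pv = hwe_chi_square(*counts)
    assert c == pytest.approx(chi2, abs=1e-10)
    if p is not None:
        assert pv == pytest.approx(p)


def test_hwe_rejects_negative_counts():
    with pytest.raises(ValueError):
        hwe_chi_square(-1, 2, 3)


def test_hwe_exact_distribution_and_asymptotics():
    """The exact conditional test: its heterozygote-count probabilities sum
    to one, monomorphic SNPs return 1, perfect HWE proportions are not
    rejected, and for a large balanced sample it agrees with the chi-square
    test to leading order."""
    from scipy.special import gammaln

    assert hwe_exact(100, 0, 0) == 1.0
    assert hwe_exact(25, 50, 25) > 0.5
    # extreme heterozygote deficit is rejected by both tests
    assert hwe_exact(50, 0, 50) < 1e-20
    # large-sample agreement with the chi-square on a mild departure
    _, p_chi = hwe_chi_square(360, 480, 160)
    p_ex = hwe_exact(360, 480, 160)
    assert p_ex == pytest.approx(p_chi, rel=0.5)
    # conditional distribution is a proper distribution
    n, nb = 40, 30
    hs = np.arange(nb % 2, min(nb, 2 * n - nb) + 1, 2)
    nbb = (nb - hs) // 2
    naa = n - hs - nbb
    logp = (gammaln(n + 1) - gammaln(naa + 1) - gammaln(hs + 1) - gammaln(nbb + 1)
            + hs * np.log(2.0) + gammaln(nb + 1) + gammaln(2 * n - nb + 1)
            - gammaln(2 * n + 1))
    assert np.exp(logp).sum() == pytest.approx(1.0, abs=1e-12)


def test_apply_qc_exact_mode_matches_exact_pvalues():
    calls = np.tile([[AA], [AB], [BB], [AB]], (25, 1))
    bad = np.where(np.arange(100) % 2 == 0, AA, BB).astype(np.int8)
    G = make_genotypes(np.column_stack([calls[:, 0], bad]))
    kept, report = apply_qc(G, hwe_test="exact")
    assert report.n_removed_hwe == 1 and kept.p == 1
    with pytest.raises(ValueError):
        apply_qc(G, hwe_test="fisher")


# ---------------------------------------------------------------------------
# PED/MAP reading
# ---------------------------------------------------------------------------

def _write(tmp_path, ped_lines, map_lines):
    ped = tmp_path / "x.ped"
    mp = tmp_path / "x.map"
    ped.write_text("\n".join(ped_lines) + "\n")
    mp.write_text("\n".join(map_lines) + "\n")
    return ped, mp


def test_read_single_individual_single_snp(tmp_path):
    ped, mp = _write(tmp_path, ["f1 i1 0 0 0 -9 A A"], ["1 s1 0 100"])
    G = read_plink_text(ped, mp)
    assert G.calls[0, 0] == AA
    assert G.individual_ids == ["i1"]


def test_half_missing_allele_is_missing_call(tmp_path):
    ped, mp = _write(tmp_path, ["f1 i1 0 0 0 -9 A 0"], ["1 s1 0 100"])
    G = read_plink_text(ped, mp)
    assert G.calls[0, 0] == MISSING


def test_minor_allele_becomes_allele_b(tmp_path):
    ped, mp = _write(
        tmp_path,
        ["f i1 0 0 0 -9 A A", "f i2 0 0 0 -9 A G", "f i3 0 0 0 -9 G G"],
        ["1 s1 0 100"],
    )
    G = read_plink_text(ped, mp)
    st_ = snp_stats(G)
    assert st_.p_b[0] == pytest.approx(0.5)
    assert (G.calls[:, 0] == AB).sum() == 1
    # tie at 0.5: B is the lexicographically later allele
    assert G.snps["allele_b"].iloc[0] == "G"


def test_malformed_line_reports_line_number(tmp_path):
    ped, mp = _write(tmp_path, ["f1 i1 0 0 0 -9 A"], ["1 s1 0 100"])
    with pytest.raises(ValueError, match=":1:"):
        read_plink_text(ped, mp)


def test_round_trip_including_missing(tmp_path):
    G = make_genotypes([[AA, AB], [BB, MISSING], [AB, AA]])
    write_plink_text(G, tmp_path / "g.ped", tmp_path / "g.map")
    G2 = read_plink_text(tmp_path / "g.ped", tmp_path / "g.map")
    np.testing.assert_array_equal(G.calls, G2.calls)
    assert G2.individual_ids == G.individual_ids
    pd.testing.assert_frame_equal(G.snps[["snp_id", "chrom", "bp"]],
                                  G2.snps[["snp_id", "chrom", "bp"]])
    with pytest.raises(FileExistsError):
        write_plink_text(G, tmp_path / "g.ped", tmp_path / "g.map")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def brute_force_qc(G, maf_min=0.01, call_rate_min=0.90, hwe_p_min=1e-6):
    """Independent per-SNP filter straight from the definitions."""
    keep = []
    for j in range(G.p):
        col = G.calls[:, j]
        obs = col[col != MISSING]
        call_rate = len(obs) / len(col)
        if len(obs) == 0:
            keep.append(False)
            continue
        p_b = (2 * (obs == BB).sum() + (obs == AB).sum()) / (2 * len(obs))
        maf = min(p_b, 1 - p_b)
        _, hwe_p = hwe_chi_square(
            int((obs == AA).sum()), int((obs == AB).sum()), int((obs == BB).sum())
        )
        keep.append(
            not (maf < maf_min or call_rate < call_rate_min or hwe_p < hwe_p_min)
        )
    return np.array(keep)


def test_low_maf_snp_removed_with_maf_reason():
    # 1000 individuals, 8 carry one B allele: maf = 0.004 < 1%
    calls = np.zeros((1000, 1), dtype=np.int8)
    calls[:8, 0] = AB
    G = make_genotypes(calls)
    with pytest.raises(ValueError):
        apply_qc(G)  # sole SNP removed -> empty design is an error
    G2 = make_genotypes(np.hstack([calls, np.tile([[AA], [AB], [BB], [AB]], (250, 1))]))
    kept, report = apply_qc(G2)
    assert report.n_removed_maf == 1
    assert report.reasons["reason"].iloc[0] == "maf"
    assert kept.p == 1


def test_clean_snp_retained():
    calls = np.tile([[AA], [AB], [BB], [AB]], (25, 1))
    _, report = apply_qc(make_genotypes(calls))
    assert report.n_retained == 1


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_qc_equals_brute_force_on_random_panels(seed):
    rng = np.random.default_rng(seed)
    n, p = 120, 25
    calls = rng.choice(
        [MISSING, AA, AB, BB], size=(n, p), p=[0.05, 0.35, 0.3, 0.3]
    ).astype(np.int8)
    # plant some degenerate columns
    calls[:, 0] = AA                      # monomorphic -> maf 0
    calls[: n // 2, 1] = MISSING          # low call rate
    calls[:, 2] = np.where(np.arange(n) % 2 == 0, AA, BB)  # het deficit -> HWE
    G = make_genotypes(calls)
    expected = brute_force_qc(G)
    if not expected.any():
        return
    kept, report = apply_qc(G)
    got = report.reasons["status"].to_numpy() == "retained"
    np.testing.assert_array_equal(got, expected)
    assert list(kept.snps["snp_id"]) == [f"snp{j}" for j in np.flatnonzero(expected)]


def test_qc_boundaries_are_strict():
    """MAF exactly 0.01 and HWE P exactly 1e-6 survive (rules use strict <)."""
    n = 100
    # maf exactly 0.01: 2 B alleles among 200
    col_maf = np.zeros(n, dtype=np.int8)
    col_maf[0] = AB
    col_maf[1] = AB
    G = make_genotypes(col_maf[:, None])
    st_ = snp_stats(G)
    assert st_.maf[0] == pytest.approx(0.01)
    _, report = apply_qc(G)
    assert report.n_retained == 1
    # call rate exactly 0.90 survives
    col_cr = np.tile([AA, AB, BB, AB, AA, AB, BB, AB, AA, MISSING], 10).astype(np.int8)
    _, report = apply_qc(make_genotypes(col_cr[:, None]))
    assert report.n_retained == 1


def test_maf_ignores_missing_calls():
    col = np.array([AA, AB, BB, MISSING, MISSING], dtype=np.int8)
    st_ = snp_stats(make_genotypes(col[:, None]))
    assert st_.p_b[0] == pytest.approx(0.5)
    assert st_.call_rate[0] == pytest.approx(0.6)


# ---------------------------------------------------------------------------
# coding
# ---------------------------------------------------------------------------

def test_coding_values_and_mean_imputation():
    G = make_genotypes([[AA], [AB], [BB]])
    np.testing.assert_allclose(code_genotypes(G)[:, 0], [-1, 0, 1])
    G = make_genotypes([[AA], [MISSING]])
    np.testing.assert_allclose(code_genotypes(G)[:, 0], [-1, -1])
    G = make_genotypes([[AA], [BB], [MISSING]])
    np.testing.assert_allclose(code_genotypes(G)[:, 0], [-1, 1, 0])


def test_coding_is_odd_under_allele_swap(rng):
    calls = rng.choice([MISSING, AA, AB, BB], size=(30, 5), p=[0.1, 0.3, 0.3, 0.3])
    G = make_genotypes(calls.astype(np.int8))
    swapped = calls.copy()
    swapped[calls == AA] = BB
    swapped[calls == BB] = AA
    G2 = make_genotypes(swapped.astype(np.int8))
    np.testing.assert_allclose(code_genotypes(G), -code_genotypes(G2), atol=1e-12)


def test_fully_missing_column_is_an_error():
    G = make_genotypes([[MISSING], [MISSING]])
    with pytest.raises(ValueError):
        code_genotypes(G)


# ---------------------------------------------------------------------------
# spacing
# ---------------------------------------------------------------------------

def test_spacing_single_gap():
    G = make_genotypes([[AA, AB]], bp=[1, 101])
    assert spacing_summary(G) == (100.0, 100.0)


def test_spacing_hand_computed():
    G = make_genotypes([[AA, AB, BB]], bp=[1, 11, 31])
    assert spacing_summary(G) == (15.0, 15.0)


def test_spacing_pools_chromosomes():
    G = make_genotypes([[AA, AB, BB, AA]], chrom=["1", "1", "2", "2"], bp=[1, 11, 5, 105])
    mean, med = spacing_summary(G)
    assert mean == 55.0


def test_spacing_requires_a_multi_snp_chromosome():
    G = make_genotypes([[AA, AB]], chrom=["1", "2"], bp=[1, 5])
    with pytest.raises(ValueError):
        spacing_summary(G)
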