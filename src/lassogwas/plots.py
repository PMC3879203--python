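"""Manhattan and QQ plots for scan results, and the per-SNP heritability
profile with its permutation threshold."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def manhattan(scan_df: pd.DataFrame, out_path: str | Path, threshold: float | None = None):
    """-log10 P by genome position, chromosomes alternating in shade."""
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for k, (chrom, grp) in enumerate(scan_df.groupby("chrom", sort=False)):
        x = grp["bp"].to_numpy() + offset
        ax.scatter(x, grp["neg_log10_p"], s=4, color="C0" if k % 2 == 0 else "C7")
        ticks.append(offset + grp["bp"].max() / 2)
        labels.append(str(chrom))
        offset += grp["bp"].max()
    if threshold is not None:
        ax.axhline(threshold, ls="--", color="red", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} P$")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def qq(p_values: np.ndarray, out_path: str | Path):
    """Observed vs expected -log10 P under the uniform null."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = len(p)
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    obs = -np.log10(np.clip(p, np.finfo(float).tiny, 1.0))
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.plot(exp, obs, ".", ms=3)
    lim = max(exp.max(), obs.max())
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} P$")
    ax.set_ylabel("observed $-\\log_{10} P$")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def h2_profile(fit_df: pd.DataFrame, threshold: float, out_path: str | Path):
    """Per-SNP heritability of the multi-SNP fit with the permutation
    threshold as a dotted line."""
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.vlines(np.arange(len(fit_df)), 0, fit_df["h2"], lw=1)
    ax.axhline(threshold, ls=":", color="red", lw=1)
    ax.set_xlabel("SNP (map order)")
    ax.set_ylabel(r"$h_j^2$")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
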