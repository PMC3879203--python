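"""Nearest-gene annotation, genetic-correlation binning and report tables.

Gene coordinates are held 1-based inclusive; BED input (0-based half-open)
is converted on ingestion.  A SNP's distance to a gene is zero when the SNP
lies inside the gene body, else the distance to the nearer boundary; only
genes on the SNP's chromosome within a 1 Mb window qualify, ties going to
the gene with the smaller start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]

CORR_BOUNDS = (-1.0, -0.66, -0.33, 0.33, 0.66, 1.0)
CORR_LABELS = [
    "(-1 to -0.66)",
    "(-0.66 to -0.33)",
    "(-0.33 to 0.33)",
    "(0.33 to 0.66)",
    "(0.66 to 1)",
]


@dataclass
class CorrelationBinning:
    """Counts of trait-pair genetic correlations in the five strength levels."""

    counts: list[int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts) != self.total:
            raise ValueError("level counts must sum to the pair total")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": CORR_LABELS,
                "count": self.counts,
                "frequency": [c / self.total for c in self.counts],
            }
        )


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Gene coordinates from BED (``.bed``: chrom, start, end, name[, score,
    strand], 0-based half-open) or TSV with named 1-based columns."""
    path = Path(path)
    if path.suffix == ".bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        ncol = df.shape[1]
        if ncol < 4:
            raise ValueError("BED gene file needs at least chrom,start,end,name")
        out = pd.DataFrame(
            {
                "gene_id": df[3].astype(str),
                "chrom": df[0].astype(str),
                "start": df[1].astype(int) + 1,  # to 1-based inclusive
                "end": df[2].astype(int),
                "strand": df[5].astype(str) if ncol > 5 else "unknown",
            }
        )
    else:
        out = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        need = {"gene_id", "chrom", "start", "end"}
        if not need.issubset(out.columns):
            raise ValueError(f"gene TSV must have columns {sorted(need)}")
        if "strand" not in out.columns:
            out["strand"] = "unknown"
    if (out["start"] > out["end"]).any() or (out["start"] <= 0).any():
        raise ValueError("gene coordinates must be positive with start <= end")
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def nearest_gene(
    snp_chrom: str,
    snp_bp: int,
    genes: pd.DataFrame,
    window: int = 1_000_000,
) -> tuple[str, int, bool] | None:
    """Nearest gene within ``window`` bp: (gene_id, distance, within_gene),
    or None when no same-chromosome gene lies within the window."""
    sub = genes[genes["chrom"] == str(snp_chrom)]
    if sub.empty:
        if str(snp_chrom) not in set(genes["chrom"]):
            warnings.warn(f"chromosome {snp_chrom!r} absent from gene table")
        return None
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    inside = (start <= snp_bp) & (snp_bp <= end)
    dist = np.where(
        inside, 0, np.minimum(np.abs(snp_bp - start), np.abs(snp_bp - end))
    )
    order = np.lexsort((start, dist))  # ties -> smaller start
    best = order[0]
    if dist[best] > window:
        return None
    return (
        str(sub["gene_id"].iloc[best]),
        int(dist[best]),
        bool(inside[best]),
    )


def bin_correlations(corr: np.ndarray | pd.DataFrame) -> CorrelationBinning:
    """Bin the upper-triangle trait-pair correlations into the five levels
    bounded at -0.66, -0.33, 0.33, 0.66.  Interior boundary values go to the
    higher-index interval; the outer intervals are closed at -1 and 1."""
    C = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if np.any(np.abs(C) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    T = C.shape[0]
    iu = np.triu_indices(T, k=1)
    vals = C[iu]
    inner = np.asarray(CORR_BOUNDS[1:-1])
    idx = np.searchsorted(inner, vals, side="right")
    counts = [int(np.sum(idx == k)) for k in range(5)]
    return CorrelationBinning(counts=counts, total=len(vals))


def render_report(
    per_trait: dict[str, pd.DataFrame],
    out_dir: str | Path,
    groups: dict[str, str] | None = None,
) -> dict[str, Path]:
    """Write per-trait(-group) significant-SNP tables and a combined table.

    Each value of ``per_trait`` is a DataFrame with columns snp_id, chrom,
    bp, gene, distance (int, 0 = inside the gene), h2, threshold.  In the
    rendered tables a zero distance prints as "within" and h2/threshold are
    rendered to 5 decimals.  Traits with no significant SNP are omitted.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    frames = []
    for trait, df in per_trait.items():
        if df.empty:
            continue
        shown = df.copy()
        shown.insert(0, "trait", trait)
        frames.append(shown)
    if not frames:
        combined = pd.DataFrame(
            columns=["trait", "snp_id", "chrom", "bp", "gene", "distance", "h2", "threshold"]
        )
    else:
        combined = pd.concat(frames, ignore_index=True)

    def _fmt(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        if "distance" in df.columns:
            df["distance"] = [
                "within" if (pd.notna(d) and int(d) == 0) else ("" if pd.isna(d) else str(int(d)))
                for d in df["distance"]
            ]
        for col in ("h2", "threshold"):
            if col in df.columns:
                df[col] = df[col].map(lambda v: f"{v:.5f}")
        return df

    key = (lambda t: groups.get(t, t)) if groups else (lambda t: t)
    if not combined.empty:
        for gname, gdf in combined.groupby(combined["trait"].map(key), sort=False):
            path = out / f"significant_{str(gname).replace(' ', '_')}.tsv"
            _fmt(gdf).to_csv(path, sep="\t", index=False)
            written[str(gname)] = path
    path = out / "significant_all.tsv"
    _fmt(combined).to_csv(path, sep="\t", index=False)
    written["combined"] = path
    return written
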