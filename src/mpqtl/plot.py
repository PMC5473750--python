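"""Basic Manhattan and allele-frequency track plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def _genome_x(df: pd.DataFrame, chrom_col: str, pos_col: str) -> tuple[np.ndarray, dict[str, float]]:
    """Concatenate per-chromosome positions onto one genome axis."""
    offsets: dict[str, float] = {}
    x = np.empty(len(df), dtype=float)
    offset = 0.0
    for chrom in pd.unique(df[chrom_col]):
        mask = (df[chrom_col] == chrom).to_numpy()
        pos = df.loc[mask, pos_col].to_numpy(float)
        x[mask] = pos + offset
        offsets[chrom] = offset + (pos.max() if len(pos) else 0) / 2
        offset += (pos.max() if len(pos) else 0) + 1.0
    return x, offsets


def manhattan(scan_df: pd.DataFrame, path: str | Path, q_threshold: float = 0.5) -> None:
    """Per-trait Manhattan plot of -log10 p along the genome.

    Markers whose BH q-value passes the threshold are drawn larger.
    """
    ok = scan_df[scan_df["status"] == "ok"].copy()
    fig, ax = plt.subplots(figsize=(10, 3.2))
    x, centers = _genome_x(ok, "chromosome", "position")
    neglogp = -np.log10(ok["p_value"].to_numpy(float))
    colors = ["#31688e", "#35b779"]
    for i, chrom in enumerate(pd.unique(ok["chromosome"])):
        mask = (ok["chromosome"] == chrom).to_numpy()
        ax.scatter(x[mask], neglogp[mask], s=6, color=colors[i % 2], linewidths=0)
    sig = (ok["q_value"] <= q_threshold).to_numpy()
    if sig.any():
        ax.scatter(x[sig], neglogp[sig], s=18, color="#d62828", linewidths=0, label=f"q <= {q_threshold}")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xticks(list(centers.values()))
    ax.set_xticklabels(list(centers), fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 p")
    traits = ", ".join(pd.unique(ok["trait"]))
    ax.set_title(f"Wald genome scan: {traits}", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def af_track(af_df: pd.DataFrame, path: str | Path, q_threshold: float = 0.001) -> None:
    """Allele-frequency test track: -log10 p per SNP along the genome."""
    fig, ax = plt.subplots(figsize=(10, 3.2))
    x, centers = _genome_x(af_df, "chrom", "pos")
    neglogp = -np.log10(af_df["p_value"].to_numpy(float))
    ax.scatter(x, neglogp, s=6, color="#31688e", linewidths=0)
    if "q_value" in af_df.columns:
        sig = (af_df["q_value"] <= q_threshold).to_numpy()
        if sig.any():
            ax.scatter(x[sig], neglogp[sig], s=18, color="#d62828", linewidths=0,
                       label=f"q <= {q_threshold}")
            ax.legend(frameon=False, fontsize=8)
    ax.set_xticks(list(centers.values()))
    ax.set_xticklabels(list(centers), fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 Fisher p")
    ax.set_title("Pooled allele-frequency contrast (HLA vs LLA)", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
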