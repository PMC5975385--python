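"""Figures regenerated from the pipeline's report TSVs.

Every figure is derived only from the TSV reports in a pipeline output
directory, so plotting can be rerun offline without the raw inputs.
"""
from __future__ import annotations

from pathlib import Path
from typing import List

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def _read(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def make_figures(report_dir, fig_dir=None) -> List[Path]:
    """Render the standard figure set from a report directory."""
    report_dir = Path(report_dir)
    fig_dir = Path(fig_dir) if fig_dir else report_dir / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    consensus = _read(report_dir / "consensus.tsv")

    # per-sample counts of validated calls, by type
    fig, axes = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    validated = consensus[consensus["validated"] == True]  # noqa: E712
    for ax, cnv_type in zip(axes, ("DUP", "DEL")):
        counts = (
            validated[validated["cnv_type"] == cnv_type]
            .groupby("sample_id")
            .size()
            .reindex(sorted(consensus["sample_id"].unique()), fill_value=0)
        )
        ax.bar(range(len(counts)), counts.values, color="steelblue")
        ax.set_ylabel(f"{cnv_type} count")
        ax.set_xticks(range(len(counts)))
        ax.set_xticklabels(counts.index, rotation=90, fontsize=6)
    axes[0].set_title("Validated CNV calls per sample")
    path = fig_dir / "counts_per_sample.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    # length distributions
    fig, ax = plt.subplots(figsize=(7, 4))
    for cnv_type, color in (("DUP", "steelblue"), ("DEL", "firebrick")):
        lengths = validated.loc[validated["cnv_type"] == cnv_type, "length"]
        if not lengths.empty:
            ax.hist(lengths, bins=40, alpha=0.5, label=cnv_type, color=color)
    ax.set_xlabel("CNV length (bp)")
    ax.set_ylabel("count")
    ax.legend()
    ax.set_title("Validated CNV length distribution")
    path = fig_dir / "length_distributions.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    # genic / non-genic fractions, if annotations exist
    anno_path = report_dir / "annotations.tsv"
    if anno_path.exists():
        anno = _read(anno_path)
        fig, ax = plt.subplots(figsize=(6, 4))
        frac = (
            anno.groupby("cnv_type")["genic"].mean().reindex(["DUP", "DEL"]).fillna(0.0) * 100
        )
        ax.bar(frac.index, frac.values, color=["steelblue", "firebrick"])
        ax.set_ylabel("% genic")
        ax.set_ylim(0, 100)
        ax.set_title("Fraction of CNV clusters overlapping genes")
        path = fig_dir / "genic_fractions.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    # breed-specific percentages
    specific = _read(report_dir / "breed_specific.tsv")
    clusters = _read(report_dir / "clusters.tsv")
    fig, ax = plt.subplots(figsize=(7, 4))
    breeds = sorted(specific["breed"].unique()) if not specific.empty else []
    width = 0.35
    for offset, cnv_type, color in ((0, "DUP", "steelblue"), (width, "DEL", "firebrick")):
        values = []
        for breed in breeds:
            num = len(specific[(specific["breed"] == breed) & (specific["cnv_type"] == cnv_type)])
            denom = clusters[
                (clusters["cnv_type"] == cnv_type)
                & clusters["breed_counts"].fillna("").str.contains(breed)
            ]
            values.append(100.0 * num / len(denom) if len(denom) else 0.0)
        ax.bar([i + offset for i in range(len(breeds))], values, width, label=cnv_type, color=color)
    ax.set_xticks([i + width / 2 for i in range(len(breeds))])
    ax.set_xticklabels(breeds, rotation=30)
    ax.set_ylabel("% breed-specific")
    ax.legend()
    ax.set_title("Breed-specific share of each breed's observed CNV clusters")
    path = fig_dir / "breed_specific_percent.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    return written
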