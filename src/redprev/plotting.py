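"""Publication-style figures: forest plots, prevalence-by-age areas, scatter.

Thin matplotlib wrappers used by the analysis scripts; everything they draw
comes from the tabular outputs of the other modules.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def forest_plot(freq_table: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Forest plot of carrier frequencies (per 100k, log x) with Wilson CIs."""
    df = freq_table.dropna(subset=["per_100k"]).reset_index(drop=True)
    if df.empty:
        raise ValueError("no rows with a defined point estimate")
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(df) + 1.5))
    y = np.arange(len(df))[::-1]
    # the point estimate comes from the rounded "1 in x" and can sit a hair
    # outside the unrounded Wilson band; clip bar lengths at zero
    xerr = [
        np.maximum(0.0, df["per_100k"] - df["per_100k_low"]),
        np.maximum(0.0, df["per_100k_high"] - df["per_100k"]),
    ]
    ax.errorbar(
        df["per_100k"], y, xerr=xerr,
        fmt="s", color="black", ecolor="gray", capsize=2, markersize=4,
    )
    ax.set_yticks(y)
    ax.set_yticklabels(df["locus"] + " (" + df["category"] + ", " + df["population"] + ")")
    ax.set_xscale("log")
    ax.set_xlabel("carriers per 100,000 (95% Wilson CI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def prevalence_by_age_plot(
    bin_starts: np.ndarray,
    estimated: np.ndarray,
    reported: np.ndarray | None,
    path: str | Path,
    title: str = "",
) -> None:
    """Stacked-area style comparison of modelled vs reported cases by age."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.fill_between(bin_starts, estimated, step="post", alpha=0.7,
                    color="#1f4e79", label="modelled from carrier frequency")
    if reported is not None:
        ax.fill_between(bin_starts, reported, step="post", alpha=0.6,
                        color="#9dc3e6", label="reported prevalence")
    ax.set_xlabel("age (5-year bins)")
    ax.set_ylabel("expected affected individuals")
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def intermediate_pathogenic_scatter(
    scatter: pd.DataFrame, path: str | Path, annotation: str = ""
) -> None:
    """Intermediate vs pathogenic allele fractions, point size = allele count."""
    fig, ax = plt.subplots(figsize=(6, 5))
    sizes = scatter.get("n_intermediate", pd.Series(np.full(len(scatter), 20)))
    for pop, sub in scatter.groupby("population"):
        ax.scatter(
            sub["frac_intermediate"], sub["frac_pathogenic"],
            s=10 + 3 * np.sqrt(sizes.loc[sub.index].astype(float)), alpha=0.7, label=pop,
        )
    ax.set_xlabel("intermediate allele fraction")
    ax.set_ylabel("pathogenic allele fraction")
    ax.legend(title="population", fontsize=8)
    if annotation:
        ax.set_title(annotation)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
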