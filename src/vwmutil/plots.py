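"""Optional figure outputs: condition means with within-subject CIs and a
correlation-matrix heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["save_figures"]


def save_figures(scored: dict, results: dict, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    paths = []

    ci = results["utilization_ci"]
    conds = list(ci["condition_means"])
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(
        conds,
        [ci["condition_means"][c] for c in conds],
        yerr=[ci["ci_half_width"][c] for c in conds],
        capsize=4,
        color="steelblue",
    )
    if "capacity" in results:
        ax.axhline(results["capacity"]["mean_k"], ls="--", c="gray",
                   label="mean K (change detection)")
        ax.legend(fontsize=7)
    ax.set_ylabel("utilization (items/view)")
    ax.set_xlabel("set size")
    fig.tight_layout()
    p = out_dir / "utilization.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)

    mat = pd.DataFrame(results["correlation_matrix"])
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(mat.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(mat.index)), mat.index)
    for i in range(len(mat.index)):
        for j in range(len(mat.columns)):
            v = mat.iloc[i, j]
            if pd.notna(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, shrink=0.8)
    fig.tight_layout()
    p = out_dir / "correlation_matrix.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)
    return paths
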