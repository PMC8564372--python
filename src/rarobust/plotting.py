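"""Basic diagnostic plots: COMPACT heat maps and 3-D trajectories."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from rarobust.compact import CompactMatrix
from rarobust.trajectory import PrincipalCurve


def plot_compact(matrix, path: str | Path, title: str = "COMPACT") -> None:
    """Heat map of a COMPACT count grid (fine or coarse).

    Accepts a :class:`CompactMatrix` (plots the non-zero submatrix) or a
    labelled DataFrame such as the coarse 9 x 9 grid.
    """
    frame = matrix.nonzero_submatrix() if isinstance(matrix, CompactMatrix) else matrix
    fig, ax = plt.subplots(figsize=(max(4, frame.shape[1] * 0.3),
                                    max(4, frame.shape[0] * 0.3)))
    counts = frame.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        im = ax.imshow(np.log10(counts, where=counts > 0, out=np.full_like(counts, -1)),
                       cmap="viridis")
    ax.set_xticks(range(frame.shape[1]), frame.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(frame.shape[0]), frame.index, fontsize=6)
    ax.set_xlabel("RA pattern")
    ax.set_ylabel("DEAB pattern")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="log10 gene count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trajectory(
    scores: pd.DataFrame,
    curve: PrincipalCurve,
    metadata: pd.DataFrame,
    path: str | Path,
    title: str = "principal curve",
) -> None:
    """3-D scatter of PCA scores with the fitted curve, colored by treatment."""
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    meta = metadata.loc[scores.index]
    colors = {"Control": "tab:gray", "RA": "tab:red", "DEAB": "tab:blue"}
    for trt, sub in scores.groupby(meta["treatment"]):
        ax.scatter(sub["PC1"], sub["PC2"], sub["PC3"], s=12,
                   color=colors.get(trt, "tab:green"), label=str(trt), alpha=0.7)
    v = curve.vertices
    ax.plot(v[:, 0], v[:, 1], v[:, 2], color="black", lw=1.5)
    ax.scatter(*v[0], color="black", marker="*", s=90)  # curve start (λ = 0)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_zlabel("PC3")
    ax.legend(fontsize=8)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
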