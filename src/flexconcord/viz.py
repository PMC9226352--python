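"""Figures: PAE/DV heatmaps and per-residue profile overlays.

Heatmaps use a 256-bin colour scale running from dark green (lowest value)
to white (highest value). Explicit break lists produce piecewise bins that
honour the breaks exactly — useful when a matrix's dynamic range hides
block structure under equal-width binning. A histogram of the matrix values
is drawn alongside the colour bar so the value distribution is visible.

Every figure has a numeric TSV sidecar; no result exists only as pixels.
"""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm, LinearSegmentedColormap

#: Dark green -> white, low -> high.
GREEN_WHITE = LinearSegmentedColormap.from_list(
    "flexconcord_green_white", ["#00441b", "#ffffff"], N=256
)


def save_matrix_tsv(values: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(values, dtype=float), delimiter="\t", fmt="%.6g")


def heatmap(
    matrix,
    out_path,
    breaks: Optional[Sequence[float]] = None,
    title: str = "",
    sidecar_path=None,
):
    """Render a square matrix as a green-to-white heatmap.

    ``breaks`` (strictly increasing values, units of the matrix) switch the
    colour mapping to piecewise bins with those boundaries. The colour-bar
    axis carries a histogram of the matrix values.
    """
    values = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"heatmap needs a square matrix, got {values.shape}")
    if breaks is not None:
        breaks = [float(b) for b in breaks]
        if len(breaks) < 2 or np.any(np.diff(breaks) <= 0):
            raise ValueError("breaks must be strictly increasing")
        norm = BoundaryNorm(breaks, ncolors=256)
    else:
        norm = None

    fig, (ax, cax) = plt.subplots(
        1, 2, figsize=(7.2, 6), gridspec_kw={"width_ratios": [12, 1]}
    )
    im = ax.imshow(values, cmap=GREEN_WHITE, norm=norm, origin="lower")
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    if title:
        ax.set_title(title)
    fig.colorbar(im, cax=cax)
    # value histogram alongside the colour bar
    hist_ax = cax.twiny()
    counts, edges = np.histogram(values.ravel(), bins=64)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist_ax.barh(
        centers,
        counts,
        height=np.diff(edges),
        color="0.3",
        alpha=0.55,
        align="center",
    )
    hist_ax.set_xticks([])
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    if sidecar_path is not None:
        save_matrix_tsv(values, sidecar_path)
    return out_path


def profile_overlay(profile, out_path, columns: Optional[Sequence[str]] = None):
    """Overlay normalised per-residue score traces (one line per column)."""
    from .scores import minmax_normalize

    cols = list(columns) if columns is not None else profile.columns()
    fig, ax = plt.subplots(figsize=(8, 3.2))
    x = np.arange(profile.residue_count)
    styles = {
        "rmsf": dict(color="crimson"),
        "af2_score": dict(color="black"),
        "plddt": dict(color="gray", linestyle=":"),
        "sqrt_b": dict(color="saddlebrown"),
        "external_disorder": dict(color="steelblue", linestyle="--"),
    }
    for col in cols:
        v = getattr(profile, col, None)
        if v is None:
            continue
        if np.ptp(v) > 0:
            v = minmax_normalize(v)
        ax.plot(x, v, label=col, **styles.get(col, {}))
    ax.set_xlabel("residue index")
    ax.set_ylabel("normalized score (AU)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
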