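"""Attention heatmap rendering.

Three modes mirror the usual diagnostic views of multi-head attention:
a single head's full map, a lattice of all guided heads, and the map averaged
over all collected heads. Axes are labeled with the token strings (prefix key
columns get ``<p0>..`` labels in single-head mode when shown).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .prefix_encoder import AttentionMapStack

__all__ = ["render_attention_heatmap"]


def render_attention_heatmap(
    stack: AttentionMapStack,
    tokens: list[str],
    out_path: str | Path,
    mode: str = "averaged",
    batch_index: int = 0,
    head_index: int = 0,
    include_prefix: bool = False,
) -> Path:
    """Render attention maps for one sentence of a batch to an image file.

    ``mode``: ``single-head`` (one panel for ``head_index``), ``all-heads``
    (panel lattice over every collected head) or ``averaged`` (mean over all
    heads). Token axes are restricted to real (unmasked) positions; prefix
    columns are appended only when ``include_prefix`` is set.
    """
    maps = stack.maps.data[batch_index]  # (m, L, L+P)
    valid = stack.query_mask[batch_index].astype(bool)
    L = int(valid.sum())
    P = stack.P if include_prefix else 0
    labels = list(tokens)[:L]
    if len(labels) < L:
        labels += [f"<{i}>" for i in range(len(labels), L)]
    col_labels = labels + [f"<p{i}>" for i in range(P)]

    def crop(a: np.ndarray) -> np.ndarray:
        cols = np.concatenate([np.arange(L), stack.L + np.arange(P)]) if P else np.arange(L)
        return a[np.ix_(np.arange(L), cols)]

    out_path = Path(out_path)
    if mode == "single-head":
        fig, ax = plt.subplots(figsize=(6, 5))
        _panel(ax, crop(maps[head_index]), labels, col_labels)
        ax.set_title(f"head {head_index}")
    elif mode == "all-heads":
        m = maps.shape[0]
        ncols = min(m, 4)
        nrows = int(np.ceil(m / ncols))
        fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.6 * nrows),
                                 squeeze=False)
        for i in range(nrows * ncols):
            ax = axes[i // ncols][i % ncols]
            if i < m:
                _panel(ax, crop(maps[i]), None, None)
                ax.set_title(f"head {i}", fontsize=8)
            else:
                ax.axis("off")
    elif mode == "averaged":
        fig, ax = plt.subplots(figsize=(6, 5))
        _panel(ax, crop(maps.mean(axis=0)), labels, col_labels)
        ax.set_title("attention averaged over all collected heads")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def _panel(ax, mat: np.ndarray, row_labels, col_labels):
    ax.imshow(mat, cmap="Blues", aspect="auto", vmin=0.0)
    if row_labels is not None:
        ax.set_yticks(range(len(row_labels)), row_labels, fontsize=7)
        ax.set_xticks(range(len(col_labels)), col_labels, fontsize=7, rotation=90)
    else:
        ax.set_xticks([])
        ax.set_yticks([])
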