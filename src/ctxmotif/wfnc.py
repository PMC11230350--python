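"""Windowed functional network connectivity (wFNC) baseline.

A window's wFNC is the Pearson correlation matrix of its N channels over the
W timesteps, vectorized as the upper triangle (i < j, row-major, diagonal
excluded) into a length ``N(N-1)/2`` vector.  PCA on train+val wFNC vectors
gives size-matched embeddings for comparison against the latent models.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .data import WindowSet

__all__ = [
    "window_fnc", "windowset_fnc", "vectorize_fnc", "devectorize_fnc",
    "fit_pca", "mean_fnc", "load_domain_labels", "export_fnc_csv",
    "plot_fnc_heatmap",
]


def vectorize_fnc(matrix: np.ndarray) -> np.ndarray:
    """Upper triangle (i < j, row-major) of a square matrix as a vector."""
    matrix = np.asarray(matrix, dtype=float)
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def devectorize_fnc(values: np.ndarray, fill_diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric matrix from an upper-triangle vector."""
    values = np.asarray(values, dtype=float)
    # n(n-1)/2 = len  ->  n
    n = int(round((1 + np.sqrt(1 + 8 * len(values))) / 2))
    if n * (n - 1) // 2 != len(values):
        raise ValueError(f"vector length {len(values)} is not n(n-1)/2 for integer n")
    mat = np.full((n, n), fill_diagonal, dtype=float)
    iu = np.triu_indices(n, k=1)
    mat[iu] = values
    mat[(iu[1], iu[0])] = values
    return mat


def window_fnc(window: np.ndarray, window_id=None) -> np.ndarray:
    """Pearson correlations between all channel pairs within one window.

    ``window`` is ``[N, W]``; returns the vectorized upper triangle, all
    values in [-1, 1].  Correlations are invariant to per-channel positive
    scaling and constant shifts.  A channel with zero variance inside the
    window is an error naming the channel (and window, when provided).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValueError("window must be [N channels, W timesteps]")
    sd = window.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        where = f" in window {window_id}" if window_id is not None else ""
        raise ValueError(f"zero-variance channel(s) {zero.tolist()}{where}: "
                         "Pearson correlation undefined")
    corr = np.corrcoef(window)
    return np.clip(vectorize_fnc(corr), -1.0, 1.0)


def windowset_fnc(window_set: WindowSet | np.ndarray) -> np.ndarray:
    """wFNC vectors for every window, shape ``[M, N(N-1)/2]``."""
    windows = window_set.windows if isinstance(window_set, WindowSet) else np.asarray(window_set)
    return np.stack([window_fnc(w, window_id=j) for j, w in enumerate(windows)])


def fit_pca(train_val_fncs: np.ndarray | Sequence[np.ndarray], n_components: int) -> PCA:
    """Centered PCA fitted on train+val wFNC vectors only.

    The returned embedder transforms any wFNC vector into the train+val PCA
    space (the test set is never part of the fit).
    """
    X = np.asarray(train_val_fncs, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a [n_vectors, n_features] array of wFNC vectors")
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_vectors, n_features)={min(X.shape)}"
        )
    return PCA(n_components=n_components, svd_solver="full").fit(X)


def mean_fnc(fncs: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise mean of wFNC vectors (e.g. over one cluster's windows)."""
    X = np.asarray(fncs, dtype=float)
    if X.size == 0:
        raise ValueError("mean_fnc of an empty collection is undefined")
    return X.mean(axis=0) if X.ndim == 2 else X


def load_domain_labels(path: str | None = None) -> list[str]:
    """Per-component functional-domain labels, in matrix order.

    Defaults to the shipped 53-component NeuroMark fMRI 1.0 ordering
    (contiguous domain blocks); pass a YAML file with the same layout for
    other templates.
    """
    import importlib.resources

    import yaml

    if path is None:
        ref = importlib.resources.files("ctxmotif") / "neuromark_domains.yaml"
        doc = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    labels: list[str] = []
    for dom in doc["domains"]:
        labels.extend([dom["name"]] * int(dom["n_components"]))
    return labels


def export_fnc_csv(values: np.ndarray, path: str) -> str:
    """Write a wFNC (vector or square matrix) as a CSV correlation matrix."""
    values = np.asarray(values, dtype=float)
    mat = devectorize_fnc(values) if values.ndim == 1 else values
    np.savetxt(path, mat, delimiter=",", fmt="%.10g")
    return path


def plot_fnc_heatmap(
    values: np.ndarray,
    out: str,
    domain_labels: Sequence[str] | None = None,
    title: str | None = None,
    vmax: float | None = None,
) -> str:
    """Render a wFNC (vector or matrix) as a heatmap.

    When ``domain_labels`` (one per component, contiguous blocks) are given
    and match the matrix size, domain boundaries are drawn and ticks placed
    at block centres.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    mat = devectorize_fnc(values, fill_diagonal=0.0) if values.ndim == 1 else values
    n = mat.shape[0]
    limit = vmax if vmax is not None else float(np.max(np.abs(mat))) or 1.0
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-limit, vmax=limit)
    fig.colorbar(im, ax=ax, label="correlation")
    if domain_labels is not None and len(domain_labels) == n:
        bounds, ticks, names = [], [], []
        start = 0
        for i in range(1, n + 1):
            if i == n or domain_labels[i] != domain_labels[start]:
                bounds.append(i - 0.5)
                ticks.append((start + i - 1) / 2)
                names.append(domain_labels[start])
                start = i
        for b in bounds[:-1]:
            ax.axhline(b, color="k", lw=0.5)
            ax.axvline(b, color="k", lw=0.5)
        ax.set_xticks(ticks, names, rotation=90, fontsize=7)
        ax.set_yticks(ticks, names, fontsize=7)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
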