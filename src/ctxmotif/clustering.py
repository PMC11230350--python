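"""Context-space cluster analysis of patient windows.

Patient (SZ) window context embeddings are clustered with k-means (default
k=3, matching the three patient states seen in the context space); per-subject
*dwell counts* — how many of a subject's windows land in each cluster — proxy
time spent in each state.  Cluster membership and dwell counts are then
related to demographics (age) and cognition (CMINDS-like scores) with t-tests
and Pearson correlations, and each cluster is visualized as its mean wFNC
pattern minus the overall patient mean.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .data import WindowSet
from .evaluation import group_ttest, pearson_r
from .wfnc import mean_fnc, windowset_fnc

__all__ = [
    "ClusterResult", "ClusterFNCMap", "kmeans_context",
    "cluster_membership_test", "dwell_correlation", "cluster_fnc_maps",
    "plot_context_space", "match_clusters_to_modes",
]


@dataclasses.dataclass
class ClusterResult:
    """K-means clustering of patient windows with per-subject dwell counts."""

    k: int
    centers: np.ndarray                 #: [k, CS]
    window_assignments: np.ndarray      #: cluster id per patient window
    window_subjects: np.ndarray         #: source subject id per patient window
    dwell_counts: pd.DataFrame          #: [n_subjects x k], rows indexed by subject_id
    kmeans_seed: int
    inertia: float


@dataclasses.dataclass
class ClusterFNCMap:
    """Per-cluster mean wFNC and its difference from the overall patient mean."""

    cluster_means: np.ndarray       #: [k, N(N-1)/2]
    cluster_differences: np.ndarray #: cluster mean - overall SZ mean
    overall_mean: np.ndarray
    cluster_sizes: np.ndarray


def kmeans_context(
    patient_context_embeddings: np.ndarray,
    window_subjects: Sequence[str],
    k: int = 3,
    kmeans_seed: int = 0,
    n_init: int = 10,
) -> ClusterResult:
    """Cluster patient window embeddings with seeded k-means (k-means++ init,
    ``n_init`` restarts, best inertia kept).

    Only patient windows should be passed (controls are projected for
    plotting but not clustered).  Dwell counts per subject sum to that
    subject's window count.
    """
    X = np.asarray(patient_context_embeddings, dtype=float)
    subjects = np.asarray(window_subjects)
    if X.shape[0] != len(subjects):
        raise ValueError("one subject id is required per window")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of windows ({X.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=kmeans_seed).fit(X)
    ids = pd.unique(subjects)
    counts = pd.DataFrame(0, index=pd.Index(ids, name="subject_id"),
                          columns=range(k), dtype=int)
    for sid, lab in zip(subjects, km.labels_):
        counts.loc[sid, lab] += 1
    return ClusterResult(
        k=k,
        centers=km.cluster_centers_,
        window_assignments=km.labels_.copy(),
        window_subjects=subjects,
        dwell_counts=counts,
        kmeans_seed=kmeans_seed,
        inertia=float(km.inertia_),
    )


def cluster_membership_test(
    cluster_id: int,
    cluster_result: ClusterResult,
    subject_metadata: pd.DataFrame,
    covariate: str,
) -> tuple[float, float]:
    """Welch t-test on a covariate between patients with and without windows
    in a cluster.

    "Present in the cluster" means dwell count > 0.  Positive t means members
    have the larger covariate mean (e.g. older members).
    """
    dwell = cluster_result.dwell_counts[cluster_id]
    values = subject_metadata.loc[dwell.index, covariate].astype(float)
    member = values[dwell > 0].dropna()
    non_member = values[dwell == 0].dropna()
    if len(member) < 2 or len(non_member) < 2:
        raise ValueError(
            f"cluster {cluster_id}: need >= 2 member and non-member subjects with "
            f"{covariate!r} (have {len(member)}/{len(non_member)})"
        )
    return group_ttest(member.to_numpy(), non_member.to_numpy())


def dwell_correlation(
    cluster_id: int,
    cluster_result: ClusterResult,
    subject_metadata: pd.DataFrame,
    covariate: str,
) -> tuple[float, float]:
    """Pearson correlation between time spent in a cluster and a covariate.

    Dwell counts are the clustered (patient) subjects'; subjects with a
    missing covariate are dropped.
    """
    dwell = cluster_result.dwell_counts[cluster_id]
    values = subject_metadata.loc[dwell.index, covariate].astype(float)
    keep = values.notna()
    if keep.sum() < 3:
        raise ValueError(f"need >= 3 subjects with {covariate!r}")
    return pearson_r(dwell[keep].to_numpy(dtype=float), values[keep].to_numpy())


def cluster_fnc_maps(cluster_result: ClusterResult, window_set: WindowSet) -> ClusterFNCMap:
    """Mean wFNC per cluster and its difference from the overall patient mean.

    ``window_set`` must hold the same patient windows, in the same order, that
    were clustered.  The size-weighted average of cluster means reconstructs
    the overall mean exactly.
    """
    if len(window_set) != len(cluster_result.window_assignments):
        raise ValueError("window set and cluster assignments are misaligned")
    fncs = windowset_fnc(window_set)
    overall = mean_fnc(fncs)
    means, sizes = [], []
    for c in range(cluster_result.k):
        members = fncs[cluster_result.window_assignments == c]
        if members.shape[0] == 0:
            raise ValueError(f"cluster {c} is empty")
        means.append(mean_fnc(members))
        sizes.append(members.shape[0])
    means = np.stack(means)
    return ClusterFNCMap(
        cluster_means=means,
        cluster_differences=means - overall,
        overall_mean=overall,
        cluster_sizes=np.array(sizes),
    )


def match_clusters_to_modes(
    cluster_result: ClusterResult,
    true_modes_per_window: np.ndarray,
) -> dict[int, int]:
    """Map ground-truth mode -> cluster id by maximal-overlap (Hungarian)
    assignment.  Only meaningful on synthetic cohorts where window-level mode
    labels exist; real data needs no such step.
    """
    from scipy.optimize import linear_sum_assignment

    modes = np.asarray(true_modes_per_window)
    mode_ids = np.unique(modes)
    overlap = np.zeros((len(mode_ids), cluster_result.k))
    for i, m in enumerate(mode_ids):
        for c in range(cluster_result.k):
            overlap[i, c] = np.sum((modes == m) & (cluster_result.window_assignments == c))
    rows, cols = linear_sum_assignment(-overlap)
    return {int(mode_ids[r]): int(c) for r, c in zip(rows, cols)}


def plot_context_space(
    context_embeddings: np.ndarray,
    color_values: np.ndarray,
    color_by: str,
    out: str,
    title: str | None = None,
) -> str:
    """Scatter the context space colored by cluster/diagnosis/age/score.

    2-D embeddings are plotted directly; higher-dimensional ones are
    projected onto their first two principal components (axes labeled PC1 /
    PC2).  Categorical colorings (``cluster``, ``diagnosis``) get a legend
    with one entry per category; continuous ones a colorbar.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if color_by not in ("cluster", "diagnosis", "age", "score"):
        raise ValueError("color_by must be one of cluster/diagnosis/age/score")
    Z = np.asarray(context_embeddings, dtype=float)
    if Z.shape[1] == 2:
        xy, labels = Z, ("context dim 1", "context dim 2")
    else:
        from sklearn.decomposition import PCA

        xy = PCA(n_components=2, svd_solver="full").fit_transform(Z)
        labels = ("PC1", "PC2")
    fig, ax = plt.subplots(figsize=(5, 4))
    color_values = np.asarray(color_values)
    if color_by in ("cluster", "diagnosis"):
        for value in np.unique(color_values):
            sel = color_values == value
            ax.scatter(xy[sel, 0], xy[sel, 1], s=8, label=str(value))
        ax.legend(title=color_by)
    else:
        sc = ax.scatter(xy[:, 0], xy[:, 1], s=8, c=color_values.astype(float))
        fig.colorbar(sc, ax=ax, label=color_by)
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
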