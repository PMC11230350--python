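"""Quantitative evaluations of window embeddings.

Four families, each deterministic given its seed(s):

* **Window classification** — linear SVM separating patient from control
  windows in an embedding space, trained on train+val subjects and scored on
  held-out subjects' windows.
* **Cross-seed reliability** — how well one training seed's context space
  predicts another's under a linear map, averaged over all ordered seed
  pairs (R² of multi-output OLS).
* **Manifold comparison** — R² of a linear regression from normalized
  pairwise distances in the wFNC space to distances in a latent space; low
  values mean the latent features are complementary to connectivity.
* **Step-distance statistics** — per-subject mean Euclidean step length of
  the local-embedding trajectory, compared between groups with a
  subject-level permutation z-score.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "classify_windows", "cross_seed_reliability", "distance_manifold_r2",
    "step_distances", "step_distance_permutation", "PermutationResult",
    "group_ttest", "pearson_r",
]


def classify_windows(
    train_embeddings: np.ndarray,
    train_labels: np.ndarray,
    test_embeddings: np.ndarray,
    test_labels: np.ndarray,
    C: float = 1.0,
) -> float:
    """Test accuracy of a linear SVM separating the two diagnosis groups.

    Embeddings are standardized on the training (train+val) set; the caller
    is responsible for drawing train and test windows from disjoint subjects.
    """
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training labels contain a single class")
    scaler = StandardScaler().fit(train_embeddings)
    svm = SVC(kernel="linear", C=C).fit(scaler.transform(train_embeddings), train_labels)
    return float(svm.score(scaler.transform(test_embeddings), test_labels))


def cross_seed_reliability(
    embeddings_by_seed: Mapping[int, np.ndarray] | Sequence[np.ndarray],
    return_pairs: bool = False,
):
    """Mean R² of linear maps between seeds' embeddings of the same windows.

    For every ordered pair of seeds (a -> b), fit ordinary least squares from
    a's embeddings to b's (with intercept) and score R² uniformly averaged
    over output dimensions; return the mean over all ordered pairs.  R² = 1
    iff the spaces agree up to an affine map; independent spaces give R² ≈ 0.
    """
    if isinstance(embeddings_by_seed, Mapping):
        keys = list(embeddings_by_seed.keys())
        spaces = [np.asarray(embeddings_by_seed[k], dtype=float) for k in keys]
    else:
        keys = list(range(len(embeddings_by_seed)))
        spaces = [np.asarray(e, dtype=float) for e in embeddings_by_seed]
    if len(spaces) < 2:
        raise ValueError("need at least two seeds")
    n = spaces[0].shape[0]
    if any(s.shape[0] != n for s in spaces):
        raise ValueError("all seeds must embed the same windows (row counts differ)")
    pairs = {}
    for i, j in itertools.permutations(range(len(spaces)), 2):
        reg = LinearRegression().fit(spaces[i], spaces[j])
        pairs[(keys[i], keys[j])] = float(
            r2_score(spaces[j], reg.predict(spaces[i]), multioutput="uniform_average")
        )
    mean = float(np.mean(list(pairs.values())))
    return (mean, pairs) if return_pairs else mean


def distance_manifold_r2(
    latent_embeddings: np.ndarray,
    fnc_vectors: np.ndarray,
    n_pairs: int | None = 100_000,
    pair_seed: int = 0,
) -> float:
    """R² of predicting latent-space distances from wFNC-space distances.

    Samples ``n_pairs`` distinct window pairs without replacement (seeded;
    ``None`` uses all pairs), computes Euclidean distances in both spaces,
    standardizes each distance set, and regresses latent on wFNC distances.
    """
    Z = np.asarray(latent_embeddings, dtype=float)
    F = np.asarray(fnc_vectors, dtype=float)
    if Z.shape[0] != F.shape[0]:
        raise ValueError("embedding and wFNC row counts differ")
    m = Z.shape[0]
    total = m * (m - 1) // 2
    if n_pairs is None or n_pairs >= total:
        if n_pairs is not None and n_pairs > total:
            raise ValueError(f"n_pairs={n_pairs} exceeds the {total} available pairs")
        ii, jj = np.triu_indices(m, k=1)
    else:
        rng = np.random.default_rng(pair_seed)
        flat = rng.choice(total, size=n_pairs, replace=False)
        # invert the row-major upper-triangle linear index
        ii = (m - 2 - np.floor(np.sqrt(-8 * flat + 4 * m * (m - 1) - 7) / 2 - 0.5)).astype(int)
        jj = (flat + ii + 1 - ii * (2 * m - ii - 1) // 2).astype(int)
    dz = np.linalg.norm(Z[ii] - Z[jj], axis=1)
    df = np.linalg.norm(F[ii] - F[jj], axis=1)
    dz = (dz - dz.mean()) / dz.std()
    df = (df - df.mean()) / df.std()
    reg = LinearRegression().fit(df[:, None], dz)
    return float(r2_score(dz, reg.predict(df[:, None])))


def step_distances(
    local_by_subject: Mapping[str, np.ndarray],
) -> dict[str, float]:
    """Per-subject mean Euclidean distance between consecutive timesteps.

    Input maps subject_id to a temporally ordered ``[T', d]`` trajectory
    (by default local embeddings from non-overlapping windows, so every
    timestep appears once).  Homogeneous: scaling a trajectory by ``a``
    scales its mean step by ``|a|``.
    """
    out = {}
    for sid, traj in local_by_subject.items():
        traj = np.asarray(traj, dtype=float)
        if traj.ndim == 1:
            traj = traj[:, None]
        if traj.shape[0] < 2:
            raise ValueError(f"subject {sid}: need at least 2 timesteps")
        out[sid] = float(np.mean(np.linalg.norm(np.diff(traj, axis=0), axis=1)))
    return out


@dataclasses.dataclass
class PermutationResult:
    """Subject-level permutation test of a group difference in mean step length."""

    observed_difference: float  #: mean(SZ steps) - mean(HC steps)
    null_mean: float
    null_sd: float
    z_score: float
    n_permutations: int
    permutation_seed: int | None


def step_distance_permutation(
    per_subject_steps: Sequence[float] | np.ndarray,
    diagnoses: Sequence[str] | np.ndarray,
    n_permutations: int | str = 10_000,
    permutation_seed: int = 0,
) -> PermutationResult:
    """Permutation z-score for the SZ-minus-HC difference in mean step length.

    Subject labels are permuted ``n_permutations`` times (or exhaustively with
    ``n_permutations="exhaustive"``, enumerating every way to assign the SZ
    labels); the z-score standardizes the observed difference by the null's
    mean and sd.  Negative z means patients take smaller steps.
    """
    steps = np.asarray(per_subject_steps, dtype=float)
    dx = np.asarray(diagnoses)
    is_sz = dx == "SZ"
    n_sz = int(is_sz.sum())
    if n_sz == 0 or n_sz == len(dx):
        raise ValueError("both diagnosis groups must be non-empty")
    observed = float(steps[is_sz].mean() - steps[~is_sz].mean())

    n = len(steps)
    if n_permutations == "exhaustive":
        diffs = np.array([
            steps[list(combo)].mean() - np.delete(steps, list(combo)).mean()
            for combo in itertools.combinations(range(n), n_sz)
        ])
        n_perm = len(diffs)
        seed_used = None
    else:
        n_perm = int(n_permutations)
        rng = np.random.default_rng(permutation_seed)
        diffs = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(n)
            sz_idx = perm[:n_sz]
            hc_idx = perm[n_sz:]
            diffs[i] = steps[sz_idx].mean() - steps[hc_idx].mean()
        seed_used = permutation_seed
    null_mean = float(diffs.mean())
    null_sd = float(diffs.std())
    if null_sd == 0:
        raise ValueError("degenerate permutation null (all permuted differences equal)")
    return PermutationResult(
        observed_difference=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=(observed - null_mean) / null_sd,
        n_permutations=n_perm,
        permutation_seed=seed_used,
    )


def group_ttest(values_a, values_b) -> tuple[float, float]:
    """Two-sided independent-samples t-test (Welch), a minus b direction."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both groups have zero variance; t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
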