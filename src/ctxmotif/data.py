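"""Domain types and IO for ICA component timecourse cohorts.

A cohort is a set of subjects, each carrying a ``[N components x T timesteps]``
timecourse matrix (e.g. NeuroMark ICA components, N=53) plus clinical metadata
(diagnosis SZ/HC, age, sex, cognition and symptom scores).  Timecourses live in
one delimited matrix file per subject (rows = components, no header) next to a
metadata CSV.  Modelling consumes overlapping windows of these matrices.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DIAGNOSES = ("SZ", "HC")

#: metadata CSV columns, in the order they are written
METADATA_COLUMNS = [
    "subject_id",
    "diagnosis",
    "age",
    "sex",
    "site",
    "cmnds_score",
    "panss_pos",
    "panss_neg",
    "panss_comp",
]


@dataclasses.dataclass
class SubjectRecord:
    """One subject: component timecourses plus clinical metadata.

    ``timecourses`` has shape ``[N, T]`` with rows = ICA components and
    columns = timesteps.  ``cmnds_score`` is a composite cognition score
    (negative = worse than the control mean); PANSS fields are symptom scores
    and may be missing (None) for controls.
    """

    subject_id: str
    diagnosis: str
    age: float
    timecourses: np.ndarray
    sex: str = "U"
    site: str | None = None
    cmnds_score: float | None = None
    panss_pos: float | None = None
    panss_neg: float | None = None
    panss_comp: float | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(
                f"subject {self.subject_id}: diagnosis must be one of "
                f"{DIAGNOSES}, got {self.diagnosis!r}"
            )
        self.timecourses = np.asarray(self.timecourses, dtype=float)
        if self.timecourses.ndim != 2:
            raise ValueError(
                f"subject {self.subject_id}: timecourses must be 2-D "
                f"[components x timesteps], got shape {self.timecourses.shape}"
            )
        if not np.all(np.isfinite(self.timecourses)):
            bad = np.argwhere(~np.isfinite(self.timecourses))[0]
            raise ValueError(
                f"subject {self.subject_id}: non-finite value in timecourses "
                f"at (component {bad[0]}, timestep {bad[1]})"
            )

    @property
    def n_components(self) -> int:
        return self.timecourses.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.timecourses.shape[1]


@dataclasses.dataclass
class WindowSet:
    """Overlapping windows extracted from a cohort, with provenance.

    ``windows`` has shape ``[M, N, W]``; ``index[j] = (subject_id, start)``
    gives the source subject and the 0-based first timestep of window ``j``
    (windows are half-open slices ``[start, start + W)``).
    """

    windows: np.ndarray
    index: list[tuple[str, int]]
    window_length: int
    stride: int

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3:
            raise ValueError("windows must be [M, N, W]")
        if self.windows.shape[0] != len(self.index):
            raise ValueError("index length must equal the number of windows")
        if self.windows.shape[2] != self.window_length:
            raise ValueError("third axis must equal window_length")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def n_components(self) -> int:
        return self.windows.shape[1]

    @property
    def subject_ids(self) -> np.ndarray:
        """Source subject of every window, shape ``[M]``."""
        return np.array([s for s, _ in self.index])

    def select_subjects(self, subject_ids: Iterable[str]) -> "WindowSet":
        """Sub-WindowSet containing only windows from the given subjects."""
        keep = set(subject_ids)
        mask = np.array([s in keep for s, _ in self.index])
        return WindowSet(
            windows=self.windows[mask],
            index=[ix for ix, m in zip(self.index, mask) if m],
            window_length=self.window_length,
            stride=self.stride,
        )


@dataclasses.dataclass
class CohortSplit:
    """Subject-level train/val/test partition (no window-level leakage)."""

    train: list[str]
    val: list[str]
    test: list[str]
    split_seed: int

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.val), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = parts[i] & parts[j]
                if overlap:
                    raise ValueError(
                        f"subjects appear in two partitions: {sorted(overlap)}"
                    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _read_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def load_cohort(timecourse_dir: str | Path, metadata_table: str | Path) -> list[SubjectRecord]:
    """Load one TSV matrix per subject listed in the metadata CSV.

    Raises a descriptive error naming the subject for a missing file, a
    non-numeric/NaN cell, or an N (component count) mismatch across subjects.
    """
    timecourse_dir = Path(timecourse_dir)
    meta = pd.read_csv(metadata_table)
    if "subject_id" not in meta.columns or "diagnosis" not in meta.columns:
        raise ValueError("metadata table must have subject_id and diagnosis columns")

    records: list[SubjectRecord] = []
    for row in meta.itertuples(index=False):
        sid = str(row.subject_id)
        path = timecourse_dir / f"{sid}.tsv"
        if not path.exists():
            raise FileNotFoundError(
                f"no timecourse file for subject {sid} (expected {path})"
            )
        try:
            mat = np.loadtxt(path, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"subject {sid}: non-numeric cell in {path}: {exc}") from exc
        if not np.all(np.isfinite(mat)):
            bad = np.argwhere(~np.isfinite(mat))[0]
            raise ValueError(
                f"subject {sid}: non-finite value in {path} at "
                f"(row {bad[0]}, column {bad[1]})"
            )
        records.append(
            SubjectRecord(
                subject_id=sid,
                diagnosis=str(row.diagnosis),
                age=float(row.age),
                sex=str(getattr(row, "sex", "U")),
                site=(str(row.site) if getattr(row, "site", None) not in (None, "", float("nan")) and not pd.isna(getattr(row, "site", None)) else None),
                cmnds_score=_read_optional_float(getattr(row, "cmnds_score", None)),
                panss_pos=_read_optional_float(getattr(row, "panss_pos", None)),
                panss_neg=_read_optional_float(getattr(row, "panss_neg", None)),
                panss_comp=_read_optional_float(getattr(row, "panss_comp", None)),
                timecourses=mat,
            )
        )

    ns = {r.n_components for r in records}
    if len(ns) > 1:
        detail = ", ".join(f"{r.subject_id}: N={r.n_components}" for r in records)
        raise ValueError(f"component count differs across subjects ({detail})")
    return records


def write_cohort(records: Sequence[SubjectRecord], out_dir: str | Path) -> Path:
    """Write one TSV per subject plus ``metadata.csv``; inverse of load_cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        np.savetxt(out_dir / f"{r.subject_id}.tsv", r.timecourses, delimiter="\t", fmt="%.17g")
        rows.append(
            {
                "subject_id": r.subject_id,
                "diagnosis": r.diagnosis,
                "age": r.age,
                "sex": r.sex,
                "site": r.site,
                "cmnds_score": r.cmnds_score,
                "panss_pos": r.panss_pos,
                "panss_neg": r.panss_neg,
                "panss_comp": r.panss_comp,
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(out_dir / "metadata.csv", index=False)
    return out_dir


def save_windows(window_set: WindowSet, path: str | Path) -> Path:
    """Cache a WindowSet (windows + provenance index) as one HDF5 file."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("windows", data=window_set.windows)
        fh.create_dataset(
            "subject_ids",
            data=np.array([s for s, _ in window_set.index], dtype="S"),
        )
        fh.create_dataset("starts", data=np.array([t for _, t in window_set.index]))
        fh.attrs["window_length"] = window_set.window_length
        fh.attrs["stride"] = window_set.stride
    return path


def load_windows(path: str | Path) -> WindowSet:
    """Inverse of :func:`save_windows`; bit-identical round trip."""
    import h5py

    with h5py.File(path, "r") as fh:
        windows = fh["windows"][()]
        ids = [s.decode() for s in fh["subject_ids"][()]]
        starts = fh["starts"][()]
        return WindowSet(
            windows=windows,
            index=list(zip(ids, (int(t) for t in starts))),
            window_length=int(fh.attrs["window_length"]),
            stride=int(fh.attrs["stride"]),
        )


def metadata_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Per-subject metadata as a DataFrame indexed by subject_id."""
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "diagnosis": [r.diagnosis for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "site": [r.site for r in records],
            "cmnds_score": [r.cmnds_score for r in records],
            "panss_pos": [r.panss_pos for r in records],
            "panss_neg": [r.panss_neg for r in records],
            "panss_comp": [r.panss_comp for r in records],
        }
    )
    return df.set_index("subject_id")


# ---------------------------------------------------------------------------
# Normalization / windowing / splitting
# ---------------------------------------------------------------------------

def zscore_timecourses(record: SubjectRecord, ddof: int = 1) -> SubjectRecord:
    """Z-score each component row over time (mean 0, unit variance).

    Unit-variance inputs match the fixed-variance Gaussian likelihood used by
    the latent models.  A zero-variance component is an error (its z-score is
    undefined) naming the component index.
    """
    x = record.timecourses
    sd = x.std(axis=1, ddof=ddof)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"subject {record.subject_id}: zero-variance component(s) "
            f"{zero.tolist()} cannot be z-scored"
        )
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return dataclasses.replace(record, timecourses=z)


def extract_windows(
    records: Sequence[SubjectRecord], window_length: int = 30, stride: int = 1
) -> WindowSet:
    """Slice every subject into overlapping windows of ``window_length``.

    Each subject contributes ``floor((T - W) / stride) + 1`` windows; the
    index records (subject_id, start timestep) for every window.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    windows, index = [], []
    for r in records:
        if r.n_timesteps < window_length:
            raise ValueError(
                f"subject {r.subject_id}: T={r.n_timesteps} is shorter than "
                f"window length {window_length}"
            )
        for start in range(0, r.n_timesteps - window_length + 1, stride):
            windows.append(r.timecourses[:, start : start + window_length])
            index.append((r.subject_id, start))
    return WindowSet(
        windows=np.stack(windows), index=index, window_length=window_length, stride=stride
    )


def window_labels(window_set: WindowSet, records: Sequence[SubjectRecord]) -> np.ndarray:
    """Diagnosis label per window, inherited from the source subject."""
    by_id = {r.subject_id: r.diagnosis for r in records}
    return np.array([by_id[s] for s, _ in window_set.index])


def split_subjects(
    records: Sequence[SubjectRecord],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    split_seed: int = 0,
) -> CohortSplit:
    """Deterministic subject-level split, stratified by diagnosis.

    Window-level leakage is forbidden: every subject lands in exactly one of
    train/val/test.  Within each diagnosis the subjects are shuffled with
    ``split_seed`` and cut at the cumulative fractions, so each partition's
    diagnosis proportions track the cohort's to within one subject.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(split_seed)
    parts: list[list[str]] = [[], [], []]
    for dx in DIAGNOSES:
        ids = sorted(r.subject_id for r in records if r.diagnosis == dx)
        if not ids:
            continue
        rng.shuffle(ids)
        n = len(ids)
        cut1 = round(fractions[0] * n)
        cut2 = round((fractions[0] + fractions[1]) * n)
        for part, chunk in zip(parts, (ids[:cut1], ids[cut1:cut2], ids[cut2:])):
            part.extend(chunk)
    split = CohortSplit(train=parts[0], val=parts[1], test=parts[2], split_seed=split_seed)
    present = {r.diagnosis for r in records}
    if len(present) == 2:
        for name, part in (("train", split.train), ("val", split.val), ("test", split.test)):
            by_id = {r.subject_id: r.diagnosis for r in records}
            dxs = {by_id[s] for s in part}
            if dxs != set(DIAGNOSES):
                raise ValueError(
                    f"stratified split infeasible: partition {name!r} is missing a "
                    f"diagnosis group (has {sorted(dxs)}); add subjects or change fractions"
                )
    return split
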