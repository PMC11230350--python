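"""End-to-end experiment orchestration.

``run_experiment`` drives the full study on one cohort: generate or load
data, window it, train every (model kind, local size, context size) at every
seed, then run the evaluation suites (window classification incl. the
wFNC+PCA baseline, cross-seed reliability, manifold comparison, step-distance
permutation) and the patient context-space cluster analysis.  Every stage
writes JSON reports carrying the settings that produced them; the run
directory holds a manifest with the config hash and per-stage status, so a
completed stage is skipped on resume and a changed config is refused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import clustering, evaluation, models, synth, wfnc
from .data import (
    CohortSplit, WindowSet, extract_windows, load_cohort, metadata_frame,
    split_subjects, window_labels, write_cohort, zscore_timecourses,
)

logger = logging.getLogger("ctxmotif")

DEFAULT_GRID = (
    [{"model_kind": "DSVAE", "local_size": ls, "context_size": cs}
     for ls in (2, 4, 8) for cs in (2, 4, 8)]
    + [{"model_kind": "IDSVAE", "local_size": ls, "context_size": cs}
       for ls in (2, 4, 8) for cs in (2, 4, 8)]
    + [{"model_kind": "LVAE", "local_size": ls, "context_size": ls} for ls in (2, 4, 8)]
    + [{"model_kind": "CO", "local_size": 2, "context_size": cs} for cs in (2, 4, 8)]
)

ALL_SUITES = ("classification", "reliability", "manifold", "steps", "clusters")


@dataclasses.dataclass
class ExperimentConfig:
    """Validated, fully serializable configuration of one experiment."""

    out_dir: str
    data_dir: str | None = None             #: existing cohort (TSVs + metadata.csv)
    synth: dict | None = None               #: SyntheticParams overrides
    window_length: int = 30
    stride: int = 1
    models: list[dict] = dataclasses.field(default_factory=lambda: [dict(m) for m in DEFAULT_GRID])
    seeds: list[int] = dataclasses.field(default_factory=lambda: list(models.DEFAULT_SEEDS))
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    split_seed: int = 0
    training: dict = dataclasses.field(default_factory=dict)  #: beta/gamma/lr/epochs/...
    suites: list[str] = dataclasses.field(default_factory=lambda: list(ALL_SUITES))
    cluster_k: int = 3
    n_permutations: int = 10_000
    manifold_pairs: int = 100_000
    zscore: bool = True

    def __post_init__(self) -> None:
        if self.data_dir is None and self.synth is None:
            self.synth = {}
        for m in self.models:
            kind = m.get("model_kind")
            if kind not in models.MODEL_KINDS:
                raise ValueError(f"unknown model_kind {kind!r} in model grid")
        for s in self.suites:
            if s not in ALL_SUITES:
                raise ValueError(f"unknown evaluation suite {s!r}")
        if len(self.seeds) < 1:
            raise ValueError("need at least one seed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_fractions"] = list(d["split_fractions"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _model_tag(spec: dict) -> str:
    return f"{spec['model_kind']}_ls{spec['local_size']}_cs{spec['context_size']}"


def _write_json(path: Path, obj: Any) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)


class _Run:
    """One experiment directory with manifest-based resume."""

    def __init__(self, config: ExperimentConfig) -> None:
        self.config = config
        self.dir = Path(config.out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.dir / "manifest.json"
        if self.manifest_path.exists():
            with open(self.manifest_path) as fh:
                self.manifest = json.load(fh)
            if self.manifest["config_digest"] != config.digest():
                raise RuntimeError(
                    f"run directory {self.dir} was produced by a different config "
                    f"(digest {self.manifest['config_digest']} vs {config.digest()}); "
                    "use a fresh --out directory or restore the original config"
                )
        else:
            self.manifest = {
                "config_digest": config.digest(),
                "config": config.to_dict(),
                "stages": {},
            }
            self._flush()

    def _flush(self) -> None:
        _write_json(self.manifest_path, self.manifest)

    def done(self, stage: str) -> bool:
        return self.manifest["stages"].get(stage) == "done"

    def mark(self, stage: str) -> None:
        self.manifest["stages"][stage] = "done"
        self._flush()


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute every stage of the experiment; returns the run directory."""
    run = _Run(config)
    out = run.dir

    # ---- stage: data -------------------------------------------------------
    data_dir = out / "data"
    if not run.done("data"):
        logger.info("stage data: preparing cohort")
        if config.data_dir is not None:
            records = load_cohort(Path(config.data_dir), Path(config.data_dir) / "metadata.csv")
            write_cohort(records, data_dir)
        else:
            params = synth.SyntheticParams(**config.synth)
            records, truth = synth.generate_cohort(params)
            write_cohort(records, data_dir)
            save_ground_truth(truth, data_dir / "ground_truth.h5")
        run.mark("data")
    records = load_cohort(data_dir, data_dir / "metadata.csv")
    if config.zscore:
        records = [zscore_timecourses(r) for r in records]
    meta = metadata_frame(records)
    split = split_subjects(records, config.split_fractions, config.split_seed)
    windows = extract_windows(records, config.window_length, config.stride)
    w_trainval = windows.select_subjects(split.train + split.val)
    w_train = windows.select_subjects(split.train)
    w_val = windows.select_subjects(split.val)
    w_test = windows.select_subjects(split.test)
    labels_trainval = window_labels(w_trainval, records)
    labels_test = window_labels(w_test, records)

    # ---- stage: training ---------------------------------------------------
    ckpt_dir = out / "checkpoints"
    for spec in config.models:
        tag = _model_tag(spec)
        for seed in config.seeds:
            stage = f"train/{tag}/{seed}"
            path = ckpt_dir / tag / f"seed{seed}.npz"
            if run.done(stage) and path.exists():
                continue
            logger.info("training %s seed %s", tag, seed)
            cfg = {**spec, **config.training, "seed": seed}
            model = models.train(cfg, w_train, w_val)
            path.parent.mkdir(parents=True, exist_ok=True)
            models.save_model(model, path)
            run.mark(stage)

    def model_for(spec: dict, seed: int):
        return models.load_model(ckpt_dir / _model_tag(spec) / f"seed{seed}.npz")

    reports = out / "reports"

    # ---- stage: classification --------------------------------------------
    if "classification" in config.suites and not run.done("classification"):
        logger.info("stage classification")
        rows = []
        for spec in config.models:
            tag = _model_tag(spec)
            for seed in config.seeds:
                m = model_for(spec, seed)
                acc = evaluation.classify_windows(
                    m.transform(w_trainval), labels_trainval,
                    m.transform(w_test), labels_test,
                )
                rows.append({"model": tag, "seed": seed, "accuracy": acc})
        # size-matched wFNC + PCA baseline
        fnc_trainval = wfnc.windowset_fnc(w_trainval)
        fnc_test = wfnc.windowset_fnc(w_test)
        for cs in sorted({spec["context_size"] for spec in config.models}):
            pca = wfnc.fit_pca(fnc_trainval, n_components=cs)
            acc = evaluation.classify_windows(
                pca.transform(fnc_trainval), labels_trainval,
                pca.transform(fnc_test), labels_test,
            )
            rows.append({"model": f"wFNC_pca{cs}", "seed": None, "accuracy": acc})
        _write_json(reports / "classification.json", {
            "settings": {"split_seed": config.split_seed, "svm_C": 1.0},
            "results": rows,
        })
        run.mark("classification")

    # ---- stage: reliability ------------------------------------------------
    if "reliability" in config.suites and not run.done("reliability"):
        logger.info("stage reliability")
        rows = []
        if len(config.seeds) >= 2:
            for spec in config.models:
                if spec["model_kind"] == "CO":
                    continue
                tag = _model_tag(spec)
                spaces = {s: model_for(spec, s).transform(w_trainval) for s in config.seeds}
                mean, pairs = evaluation.cross_seed_reliability(spaces, return_pairs=True)
                rows.append({
                    "model": tag, "mean_r2": mean,
                    "pairs": {f"{a}->{b}": v for (a, b), v in pairs.items()},
                })
        _write_json(reports / "reliability.json", {
            "settings": {"seeds": config.seeds}, "results": rows,
        })
        run.mark("reliability")

    # ---- stage: manifold ---------------------------------------------------
    ref_spec = config.models[0]
    ref_seed = config.seeds[0]
    if "manifold" in config.suites and not run.done("manifold"):
        logger.info("stage manifold")
        m = model_for(ref_spec, ref_seed)
        fnc_all = wfnc.windowset_fnc(windows)
        total_pairs = len(windows) * (len(windows) - 1) // 2
        r2 = evaluation.distance_manifold_r2(
            m.transform(windows), fnc_all,
            n_pairs=min(config.manifold_pairs, total_pairs), pair_seed=config.split_seed,
        )
        _write_json(reports / "manifold.json", {
            "settings": {"model": _model_tag(ref_spec), "seed": ref_seed,
                         "n_pairs": min(config.manifold_pairs, total_pairs)},
            "r2": r2,
        })
        run.mark("manifold")

    # ---- stage: steps ------------------------------------------------------
    if "steps" in config.suites and not run.done("steps"):
        logger.info("stage steps")
        diag = {r.subject_id: r.diagnosis for r in records}
        results = {}
        # latent models with a local space (first seed), plus the raw input
        reps: dict[str, dict[str, np.ndarray]] = {}
        for spec in config.models:
            if spec["model_kind"] in ("DSVAE", "LVAE"):
                m = model_for(spec, ref_seed)
                reps[_model_tag(spec)] = {
                    r.subject_id: m.local_trajectory(r.timecourses) for r in records
                }
        reps["raw_input"] = {r.subject_id: r.timecourses.T for r in records}
        for name, traj in reps.items():
            steps = evaluation.step_distances(traj)
            sids = list(steps)
            res = evaluation.step_distance_permutation(
                [steps[s] for s in sids], [diag[s] for s in sids],
                n_permutations=config.n_permutations, permutation_seed=config.split_seed,
            )
            results[name] = dataclasses.asdict(res)
        _write_json(reports / "steps.json", {
            "settings": {"seed": ref_seed, "n_permutations": config.n_permutations},
            "results": results,
        })
        run.mark("steps")

    # ---- stage: clusters ---------------------------------------------------
    if "clusters" in config.suites and not run.done("clusters"):
        logger.info("stage clusters")
        m = model_for(ref_spec, ref_seed)
        sz_ids = [r.subject_id for r in records if r.diagnosis == "SZ"]
        w_sz = windows.select_subjects(sz_ids)
        ctx = m.transform(w_sz)
        result = clustering.kmeans_context(
            ctx, w_sz.subject_ids, k=config.cluster_k, kmeans_seed=config.split_seed,
        )
        stats_rows = []
        for c in range(result.k):
            row: dict[str, Any] = {"cluster": c,
                                   "n_windows": int((result.window_assignments == c).sum())}
            for cov in ("age", "cmnds_score"):
                try:
                    t, p = clustering.cluster_membership_test(c, result, meta, cov)
                    row[f"membership_t_{cov}"], row[f"membership_p_{cov}"] = t, p
                except ValueError as exc:
                    row[f"membership_t_{cov}"] = None
                    row[f"membership_note_{cov}"] = str(exc)
                try:
                    r, p = clustering.dwell_correlation(c, result, meta, cov)
                    row[f"dwell_r_{cov}"], row[f"dwell_p_{cov}"] = r, p
                except ValueError as exc:
                    row[f"dwell_r_{cov}"] = None
                    row[f"dwell_note_{cov}"] = str(exc)
            stats_rows.append(row)
        maps = clustering.cluster_fnc_maps(result, w_sz)
        figures = out / "figures"
        figures.mkdir(exist_ok=True)
        clustering.plot_context_space(
            ctx, result.window_assignments, "cluster",
            str(figures / "context_clusters.png"),
            title=f"{_model_tag(ref_spec)} patient context space",
        )
        all_ctx = m.transform(windows)
        clustering.plot_context_space(
            all_ctx, window_labels(windows, records), "diagnosis",
            str(figures / "context_diagnosis.png"),
        )
        result.dwell_counts.to_csv(reports / "dwell_counts.csv")
        np.savetxt(reports / "cluster_fnc_differences.csv",
                   maps.cluster_differences, delimiter=",")
        n_comp = windows.n_components
        try:
            domains = wfnc.load_domain_labels()
        except Exception:
            domains = None
        if domains is not None and len(domains) != n_comp:
            domains = None
        for c in range(result.k):
            wfnc.plot_fnc_heatmap(
                maps.cluster_differences[c],
                str(figures / f"cluster{c}_fnc_diff.png"),
                domain_labels=domains,
                title=f"cluster {c} mean wFNC − patient mean",
            )
        _write_json(reports / "clusters.json", {
            "settings": {"model": _model_tag(ref_spec), "seed": ref_seed,
                         "k": config.cluster_k, "kmeans_seed": config.split_seed},
            "inertia": result.inertia,
            "cluster_sizes": maps.cluster_sizes.tolist(),
            "stats": stats_rows,
        })
        run.mark("clusters")

    run.mark("complete")
    return out


def make_report(run_dir: str | Path) -> Path:
    """Render a single markdown summary of every report in a run directory."""
    run_dir = Path(run_dir)
    reports = run_dir / "reports"
    lines = ["# Experiment summary", ""]
    manifest = run_dir / "manifest.json"
    if manifest.exists():
        with open(manifest) as fh:
            digest = json.load(fh)["config_digest"]
        lines.append(f"Config digest: `{digest}`")
        lines.append("")
    missing = []

    def section(name: str, path: Path, render) -> None:
        lines.append(f"## {name}")
        if not path.exists():
            lines.append("_missing — stage did not run_")
            missing.append(name)
        else:
            with open(path) as fh:
                render(json.load(fh))
        lines.append("")

    def render_classification(doc):
        lines.append("| model | seed | window accuracy |")
        lines.append("|---|---|---|")
        for row in doc["results"]:
            lines.append(f"| {row['model']} | {row['seed']} | {row['accuracy']:.3f} |")

    def render_reliability(doc):
        lines.append("| model | mean R² across seed pairs |")
        lines.append("|---|---|")
        for row in doc["results"]:
            lines.append(f"| {row['model']} | {row['mean_r2']:.3f} |")

    def render_manifold(doc):
        lines.append(f"Latent-vs-wFNC distance R² = {doc['r2']:.3f} "
                     f"({doc['settings']['n_pairs']} window pairs).")

    def render_steps(doc):
        lines.append("| representation | observed SZ−HC step diff | z |")
        lines.append("|---|---|---|")
        for name, res in doc["results"].items():
            lines.append(f"| {name} | {res['observed_difference']:.4f} | "
                         f"{res['z_score']:.2f} |")

    def render_clusters(doc):
        lines.append(f"k = {doc['settings']['k']}, sizes = {doc['cluster_sizes']}")
        lines.append("")
        lines.append("| cluster | membership t (age) | dwell r (age) | "
                     "membership t (score) | dwell r (score) |")
        lines.append("|---|---|---|---|---|")
        for row in doc["stats"]:
            def fmt(v):
                return "–" if v is None else f"{v:.3f}"
            lines.append(
                f"| {row['cluster']} | {fmt(row.get('membership_t_age'))} | "
                f"{fmt(row.get('dwell_r_age'))} | "
                f"{fmt(row.get('membership_t_cmnds_score'))} | "
                f"{fmt(row.get('dwell_r_cmnds_score'))} |"
            )

    section("Window classification", reports / "classification.json", render_classification)
    section("Cross-seed reliability", reports / "reliability.json", render_reliability)
    section("Manifold comparison", reports / "manifold.json", render_manifold)
    section("Step distances", reports / "steps.json", render_steps)
    section("Context-space clusters", reports / "clusters.json", render_clusters)
    if missing:
        lines.insert(2, "**Missing sections:** " + ", ".join(missing) + "\n")
    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out


def save_ground_truth(truth: synth.GroundTruth, path: str | Path) -> None:
    """Persist synthetic ground truth as HDF5 (per-subject groups)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["age_mode"] = truth.age_mode
        fh.create_dataset("mode_centers", data=truth.mode_centers)
        for sid in truth.context:
            g = fh.create_group(f"subjects/{sid}")
            g.create_dataset("context", data=truth.context[sid])
            g.create_dataset("modes", data=truth.modes[sid])
            g.create_dataset("local", data=truth.local[sid])
            if sid in truth.occupancy:
                g.create_dataset("occupancy", data=truth.occupancy[sid])


def load_ground_truth(path: str | Path) -> synth.GroundTruth:
    import h5py

    context, modes, local, occupancy = {}, {}, {}, {}
    with h5py.File(path, "r") as fh:
        age_mode = int(fh.attrs["age_mode"])
        centers = fh["mode_centers"][()]
        for sid, g in fh["subjects"].items():
            context[sid] = g["context"][()]
            modes[sid] = g["modes"][()]
            local[sid] = g["local"][()]
            if "occupancy" in g:
                occupancy[sid] = g["occupancy"][()]
    return synth.GroundTruth(context=context, modes=modes, local=local,
                             occupancy=occupancy, mode_centers=centers, age_mode=age_mode)
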