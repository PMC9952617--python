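"""End-to-end workflow: simulate -> preprocess -> annotate -> diffpeaks ->
features -> split -> train -> evaluate -> aggregate.

Two surfaces are provided. The in-memory helpers (:func:`simulate_cohort`,
:func:`preprocess_patient`, :func:`stroma_feature_table`, ...) run the same
logic without touching disk and are what scripts and tests compose. The
disk-based :func:`run_pipeline` writes every stage's outputs under the
configured output directory, records a manifest (input hashes, output
hashes, seeds, timestamps), and can resume from cached stage outputs when
the stage's inputs are unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .annotate import TaggedSpectrumTable, bin_mask, stroma_mesh, tag_spectra, write_tagged, read_tagged
from .classify import (
    evaluate,
    mesh_features,
    patient_aggregate,
    stratified_split,
    train_models,
)
from .config import CohortConfig, PipelineConfig, PreprocessConfig
from .core import AnnotationMask, DataError, SpectralCube
from .diffstats import differential_peaks, patient_means
from .io import read_cube, read_mask, read_table, sha256_file, write_cube, write_mask, write_table
from .preprocess import BaselineFitParams, bin_pixels, calibrate, subtract_baseline
from .synthgen import DEFAULT_FEATURE_WAVENUMBERS, simulate_patient

logger = logging.getLogger("sersstroma")

__all__ = [
    "PatientData",
    "simulate_cohort",
    "preprocess_patient",
    "stroma_feature_table",
    "cohort_patient_means",
    "RunManifest",
    "run_pipeline",
    "STAGES",
]


@dataclass
class PatientData:
    patient_id: str
    diagnosis: str
    cube: SpectralCube
    mask: AnnotationMask
    silicon: np.ndarray


def simulate_cohort(cfg: CohortConfig) -> list[PatientData]:
    """Seeded synthetic cohort: DCIS patients first, then invasive.

    One child seed stream per patient, spawned from the cohort master seed.
    """
    axis = cfg.axis.build()
    # marker bands falling outside a restricted axis are omitted from the
    # shipped library rather than erroring; render_cube itself stays strict
    library = [
        pk for pk in cfg.peaks.build()
        if axis.contains(pk.center + cfg.calibration_shift)
    ]
    baseline = cfg.baseline.build()
    layout = cfg.layout.build()
    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(cfg.n_dcis + cfg.n_ibc)
    cohort: list[PatientData] = []
    idx = 0
    for diagnosis, count in (("DCIS", cfg.n_dcis), ("IBC", cfg.n_ibc)):
        for i in range(count):
            pid = f"{diagnosis}-{i + 1:02d}"
            _, cube, mask, silicon = simulate_patient(
                pid, diagnosis, cfg.image_shape, axis, library,
                baseline=baseline, layout=layout,
                noise_sd=cfg.noise_sd, hotspot_cv=cfg.hotspot_cv,
                calibration_shift=cfg.calibration_shift,
                seed_sequence=children[idx],
            )
            cohort.append(PatientData(pid, diagnosis, cube, mask, silicon))
            idx += 1
    return cohort


def preprocess_patient(
    patient: PatientData, pcfg: PreprocessConfig
) -> tuple[SpectralCube, AnnotationMask]:
    """Calibrate, bin and baseline-subtract one patient; bin the mask to match."""
    cube = calibrate(patient.cube, patient.silicon)
    cube = bin_pixels(cube, pcfg.bin_factor)
    cube = subtract_baseline(
        cube,
        BaselineFitParams(
            lam=pcfg.baseline_lam, method=pcfg.baseline_method,
            clip_k=pcfg.baseline_clip_k, p=pcfg.baseline_p,
            max_iter=pcfg.baseline_max_iter, tol=pcfg.baseline_tol,
        ),
    )
    mask = bin_mask(patient.mask, pcfg.bin_factor)
    return cube, mask


def stroma_feature_table(
    processed: list[tuple[str, str, SpectralCube, AnnotationMask]],
    wavenumbers=DEFAULT_FEATURE_WAVENUMBERS,
    halfwidth: float = 10.0,
) -> pd.DataFrame:
    """Mesh-level band features over every patient's stromal ROI mesh."""
    parts = []
    for pid, diagnosis, cube, mask in processed:
        mesh = stroma_mesh(mask, diagnosis, patient_id=pid)
        parts.append(mesh_features(cube, mesh, wavenumbers, halfwidth))
    return pd.concat(parts, ignore_index=True)


def cohort_patient_means(
    processed: list[tuple[str, str, SpectralCube, AnnotationMask]],
    annotation_filter: str = "stroma",
):
    """Tagged per-patient mean spectra over an annotation class."""
    tables = [tag_spectra(cube, mask) for _, _, cube, mask in processed]
    diagnoses = {pid: diag for pid, diag, _, _ in processed}
    return patient_means(tables, annotation_filter, diagnoses=diagnoses)


# ---------------------------------------------------------------------------
# disk-based staged pipeline


STAGES = (
    "simulate",
    "preprocess",
    "annotate",
    "diffpeaks",
    "features",
    "split",
    "train",
    "evaluate",
    "aggregate",
)


@dataclass
class StageRecord:
    name: str
    input_hash: str
    outputs: dict[str, str]  # relative path -> sha256
    seed: int
    timestamp: float
    cached: bool = False


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: list[StageRecord] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "version": self.version,
                "stages": [dataclasses.asdict(s) for s in self.stages],
            },
            indent=2,
        )

    @classmethod
    def load(cls, path: Path) -> "RunManifest | None":
        if not path.exists():
            return None
        data = json.loads(path.read_text())
        return cls(
            config_hash=data["config_hash"],
            version=data.get("version", ""),
            stages=[StageRecord(**s) for s in data["stages"]],
        )


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _stage_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([master_seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % 2**31)


class _Runner:
    def __init__(self, config: PipelineConfig, outdir: Path, resume: bool):
        self.config = config
        self.outdir = outdir
        self.resume = resume
        self.previous = RunManifest.load(outdir / "manifest.json")
        self.manifest = RunManifest(
            config_hash=_hash_obj(config.model_dump(mode="json")),
            version=_version,
        )

    def _prev_record(self, name: str) -> StageRecord | None:
        if self.previous is None:
            return None
        for s in self.previous.stages:
            if s.name == name:
                return s
        return None

    def run_stage(self, name: str, input_hash: str, seed: int, fn) -> StageRecord:
        prev = self._prev_record(name)
        if (
            self.resume
            and prev is not None
            and prev.input_hash == input_hash
            and all((self.outdir / p).exists() for p in prev.outputs)
        ):
            logger.info("stage %s: cached", name)
            rec = StageRecord(name, input_hash, prev.outputs, seed, prev.timestamp, cached=True)
            self.manifest.stages.append(rec)
            return rec
        t0 = time.time()
        try:
            out_paths = fn(seed)
        except Exception as exc:
            raise DataError(
                f"stage {name!r} failed (input hash {input_hash[:12]}): {exc}"
            ) from exc
        outputs = {
            str(Path(p).relative_to(self.outdir)): sha256_file(p) for p in out_paths
        }
        rec = StageRecord(name, input_hash, outputs, seed, t0)
        self.manifest.stages.append(rec)
        logger.info("stage %s: %d outputs in %.1fs", name, len(outputs), time.time() - t0)
        return rec


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    resume: bool = True,
    stages: tuple[str, ...] = STAGES,
) -> RunManifest:
    """Execute the staged workflow, writing all outputs under ``outdir``.

    Stages run in the fixed order of :data:`STAGES`; ``stages`` may name a
    prefix of that order. Each stage's inputs are hashed (config section +
    upstream output hashes); with ``resume`` a stage whose inputs are
    unchanged and whose outputs still exist is skipped. A validated copy of
    the config and the manifest are written beside the outputs.
    """
    for s in stages:
        if s not in STAGES:
            raise DataError(f"unknown stage {s!r}")
    last = max(STAGES.index(s) for s in stages)
    todo = STAGES[: last + 1]

    out = Path(outdir) if outdir is not None else Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    r = _Runner(config, out, resume)
    cfg = config
    seed = cfg.cohort.seed
    chash = r.manifest.config_hash

    patients_tsv = out / "patients.tsv"

    def stage_simulate(_seed):
        cohort = simulate_cohort(cfg.cohort)
        rows, paths = [], []
        for p in cohort:
            cube_path = out / "raw" / f"{p.patient_id}.h5"
            mask_path = out / "raw" / f"{p.patient_id}.png"
            write_cube(p.cube, cube_path, silicon=p.silicon)
            write_mask(p.mask, mask_path)
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "diagnosis": p.diagnosis,
                    "cube": str(cube_path.relative_to(out)),
                    "mask": str(mask_path.relative_to(out)),
                }
            )
            paths += [cube_path, mask_path, mask_path.with_suffix(".labels.json")]
        write_table(pd.DataFrame(rows), patients_tsv)
        return paths + [patients_tsv]

    sim_rec = r.run_stage(
        "simulate", _hash_obj(cfg.cohort.model_dump(mode="json")), seed, stage_simulate
    )

    def load_patients() -> pd.DataFrame:
        return read_table(patients_tsv)

    def stage_preprocess(_seed):
        paths = []
        for _, row in load_patients().iterrows():
            cube, silicon = read_cube(out / row["cube"], with_silicon=True)
            mask = read_mask(out / row["mask"])
            p = PatientData(row["patient_id"], row["diagnosis"], cube, mask, silicon)
            proc_cube, proc_mask = preprocess_patient(p, cfg.preprocess)
            cpath = out / "proc" / f"{p.patient_id}.h5"
            mpath = out / "proc" / f"{p.patient_id}.png"
            write_cube(proc_cube, cpath)
            write_mask(proc_mask, mpath)
            paths += [cpath, mpath, mpath.with_suffix(".labels.json")]
        return paths

    pre_rec = None
    if "preprocess" in todo:
        pre_rec = r.run_stage(
            "preprocess",
            _hash_obj([sim_rec.outputs, cfg.preprocess.model_dump(mode="json")]),
            seed,
            stage_preprocess,
        )

    def load_processed():
        recs = []
        for _, row in load_patients().iterrows():
            cube = read_cube(out / "proc" / f"{row['patient_id']}.h5")
            mask = read_mask(out / "proc" / f"{row['patient_id']}.png")
            recs.append((row["patient_id"], row["diagnosis"], cube, mask))
        return recs

    def stage_annotate(_seed):
        paths = []
        for pid, _, cube, mask in load_processed():
            table = tag_spectra(cube, mask)
            tpath = out / "tagged" / f"{pid}.tsv"
            tpath.parent.mkdir(parents=True, exist_ok=True)
            write_tagged(table, tpath)
            paths.append(tpath)
        return paths

    def stage_diffpeaks(_seed):
        processed = load_processed()
        matrix = cohort_patient_means(processed, cfg.stats.annotation_filter)
        report = differential_peaks(
            matrix,
            alpha=cfg.stats.alpha,
            merge_distance=cfg.stats.merge_distance,
            peak_separation=cfg.stats.peak_separation,
            min_channels=cfg.stats.min_channels,
            min_effect=cfg.stats.min_effect,
            correction=cfg.stats.correction,
        )
        p1, p2 = out / "diffpeaks_channels.tsv", out / "diffpeaks_peaks.tsv"
        write_table(report.channels, p1)
        write_table(report.peaks, p2)
        return [p1, p2]

    def stage_features(_seed):
        processed = load_processed()
        wns = cfg.classify.wavenumbers or list(DEFAULT_FEATURE_WAVENUMBERS)
        lo = processed[0][2].wavenumbers.min()
        hi = processed[0][2].wavenumbers.max()
        wns = [w for w in wns if lo <= w <= hi]
        table = stroma_feature_table(
            processed, wns, cfg.classify.feature_halfwidth
        )
        fpath = out / "features.tsv"
        write_table(table, fpath)
        return [fpath]

    def stage_split(stage_seed):
        patients = load_patients()
        plan = stratified_split(patients, cfg.classify.n_sets, seed=stage_seed)
        spath = out / "split.json"
        spath.write_text(
            json.dumps(
                {
                    "assignments": plan.assignments,
                    "n_sets": plan.n_sets,
                    "evaluation_set": plan.evaluation_set,
                },
                indent=2,
                sort_keys=True,
            )
        )
        return [spath]

    def stage_train(stage_seed):
        features = read_table(out / "features.tsv")
        split = json.loads((out / "split.json").read_text())
        eval_set = split["evaluation_set"]
        train_pats = {p for p, s in split["assignments"].items() if s != eval_set}
        train_table = features[features["patient_id"].isin(train_pats)]
        report = train_models(
            train_table,
            algorithms=cfg.classify.algorithms,
            k_folds=cfg.classify.k_folds,
            seed=stage_seed,
        )
        cvpath = out / "cv_report.tsv"
        write_table(report.cv_table, cvpath)
        mpath = out / "models.pkl"
        with open(mpath, "wb") as fh:
            pickle.dump(report.models, fh)
        return [cvpath, mpath]

    def stage_evaluate(_seed):
        features = read_table(out / "features.tsv")
        split = json.loads((out / "split.json").read_text())
        eval_set = split["evaluation_set"]
        eval_pats = {p for p, s in split["assignments"].items() if s == eval_set}
        eval_table = features[features["patient_id"].isin(eval_pats)]
        with open(out / "models.pkl", "rb") as fh:
            models = pickle.load(fh)
        best = max(models, key=lambda f: models[f].cv_kappa)
        report = evaluate(models[best], eval_table)
        epath = out / "eval.json"
        epath.write_text(
            json.dumps(
                {
                    "best_family": best,
                    "kappa": report.kappa,
                    "accuracy": report.accuracy,
                    "f1": report.f1,
                    "precision": report.precision,
                    "recall": report.recall,
                    "confusion": report.confusion.tolist(),
                },
                indent=2,
                sort_keys=True,
            )
        )
        ppath = out / "eval_predictions.tsv"
        write_table(report.predictions, ppath)
        return [epath, ppath]

    def stage_aggregate(_seed):
        preds = read_table(out / "eval_predictions.tsv")
        agg = patient_aggregate(preds)
        apath = out / "aggregate.tsv"
        write_table(agg, apath)
        return [apath]

    stage_fns = {
        "annotate": (stage_annotate, lambda: _hash_obj(pre_rec.outputs)),
        "diffpeaks": (
            stage_diffpeaks,
            lambda: _hash_obj([pre_rec.outputs, cfg.stats.model_dump(mode="json")]),
        ),
        "features": (
            stage_features,
            lambda: _hash_obj([pre_rec.outputs, cfg.classify.model_dump(mode="json")]),
        ),
        "split": (
            stage_split,
            lambda: _hash_obj([sim_rec.outputs, cfg.classify.n_sets, seed]),
        ),
    }
    records = {"simulate": sim_rec}
    if pre_rec is not None:
        records["preprocess"] = pre_rec
    for name in ("annotate", "diffpeaks", "features", "split"):
        if name in todo:
            fn, hash_fn = stage_fns[name]
            records[name] = r.run_stage(name, hash_fn(), _stage_seed(seed, name), fn)

    if "train" in todo:
        records["train"] = r.run_stage(
            "train",
            _hash_obj([records["features"].outputs, records["split"].outputs,
                       cfg.classify.model_dump(mode="json")]),
            _stage_seed(seed, "train"),
            stage_train,
        )
    if "evaluate" in todo:
        records["evaluate"] = r.run_stage(
            "evaluate",
            _hash_obj([records["train"].outputs]),
            _stage_seed(seed, "evaluate"),
            stage_evaluate,
        )
    if "aggregate" in todo:
        records["aggregate"] = r.run_stage(
            "aggregate",
            _hash_obj([records["evaluate"].outputs]),
            _stage_seed(seed, "aggregate"),
            stage_aggregate,
        )

    r.manifest.stages = [records[n] for n in todo if n in records]
    (out / "manifest.json").write_text(r.manifest.to_json())
    return r.manifest
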