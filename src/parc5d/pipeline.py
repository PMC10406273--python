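"""End-to-end study pipeline: simulate -> train -> predict 5D maps ->
voxel-wise statistics -> FNC/dFNC states -> reports.

Stages exchange files, not in-memory objects, so any stage can be re-run
on maps from another source.  Each stage directory carries a marker with
the configuration hash; a re-run with an unchanged configuration skips
completed stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fnc as fnc_mod
from . import spatiodynamics as sd
from .io import load_nifti, read_manifest, save_nifti
from .model import (ModelSpec, build_model, load_checkpoint, predict_subject,
                    save_checkpoint)
from .synthetic import (GroundTruthSubject, SyntheticStudyConfig,
                        make_group_study, make_network_templates, study_mask)
from .training import TrainConfig, make_volume_dataset, train_model

logger = logging.getLogger("parc5d")

STAGES = ("simulate", "train", "predict", "stats", "fnc")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything needed to run (and bit-reproduce) a study."""

    out_dir: Path
    study: SyntheticStudyConfig = field(
        default_factory=SyntheticStudyConfig.small)
    model: ModelSpec = field(default_factory=ModelSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    window: fnc_mod.WindowSpec = field(default_factory=fnc_mod.WindowSpec)
    mask_level: float = 0.1
    fdr_q: float = 0.05
    val_fraction: float = 0.25
    state_k_candidates: tuple[int, ...] = (2, 3, 4, 5, 6)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, out_dir=None) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        study_raw = dict(raw.get("study", {}))
        preset = study_raw.pop("preset", None)
        if "coupling_effect" in study_raw:
            study_raw["coupling_effect"] = {
                tuple(k.split("-")): v
                for k, v in study_raw["coupling_effect"].items()}
        for key in ("amplitude_effect", "deviation_effect"):
            if key in study_raw:
                study_raw[key] = {int(k): v
                                  for k, v in study_raw[key].items()}
        if preset:
            study = getattr(SyntheticStudyConfig, preset)(**study_raw)
        else:
            study = SyntheticStudyConfig(**study_raw)
        model_raw = {k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.get("model", {}).items()}
        kw = dict(
            out_dir=Path(out_dir or raw.get("out_dir", "parc5d_out")),
            study=study,
            model=ModelSpec(**model_raw),
            train=TrainConfig(**raw.get("train", {})),
            window=fnc_mod.WindowSpec(**raw.get("window", {})),
            seed=int(raw.get("seed", 0)),
        )
        for key in ("mask_level", "fdr_q", "val_fraction"):
            if key in raw:
                kw[key] = float(raw[key])
        if "state_k_candidates" in raw:
            kw["state_k_candidates"] = tuple(raw["state_k_candidates"])
        return cls(**kw)

    def config_hash(self) -> str:
        payload = {
            "study": self.study.to_jsonable(),
            "model": dataclasses.asdict(self.model),
            "train": dataclasses.asdict(self.train),
            "window": dataclasses.asdict(self.window),
            "mask_level": self.mask_level, "fdr_q": self.fdr_q,
            "val_fraction": self.val_fraction,
            "state_k_candidates": list(self.state_k_candidates),
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    """Locations of every pipeline product plus the run manifest."""

    out_dir: Path
    manifest_path: Path
    map_dir: Path
    stats_dir: Path
    fnc_dir: Path
    run_manifest: dict


# ---------------------------------------------------------------------------

def _stage_marker(stage_dir: Path) -> Path:
    return stage_dir / ".stage.json"


def _stage_done(stage_dir: Path, cfg_hash: str) -> bool:
    marker = _stage_marker(stage_dir)
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("config_hash") == cfg_hash
    except json.JSONDecodeError:
        return False


def _mark_done(stage_dir: Path, stage: str, cfg_hash: str, seconds: float):
    stage_dir.mkdir(parents=True, exist_ok=True)
    _stage_marker(stage_dir).write_text(json.dumps(
        {"stage": stage, "config_hash": cfg_hash,
         "seconds": round(seconds, 2)}))


def _network_labels(study: SyntheticStudyConfig) -> list[str]:
    labels = [""] * study.n_networks
    for domain, members in study.domains.items():
        for j, nid in enumerate(members, start=1):
            labels[nid - 1] = f"{domain}{j}"
    return labels


def _load_truth_subject(out_dir: Path, sid: str, group: str, index: int,
                        k: int) -> GroundTruthSubject:
    truth_dir = out_dir / "study" / "truth" / sid
    maps = [load_nifti(truth_dir / f"net_{i:02d}.nii.gz")
            for i in range(1, k + 1)]
    tc = np.loadtxt(truth_dir / "timecourses.csv", delimiter=",")
    return GroundTruthSubject(subject_id=sid, group=group,
                              subject_index=index, score_maps=maps,
                              timecourses=np.atleast_2d(tc))


def run_pipeline(cfg: PipelineConfig,
                 last_stage: str | None = None) -> StudyResult:
    """Execute the stages in order, skipping stages already completed
    under the same configuration hash; optionally stop after
    ``last_stage``."""
    if last_stage is not None and last_stage not in STAGES:
        raise ValueError(f"unknown stage {last_stage!r}; stages: {STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    labels = _network_labels(cfg.study)
    k = cfg.study.n_networks
    timings = {}

    def result():
        run_manifest = {
            "config_hash": cfg_hash,
            "seed": cfg.seed,
            "study": cfg.study.to_jsonable(),
            "stage_seconds": {s: round(t, 2) for s, t in timings.items()},
            "versions": {"numpy": np.__version__,
                         "pandas": pd.__version__},
        }
        (out / "run_manifest.json").write_text(
            json.dumps(run_manifest, indent=1))
        return StudyResult(out_dir=out, manifest_path=out / "study" / "manifest.csv",
                           map_dir=out / "maps", stats_dir=out / "stats",
                           fnc_dir=out / "fnc", run_manifest=run_manifest)

    def run_stage(name, stage_dir, fn):
        if _stage_done(stage_dir, cfg_hash):
            logger.info("stage %s: up to date, skipping", name)
            return
        logger.info("stage %s: running", name)
        t0 = time.time()
        try:
            fn(stage_dir)
        except Exception as exc:
            marker = _stage_marker(stage_dir)
            if marker.exists():
                marker.unlink()
            raise StageError(name, exc) from exc
        timings[name] = time.time() - t0
        _mark_done(stage_dir, name, cfg_hash, timings[name])
        logger.info("stage %s: done in %.1fs", name, timings[name])

    # 1. simulate ------------------------------------------------------
    study_dir = out / "study"

    def stage_simulate(d):
        make_group_study(cfg.study, d)

    run_stage("simulate", study_dir, stage_simulate)
    if last_stage == "simulate":
        return result()
    manifest_path = study_dir / "manifest.csv"
    manifest = read_manifest(manifest_path)
    templates = make_network_templates(cfg.study)
    mask = study_mask(templates, cfg.mask_level)

    def iter_subjects():
        counters = {"control": 0, "patient": 0}
        for _, row in manifest.iterrows():
            idx = counters[row["group"]]
            counters[row["group"]] += 1
            yield row["subject_id"], row["group"], idx, row["path"]

    # 2. train ---------------------------------------------------------
    model_dir = out / "models"

    def stage_train(d):
        d.mkdir(parents=True, exist_ok=True)
        subjects = []
        for sid, group, idx, vol_path in iter_subjects():
            volume = load_nifti(vol_path)
            subjects.append((volume,
                             _load_truth_subject(out, sid, group, idx, k)))
        for nid in range(1, k + 1):
            train_set, val_set = make_volume_dataset(
                subjects, nid, cfg.val_fraction, seed=cfg.seed)
            model = build_model(cfg.model, cfg.study.grid_dims,
                                seed=cfg.seed + nid)
            model, history = train_model(model, train_set, val_set,
                                         cfg.train)
            save_checkpoint(model, d / f"net_{nid:02d}.npz", network_id=nid)
            pd.DataFrame(history).to_csv(d / f"net_{nid:02d}_history.csv",
                                         index=False)
            logger.info("trained network %d/%d (%d epochs)",
                        nid, k, len(history))

    run_stage("train", model_dir, stage_train)
    if last_stage == "train":
        return result()

    # 3. predict -------------------------------------------------------
    map_dir = out / "maps"

    def stage_predict(d):
        models = [load_checkpoint(model_dir / f"net_{nid:02d}.npz")
                  for nid in range(1, k + 1)]
        for sid, group, idx, vol_path in iter_subjects():
            volume = load_nifti(vol_path)
            maps = predict_subject(models, volume)
            for nid, omega in enumerate(maps, start=1):
                save_nifti(omega, d / sid / f"net_{nid:02d}.nii.gz",
                           cfg.study.voxel_size)

    run_stage("predict", map_dir, stage_predict)
    if last_stage == "predict":
        return result()

    def load_maps(sid):
        return [load_nifti(map_dir / sid / f"net_{nid:02d}.nii.gz")
                for nid in range(1, k + 1)]

    # 4. stats ---------------------------------------------------------
    stats_dir = out / "stats"

    def stage_stats(d):
        d.mkdir(parents=True, exist_ok=True)
        save_nifti(mask.astype(np.float32), d / "mask.nii.gz",
                   cfg.study.voxel_size)
        per_group = {"control": {}, "patient": {}}
        subject_means = {}
        for sid, group, idx, _ in iter_subjects():
            maps = load_maps(sid)
            means = [sd.time_mean(m) for m in maps]
            devs = [sd.temporal_deviation(m) for m in maps]
            per_group[group].setdefault("mean", []).append(means)
            per_group[group].setdefault("dev", []).append(devs)
            subject_means[sid] = (group, means)
        peak_rows = []
        for nid in range(1, k + 1):
            name = labels[nid - 1]
            for kind, key in (("mean", "mean"), ("deviation", "dev")):
                gc = [mats[nid - 1] for mats in per_group["control"][key]]
                gs = [mats[nid - 1] for mats in per_group["patient"][key]]
                gm_c, gm_s = sd.subject_mean(gc), sd.subject_mean(gs)
                diff = sd.difference_map(gm_c, gm_s)
                tt = sd.voxelwise_ttest(gc, gs)
                save_nifti(gm_c.data, d / f"{name}_{kind}_control.nii.gz",
                           cfg.study.voxel_size)
                save_nifti(gm_s.data, d / f"{name}_{kind}_patient.nii.gz",
                           cfg.study.voxel_size)
                save_nifti(diff.data, d / f"{name}_{kind}_diff.nii.gz",
                           cfg.study.voxel_size)
                save_nifti(tt.tmap.data, d / f"{name}_{kind}_tmap.nii.gz",
                           cfg.study.voxel_size)
            # peak-voxel table from the time-mean difference map
            gc = [mats[nid - 1] for mats in per_group["control"]["mean"]]
            gs = [mats[nid - 1] for mats in per_group["patient"]["mean"]]
            diff = sd.difference_map(sd.subject_mean(gc), sd.subject_mean(gs))
            sel = sd.select_peaks(diff, mask)
            sids = list(subject_means)
            maps_n = [subject_means[s][1][nid - 1] for s in sids]
            grp = [subject_means[s][0] for s in sids]
            sel = sd.collect_peak_values(sel, maps_n, grp)
            for sign, (grps, vals) in sel.values.items():
                voxel = sel.positive if sign == "positive" else sel.negative
                for s, g, v in zip(sids, grps, vals):
                    peak_rows.append((name, sign, str(voxel), s, g, v))
        pd.DataFrame(peak_rows, columns=["network", "peak_sign", "voxel",
                                         "subject_id", "group", "value"]
                     ).to_csv(d / "peak_values.csv", index=False)

    run_stage("stats", stats_dir, stage_stats)
    if last_stage == "stats":
        return result()

    # 5. fnc -----------------------------------------------------------
    fnc_dir = out / "fnc"

    def stage_fnc(d):
        d.mkdir(parents=True, exist_ok=True)
        sfnc = {"control": [], "patient": []}
        windows_all = []
        subject_windows = {}
        groups = {}
        for sid, group, idx, _ in iter_subjects():
            maps = load_maps(sid)
            m = fnc_mod.sfnc_matrix(maps, mask=mask, labels=labels,
                                    subject_id=sid)
            sfnc[group].append(m)
            pd.DataFrame(m.data, index=labels, columns=labels).to_csv(
                d / f"sfnc_{sid}.csv")
            wins = fnc_mod.dfnc_windows(maps, cfg.window, mask=mask,
                                        labels=labels, subject_id=sid)
            subject_windows[sid] = wins
            groups[sid] = group
            windows_all.extend(wins)
        t_mat, sig, p_adj = fnc_mod.fnc_group_test(
            sfnc["control"], sfnc["patient"], q=cfg.fdr_q)
        pd.DataFrame(t_mat, index=labels, columns=labels).to_csv(
            d / "sfnc_group_t.csv")
        pd.DataFrame(sig.astype(int), index=labels, columns=labels).to_csv(
            d / "sfnc_group_sig.csv")
        k_cands = [c for c in cfg.state_k_candidates
                   if c <= len(windows_all)]
        state = fnc_mod.fit_states(windows_all, k_cands, seed=cfg.seed)
        occ_rows = []
        for sid, wins in subject_windows.items():
            occ = fnc_mod.occupancy_ratio(
                fnc_mod.assign_states(wins, state), state.k)
            occ_rows.append([sid, groups[sid]] + occ.tolist())
        pd.DataFrame(
            occ_rows, columns=["subject_id", "group"]
            + [f"state_{i + 1}" for i in range(state.k)]
        ).to_csv(d / "occupancy.csv", index=False)
        (d / "states.json").write_text(json.dumps({
            "k": state.k,
            "inertia_curve": state.inertia_curve,
            "centroids": [c.tolist() for c in state.centroid_matrices()],
            "labels": labels, "seed": state.seed}, indent=1))

    run_stage("fnc", fnc_dir, stage_fnc)
    return result()
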