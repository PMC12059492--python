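"""End-to-end orchestration: simulate -> preprocess -> train -> predict ->
attribute -> evaluate, driven by one YAML config and one global seed.

Every stage reads its prerequisites from, and writes its artifacts to, the
run's working directory, so stages can be re-run individually from the CLI.
The global seed deterministically derives one child seed per stage through
``numpy.random.SeedSequence(seed).spawn``, so a fixed config + seed gives
bit-identical artifacts end to end.  Each run directory carries the frozen
config and a manifest with the config hash, package version, per-stage
timing, and row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

import tbal
from tbal.attribution import integrated_gradients, rank_features
from tbal.data_model import Cohort, filter_eligible, load_cohort, write_cohort
from tbal.evaluate import metric_report, subgroup_report, temporal_curve
from tbal.model import TBALConfig, TBALModel, predict_risks
from tbal.preprocess import (NormalizationStats, PreprocessedCohort,
                             EncodedStay, preprocess_cohort)
from tbal.synthetic import SimConfig, simulate_cohort, write_ground_truth
from tbal.tasks import (TaskSpec, attach_split, check_no_leakage,
                        make_dynamic_labels, make_static_labels,
                        split_by_patient)
from tbal.train import TrainConfig, fit

ALL_STAGES = ("simulate", "preprocess", "train", "predict", "attribute",
              "evaluate")


@dataclasses.dataclass
class RunConfig:
    """Everything one end-to-end run needs."""

    workdir: str
    seed: int = 0
    sim: dict = dataclasses.field(default_factory=dict)
    task: dict = dataclasses.field(default_factory=dict)
    model: dict = dataclasses.field(default_factory=dict)
    train: dict = dataclasses.field(default_factory=dict)
    eval: dict = dataclasses.field(default_factory=dict)
    attribution: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        children = np.random.SeedSequence(self.seed).spawn(len(ALL_STAGES))
        return int(children[ALL_STAGES.index(stage)].generate_state(1)[0]
                   % (2 ** 31))

    def task_spec(self) -> TaskSpec:
        kw = dict(self.task)
        if kw.get("horizon_h") == "inf":
            kw["horizon_h"] = float("inf")
        kw.setdefault("kind", "dynamic")
        if kw["kind"] == "dynamic":
            kw.setdefault("trigger_h", 1.0)
        return TaskSpec(**kw)


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path.name}; run the '{produced_by}' "
            f"stage first")
    return path


def _save_encoded(prep: PreprocessedCohort, path: Path) -> None:
    arrays = {}
    for sid, enc in prep.encoded.items():
        arrays[f"Z/{sid}"] = enc.Z
        arrays[f"grid/{sid}"] = enc.grid_h
    sample = next(iter(prep.encoded.values()))
    meta = {"feature_names": sample.feature_names,
            "feature_parent": sample.feature_parent,
            "skipped": prep.skipped}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), np.uint8)
    np.savez(path, **arrays)


def _load_encoded(path: Path) -> tuple[dict[str, EncodedStay], dict]:
    encoded = {}
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        for key in data.files:
            if not key.startswith("Z/"):
                continue
            sid = key[2:]
            encoded[sid] = EncodedStay(
                stay_id=sid, Z=data[key],
                feature_names=meta["feature_names"],
                feature_parent=meta["feature_parent"],
                grid_h=data[f"grid/{sid}"])
    return encoded, meta


def run_pipeline(config: RunConfig,
                 stages: Sequence[str] = ALL_STAGES) -> dict:
    """Execute the requested stages in order; returns the manifest."""
    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    (wd / "run_config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8")
    manifest: dict = {"config_hash": config.config_hash(),
                      "version": tbal.__version__, "stages": {}}
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        t0 = time.time()
        counts = _STAGE_FNS[stage](config, wd)
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 2), **counts}
        (wd / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                          encoding="utf-8")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, wd: Path) -> dict:
    sim_kw = dict(config.sim)
    sim_kw.setdefault("seed", config.stage_seed("simulate"))
    sim = SimConfig(**sim_kw)
    cohort, truth = simulate_cohort(sim)
    write_cohort(cohort, wd / "events.csv", wd / "stays.csv",
                 wd / "dictionary.csv")
    write_ground_truth(truth, wd / "gt_stays.csv", wd / "gt_variables.csv")
    return {"stays": cohort.n_stays, "events": len(cohort.events),
            "mortality": round(truth.achieved_mortality, 4)}


def _load_run_cohort(wd: Path, stage: str) -> Cohort:
    return load_cohort(_require(wd / "events.csv", stage, "simulate"),
                       wd / "stays.csv", wd / "dictionary.csv")


def _stage_preprocess(config: RunConfig, wd: Path) -> dict:
    cohort = _load_run_cohort(wd, "preprocess")
    eligible, tally = filter_eligible(cohort)
    (wd / "exclusions.json").write_text(json.dumps(tally), encoding="utf-8")
    assignment = split_by_patient(eligible,
                                  seed=config.stage_seed("preprocess"))
    pd.DataFrame(sorted(assignment.items()),
                 columns=["patient_id", "split"]).to_csv(
        wd / "splits.csv", index=False)
    train_ids = [str(r.stay_id) for _, r in eligible.stays.iterrows()
                 if assignment[str(r.patient_id)] == "train"]
    prep = preprocess_cohort(eligible, train_stay_ids=train_ids)
    prep.stats.save(wd / "stats.yaml")
    _save_encoded(prep, wd / "encoded.npz")
    eligible.stays.to_csv(wd / "stays_eligible.csv", index=False)
    return {"stays": len(eligible.stays), "skipped": len(prep.skipped),
            "excluded": tally["excluded_total"]}


def _labels_for(config: RunConfig, wd: Path, cohort: Cohort,
                encoded: dict[str, EncodedStay]) -> pd.DataFrame:
    task = config.task_spec()
    if task.kind == "dynamic":
        grids = {sid: enc.grid_h for sid, enc in encoded.items()}
        labels = make_dynamic_labels(cohort, task, grids)
    else:
        labels = make_static_labels(cohort, task)
    splits = pd.read_csv(_require(wd / "splits.csv", "train", "preprocess"),
                         dtype=str)
    assignment = dict(zip(splits["patient_id"], splits["split"]))
    labels = attach_split(labels, cohort, assignment)
    check_no_leakage(labels, cohort)
    return labels


def _stage_train(config: RunConfig, wd: Path) -> dict:
    encoded, _ = _load_encoded(_require(wd / "encoded.npz", "train",
                                        "preprocess"))
    stays = pd.read_csv(_require(wd / "stays_eligible.csv", "train",
                                 "preprocess"),
                        dtype={"stay_id": str, "patient_id": str})
    cohort = Cohort(stays=stays, events=pd.DataFrame(columns=[
        "stay_id", "time_h", "variable", "value"]), dictionary={})
    labels = _labels_for(config, wd, cohort, encoded)
    labels.to_csv(wd / "labels.csv", index=False)

    sample = next(iter(encoded.values()))
    model_kw = dict(config.model)
    model_kw.setdefault("seed", config.stage_seed("train"))
    mcfg = TBALConfig(input_dim=sample.F, **model_kw)
    stats = NormalizationStats.load(wd / "stats.yaml")
    model = TBALModel.initialize(mcfg, sample.feature_names,
                                 sample.feature_parent, stats)
    train_kw = dict(config.train)
    train_kw.setdefault("seed", config.stage_seed("train"))
    tcfg = TrainConfig(task=config.task_spec(), **train_kw)
    tr = labels[labels["split"] == "train"]
    va = labels[labels["split"] == "val"]
    model, log = fit(model, tr, va, encoded, tcfg)
    model.save(wd / "checkpoint.npz")
    log.to_frame().to_csv(wd / "training_log.csv", index=False)
    return {"train_examples": len(tr), "epochs": len(log.epochs),
            "best_epoch": log.best_epoch}


def _stage_predict(config: RunConfig, wd: Path) -> dict:
    model = TBALModel.load(_require(wd / "checkpoint.npz", "predict",
                                    "train"))
    encoded, _ = _load_encoded(wd / "encoded.npz")
    labels = pd.read_csv(_require(wd / "labels.csv", "predict", "train"),
                         dtype={"stay_id": str})
    stride = float(config.eval.get("stride_h", 4.0))
    if config.task_spec().kind == "dynamic":
        on_mark = np.isclose(np.mod(labels["trigger_h"].to_numpy(float),
                                    stride), 0.0)
        labels = labels[on_mark].reset_index(drop=True)
    risks = predict_risks(model, encoded, labels)
    out = labels.copy()
    out["risk"] = risks
    out = out[np.isfinite(risks)]
    out.to_csv(wd / "predictions.csv", index=False)
    return {"predictions": len(out)}


def _stage_attribute(config: RunConfig, wd: Path) -> dict:
    model = TBALModel.load(_require(wd / "checkpoint.npz", "attribute",
                                    "train"))
    encoded, _ = _load_encoded(wd / "encoded.npz")
    preds = pd.read_csv(_require(wd / "predictions.csv", "attribute",
                                 "predict"), dtype={"stay_id": str})
    test_preds = preds[preds["split"] == "test"]
    m_steps = int(config.attribution.get("m_steps", 50))
    stride = float(config.attribution.get("stride_h", 8.0))
    max_stays = int(config.attribution.get("max_stays", 100))
    rng = np.random.default_rng(config.stage_seed("attribute"))
    stay_ids = sorted(test_preds["stay_id"].unique())
    if len(stay_ids) > max_stays:
        stay_ids = sorted(rng.choice(stay_ids, size=max_stays,
                                     replace=False))
    maps = []
    for sid in stay_ids:
        enc = encoded[sid]
        triggers = test_preds.loc[test_preds["stay_id"] == sid, "trigger_h"]
        triggers = [t for t in triggers
                    if np.isclose(t % stride, 0.0)] or \
                   [float(triggers.iloc[-1])]
        for trig in triggers:
            maps.append(integrated_gradients(model, enc, float(trig),
                                             m_steps=m_steps))
    sample = next(iter(encoded.values()))
    ranking = rank_features(maps, sample.feature_names, sample.feature_parent)
    ranking.to_csv(wd / "ig_ranking.csv", index=False)
    return {"maps": len(maps), "stays": len(stay_ids)}


def _stage_evaluate(config: RunConfig, wd: Path) -> dict:
    preds = pd.read_csv(_require(wd / "predictions.csv", "evaluate",
                                 "predict"), dtype={"stay_id": str})
    stays = pd.read_csv(wd / "stays_eligible.csv",
                        dtype={"stay_id": str, "patient_id": str})
    n_boot = int(config.eval.get("n_boot", 1000))
    seed = config.stage_seed("evaluate")
    test = preds[preds["split"] == "test"]
    report = metric_report(test["risk"], test["label"], test["stay_id"],
                           n_boot=n_boot, seed=seed)
    report.to_frame().to_csv(wd / "report_pooled.csv", index=False)
    if config.task_spec().kind == "dynamic":
        curve = temporal_curve(test, n_boot=min(n_boot, 200), seed=seed)
        curve.to_csv(wd / "report_temporal.csv", index=False)
    sub = subgroup_report(test, stays, n_boot=min(n_boot, 200), seed=seed)
    sub.to_csv(wd / "report_subgroup.csv", index=False)
    return {"test_examples": len(test),
            "test_auroc": round(report.auroc, 4)}


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "train": _stage_train,
    "predict": _stage_predict,
    "attribute": _stage_attribute,
    "evaluate": _stage_evaluate,
}
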