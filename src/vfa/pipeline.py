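"""End-to-end orchestration: simulate -> extract -> select -> train ->
predict -> evaluate, with manifests for reproducibility.

A single master seed is fanned out deterministically to per-stage seeds
(by hashing the stage name together with the master seed), so one number
reproduces the whole study. Every stage writes its outputs plus a manifest
recording inputs, parameters, seed and content hashes; rerunning an
identical configuration reproduces identical manifests for deterministic
stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import evaluation, feature_selection, inference, spot_map, synthetic_data

__all__ = ["RunConfig", "validate_config", "run_pipeline", "stage_seed"]

_STAGES = ("layout", "simulate", "select", "train", "predict", "evaluate")

_DEFAULTS: dict = {
    "seed": 0,
    "stages": list(_STAGES),
    "layout": {
        "rows": 9,
        "cols": 9,
        "periodicity_mm": 1.3,
        "tolerance": 0.10,
    },
    "simulate": {
        "n_hs_samples": 85,
        "replicates": 3,
        "concentration_range": [0.1, 10.0],
        "acute_concentrations": [83.6, 200.0, 500.0, 1000.0],
        "rids": [1, 2],
        "fids": [1, 2, 3],
        "noise_cv": 0.10,
    },
    "select": {
        "k": 5,
        "window": 5,
        "hidden": [32],
        "dropout": 0.1,
        "epochs": 200,
    },
    "train": {
        "hidden": [512, 64],
        "dropout": 0.5,
        "epochs": 2000,
        "test_fraction": 0.215,
    },
    "evaluate": {},
    "predict": {},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (one YAML file, per-stage blocks)."""

    raw: dict

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        merged = json.loads(json.dumps(_DEFAULTS))
        unknown = [k for k in cfg if k not in merged]
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        for key, val in cfg.items():
            if isinstance(val, dict):
                bad = [k for k in val if k not in merged[key]]
                if bad:
                    raise ValueError(f"unknown key(s) in {key!r} block: {bad}")
                merged[key].update(val)
            else:
                merged[key] = val
        return cls(merged)

    def __getitem__(self, key):
        return self.raw[key]

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Statically checkable precondition violations; empty list iff valid."""
    v: list[str] = []
    c = config.raw
    lay = c["layout"]
    if lay["rows"] < 1 or lay["cols"] < 1:
        v.append("layout.rows/cols must be >= 1")
    sim = c["simulate"]
    if sim["n_hs_samples"] < 1:
        v.append("simulate.n_hs_samples must be >= 1")
    if sim["replicates"] < 1:
        v.append("simulate.replicates must be >= 1")
    if sim["noise_cv"] < 0:
        v.append("simulate.noise_cv must be >= 0")
    if c["select"]["k"] < 2:
        v.append("select.k must be >= 2")
    n_tests = (sim["n_hs_samples"] + len(sim["acute_concentrations"])) * sim[
        "replicates"
    ]
    if c["select"]["k"] > n_tests:
        v.append("select.k exceeds the number of simulated tests")
    if not (0.0 <= c["train"]["test_fraction"] <= 1.0):
        v.append("train.test_fraction must be in [0, 1]")
    for stage in c["stages"]:
        if stage not in _STAGES:
            v.append(f"unknown stage {stage!r}")
    return v


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the master seed."""
    digest = hashlib.sha256(f"{stage}:{master_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _manifest(outdir: Path, stage: str, seed: int, params: dict,
              outputs: list[Path]) -> None:
    doc = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in outputs
        },
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(doc, indent=1))


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the enabled stages in order, writing artifacts + manifests.

    On a stage failure the exception is re-raised annotated with the stage
    name, and a ``failed`` marker naming the stage is left in the artifact
    directory alongside any partial outputs.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    c = config.raw
    master = int(c["seed"])
    stages = c["stages"]
    state: dict = {}

    def log(stage, msg):
        print(f"[vfa:{stage} seed={stage_seed(master, stage)}] {msg}")

    current = None
    try:
        if "layout" in stages:
            current = "layout"
            seed = stage_seed(master, "layout")
            lay = c["layout"]
            conds = spot_map.default_conditions()
            smap = spot_map.generate_spot_map(
                lay["rows"], lay["cols"], lay["periodicity_mm"], conds,
                seed=seed, tolerance=lay["tolerance"],
            )
            path = outdir / "map.json"
            spot_map.write_spot_map(smap, path)
            state["map"] = smap
            _manifest(outdir, "layout", seed, lay, [path])
            log("layout", f"{smap.n_spots} spots, {len(conds)} conditions")

        if "simulate" in stages:
            current = "simulate"
            seed = stage_seed(master, "simulate")
            sim = c["simulate"]
            smap = state.get("map") or spot_map.read_spot_map(outdir / "map.json")
            design = synthetic_data.CohortDesign(
                n_hs_samples=sim["n_hs_samples"],
                concentration_range=tuple(sim["concentration_range"]),
                replicates=sim["replicates"],
                acute_concentrations=tuple(sim["acute_concentrations"]),
                rids=tuple(sim["rids"]),
                fids=tuple(sim["fids"]),
            )
            cohort = synthetic_data.simulate_cohort(
                design, smap,
                noise_model=synthetic_data.NoiseModel(cv=sim["noise_cv"]),
                seed=seed,
            )
            path = outdir / "cohort.csv"
            cohort.table().to_csv(path, index=False)
            state["cohort"] = cohort
            _manifest(outdir, "simulate", seed, sim, [path])
            log("simulate", f"{len(cohort.tests)} tests")

        if any(s in stages for s in ("select", "train", "predict", "evaluate")):
            cohort = state["cohort"]
            smap = state["map"]
            train_tests, test_tests = evaluation.partition_train_test(
                cohort, c["train"]["test_fraction"],
                seed=stage_seed(master, "train"),
            )
            training = feature_selection.TrainingSet.from_tests(train_tests, smap)

        if "select" in stages:
            current = "select"
            seed = stage_seed(master, "select")
            sel = c["select"]
            cfg = inference.NetworkConfig(
                hidden=tuple(sel["hidden"]), dropout=sel["dropout"],
                epochs=sel["epochs"], patience=20, seed=seed,
            )
            trace = feature_selection.eliminate_spots_cv(
                training, cfg, k=sel["k"], seed=seed
            )
            spots = feature_selection.select_spot_subset(trace, sel["window"])
            ctrace, order, conds = feature_selection.eliminate_conditions_cv(
                training, spots, cfg, k=sel["k"], seed=seed
            )
            p1 = outdir / "spot_trace.csv"
            p2 = outdir / "condition_trace.csv"
            trace.to_frame().to_csv(p1, index=False)
            ctrace.to_frame().to_csv(p2, index=False)
            sel_doc = outdir / "selection.json"
            sel_doc.write_text(json.dumps(
                {"spots": [list(rc) for rc in spots], "conditions": conds,
                 "condition_elimination_order": order}, indent=1))
            state["spots"], state["conditions"] = spots, conds
            _manifest(outdir, "select", seed, sel, [p1, p2, sel_doc])
            log("select", f"{len(spots)} spots, {len(conds)} conditions selected")

        if "train" in stages:
            current = "train"
            seed = stage_seed(master, "train")
            tr = c["train"]
            spots = state.get("spots")
            conds = state.get("conditions")
            bundle = inference.train_model_bundle(
                training,
                spot_subset=spots,
                conditions=conds,
                quantifier_config=inference.NetworkConfig(
                    hidden=tuple(tr["hidden"]), dropout=tr["dropout"],
                    epochs=tr["epochs"], seed=seed,
                ),
                seed=seed,
            )
            bdir = outdir / "bundle"
            bundle.save(bdir)
            state["bundle"] = bundle
            _manifest(outdir, "train", seed, tr,
                      sorted(bdir.glob("*.json")))
            log("train", f"bundle over {len(bundle.conditions)} conditions")

        if "predict" in stages or "evaluate" in stages:
            current = "predict"
            bundle = state["bundle"]
            rows = []
            for t in test_tests:
                res = inference.predict(bundle, t)
                rows.append({
                    "test_id": t.test_id, "sample_id": t.sample_id,
                    "truth_mg_L": t.truth_mg_l, "mode": res.mode,
                    "concentration": res.concentration,
                    "confidence": res.confidence, "stratum": res.risk_stratum,
                })
            preds = pd.DataFrame(rows)
            path = outdir / "predictions.csv"
            preds.to_csv(path, index=False)
            state["predictions"] = preds
            _manifest(outdir, "predict", stage_seed(master, "predict"), {}, [path])
            log("predict", f"{len(preds)} tests predicted")

        if "evaluate" in stages:
            current = "evaluate"
            report = evaluation.evaluate_predictions(state["predictions"])
            path = outdir / "report.json"
            path.write_text(json.dumps(report.to_dict(), indent=1))
            _manifest(outdir, "evaluate", stage_seed(master, "evaluate"), {}, [path])
            log("evaluate",
                f"R2={report.r2:.3f} CV={report.overall_cv_percent:.1f}%")
    except Exception as exc:
        (outdir / "failed").write_text(f"stage {current}: {exc}\n")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    (outdir / "run.json").write_text(json.dumps(
        {"config_hash": config.hash(), "master_seed": master,
         "stages": stages, "finished": time.strftime("%Y-%m-%dT%H:%M:%S")},
        indent=1))
    return outdir
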