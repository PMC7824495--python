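"""End-to-end pipeline: simulate -> match/merge -> normalize -> evaluate -> zscore -> detect.

A single :class:`RunConfig` (a plain dict, usually loaded from YAML)
plus one master seed fully determine a run.  Per-stage seeds derive from
the master seed by stable hashing of the stage name, so inserting a
stage never reshuffles the randomness of the others.  Every intermediate
is written into the run directory alongside a JSON manifest.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from pathlib import Path

from .core_io import BiomarkerExpectation, TransformSpec, write_feature_table
from .detection import detection_curve
from .matching import MatchCriteria, merge_all
from .metrics import evaluate
from .normalize import (
    apply_metchalizer,
    apply_transform,
    fit_metchalizer,
    normalize_anchor,
    normalize_best_correlated_is,
    normalize_pqn,
)
from .reference import compute_zscores
from .synthetic import SimulationConfig, simulate_dataset, simulate_split_batches

logger = logging.getLogger("metchalizer")

DEFAULT_CONFIG = {
    "simulation": {},
    "matching": {"enabled": False, "rt_drift_pct": 0.5, "ppm_jitter": 0.3, "reference_index": 0},
    "normalization": {"method": "metchalizer", "transform": "log"},
    "zscore": {"strategy": "15out", "n_ref": 15},
    "detection": {"score": "z"},
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def _transform_spec(name: str) -> TransformSpec | None:
    if name in (None, "none"):
        return None
    if name == "log":
        return TransformSpec(kind="log")
    if name in ("boxcox", "bc"):
        return TransformSpec(kind="boxcox")
    raise ValueError(f"unknown transform {name!r}")


def normalize_table(table, method: str, transform: str, raw_table=None):
    """Dispatch one ``{transform}-{method}`` normalization."""
    spec = _transform_spec(transform)
    if method == "metchalizer":
        fit = fit_metchalizer(table, transform_spec=spec or TransformSpec(kind="log"))
        return apply_metchalizer(table, fit)
    work = apply_transform(table, spec) if spec is not None else table
    if method == "raw":
        return work if spec is not None else apply_transform(table, TransformSpec(kind="none"))
    if method == "best_is":
        return normalize_best_correlated_is(work, transform_spec=spec)
    if method == "anchor":
        return normalize_anchor(work, transform_spec=spec)
    if method == "pqn":
        return normalize_pqn(work, transform_spec=spec)
    raise ValueError(f"unknown normalization method {method!r}")


def run_pipeline(config: dict, out_dir: str | Path, seed: int = 0) -> dict:
    """Run the full synthetic pipeline; returns the manifest dict.

    Stage failures abort with the stage named; partial outputs written so
    far are preserved in ``out_dir``.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "config": cfg, "stages": {}}
    t_start = time.time()

    def _stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"seed": stage_seed(seed, name)}
        return time.time()

    try:
        t = _stage("simulate")
        sim_cfg = SimulationConfig(**cfg["simulation"], rng_seed=stage_seed(seed, "simulate"))
        table, truth = simulate_dataset(sim_cfg)
        write_feature_table(table, out / "simulated.csv")
        manifest["stages"]["simulate"]["seconds"] = time.time() - t

        if cfg["matching"].get("enabled"):
            t = _stage("match")
            m = cfg["matching"]
            splits = simulate_split_batches(
                table, truth,
                rt_drift_pct=m.get("rt_drift_pct", 0.5),
                ppm_jitter=m.get("ppm_jitter", 0.3),
                reference_index=m.get("reference_index", 0),
                seed=stage_seed(seed, "match"),
            )
            merged = merge_all(splits, reference_index=m.get("reference_index", 0),
                               criteria=MatchCriteria())
            table = merged.table
            write_feature_table(table, out / "merged.csv")
            manifest["stages"]["match"]["retained_features"] = table.n_features
            manifest["stages"]["match"]["seconds"] = time.time() - t

        t = _stage("normalize")
        n = cfg["normalization"]
        norm = normalize_table(table, n.get("method", "metchalizer"), n.get("transform", "log"))
        write_feature_table(norm, out / "normalized.csv")
        manifest["stages"]["normalize"]["label"] = norm.label
        manifest["stages"]["normalize"]["seconds"] = time.time() - t

        t = _stage("evaluate")
        report = evaluate(norm, seed=stage_seed(seed, "evaluate"))
        manifest["stages"]["evaluate"].update(report.medians)
        (out / "evaluation.json").write_text(json.dumps(report.medians, indent=2))
        manifest["stages"]["evaluate"]["seconds"] = time.time() - t

        t = _stage("zscore")
        zc = cfg["zscore"]
        zres = compute_zscores(norm, zc.get("strategy", "15out"), n_ref=zc.get("n_ref", 15))
        zres.mean_z.to_csv(out / "zscores.csv")
        zres.pvalues.to_csv(out / "pvalues.csv")
        manifest["stages"]["zscore"]["strategy"] = zres.strategy
        manifest["stages"]["zscore"]["seconds"] = time.time() - t

        t = _stage("detect")
        expectations = [
            BiomarkerExpectation(iem_name=f"IEM_{tid}", feature=fid, expected_sign=sign)
            for tid, fid, _, sign in truth.spikes
        ]
        curve = detection_curve(zres, expectations, norm,
                                score=cfg["detection"].get("score", "z"), raw_table=table)
        curve_out = {
            "score": curve.score,
            "auc": curve.auc,
            "n_evaluable": curve.n_evaluable,
            "x": curve.avg_positives_per_patient.tolist(),
            "y": curve.detected_biomarkers.tolist(),
        }
        (out / "detection_curve.json").write_text(json.dumps(curve_out, indent=2))
        manifest["stages"]["detect"]["auc"] = curve.auc
        manifest["stages"]["detect"]["seconds"] = time.time() - t
    except Exception as exc:
        manifest["error"] = {"stage": list(manifest["stages"])[-1] if manifest["stages"] else None,
                             "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    manifest["total_seconds"] = time.time() - t_start
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
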