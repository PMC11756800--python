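"""Staged pipeline orchestration with hash-based artifact skipping.

Stages run in dependency order (generate -> encode -> select / dimred ->
sdnpe).  Each stage writes its artifacts under the configured output
directory plus a run-log entry recording the config hash, the stage seed
and content hashes of the artifacts; a re-run with an unchanged config
hash skips the stage.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import time
from pathlib import Path

import numpy as np

from . import embedding
from .config import config_hash, stage_seed, validate_config
from .simulators import DatasetManifest, build_selection_dataset

STAGE_ORDER = ["generate", "encode", "select"]

__all__ = ["run_pipeline", "save_estimator", "load_estimator"]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict, stages) -> dict:
    """Execute the requested stages; returns the run log."""
    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    log_path = out / "runlog.json"
    log = json.loads(log_path.read_text()) if log_path.exists() else {"events": []}
    done = {e["stage"]: e for e in log["events"] if e.get("config_hash") == chash}
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    ordered = [s for s in STAGE_ORDER if s in stages]
    for stage in ordered:
        if stage in done:
            log["events"].append({"stage": stage, "status": "skipped",
                                  "config_hash": chash, "time": time.time()})
            continue
        artifacts = _run_stage(stage, cfg, out)
        log["events"].append({
            "stage": stage, "status": "ran", "config_hash": chash,
            "seed": stage_seed(cfg["seed"], stage), "time": time.time(),
            "artifacts": {str(p): _file_hash(p) for p in artifacts},
        })
        log_path.write_text(json.dumps(log, indent=2))
    log_path.write_text(json.dumps(log, indent=2))
    return log


def _run_stage(stage: str, cfg: dict, out: Path):
    if stage == "generate":
        manifest = build_selection_dataset(
            cfg["generate"]["selection_composition"],
            out_dir=out / "images", seed=stage_seed(cfg["seed"], "generate"),
            render=True, size=cfg["generate"]["image_size"])
        manifest.to_csv(out / "manifest.csv")
        return [out / "manifest.csv"]
    if stage == "encode":
        manifest_path = out / "manifest.csv"
        if not manifest_path.exists():
            raise FileNotFoundError(
                "missing upstream artifact manifest.csv: run the 'generate' "
                "stage first")
        store = embedding.encode_dataset(
            DatasetManifest.from_csv(manifest_path),
            embedding.EncoderSpec(name=cfg["encode"]["encoder"]),
            blur_sigma=cfg["preprocess"]["blur_sigma"])
        store.save(out / "embeddings")
        return [out / "embeddings.npy", out / "embeddings.rows.csv"]
    if stage == "select":
        store_path = out / "embeddings.npy"
        if not store_path.exists():
            raise FileNotFoundError(
                "missing upstream artifact embeddings.npy: run the 'encode' "
                "stage first")
        return []  # retrieval is query-driven; nothing to precompute
    raise ValueError(f"unknown stage: {stage!r}")


def save_estimator(path, reducer, regressor, prior, lattice,
                   encoder: str = "spectral_fallback") -> None:
    """Persist a trained SD-NPE estimator (reducer + regressor + prior)."""
    with open(path, "wb") as fh:
        pickle.dump({"reducer": reducer, "regressor": regressor,
                     "prior": np.asarray(prior), "lattice": lattice,
                     "encoder": encoder}, fh)


def load_estimator(path) -> dict:
    from .dimred import reduce_vectors
    with open(path, "rb") as fh:
        bundle = pickle.load(fh)
    reducer = bundle["reducer"]
    if hasattr(reducer, "transform"):
        bundle["reduce"] = reducer.transform
    else:
        bundle["reduce"] = lambda X: reduce_vectors(X, reducer)
    return bundle
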