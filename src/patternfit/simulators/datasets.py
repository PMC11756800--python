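"""Dataset manifests: the selection library and the estimation dataset.

A manifest is a table of (model, parameter record, rng seed, time point,
image path, split) rows plus a composition summary.  Every row is fully
re-generable from its recorded parameters and seed, so the manifest — not
a fixed set of pixels — is the dataset contract.  Images are rendered to
8-bit grayscale PNG on demand (``render=True``); manifest-level checks
(composition, parameter ranges) need no rendering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .. import imaging
from ..stability import TuringParams
from ._common import GRID_SIZE
from .cahn_hilliard import CahnHilliardParams, simulate_cahn_hilliard
from .ew import EWParams, simulate_edwards_wilkinson
from .gray_scott import GrayScottParams, simulate_gray_scott
from .growth import GrowthTruncationWarning, StochasticGrowthConfig, simulate_growth
from .kt import KTParams, simulate_kt
from .lsystem import LSystemSpec, generate_l_system
from .phase_field import PhaseFieldParams, simulate_phase_field
from .turing import simulate_turing

__all__ = [
    "DatasetManifest",
    "SELECTION_COMPOSITION",
    "build_selection_dataset",
    "build_estimation_dataset",
    "regenerate_row",
]

# Per-model image counts of the default selection library.
SELECTION_COMPOSITION = {
    "turing": 228,
    "kt": 288,
    "gray_scott": 486,
    "edwards_wilkinson": 99,
    "eden": 182,
    "dla": 300,
    "l_system": 133,
    "phase_field": 83,
}

MANIFEST_COLUMNS = ["model", "param_json", "seed", "time_point", "path", "split"]


@dataclass
class DatasetManifest:
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if self.rows["path"].duplicated().any():
            raise ValueError("duplicate output paths in manifest")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def composition(self) -> dict:
        return self.rows["model"].value_counts().to_dict()

    def to_csv(self, path) -> None:
        path = Path(path)
        self.rows.to_csv(path, index=False)
        sidecar = path.with_suffix(".composition.json")
        sidecar.write_text(json.dumps({"total": len(self),
                                       "composition": self.composition}, indent=2))

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        return cls(pd.read_csv(path, keep_default_na=False))


# --- per-model samplers --------------------------------------------------
# Per-model parameter samplers are this package's own choices, picked to
# produce the reference per-model counts and visually
# diverse regimes, and every draw is recorded in the manifest.

_GS_CAPTURES = (500, 1000, 2000, 4000, 8000, 16000)


def _sample_turing(rng) -> dict:
    # rejection-sample (f_v, g_v) with a positive dispersion band
    from ..stability import has_positive_band
    while True:
        fv = float(rng.uniform(0.6, 1.0))
        gv = float(rng.uniform(0.6, 1.0))
        if has_positive_band(TuringParams(f_v=fv, g_v=gv)):
            return {"f_v": fv, "g_v": gv}


def _sample_kt(rng) -> dict:
    act_r = float(rng.uniform(2.0, 4.5))
    return {
        "act_amp": float(rng.uniform(0.05, 0.12)),
        "act_radius": act_r,
        "inh_amp": float(rng.uniform(0.008, 0.025)),
        "inh_radius": float(rng.uniform(act_r + 2.0, act_r + 8.0)),
    }


def _sample_gray_scott(rng) -> dict:
    return {"F": float(rng.uniform(0.022, 0.055)),
            "k": float(rng.uniform(0.055, 0.066))}


def _sample_ew(rng) -> dict:
    return {"nu": float(rng.uniform(0.5, 2.4)),
            "noise_amp": float(rng.uniform(0.5, 2.0)),
            "steps": int(rng.integers(500, 3000))}


def _sample_eden(rng) -> dict:
    return {"events": int(rng.integers(1500, 4500))}


def _sample_dla(rng) -> dict:
    return {"events": int(rng.integers(250, 700))}

_LS_RULES = (
    "F[+F]F[-F]F",
    "F[+F]F[-F][F]",
    "FF[+F][-F]F",
    "F[+F][-F]FF",
    "FF+[+F-F-F]-[-F+F+F]",
    "F[+FF][-FF]F",
)


def _sample_lsystem(rng) -> dict:
    return {
        "rule": _LS_RULES[int(rng.integers(len(_LS_RULES)))],
        "angle": float(rng.uniform(15.0, 45.0)),
        "iterations": int(rng.integers(3, 6)),
    }


def _sample_phase_field(rng) -> dict:
    # only the initial-noise seed varies across replicates
    return {"anisotropy": 0.10, "mode_number": 6}


_SAMPLERS = {
    "turing": _sample_turing,
    "kt": _sample_kt,
    "gray_scott": _sample_gray_scott,
    "edwards_wilkinson": _sample_ew,
    "eden": _sample_eden,
    "dla": _sample_dla,
    "l_system": _sample_lsystem,
    "phase_field": _sample_phase_field,
}

# models whose dataset rows replicate one parameter record under many seeds
_STOCHASTIC_REPLICATES = {"edwards_wilkinson": 3, "eden": 7, "dla": 5}


def render_row(model: str, params: dict, seed: int, time_point: int,
               size: int = GRID_SIZE):
    """Re-run the simulator for one manifest row; returns (image, truncated)."""
    truncated = False
    if model == "turing":
        field = simulate_turing(TuringParams(f_v=params["f_v"], g_v=params["g_v"]),
                                seed=seed, size=size, method="imex",
                                dt=0.25, steps=2400)
    elif model == "kt":
        field = simulate_kt(KTParams(**params), seed=seed, size=size)
    elif model == "gray_scott":
        snaps = simulate_gray_scott(
            GrayScottParams(capture_times=_GS_CAPTURES, **params),
            seed=seed, size=size)
        field = snaps[list(_GS_CAPTURES).index(time_point)]
    elif model == "edwards_wilkinson":
        field = simulate_edwards_wilkinson(EWParams(seed=seed, **params), size=size)
    elif model in ("eden", "dla"):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", GrowthTruncationWarning)
            field = simulate_growth(
                StochasticGrowthConfig(model=model, seed=seed, **params), size=size)
        truncated = any(issubclass(w.category, GrowthTruncationWarning)
                        for w in caught)
    elif model == "l_system":
        spec = LSystemSpec(axiom="F", productions={"F": params["rule"]},
                           iterations=params["iterations"], angle=params["angle"])
        field = generate_l_system(spec, size=size)
    elif model == "phase_field":
        field = simulate_phase_field(PhaseFieldParams(seed=seed, **params), size=size)
    elif model == "cahn_hilliard":
        field = simulate_cahn_hilliard(CahnHilliardParams(seed=seed, **params),
                                       size=size)
    else:
        raise ValueError(f"unknown model: {model!r}")
    return imaging.normalize_field(field, provenance=f"{model}:{seed}"), truncated


def regenerate_row(row, size: int = GRID_SIZE):
    """Reproduce the image of a manifest row from its recorded record."""
    params = json.loads(row["param_json"])
    img, _ = render_row(row["model"], params, int(row["seed"]),
                        int(row["time_point"]), size=size)
    return img


def build_selection_dataset(config: dict | None = None, out_dir=None,
                            seed: int = 0, render: bool = False,
                            size: int = GRID_SIZE) -> DatasetManifest:
    """Build (and optionally render) the model-selection library manifest.

    ``config`` maps model name -> image count; defaults to the reference
    composition (total 1799).  Every row records its sampler draw and rng
    seed so images are re-generable byte-for-byte.
    """
    comp = SELECTION_COMPOSITION if config is None else config
    out_dir = Path(out_dir) if out_dir is not None else Path("selection_dataset")
    rng = np.random.default_rng(seed)
    records = []
    for model, count in comp.items():
        if model not in _SAMPLERS:
            raise ValueError(f"unknown model in config: {model!r}")
        sampler = _SAMPLERS[model]
        made = 0
        while made < count:
            params = sampler(rng)
            if model == "gray_scott":
                # one simulation contributes one row per capture time
                sim_seed = int(rng.integers(2**31))
                for t in _GS_CAPTURES:
                    if made >= count:
                        break
                    records.append((model, params, sim_seed, t))
                    made += 1
            elif model in _STOCHASTIC_REPLICATES or model == "phase_field":
                reps = _STOCHASTIC_REPLICATES.get(model, 1)
                for _ in range(reps):
                    if made >= count:
                        break
                    records.append((model, params, int(rng.integers(2**31)), 0))
                    made += 1
            else:
                records.append((model, params, int(rng.integers(2**31)), 0))
                made += 1
    rows = pd.DataFrame(
        [{"model": m, "param_json": json.dumps(p, sort_keys=True), "seed": s,
          "time_point": t, "path": str(out_dir / f"{m}_{i:05d}.png"),
          "split": "library"}
         for i, (m, p, s, t) in enumerate(records)],
        columns=MANIFEST_COLUMNS)
    manifest = DatasetManifest(rows)
    if render:
        _render_manifest(manifest, size)
    return manifest


def build_estimation_dataset(n_train: int = 9700, n_val: int = 600,
                             box=((0.6, 1.0), (0.6, 1.0)), seed: int = 0,
                             out_dir=None, render: bool = False,
                             size: int = GRID_SIZE) -> DatasetManifest:
    """Turing estimation dataset: uniform (f_v, g_v) draws with split flags.

    Labels are the (f_v, g_v) pairs recorded in ``param_json``; the
    remaining coefficients are the protocol constants.
    """
    (flo, fhi), (glo, ghi) = box
    if not (0.0 < flo < fhi and 0.0 < glo < ghi):
        raise ValueError("parameter box outside the simulator-valid region")
    out_dir = Path(out_dir) if out_dir is not None else Path("estimation_dataset")
    rng = np.random.default_rng(seed)
    n = n_train + n_val
    fv = rng.uniform(flo, fhi, size=n)
    gv = rng.uniform(glo, ghi, size=n)
    seeds = rng.integers(2**31, size=n)
    split = ["train"] * n_train + ["val"] * n_val
    rows = pd.DataFrame({
        "model": "turing",
        "param_json": [json.dumps({"f_v": float(a), "g_v": float(b)},
                                  sort_keys=True) for a, b in zip(fv, gv)],
        "seed": seeds,
        "time_point": 0,
        "path": [str(out_dir / f"turing_{i:05d}.png") for i in range(n)],
        "split": split,
    }, columns=MANIFEST_COLUMNS)
    manifest = DatasetManifest(rows)
    if render:
        _render_manifest(manifest, size)
    return manifest


def _render_manifest(manifest: DatasetManifest, size: int) -> None:
    for _, row in manifest.rows.iterrows():
        path = Path(row["path"])
        path.parent.mkdir(parents=True, exist_ok=True)
        imaging.write_image(regenerate_row(row, size=size), path)
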