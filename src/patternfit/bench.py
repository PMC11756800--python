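"""Scaled Turing-estimation benchmark shared by tests and the acceptance script.

Reproduces the estimation study at reduced size: a 2,000-image Turing
training set (1,800 train / 200 validation for reducer early stopping) at
reduced raster resolution, the full feature -> reducer -> probabilistic
regressor -> lattice-posterior pipeline, and two evaluations:

* HPD coverage: for each synthetic truth, 20 snapshot images are encoded
  and integrated into one posterior; the truth should fall inside the 95%
  highest-density region in the stated fraction of trials.
* Three-arm comparison: generalization error (negative mean log posterior
  density at the truths) for the contrastive reducer, a UMAP projection,
  and no reduction, averaged over independent training seeds.

Grid side, integration horizon and the train/validation split are the
package's scaled study conditions and are fixed here in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dimred import (IdentityReducer, TrainSpec, grid_label_ids,
                     reduce_vectors, train_reducer, umap_baseline)
from .embedding import encode_images
from .imaging import normalize_field
from .sdnpe import (TURING_LATTICE, estimate_prior, generalization_error,
                    hpd_region_contains, integrate_posteriors, train_regressor)
from .simulators import simulate_turing_batch

__all__ = ["TuringBenchSpec", "generate_bench_data", "run_arm",
           "run_turing_benchmark"]


@dataclass(frozen=True)
class TuringBenchSpec:
    seed: int = 0
    grid_size: int = 40
    t_final: float = 300.0
    n_train: int = 1800
    n_val: int = 200
    n_truths: int = 40
    imgs_per_truth: int = 20
    blur_sigma: float = 1.5
    n_arm_seeds: int = 3
    sim_batch: int = 100


def _simulate_many(fv, gv, seeds, spec: TuringBenchSpec):
    out = []
    for s in range(0, len(fv), spec.sim_batch):
        out.append(simulate_turing_batch(fv[s:s + spec.sim_batch],
                                         gv[s:s + spec.sim_batch],
                                         seeds[s:s + spec.sim_batch],
                                         size=spec.grid_size,
                                         t_final=spec.t_final))
    return np.concatenate(out)


def generate_bench_data(spec: TuringBenchSpec, log=None):
    """Simulate and encode the training set and the grouped target images."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_train + spec.n_val
    fv = rng.uniform(0.6, 1.0, n)
    gv = rng.uniform(0.6, 1.0, n)
    fields = _simulate_many(fv, gv, rng.integers(2**31, size=n), spec)
    emb = encode_images([normalize_field(f) for f in fields],
                        blur_sigma=spec.blur_sigma)
    if log:
        log("benchmark training set simulated and encoded")
    # truths kept slightly inside the box so their lattice cell is interior
    tfv = rng.uniform(0.62, 0.98, spec.n_truths)
    tgv = rng.uniform(0.62, 0.98, spec.n_truths)
    target_emb = []
    for i in range(spec.n_truths):
        U = simulate_turing_batch(
            np.full(spec.imgs_per_truth, tfv[i]),
            np.full(spec.imgs_per_truth, tgv[i]),
            rng.integers(2**31, size=spec.imgs_per_truth),
            size=spec.grid_size, t_final=spec.t_final)
        target_emb.append(encode_images([normalize_field(u) for u in U],
                                        blur_sigma=spec.blur_sigma))
    if log:
        log("benchmark target groups simulated and encoded")
    return {"emb": emb, "fv": fv, "gv": gv, "spec": spec,
            "truths": np.column_stack([tfv, tgv]),
            "target_emb": np.stack(target_emb)}


def _fit_reducer(kind: str, data, seed: int):
    spec = data["spec"]
    emb, fv, gv = data["emb"], data["fv"], data["gv"]
    n_train = spec.n_train
    if kind == "contrastive":
        labels = grid_label_ids(fv, gv)
        model = train_reducer(emb[:n_train], labels[:n_train],
                              emb[n_train:], labels[n_train:],
                              TrainSpec(seed=seed))
        return lambda X: reduce_vectors(X, model)
    if kind == "umap":
        model = umap_baseline(emb[:n_train], seed=seed)
        return model.transform
    if kind == "no_reduction":
        return IdentityReducer().transform
    raise ValueError(f"unknown arm: {kind!r}")


def run_arm(kind: str, data, seed: int = 0):
    """Train one arm and evaluate coverage + generalization error."""
    spec = data["spec"]
    reduce_fn = _fit_reducer(kind, data, seed)
    n_train = spec.n_train
    feats = reduce_fn(data["emb"][:n_train])
    y = np.column_stack([data["fv"], data["gv"]])[:n_train]
    reg = train_regressor(feats, y, seed=seed)
    prior = estimate_prior(reg, feats)
    # batch-predict all target posteriors in one pass over the trees
    flat = data["target_emb"].reshape(-1, data["target_emb"].shape[-1])
    posts = reg.predict_posteriors(reduce_fn(flat))
    k = spec.imgs_per_truth
    hits = 0
    lattice_posts = []
    for i, truth in enumerate(data["truths"]):
        post = integrate_posteriors(posts[i * k:(i + 1) * k], prior,
                                    TURING_LATTICE)
        lattice_posts.append(post)
        hits += hpd_region_contains(post, TURING_LATTICE, truth, 0.95)
    ge = generalization_error(lattice_posts, list(data["truths"]))
    return {"coverage": hits / spec.n_truths, "gen_error": ge,
            "posteriors": lattice_posts}


def run_turing_benchmark(spec: TuringBenchSpec = TuringBenchSpec(), log=None):
    """Full benchmark: coverage (contrastive arm) + 3-seed arm comparison."""
    data = generate_bench_data(spec, log=log)
    arm_errors = {"contrastive": [], "umap": [], "no_reduction": []}
    coverage = None
    for s in range(spec.n_arm_seeds):
        for arm in arm_errors:
            res = run_arm(arm, data, seed=spec.seed + s)
            arm_errors[arm].append(res["gen_error"])
            if arm == "contrastive" and s == 0:
                coverage = res["coverage"]
            if log:
                log(f"arm {arm} seed {s}: gen err {res['gen_error']:.3f}, "
                    f"coverage {res['coverage']:.2f}")
    return {
        "coverage": coverage,
        "n_truths": spec.n_truths,
        "gen_error": {arm: float(np.mean(v)) for arm, v in arm_errors.items()},
        "gen_error_per_seed": arm_errors,
    }
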