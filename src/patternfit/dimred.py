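"""Contrastive 512 -> 2 dimensionality reduction for parameter regression.

The reducer is an MLP (layer widths 512-256-128-128-64-64-32-32-16-2,
ReLU hidden activations, batch normalization on hidden layers 1-2,
dropout 0.2 on hidden layers 1, 2 and 4) trained by a modified
contrastive scheme that adapts metric learning to *regression* labels:

* the (f_v, g_v) parameter box is divided into a 10 x 10 grid and two
  samples are "same class" iff they fall in the same grid cell;
* triplets are mined per batch by multi-similarity mining (epsilon 0.2)
  in the current reduced space;
* a triplet is excluded from the loss whenever the anchor-negative cosine
  similarity in the *input* latent space exceeds the anchor-positive one —
  different parameters can legitimately produce near-identical patterns,
  and such triplets would teach the reducer to separate the inseparable;
* the loss is the triplet margin loss (margin 0.1, Euclidean distance in
  the reduced space), averaged over triplets with non-zero loss;
* training uses Adam (lr 0.001, weight decay 0.001), batch size 32, at
  most 100 epochs, early-stopped when validation MAP@R has not improved
  for 20 epochs; the best-MAP@R checkpoint is returned.

A seeded UMAP projection and an identity (no-reduction) pass-through are
provided as comparison arms for the downstream regression benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRID_N",
    "assign_grid_label",
    "mine_triplets",
    "triplet_loss",
    "MLPReducer",
    "TrainSpec",
    "train_reducer",
    "reduce_vectors",
    "map_at_r",
    "umap_baseline",
    "IdentityReducer",
]

GRID_N = 10
DEFAULT_BOX = ((0.6, 1.0), (0.6, 1.0))

LAYER_WIDTHS = (512, 256, 128, 128, 64, 64, 32, 32, 16, 2)
BN_HIDDEN = (0, 1)  # batch norm on hidden layers 1-2
DROPOUT_HIDDEN = (0, 1, 3)  # dropout on hidden layers 1, 2, 4
DROPOUT_P = 0.2


def assign_grid_label(params, box=DEFAULT_BOX, n: int = GRID_N):
    """Grid cell (i, j) of a (f_v, g_v) pair; exact upper edge clamps to n-1."""
    (flo, fhi), (glo, ghi) = box
    fv, gv = params
    if not (flo <= fv <= fhi and glo <= gv <= ghi):
        raise ValueError(f"params {params} outside box {box}")
    i = min(int((fv - flo) / ((fhi - flo) / n)), n - 1)
    j = min(int((gv - glo) / ((ghi - glo) / n)), n - 1)
    return i, j


def grid_label_ids(fv: np.ndarray, gv: np.ndarray, box=DEFAULT_BOX,
                   n: int = GRID_N) -> np.ndarray:
    """Vectorised flat grid labels i*n + j."""
    (flo, fhi), (glo, ghi) = box
    i = np.minimum(((np.asarray(fv) - flo) / ((fhi - flo) / n)).astype(int), n - 1)
    j = np.minimum(((np.asarray(gv) - glo) / ((ghi - glo) / n)).astype(int), n - 1)
    return i * n + j


def _cosine_matrix(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    Xn = X / np.maximum(norms, 1e-12)
    return Xn @ Xn.T


def mine_triplets(embeddings: np.ndarray, labels: np.ndarray,
                  clip_similarities: np.ndarray, epsilon: float = 0.2):
    """Multi-similarity mining plus the input-space exclusion rule.

    ``embeddings`` are current reduced-space vectors (mining similarities
    are computed there); ``clip_similarities`` is the precomputed cosine
    matrix of the same batch in the input latent space.  Returns a list of
    (anchor, positive, negative) index triples.  A triplet is dropped when
    the negative is *strictly* more similar to the anchor than the
    positive in the input space (ties keep the triplet).
    """
    labels = np.asarray(labels)
    sims = _cosine_matrix(np.asarray(embeddings, dtype=float))
    n = len(labels)
    triplets = []
    for a in range(n):
        same = (labels == labels[a])
        pos_idx = np.flatnonzero(same)
        pos_idx = pos_idx[pos_idx != a]
        neg_idx = np.flatnonzero(~same)
        if len(pos_idx) == 0 or len(neg_idx) == 0:
            continue
        pos_sims = sims[a, pos_idx]
        neg_sims = sims[a, neg_idx]
        keep_neg = neg_idx[neg_sims > pos_sims.min() - epsilon]
        keep_pos = pos_idx[pos_sims < neg_sims.max() + epsilon]
        for p in keep_pos:
            for ng in keep_neg:
                if clip_similarities[a, ng] > clip_similarities[a, p]:
                    continue  # pattern look-alike across the grid: excluded
                triplets.append((a, int(p), int(ng)))
    return triplets


def triplet_loss(anchor, positive, negative, margin: float = 0.1) -> float:
    """max(0, d(a,p) - d(a,n) + margin) with Euclidean distance."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    d_ap = float(np.linalg.norm(np.asarray(anchor) - np.asarray(positive)))
    d_an = float(np.linalg.norm(np.asarray(anchor) - np.asarray(negative)))
    return max(0.0, d_ap - d_an + margin)


# --- the MLP -------------------------------------------------------------


class MLPReducer:
    """Feed-forward 512->2 reducer with manual forward/backward passes."""

    def __init__(self, seed: int = 0, widths=LAYER_WIDTHS):
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        self.W, self.b = [], []
        for fan_in, fan_out in zip(self.widths[:-1], self.widths[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.W.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.b.append(rng.uniform(-bound, bound, size=fan_out))
        self.n_hidden = len(self.widths) - 2
        self.bn_gamma = {i: np.ones(self.widths[i + 1]) for i in BN_HIDDEN}
        self.bn_beta = {i: np.zeros(self.widths[i + 1]) for i in BN_HIDDEN}
        self.bn_mean = {i: np.zeros(self.widths[i + 1]) for i in BN_HIDDEN}
        self.bn_var = {i: np.ones(self.widths[i + 1]) for i in BN_HIDDEN}
        self.bn_momentum = 0.1
        self.bn_eps = 1e-5
        self.trained = False

    # parameter bookkeeping for the optimizer
    def parameters(self):
        params = []
        for i in range(len(self.W)):
            params.append(("W", i))
            params.append(("b", i))
        for i in BN_HIDDEN:
            params.append(("g", i))
            params.append(("be", i))
        return params

    def get_param(self, key):
        kind, i = key
        return {"W": self.W, "b": self.b}.get(kind, None)[i] if kind in ("W", "b") \
            else (self.bn_gamma[i] if kind == "g" else self.bn_beta[i])

    def set_param(self, key, value):
        kind, i = key
        if kind == "W":
            self.W[i] = value
        elif kind == "b":
            self.b[i] = value
        elif kind == "g":
            self.bn_gamma[i] = value
        else:
            self.bn_beta[i] = value

    def forward(self, X: np.ndarray, train: bool = False, rng=None):
        """Forward pass; in train mode returns (output, cache) for backward."""
        X = np.asarray(X, dtype=float)
        cache = {"inputs": [], "bn": {}, "relu": [], "drop": {}}
        h = X
        for layer in range(self.n_hidden):
            cache["inputs"].append(h)
            z = h @ self.W[layer] + self.b[layer]
            if layer in BN_HIDDEN:
                if train:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    m = self.bn_momentum
                    self.bn_mean[layer] = (1 - m) * self.bn_mean[layer] + m * mu
                    nb = max(z.shape[0], 2)
                    self.bn_var[layer] = (1 - m) * self.bn_var[layer] \
                        + m * var * nb / (nb - 1)
                else:
                    mu, var = self.bn_mean[layer], self.bn_var[layer]
                inv_std = 1.0 / np.sqrt(var + self.bn_eps)
                zhat = (z - mu) * inv_std
                cache["bn"][layer] = (zhat, inv_std)
                z = self.bn_gamma[layer] * zhat + self.bn_beta[layer]
            relu_mask = z > 0
            h = z * relu_mask
            cache["relu"].append(relu_mask)
            if train and layer in DROPOUT_HIDDEN:
                mask = (rng.random(h.shape) >= DROPOUT_P) / (1.0 - DROPOUT_P)
                h = h * mask
                cache["drop"][layer] = mask
        cache["inputs"].append(h)
        out = h @ self.W[-1] + self.b[-1]
        return (out, cache) if train else out

    def backward(self, grad_out: np.ndarray, cache):
        """Backprop from d(loss)/d(output); returns {param_key: grad}."""
        grads = {}
        g = grad_out
        grads[("W", len(self.W) - 1)] = cache["inputs"][-1].T @ g
        grads[("b", len(self.W) - 1)] = g.sum(axis=0)
        g = g @ self.W[-1].T
        for layer in range(self.n_hidden - 1, -1, -1):
            if layer in cache["drop"]:
                g = g * cache["drop"][layer]
            g = g * cache["relu"][layer]
            if layer in BN_HIDDEN:
                zhat, inv_std = cache["bn"][layer]
                B = g.shape[0]
                grads[("g", layer)] = (g * zhat).sum(axis=0)
                grads[("be", layer)] = g.sum(axis=0)
                gz = g * self.bn_gamma[layer]
                g = inv_std / B * (B * gz - gz.sum(axis=0)
                                   - zhat * (gz * zhat).sum(axis=0))
            grads[("W", layer)] = cache["inputs"][layer].T @ g
            grads[("b", layer)] = g.sum(axis=0)
            g = g @ self.W[layer].T
        return grads

    def state(self):
        import copy
        return copy.deepcopy({"W": self.W, "b": self.b, "g": self.bn_gamma,
                              "be": self.bn_beta, "m": self.bn_mean,
                              "v": self.bn_var})

    def load_state(self, s):
        import copy
        s = copy.deepcopy(s)
        self.W, self.b = s["W"], s["b"]
        self.bn_gamma, self.bn_beta = s["g"], s["be"]
        self.bn_mean, self.bn_var = s["m"], s["v"]


class _Adam:
    def __init__(self, keys, lr: float, weight_decay: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, model: MLPReducer, grads) -> None:
        self.t += 1
        for key, grad in grads.items():
            p = model.get_param(key)
            grad = grad + self.wd * p
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * grad
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * grad * grad
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            model.set_param(key, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


@dataclass(frozen=True)
class TrainSpec:
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    margin: float = 0.1
    miner_epsilon: float = 0.2
    max_epochs: int = 100
    patience: int = 20
    seed: int = 0
    # batch composition: "m_per_class" guarantees in-batch positives even
    # when labels are sparse (100 grid cells vs batch size 32); "random"
    # shuffles plainly
    sampler: str = "m_per_class"
    m_per_class: int = 2


def _m_per_class_batches(labels: np.ndarray, batch_size: int, m: int, rng):
    """Index batches of ``batch_size/m`` labels x m samples, covering the
    dataset roughly once per epoch (samples drawn without replacement
    until each label's pool is exhausted, then refilled)."""
    pools = {}
    for i, lab in enumerate(labels):
        pools.setdefault(lab, []).append(i)
    remaining = {lab: list(rng.permutation(idx)) for lab, idx in pools.items()}
    labels_per_batch = max(batch_size // m, 2)
    n_batches = max(len(labels) // batch_size, 1)
    for _ in range(n_batches):
        avail = [lab for lab, idx in remaining.items() if idx]
        if len(avail) < 2:
            remaining = {lab: list(rng.permutation(idx))
                         for lab, idx in pools.items()}
            avail = list(remaining)
        chosen = rng.choice(len(avail), size=min(labels_per_batch, len(avail)),
                            replace=False)
        batch = []
        for c in chosen:
            lab = avail[c]
            take = remaining[lab][:m]
            remaining[lab] = remaining[lab][m:]
            if len(take) < m:  # top up from the full pool to keep m per label
                extra = [i for i in pools[lab] if i not in take]
                if extra:
                    take = take + list(rng.choice(extra,
                                                  size=min(m - len(take),
                                                           len(extra)),
                                                  replace=False))
            batch.extend(take)
        yield np.array(batch)


def map_at_r(embeddings: np.ndarray, labels: np.ndarray) -> float:
    """Mean average precision at R in the embedded space.

    For each query, R is the number of other samples sharing its label;
    AP@R averages precision at each correct hit among the R nearest
    neighbours (Euclidean), divided by R.  Queries with R = 0 are skipped.
    """
    X = np.asarray(embeddings, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    aps = []
    for q in range(n):
        same = labels == labels[q]
        same[q] = False
        R = int(same.sum())
        if R == 0:
            continue
        order = np.argsort(d2[q], kind="stable")[:R]
        rel = same[order]
        if not rel.any():
            aps.append(0.0)
            continue
        prec = np.cumsum(rel) / (np.arange(R) + 1)
        aps.append(float((prec * rel).sum() / R))
    return float(np.mean(aps)) if aps else 0.0


def train_reducer(train_vectors: np.ndarray, train_labels: np.ndarray,
                  val_vectors: np.ndarray, val_labels: np.ndarray,
                  tspec: TrainSpec = TrainSpec(), verbose: bool = False) -> MLPReducer:
    """Train the contrastive reducer; returns the best-validation checkpoint."""
    X = np.asarray(train_vectors, dtype=float)
    y = np.asarray(train_labels)
    if len(X) == 0:
        raise ValueError("empty training set")
    model = MLPReducer(seed=tspec.seed)
    opt = _Adam(model.parameters(), tspec.learning_rate, tspec.weight_decay)
    rng = np.random.default_rng(tspec.seed + 1)
    best_score = -np.inf
    best_state = model.state()
    epochs_since_best = 0
    for epoch in range(1, tspec.max_epochs + 1):
        if tspec.sampler == "m_per_class" and len(np.unique(y)) > 1:
            batches = _m_per_class_batches(y, tspec.batch_size,
                                           tspec.m_per_class, rng)
        else:
            order = rng.permutation(len(X))
            batches = (order[s:s + tspec.batch_size]
                       for s in range(0, len(X), tspec.batch_size))
        for idx in batches:
            if len(idx) < 2:
                continue
            xb, yb = X[idx], y[idx]
            clip_sims = _cosine_matrix(xb)
            out, cache = model.forward(xb, train=True, rng=rng)
            triplets = mine_triplets(out, yb, clip_sims,
                                     epsilon=tspec.miner_epsilon)
            if not triplets:
                continue
            grad = _triplet_grad(out, triplets, tspec.margin)
            if grad is None:
                continue
            opt.step(model, model.backward(grad, cache))
        val_emb = model.forward(np.asarray(val_vectors, dtype=float), train=False)
        score = map_at_r(val_emb, val_labels)
        if verbose:  # pragma: no cover
            print(f"epoch {epoch}: val MAP@R = {score:.4f}")
        if score > best_score:
            best_score = score
            best_state = model.state()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= tspec.patience:
                break
    model.load_state(best_state)
    model.trained = True
    model.val_map_at_r = best_score
    return model


def _triplet_grad(out: np.ndarray, triplets, margin: float):
    """d(mean active triplet loss)/d(out); None if no triplet is active."""
    a = np.array([t[0] for t in triplets])
    p = np.array([t[1] for t in triplets])
    ng = np.array([t[2] for t in triplets])
    diff_ap = out[a] - out[p]
    diff_an = out[a] - out[ng]
    d_ap = np.maximum(np.linalg.norm(diff_ap, axis=1), 1e-12)
    d_an = np.maximum(np.linalg.norm(diff_an, axis=1), 1e-12)
    active = (d_ap - d_an + margin) > 0
    if not active.any():
        return None
    k = int(active.sum())
    grad = np.zeros_like(out)
    u_ap = diff_ap[active] / d_ap[active, None] / k
    u_an = diff_an[active] / d_an[active, None] / k
    np.add.at(grad, a[active], u_ap - u_an)
    np.add.at(grad, p[active], -u_ap)
    np.add.at(grad, ng[active], u_an)
    return grad


def reduce_vectors(vectors: np.ndarray, model: MLPReducer) -> np.ndarray:
    """Inference-mode reduction to 2-d (dropout off, BN running stats)."""
    if not getattr(model, "trained", False):
        raise ValueError("reducer has not been trained")
    X = np.asarray(vectors, dtype=float)
    single = X.ndim == 1
    out = model.forward(X[None] if single else X, train=False)
    return out[0] if single else out


def umap_baseline(train_vectors: np.ndarray, seed: int = 0,
                  n_neighbors: int = 15, min_dist: float = 0.1):
    """Seeded 2-d UMAP projector (the comparison arm); returns the fitted model."""
    import umap
    if len(train_vectors) < 10:
        raise ValueError("UMAP baseline needs at least 10 samples")
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    reducer.fit(np.asarray(train_vectors, dtype=float))
    return reducer


class IdentityReducer:
    """No-reduction pass-through (512-d features go straight to the regressor)."""

    trained = True

    def transform(self, X):
        return np.asarray(X, dtype=float)
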