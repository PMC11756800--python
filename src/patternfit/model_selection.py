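"""Similarity retrieval over the embedding library and MAP@k scoring.

Given a target image, the most similar library patterns are retrieved by
cosine similarity in the latent space; a center-crop scan over the target
compensates for unknown spatial scale (the crop whose best match scores
highest is adopted).  Cross-model retrieval structure is summarized by a
MAP@k matrix: entry (i, j) measures how strongly model-j images
concentrate at the top of rankings for model-i queries.  The goal is not
classification — several mechanisms can generate near-identical patterns
(notably the Turing and kernel-based Turing models) and the matrix makes
those affinities explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingStore, EncoderSpec, encode
from .imaging import PatternImage, blur, center_crop_series, DEFAULT_BLUR_SIGMA

__all__ = [
    "SimilarityRanking",
    "cosine_similarity",
    "rank_similar",
    "crop_scan_select",
    "average_precision_at_k",
    "map_matrix",
]


@dataclass
class SimilarityRanking:
    """Ordered retrieval result: store row indices with cosine scores."""

    query_id: str
    indices: np.ndarray  # store row positions, best first
    scores: np.ndarray  # non-increasing cosine scores
    models: list  # model name per retrieved row
    crop_ratio: float | None = None


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """dot(a, b) / (|a| |b|); raises on zero-norm input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _scores_against_store(query: np.ndarray, store: EmbeddingStore) -> np.ndarray:
    norms = np.linalg.norm(store.vectors, axis=1)
    if np.any(norms == 0):
        raise ValueError("embedding store contains zero-norm vectors")
    qn = np.linalg.norm(query)
    if qn == 0:
        raise ValueError("zero-norm query vector")
    return np.clip(store.vectors @ query / (norms * qn), -1.0, 1.0)


def rank_similar(query: np.ndarray, store: EmbeddingStore, top_n: int = 5,
                 exclude: int | None = None, query_id: str = "query") -> SimilarityRanking:
    """Top-n store rows by descending cosine score (ties by manifest order).

    ``exclude`` removes one store row (used when the query is itself a
    library row, to keep retrieval statistics honest).
    """
    if len(store) == 0:
        raise ValueError("empty embedding store")
    scores = _scores_against_store(query, store)
    order = np.argsort(-scores, kind="stable")  # stable: ties keep manifest order
    if exclude is not None:
        order = order[order != exclude]
    if top_n > len(order):
        warnings.warn(f"top_n={top_n} exceeds store size {len(order)}; truncating")
        top_n = len(order)
    top = order[:top_n]
    models = list(store.metadata["model"].iloc[top]) \
        if "model" in store.metadata.columns else [""] * len(top)
    return SimilarityRanking(query_id=query_id, indices=top, scores=scores[top],
                             models=models)


def crop_scan_select(target: PatternImage, store: EmbeddingStore,
                     spec: EncoderSpec = EncoderSpec(), top_n: int = 5,
                     blur_sigma: float = DEFAULT_BLUR_SIGMA) -> SimilarityRanking:
    """Encode all 11 center-crop variants; adopt the crop whose top-1 wins."""
    best = None
    for ratio, variant in center_crop_series(target):
        vec = encode(blur(variant, blur_sigma), spec)
        ranking = rank_similar(vec, store, top_n=top_n,
                               query_id=f"{target.provenance}@{ratio:.2f}")
        ranking.crop_ratio = ratio
        if best is None or ranking.scores[0] > best.scores[0]:
            best = ranking
    return best


def average_precision_at_k(ranking: SimilarityRanking, positive_model: str,
                           k: int = 50, normalize_by: str = "hits") -> float:
    """Average precision over the top k of a ranking.

    ``normalize_by="hits"`` (default) divides by the number of positives
    found within the top k, so a ranking with all its top-k hits up front
    scores 1; ``normalize_by="k"`` divides by k instead.  Returns 0 when
    no positive appears in the top k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = np.array([m == positive_model for m in ranking.models[:k]])
    hits = int(labels.sum())
    if hits == 0:
        return 0.0
    ranks = np.nonzero(labels)[0] + 1
    precisions = np.cumsum(labels)[labels.astype(bool)] / ranks
    denom = hits if normalize_by == "hits" else k
    return float(precisions.sum() / denom)


def map_matrix(store: EmbeddingStore, k: int = 50, normalize_by: str = "hits"):
    """MAP@k matrix over all models in the store.

    Every store row serves once as a query (excluded from its own
    candidate list); entry (i, j) is the mean average precision of
    model-j positives over model-i queries.  Returns
    ``(matrix, model_names)`` with entries in [0, 1].
    """
    models = list(dict.fromkeys(store.metadata["model"]))
    model_arr = np.asarray(store.metadata["model"])
    m = len(models)
    sums = np.zeros((m, m))
    counts = np.zeros(m)
    row_of = {name: i for i, name in enumerate(models)}
    top_n = min(k, len(store) - 1)
    for q in range(len(store)):
        ranking = rank_similar(store.vectors[q], store, top_n=top_n, exclude=q)
        i = row_of[model_arr[q]]
        counts[i] += 1
        for j, name in enumerate(models):
            sums[i, j] += average_precision_at_k(ranking, name, k=k,
                                                 normalize_by=normalize_by)
    matrix = sums / np.maximum(counts[:, None], 1)
    return matrix, models
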