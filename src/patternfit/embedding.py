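"""Image embedding into the shared 512-dimensional latent space.

Two encoders share one interface:

* ``clip_vit_b32`` — the zero-shot CLIP ViT-B/32 image encoder, consumed
  frozen (no fine-tuning).  It is an optional adapter: if the
  ``open_clip`` stack is not installed, selecting it raises
  :class:`EncoderUnavailableError` — never a silent substitution.
* ``spectral_fallback`` — a deterministic, weight-free encoder built from
  classical pattern statistics (radially averaged log power spectrum,
  gradient-orientation energy, intensity histogram) mapped to 512
  dimensions by a fixed seeded random projection and L2-normalized.  It
  makes the whole pipeline runnable offline and is the default test path.

Both emit 512-vectors, so every downstream interface is encoder-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .imaging import PatternImage, blur, DEFAULT_BLUR_SIGMA

__all__ = [
    "EMBED_DIM",
    "EncoderSpec",
    "EncoderUnavailableError",
    "encode",
    "encode_images",
    "encode_dataset",
    "spectral_fallback_features",
    "spectral_descriptor",
    "EmbeddingStore",
]

EMBED_DIM = 512
_N_SPECTRUM = 64
_N_ORIENT = 16
_N_INTENSITY = 32
_N_MOMENTS = 8
_DESC_DIM = _N_SPECTRUM + _N_ORIENT + _N_INTENSITY + _N_MOMENTS
_FFT_PAD = 128  # zero-pad small rasters so radial bins are resolved
_PROJECTION_SEED = 20240817  # fixed: the projection is part of the encoder definition


class EncoderUnavailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class EncoderSpec:
    name: str = "spectral_fallback"  # or "clip_vit_b32"
    deterministic: bool = True
    input_size: int = 128

    def __post_init__(self) -> None:
        if self.name not in ("spectral_fallback", "clip_vit_b32"):
            raise ValueError(f"unknown encoder: {self.name!r}")


def spectral_descriptor(image: PatternImage) -> dict:
    """Raw descriptor blocks of the fallback encoder.

    Returns ``{"spectrum": (64,), "orientation": (16,), "intensity": (32,),
    "moments": (8,)}``.  The spectrum block is the radially averaged log
    power spectrum on 64 fixed bins over (0, pi] (DC excluded), computed
    on a zero-padded FFT so the bins stay resolved for small rasters; it
    is invariant to 90-degree rotation.  Orientation is a gradient-energy
    histogram over [0, pi); intensity is a 32-bin histogram of pixel
    values; moments are scalar statistics of the radial spectrum (peak
    wavenumber and power-weighted / log-power-weighted mean, spread and
    skewness) that carry the dominant spatial scale and band width at
    sub-bin precision.
    """
    img = image.pixels
    n = img.shape[0]
    pad = max(n, _FFT_PAD)
    F = np.fft.fft2(img - img.mean(), s=(pad, pad))
    P = np.abs(F) ** 2
    freq = 2.0 * np.pi * np.fft.fftfreq(pad)
    kr = np.sqrt(freq[:, None] ** 2 + freq[None, :] ** 2).ravel()
    P = P.ravel()
    mask = (kr > 0) & (kr <= np.pi)
    kr_m, P_m = kr[mask], P[mask]
    edges = np.linspace(0.0, np.pi, _N_SPECTRUM + 1)
    which = np.clip(np.digitize(kr_m, edges) - 1, 0, _N_SPECTRUM - 1)
    power = np.bincount(which, weights=P_m, minlength=_N_SPECTRUM)
    counts = np.maximum(np.bincount(which, minlength=_N_SPECTRUM), 1)
    spectrum = np.log1p(power / counts)

    total = P_m.sum()
    if total > 0:
        w = P_m / total
        mean_k = float((w * kr_m).sum())
        sd_k = float(np.sqrt((w * (kr_m - mean_k) ** 2).sum()))
        skew_k = float((w * (kr_m - mean_k) ** 3).sum()
                       / max(sd_k, 1e-12) ** 3)
        L = np.log1p(P_m)
        wl = L / L.sum()
        mean_kl = float((wl * kr_m).sum())
        sd_kl = float(np.sqrt((wl * (kr_m - mean_kl) ** 2).sum()))
        peak_k = float(kr_m[int(np.argmax(P_m))])
        # peak sharpness: fraction of power within 10% of the peak wavenumber
        near = np.abs(kr_m - peak_k) <= 0.1 * max(peak_k, 1e-12)
        sharp = float(w[near].sum())
        moments = np.array([peak_k, mean_k, sd_k, skew_k,
                            mean_kl, sd_kl, sharp, np.log1p(total) / 25.0])
    else:
        moments = np.zeros(_N_MOMENTS)

    gy, gx = np.gradient(img)
    mag = gx ** 2 + gy ** 2
    theta = np.mod(np.arctan2(gy, gx), np.pi)
    obins = np.clip((theta / np.pi * _N_ORIENT).astype(int), 0, _N_ORIENT - 1)
    orientation = np.bincount(obins.ravel(), weights=mag.ravel(),
                              minlength=_N_ORIENT)
    osum = orientation.sum()
    if osum > 0:
        orientation = orientation / osum

    intensity, _ = np.histogram(img, bins=_N_INTENSITY, range=(0.0, 1.0))
    intensity = intensity / img.size
    return {"spectrum": spectrum, "orientation": orientation,
            "intensity": intensity, "moments": moments}


def _projection() -> np.ndarray:
    rng = np.random.default_rng(_PROJECTION_SEED)
    return rng.standard_normal((_DESC_DIM, EMBED_DIM)) / np.sqrt(_DESC_DIM)


_PROJ = _projection()


def spectral_fallback_features(image: PatternImage) -> np.ndarray:
    """Unit-norm 512-vector from the spectral descriptor (offline encoder)."""
    d = spectral_descriptor(image)
    # scale blocks to comparable magnitude before projection
    spectrum = d["spectrum"]
    ssum = np.linalg.norm(spectrum)
    if ssum > 0:
        spectrum = spectrum / ssum
    desc = np.concatenate([spectrum, d["orientation"], d["intensity"],
                           d["moments"]])
    vec = desc @ _PROJ
    norm = np.linalg.norm(vec)
    if norm == 0:  # pragma: no cover - descriptor can't be all-zero
        raise ValueError("degenerate descriptor")
    return vec / norm


class _ClipAdapter:
    """Frozen zero-shot CLIP ViT-B/32 image encoder (optional)."""

    def __init__(self) -> None:
        try:
            import open_clip  # type: ignore
            import torch  # type: ignore
        except ImportError as exc:
            raise EncoderUnavailableError(
                "CLIP encoder unavailable: the open_clip/torch stack is not "
                "installed. Use EncoderSpec(name='spectral_fallback') for the "
                "offline encoder.") from exc
        self._torch = torch
        self._model, _, self._preprocess = open_clip.create_model_and_transforms(
            "ViT-B-32", pretrained="openai")
        self._model.eval()

    def encode(self, image: PatternImage) -> np.ndarray:
        from PIL import Image as PILImage
        arr = np.uint8(np.round(image.pixels * 255.0))
        pil = PILImage.fromarray(arr, mode="L").convert("RGB")  # replicate channels
        with self._torch.no_grad():
            t = self._preprocess(pil).unsqueeze(0)
            vec = self._model.encode_image(t).squeeze(0).numpy()
        return vec.astype(float)


_clip_adapter = None


def encode(image: PatternImage, spec: EncoderSpec = EncoderSpec()) -> np.ndarray:
    """Encode one preprocessed image to a 512-vector."""
    if spec.name == "spectral_fallback":
        return spectral_fallback_features(image)
    global _clip_adapter
    if _clip_adapter is None:
        _clip_adapter = _ClipAdapter()
    return _clip_adapter.encode(image)


def encode_images(images, spec: EncoderSpec = EncoderSpec(),
                  blur_sigma: float = DEFAULT_BLUR_SIGMA) -> np.ndarray:
    """Blur and encode a sequence of images; returns an (N, 512) array."""
    return np.stack([encode(blur(img, blur_sigma), spec) for img in images])


@dataclass
class EmbeddingStore:
    """Row-aligned (N, 512) embedding array plus manifest metadata."""

    vectors: np.ndarray
    metadata: "object"  # pandas DataFrame aligned with vectors
    encoder: str = "spectral_fallback"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != EMBED_DIM:
            raise ValueError(f"embedding store must be (N, {EMBED_DIM})")
        if len(self.metadata) != len(self.vectors):
            raise ValueError("metadata rows must align with vectors")

    def __len__(self) -> int:
        return len(self.vectors)

    def save(self, prefix) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.save(prefix.with_suffix(".npy"), self.vectors)
        self.metadata.to_csv(prefix.with_suffix(".rows.csv"), index=False)
        prefix.with_suffix(".json").write_text(
            json.dumps({"encoder": self.encoder, "n": len(self)}))

    @classmethod
    def load(cls, prefix) -> "EmbeddingStore":
        import pandas as pd
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(vectors=np.load(prefix.with_suffix(".npy")),
                   metadata=pd.read_csv(prefix.with_suffix(".rows.csv"),
                                        keep_default_na=False),
                   encoder=meta["encoder"])


def encode_dataset(manifest, spec: EncoderSpec = EncoderSpec(),
                   blur_sigma: float = DEFAULT_BLUR_SIGMA) -> EmbeddingStore:
    """Encode every manifest row's image file, order-aligned with the rows.

    All paths must be readable; missing files are collected into one error
    so the caller sees the full report rather than the first failure.
    """
    from .imaging import read_image
    missing = [p for p in manifest.rows["path"] if not Path(p).is_file()]
    if missing:
        raise FileNotFoundError(
            f"{len(missing)} manifest image(s) missing, e.g. {missing[:5]}")
    images = [read_image(p) for p in manifest.rows["path"]]
    vectors = encode_images(images, spec, blur_sigma)
    return EmbeddingStore(vectors=vectors, metadata=manifest.rows.copy(),
                          encoder=spec.name)
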