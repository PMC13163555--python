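"""Classical intensity-based Decimal Descriptor Pattern (DDP) baseline.

For every interior pixel the descriptor records the (mean, max, min) of its
3x3 intensity neighborhood, concatenates the triples row-major into a raw
vector and reuses the shared normalization / quantization / histogram stages.
Sharing those stages with the gradient variant means a comparison between the
two isolates the descriptor change only.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .gradient_ddp import (
    FeatureConfig,
    FeatureVector,
    RawFeatureVector,
    histogram_features,
    normalize_vector,
    quantize,
)

__all__ = ["ddp_neighborhood_stats", "ddp_encode", "extract_slice_features"]


def ddp_neighborhood_stats(image: np.ndarray, size: int = 3) -> RawFeatureVector:
    """Per-pixel (mean, max, min) over the size x size neighborhood.

    Border pixels (those without a full neighborhood) are excluded rather
    than padded, so no fabricated intensities enter the statistics.  Triples
    are concatenated row-major: output length is 3 * number of interior
    pixels.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D slice, got {arr.ndim}D")
    if arr.shape[0] < size or arr.shape[1] < size:
        raise ValueError(f"slice {arr.shape} smaller than {size}x{size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("slice contains non-finite values")
    windows = sliding_window_view(arr, (size, size)).reshape(
        arr.shape[0] - size + 1, arr.shape[1] - size + 1, size * size
    )
    mn = windows.min(axis=-1)
    mx = windows.max(axis=-1)
    # summation round-off could push the mean a ulp outside [min, max];
    # clip so the per-pixel ordering min <= mean <= max holds exactly
    mean = np.clip(windows.mean(axis=-1), mn, mx)
    b = np.column_stack([mean.ravel(), mx.ravel(), mn.ravel()]).ravel()
    return RawFeatureVector.from_values(b)


def ddp_encode(
    raw: RawFeatureVector, config: FeatureConfig | None = None, provenance: dict | None = None
) -> FeatureVector:
    """Shared tail of the pipeline: min-max normalize, quantize, histogram."""
    cfg = config or FeatureConfig()
    normalized = normalize_vector(raw.b)
    if cfg.histogram_domain == "codes":
        codes = quantize(normalized, mode=cfg.quantizer_mode).codes
        hist = histogram_features(codes, n_bins=cfg.n_bins, value_range=(0.0, 10.0))
    else:
        hist = histogram_features(normalized, n_bins=cfg.n_bins, value_range=(0.0, 1.0))
    prov = dict(provenance or {})
    prov.setdefault("method", "ddp")
    prov["quantizer_mode"] = cfg.quantizer_mode
    return FeatureVector(hist=hist, provenance=prov)


def extract_slice_features(
    image: np.ndarray, config: FeatureConfig | None = None, provenance: dict | None = None
) -> FeatureVector:
    """Full intensity-DDP descriptor of one slice."""
    return ddp_encode(ddp_neighborhood_stats(image), config=config, provenance=provenance)
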