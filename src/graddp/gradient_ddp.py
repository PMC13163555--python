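"""Gradient-enhanced Decimal Descriptor Pattern (Gradient-DDP) features.

The descriptor replaces the classical DDP's raw-intensity neighborhood
statistics with gradient-derived ones.  For a 2D slice the pipeline is

    gradient field -> magnitude / direction
                   -> 3x3 block statistics (magnitude mean, magnitude
                      variance, circular direction mean)
                   -> whole-vector min-max normalization
                   -> 11-level rule-based quantization
                   -> 16-bin normalized histogram

The quantizer maps each entry of the raw feature vector ``b`` to a code in
``{0..10}`` anchored at ``bmin -> 0``, ``bmax -> 1`` and ``mu -> 6``, with
interval rules filling the remaining codes.  Two readings of the rules are
provided: the ``literal`` mode evaluates them exactly as printed (first match
wins, non-matching entries fall back to code 10) and the ``monotone`` mode
replaces the cut points with a proper ordered partition of ``[bmin, mu]`` and
``[mu, bmax]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "GradientField",
    "RawFeatureVector",
    "CodeVector",
    "FeatureVector",
    "FeatureConfig",
    "compute_gradient",
    "gradient_magnitude",
    "gradient_direction",
    "block_statistics",
    "normalize_vector",
    "quantize",
    "quantize_scalar_reference",
    "histogram_features",
    "extract_slice_features",
]

QuantizerMode = Literal["literal", "monotone"]

#: Relative tolerance used for the equality anchors of the quantizer rules.
#: Exact float equality with bmin/bmax/mu is measure-zero, so equality is
#: taken within EQ_RTOL * (bmax - bmin).
EQ_RTOL = 1e-12


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientField:
    """Per-pixel gradient components of one slice.

    ``gx``/``gy`` are the horizontal (column-wise) and vertical (row-wise)
    first derivatives in intensity units per pixel, ``gmag`` the Euclidean
    magnitude and ``gdir`` the orientation ``atan2(gy, gx)`` in radians on
    ``(-pi, pi]``.
    """

    gx: np.ndarray
    gy: np.ndarray
    gmag: np.ndarray
    gdir: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.gx.shape, self.gy.shape, self.gmag.shape, self.gdir.shape}
        if len(shapes) != 1:
            raise ValueError("gradient field components must share one shape")


@dataclass(frozen=True)
class RawFeatureVector:
    """Concatenated block statistics ``b = (b_i)`` with their summary scalars."""

    b: np.ndarray
    bmin: float
    bmax: float
    mu: float

    @classmethod
    def from_values(cls, b: np.ndarray) -> "RawFeatureVector":
        b = np.asarray(b, dtype=float).ravel()
        if b.size == 0:
            raise ValueError("feature vector is empty")
        if not np.all(np.isfinite(b)):
            raise ValueError("feature vector contains non-finite values")
        return cls(b=b, bmin=float(b.min()), bmax=float(b.max()), mu=float(b.mean()))


@dataclass(frozen=True)
class CodeVector:
    """Quantized codes ``Q(b_i)`` in ``{0..10}``."""

    codes: np.ndarray
    quantizer_mode: QuantizerMode


@dataclass(frozen=True)
class FeatureVector:
    """Final per-slice descriptor: a normalized histogram over the codes."""

    hist: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(float(self.hist.sum()), 1.0, atol=1e-9):
            raise ValueError("histogram must sum to 1")


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the feature pipeline.

    block_size: side of the square non-overlapping blocks (3 in the method).
    n_bins: histogram length (16 in the method).
    quantizer_mode: 'literal' (rules as printed) or 'monotone' (ordered
        partition re-reading).
    histogram_domain: 'codes' bins the 11 quantizer levels over [0, 10];
        'normalized' bins the pre-quantization min-max values over [0, 1].
    """

    block_size: int = 3
    n_bins: int = 16
    quantizer_mode: QuantizerMode = "literal"
    histogram_domain: Literal["codes", "normalized"] = "codes"


# ---------------------------------------------------------------------------
# gradient field
# ---------------------------------------------------------------------------

def _as_slice(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D slice, got {arr.ndim}D")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"slice must be at least 2x2, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("slice contains non-finite values")
    return arr


def compute_gradient(image: np.ndarray) -> GradientField:
    """Numerical gradient of a slice: central differences inside, one-sided
    first-order differences at the boundary (``np.gradient`` with unit
    spacing).  ``gx`` differentiates along columns (x), ``gy`` along rows (y).

    Exact on affine images; a constant slice yields zero fields everywhere
    and, by the ``atan2(0, 0) = 0`` convention, zero direction.
    """
    arr = _as_slice(image)
    gy, gx = np.gradient(arr)
    return GradientField(
        gx=gx,
        gy=gy,
        gmag=gradient_magnitude(gx, gy),
        gdir=gradient_direction(gx, gy),
    )


def gradient_magnitude(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Element-wise ``sqrt(gx**2 + gy**2)``."""
    gx = np.asarray(gx, dtype=float)
    gy = np.asarray(gy, dtype=float)
    if gx.shape != gy.shape:
        raise ValueError(f"shape mismatch: {gx.shape} vs {gy.shape}")
    return np.hypot(gx, gy)


def gradient_direction(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Element-wise ``atan2(gy, gx)`` mapped onto ``(-pi, pi]``."""
    gx = np.asarray(gx, dtype=float)
    gy = np.asarray(gy, dtype=float)
    if gx.shape != gy.shape:
        raise ValueError(f"shape mismatch: {gx.shape} vs {gy.shape}")
    gdir = np.arctan2(gy, gx)
    # arctan2 can emit -pi (e.g. gy = -0.0, gx < 0); fold onto the closed end.
    return np.where(gdir == -np.pi, np.pi, gdir + 0.0)


# ---------------------------------------------------------------------------
# block statistics
# ---------------------------------------------------------------------------

def _block_view(arr: np.ndarray, block_size: int) -> np.ndarray:
    """Reshape to (n_blocks, block_size**2), row-major block order, trailing
    rows/columns that do not fill a block discarded."""
    nr = arr.shape[0] // block_size
    nc = arr.shape[1] // block_size
    trimmed = arr[: nr * block_size, : nc * block_size]
    blocks = trimmed.reshape(nr, block_size, nc, block_size).swapaxes(1, 2)
    return blocks.reshape(nr * nc, block_size * block_size)


def circular_mean(angles: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Mean direction ``atan2(mean sin, mean cos)``; arithmetic means of
    angles are discontinuous at +-pi, the circular mean is not."""
    angles = np.asarray(angles, dtype=float)
    return np.arctan2(np.mean(np.sin(angles), axis=axis), np.mean(np.cos(angles), axis=axis))


def block_statistics(
    gmag: np.ndarray, gdir: np.ndarray, block_size: int = 3
) -> RawFeatureVector:
    """Per-block (magnitude mean, magnitude population variance, circular
    direction mean), blocks row-major, statistics concatenated grouped by
    block, with the whole-vector min/max/mean summaries attached.
    """
    gmag = np.asarray(gmag, dtype=float)
    gdir = np.asarray(gdir, dtype=float)
    if gmag.shape != gdir.shape:
        raise ValueError(f"shape mismatch: {gmag.shape} vs {gdir.shape}")
    if gmag.shape[0] < block_size or gmag.shape[1] < block_size:
        raise ValueError(
            f"image {gmag.shape} smaller than one {block_size}x{block_size} block"
        )
    mag_blocks = _block_view(gmag, block_size)
    dir_blocks = _block_view(gdir, block_size)
    means = mag_blocks.mean(axis=1)
    variances = mag_blocks.var(axis=1)  # population variance (ddof=0)
    dir_means = circular_mean(dir_blocks, axis=1)
    b = np.column_stack([means, variances, dir_means]).ravel()
    return RawFeatureVector.from_values(b)


# ---------------------------------------------------------------------------
# normalization and quantization
# ---------------------------------------------------------------------------

def normalize_vector(b: np.ndarray) -> np.ndarray:
    """Whole-vector min-max rescaling to [0, 1]; a constant vector maps to
    all zeros (declared degenerate-case convention)."""
    b = np.asarray(b, dtype=float).ravel()
    if b.size == 0:
        raise ValueError("cannot normalize an empty vector")
    if not np.all(np.isfinite(b)):
        raise ValueError("vector contains non-finite values")
    lo, hi = b.min(), b.max()
    if hi == lo:
        return np.zeros_like(b)
    return (b - lo) / (hi - lo)


def _cutpoints(bmin: float, bmax: float, mu: float, mode: QuantizerMode):
    """Interval cut points for codes 2..5 (lower half) and 7..10 (upper half).

    literal: the printed rules use (mu+bmin)*k/4 below mu and (mu+bmax)*k/4
    above mu.  These are NOT guaranteed to partition [bmin, bmax] (the upper
    cuts can fall below mu), hence the first-match/fallback semantics.

    monotone: bmin + k*(mu-bmin)/4 and mu + k*(bmax-mu)/4, a proper ordered
    partition of [bmin, mu] and [mu, bmax].
    """
    if mode == "literal":
        lower = [(mu + bmin) * k / 4.0 for k in (1, 2, 3)]
        upper = [(mu + bmax) * k / 4.0 for k in (1, 2, 3)]
    elif mode == "monotone":
        lower = [bmin + k * (mu - bmin) / 4.0 for k in (1, 2, 3)]
        upper = [mu + k * (bmax - mu) / 4.0 for k in (1, 2, 3)]
    else:
        raise ValueError(f"unknown quantizer mode: {mode!r}")
    return lower, upper


def quantize_scalar_reference(
    b: np.ndarray, mode: QuantizerMode = "literal"
) -> np.ndarray:
    """Rule-by-rule scalar evaluator of the 11-level quantizer.

    Deliberately written as a plain first-match if-chain over the printed
    rules; serves as the independent oracle for the vectorized ``quantize``.
    """
    raw = RawFeatureVector.from_values(np.asarray(b))
    bmin, bmax, mu = raw.bmin, raw.bmax, raw.mu
    eps = EQ_RTOL * (bmax - bmin)
    (l1, l2, l3), (u1, u2, u3) = _cutpoints(bmin, bmax, mu, mode)
    codes = []
    for bi in raw.b:
        if abs(bi - bmin) <= eps:
            code = 0
        elif abs(bi - bmax) <= eps:
            code = 1
        elif abs(bi - mu) <= eps:
            code = 6
        elif bmin < bi <= l1:
            code = 2
        elif l1 < bi <= l2:
            code = 3
        elif l2 < bi <= l3:
            code = 4
        elif l3 < bi < mu:
            code = 5
        elif mu < bi <= u1:
            code = 7
        elif u1 < bi <= u2:
            code = 8
        elif u2 < bi <= u3:
            code = 9
        elif u3 < bi < bmax:
            code = 10
        else:
            code = 10  # entries the printed intervals miss
        codes.append(code)
    return np.asarray(codes, dtype=np.int64)


def quantize(b: np.ndarray, mode: QuantizerMode = "literal") -> CodeVector:
    """Vectorized 11-level quantizer.

    Implements the same first-match semantics as the scalar reference: the
    equality anchors ``bmin -> 0``, ``bmax -> 1``, ``mu -> 6`` (within
    relative tolerance) take precedence, then the four lower-half and four
    upper-half interval rules; entries matched by no rule get code 10.
    Total in both modes.
    """
    raw = RawFeatureVector.from_values(np.asarray(b))
    bmin, bmax, mu = raw.bmin, raw.bmax, raw.mu
    x = raw.b
    eps = EQ_RTOL * (bmax - bmin)
    (l1, l2, l3), (u1, u2, u3) = _cutpoints(bmin, bmax, mu, mode)

    # rules in priority order: (condition, code); first match wins
    rules = [
        (np.abs(x - bmin) <= eps, 0),
        (np.abs(x - bmax) <= eps, 1),
        (np.abs(x - mu) <= eps, 6),
        ((bmin < x) & (x <= l1), 2),
        ((l1 < x) & (x <= l2), 3),
        ((l2 < x) & (x <= l3), 4),
        ((l3 < x) & (x < mu), 5),
        ((mu < x) & (x <= u1), 7),
        ((u1 < x) & (x <= u2), 8),
        ((u2 < x) & (x <= u3), 9),
        ((u3 < x) & (x < bmax), 10),
    ]
    codes = np.full(x.shape, 10, dtype=np.int64)  # fallback code
    assigned = np.zeros(x.shape, dtype=bool)
    for cond, code in rules:
        take = cond & ~assigned
        codes[take] = code
        assigned |= take
    return CodeVector(codes=codes, quantizer_mode=mode)


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

def histogram_features(
    codes: np.ndarray,
    n_bins: int = 16,
    value_range: tuple[float, float] = (0.0, 10.0),
) -> np.ndarray:
    """Normalized histogram of the codes over ``n_bins`` equal-width bins
    spanning ``value_range`` (right edge inclusive in the last bin)."""
    codes = np.asarray(codes, dtype=float).ravel()
    if codes.size == 0:
        raise ValueError("cannot build a histogram from an empty code sequence")
    hist, _ = np.histogram(codes, bins=n_bins, range=value_range)
    return hist / codes.size


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def extract_slice_features(
    image: np.ndarray,
    config: FeatureConfig | None = None,
    provenance: dict | None = None,
) -> FeatureVector:
    """Full Gradient-DDP descriptor of one slice.

    Because every stage after the gradient sees only gradient-derived values,
    the descriptor is invariant to additive intensity shifts of the slice.
    """
    cfg = config or FeatureConfig()
    grad = compute_gradient(image)
    raw = block_statistics(grad.gmag, grad.gdir, block_size=cfg.block_size)
    normalized = normalize_vector(raw.b)
    if cfg.histogram_domain == "codes":
        code_vec = quantize(normalized, mode=cfg.quantizer_mode)
        hist = histogram_features(code_vec.codes, n_bins=cfg.n_bins, value_range=(0.0, 10.0))
    elif cfg.histogram_domain == "normalized":
        hist = histogram_features(normalized, n_bins=cfg.n_bins, value_range=(0.0, 1.0))
    else:
        raise ValueError(f"unknown histogram domain: {cfg.histogram_domain!r}")
    prov = dict(provenance or {})
    prov.setdefault("method", "gradient-ddp")
    prov["quantizer_mode"] = cfg.quantizer_mode
    return FeatureVector(hist=hist, provenance=prov)
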