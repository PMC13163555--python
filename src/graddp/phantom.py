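"""Synthetic multi-modality MRI phantom with MS-like elliptical lesions.

The generator builds a download-free stand-in for simulated brain data: a
2D elliptical "brain" of concentric tissue regions (CSF ring, gray-matter
band, white-matter core), into which hyper-/hypo-intense elliptical lesions
are placed inside white matter.  Lesion count and size encode three severity
grades (mild / moderate / severe).  Each rendered slice is corrupted by a
smooth multiplicative intensity non-uniformity (INU) field and additive
noise, mimicking the standard simulated-MRI acquisition knobs.

Everything is driven by a single integer seed and is bitwise reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "LesionSpec",
    "PhantomConfig",
    "SubjectRecord",
    "TISSUE_BACKGROUND",
    "TISSUE_CSF",
    "TISSUE_GM",
    "TISSUE_WM",
    "DEFAULT_SEVERITY_SPECS",
    "DEFAULT_TISSUE_INTENSITIES",
    "generate_brain_mask",
    "place_lesions",
    "render_modality",
    "generate_subject",
    "generate_dataset",
    "dataset_checksum",
]

Modality = Literal["t1", "t2", "flair"]
Task = Literal["binary", "severity"]

# tissue labels of the anatomy map
TISSUE_BACKGROUND = 0
TISSUE_CSF = 1
TISSUE_GM = 2
TISSUE_WM = 3

#: attempts per lesion before giving up on placement (tiny masks would
#: otherwise loop forever)
PLACEMENT_BUDGET = 100


@dataclass(frozen=True)
class LesionSpec:
    """Sampling law of one severity grade's lesion load.

    Per slice, ``k ~ UniformInt(n_lesions_range)`` ellipses are drawn with
    semi-axes ``~ Uniform(semiaxis_range)`` (pixels) and uniform orientation,
    centered inside white matter.
    """

    n_lesions_range: tuple[int, int]
    semiaxis_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.n_lesions_range
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid lesion count range {self.n_lesions_range}")
        alo, ahi = self.semiaxis_range
        if alo < 1 or ahi < alo:
            raise ValueError(f"invalid semi-axis range {self.semiaxis_range} (min 1 px)")

    @property
    def expected_load(self) -> float:
        """Expected total lesion area (px^2), ignoring overlap: E[k] * pi * E[a] * E[b]."""
        k = (self.n_lesions_range[0] + self.n_lesions_range[1]) / 2
        a = (self.semiaxis_range[0] + self.semiaxis_range[1]) / 2
        return k * np.pi * a * a


#: Severity grades ordered by lesion load; counts and sizes overlap between
#: neighboring grades so the classes are separable but not trivially so.
DEFAULT_SEVERITY_SPECS: dict[str, LesionSpec] = {
    "mild": LesionSpec(n_lesions_range=(1, 3), semiaxis_range=(1.0, 3.0)),
    "moderate": LesionSpec(n_lesions_range=(4, 8), semiaxis_range=(2.0, 5.0)),
    "severe": LesionSpec(n_lesions_range=(9, 15), semiaxis_range=(4.0, 8.0)),
}

#: Mean tissue intensities (arbitrary units) per modality.  Orderings encode
#: the standard MR contrasts: T1 bright WM / dark CSF with hypointense
#: lesions; T2 bright CSF with hyperintense lesions; FLAIR like T2 but with
#: CSF suppressed below gray matter.
DEFAULT_TISSUE_INTENSITIES: dict[str, dict[str, float]] = {
    "t1": {"csf": 50.0, "gm": 120.0, "wm": 160.0, "lesion": 100.0},
    "t2": {"csf": 220.0, "gm": 120.0, "wm": 90.0, "lesion": 180.0},
    "flair": {"csf": 40.0, "gm": 130.0, "wm": 100.0, "lesion": 200.0},
}


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of one phantom acquisition."""

    image_size: tuple[int, int] = (96, 96)
    slices_per_subject: int = 30
    modality: Modality = "t2"
    tissue_intensities: dict = field(default_factory=lambda: DEFAULT_TISSUE_INTENSITIES)
    noise_sigma: float = 3.0
    noise_model: Literal["gaussian", "rician"] = "gaussian"
    inu_amplitude: float = 0.2
    severity_specs: dict = field(default_factory=lambda: DEFAULT_SEVERITY_SPECS)
    binary_ms_grade: str = "moderate"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.inu_amplitude < 1:
            raise ValueError("inu_amplitude must be in [0, 1)")
        if self.modality not in ("t1", "t2", "flair"):
            raise ValueError(f"unknown modality: {self.modality!r}")
        loads = [self.severity_specs[g].expected_load for g in ("mild", "moderate", "severe")]
        if not (loads[0] < loads[1] < loads[2]):
            raise ValueError("severity specs must have strictly increasing expected lesion load")


@dataclass
class SubjectRecord:
    """One synthetic subject: a stack of slices with ground truth."""

    subject_id: str
    modality: Modality
    label_binary: str  # "MS" | "non-MS"
    label_severity: str | None
    volume: np.ndarray  # (n_slices, rows, cols) float
    lesion_mask: np.ndarray  # same shape, bool

    def __post_init__(self) -> None:
        has_lesion = bool(self.lesion_mask.any())
        if (self.label_binary == "MS") != has_lesion:
            raise ValueError("label_binary must be MS iff the lesion mask is nonempty")
        if self.label_severity is not None and self.label_binary != "MS":
            raise ValueError("severity label present on a non-MS subject")


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------

def generate_brain_mask(
    image_size: tuple[int, int], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical brain mask plus tissue label map.

    The brain is a filled ellipse covering most of the frame, partitioned
    into a CSF ring, a gray-matter band and a white-matter core by scaling
    the ellipse radius.  A mild random eccentricity jitter (from ``rng``)
    varies anatomy across subjects while staying deterministic.

    Returns ``(mask, tissue_map)`` where tissue_map holds the labels
    TISSUE_BACKGROUND/CSF/GM/WM and partitions the mask.
    """
    rows, cols = image_size
    if rows < 32 or cols < 32:
        raise ValueError(f"image {image_size} too small for three tissue regions (min 32x32)")
    cy, cx = (rows - 1) / 2, (cols - 1) / 2
    # semi-axes ~ 42% of the frame with a few percent subject-level jitter
    ay = rows * (0.42 + 0.03 * rng.uniform(-1, 1))
    ax = cols * (0.42 + 0.03 * rng.uniform(-1, 1))
    yy, xx = np.mgrid[0:rows, 0:cols]
    r = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
    mask = r <= 1.0
    tissue = np.full(image_size, TISSUE_BACKGROUND, dtype=np.int8)
    tissue[mask] = TISSUE_CSF          # outer ring
    tissue[r <= 0.92] = TISSUE_GM      # cortical band
    tissue[r <= 0.72] = TISSUE_WM      # central core
    return mask, tissue


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------

def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], semi_axes: tuple[float, float], theta: float
) -> np.ndarray:
    cy, cx = center
    a, b = semi_axes
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def place_lesions(
    tissue_map: np.ndarray, spec: LesionSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``k ~ UniformInt(n_lesions_range)`` elliptical lesions fully
    inside the white-matter region; overlapping lesions merge (union).

    Each lesion is rejection-sampled: a center inside white matter and an
    orientation/semi-axis draw are retried until the whole ellipse fits in
    white matter, up to PLACEMENT_BUDGET attempts, after which a placement
    error is raised.
    """
    wm = tissue_map == TISSUE_WM
    if not wm.any():
        raise ValueError("tissue map has no white-matter region")
    wm_idx = np.flatnonzero(wm.ravel())
    k = int(rng.integers(spec.n_lesions_range[0], spec.n_lesions_range[1] + 1))
    mask = np.zeros(tissue_map.shape, dtype=bool)
    for _ in range(k):
        for _attempt in range(PLACEMENT_BUDGET):
            flat = rng.choice(wm_idx)
            cy, cx = divmod(int(flat), tissue_map.shape[1])
            a = rng.uniform(*spec.semiaxis_range)
            b = rng.uniform(*spec.semiaxis_range)
            theta = rng.uniform(0, np.pi)
            les = _ellipse_mask(tissue_map.shape, (cy, cx), (a, b), theta)
            if les.any() and not (les & ~wm).any():
                mask |= les
                break
        else:
            raise RuntimeError(
                f"could not place a lesion with semi-axes in {spec.semiaxis_range} "
                f"inside white matter after {PLACEMENT_BUDGET} attempts"
            )
    return mask


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _inu_field(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative bias field in [1 - amplitude, 1 + amplitude],
    built from a random second-order polynomial in normalized coordinates."""
    if amplitude == 0:
        return np.ones(shape)
    rows, cols = shape
    y = np.linspace(-1, 1, rows)[:, None]
    x = np.linspace(-1, 1, cols)[None, :]
    c = rng.uniform(-1, 1, size=6)
    poly = c[0] + c[1] * x + c[2] * y + c[3] * x * y + c[4] * x**2 + c[5] * y**2
    lo, hi = poly.min(), poly.max()
    if hi == lo:
        return np.ones(shape)
    unit = 2 * (poly - lo) / (hi - lo) - 1  # [-1, 1]
    return 1.0 + amplitude * unit


def render_modality(
    tissue_map: np.ndarray,
    lesion_mask: np.ndarray,
    config: PhantomConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one slice: tissue means, lesion contrast, INU field, noise.

    Modality contracts (before noise/INU): lesions are hyperintense relative
    to white matter on T2 and FLAIR and hypointense on T1; FLAIR suppresses
    CSF below gray matter.  The noisy image is clipped at 0 (magnitude MRI
    is nonnegative).
    """
    levels = config.tissue_intensities.get(config.modality)
    if levels is None:
        raise ValueError(f"no tissue intensities for modality {config.modality!r}")
    img = np.zeros(tissue_map.shape, dtype=float)
    img[tissue_map == TISSUE_CSF] = levels["csf"]
    img[tissue_map == TISSUE_GM] = levels["gm"]
    img[tissue_map == TISSUE_WM] = levels["wm"]
    img[lesion_mask] = levels["lesion"]
    img *= _inu_field(tissue_map.shape, config.inu_amplitude, rng)
    if config.noise_sigma > 0:
        if config.noise_model == "gaussian":
            img = img + rng.normal(0, config.noise_sigma, size=img.shape)
        elif config.noise_model == "rician":
            # magnitude of a complex signal with iid gaussian channel noise
            re = img + rng.normal(0, config.noise_sigma, size=img.shape)
            im = rng.normal(0, config.noise_sigma, size=img.shape)
            img = np.hypot(re, im)
        else:
            raise ValueError(f"unknown noise model: {config.noise_model!r}")
    return np.clip(img, 0, None)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def generate_subject(
    config: PhantomConfig,
    subject_id: str,
    grade: str | None,
    rng: np.random.Generator,
) -> SubjectRecord:
    """One subject: fixed anatomy, per-slice lesion re-sampling from the
    grade's spec (``grade=None`` means lesion-free / non-MS)."""
    _, tissue = generate_brain_mask(config.image_size, rng)
    n = config.slices_per_subject
    volume = np.empty((n, *config.image_size), dtype=float)
    lesions = np.zeros((n, *config.image_size), dtype=bool)
    spec = None if grade is None else config.severity_specs[grade]
    for s in range(n):
        if spec is not None:
            lesions[s] = place_lesions(tissue, spec, rng)
        volume[s] = render_modality(tissue, lesions[s], config, rng)
    has_lesion = bool(lesions.any())
    return SubjectRecord(
        subject_id=subject_id,
        modality=config.modality,
        label_binary="MS" if has_lesion else "non-MS",
        label_severity=grade if has_lesion else None,
        volume=volume,
        lesion_mask=lesions,
    )


def generate_dataset(
    config: PhantomConfig, n_subjects_per_class: int, task: Task
) -> list[SubjectRecord]:
    """Generate a labeled cohort.

    binary:   ``n`` lesion-free non-MS subjects plus ``n`` MS subjects whose
              lesions follow ``config.binary_ms_grade``.
    severity: ``n`` subjects per grade (mild / moderate / severe).

    Fully determined by ``config`` (including its seed).
    """
    if n_subjects_per_class < 1:
        raise ValueError("need at least one subject per class")
    if task == "binary":
        classes: list[str | None] = [None, config.binary_ms_grade]
    elif task == "severity":
        classes = ["mild", "moderate", "severe"]
    else:
        raise ValueError(f"unknown task: {task!r}")
    rng = np.random.default_rng(config.seed)
    subjects = []
    for grade in classes:
        name = "nonms" if grade is None else grade
        for i in range(n_subjects_per_class):
            subjects.append(generate_subject(config, f"{name}-{i:03d}", grade, rng))
    return subjects


def dataset_checksum(subjects: Iterable[SubjectRecord]) -> str:
    """SHA-256 over volumes, masks and labels; equal configs (and seeds)
    give equal checksums."""
    h = hashlib.sha256()
    for rec in subjects:
        h.update(rec.subject_id.encode())
        h.update(rec.label_binary.encode())
        h.update((rec.label_severity or "-").encode())
        h.update(np.ascontiguousarray(rec.volume).tobytes())
        h.update(np.packbits(rec.lesion_mask).tobytes())
    return h.hexdigest()
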