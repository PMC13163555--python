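"""Volume/slice I/O, manifests and leakage-free subject-wise splitting.

Slices of a subject are never divided across folds: the whole subject is
assigned to exactly one fold and every one of its slices inherits that fold.
This is the anti-leakage rule for slice-based medical-image classification —
neighboring slices of a brain are nearly identical, so a random slice-level
split leaks subject identity into the test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import SubjectRecord

__all__ = [
    "SliceRecord",
    "SplitAssignment",
    "load_volume",
    "save_volume",
    "load_png_directory",
    "save_png_slices",
    "subjects_to_slices",
    "write_manifest",
    "read_manifest",
    "subject_stratified_split",
]


@dataclass
class SliceRecord:
    """One 2D slice with its identity and label."""

    subject_id: str
    slice_idx: int
    modality: str
    label: int
    image: np.ndarray | None = None
    features: np.ndarray | None = None


@dataclass
class SplitAssignment:
    """Subject-to-fold map plus the rotating role schedule.

    In round ``r`` of ``n_folds`` rounds, fold ``r`` is the test set, fold
    ``(r + 1) % n_folds`` the validation set and the rest the training set,
    so every fold is the test fold exactly once and the three roles are
    subject-exclusive in every round.
    """

    fold_of_subject: dict[str, int]
    n_folds: int

    def subjects_in_fold(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.fold_of_subject.items() if f == fold)

    def roles(self, round_idx: int) -> dict[str, str]:
        """Map fold role names to 'train'/'validation'/'test' for one round."""
        test = round_idx % self.n_folds
        val = (round_idx + 1) % self.n_folds
        return {
            "test": test,
            "validation": val,
            "train": [f for f in range(self.n_folds) if f not in (test, val)],
        }

    def round_subjects(self, round_idx: int) -> dict[str, list[str]]:
        r = self.roles(round_idx)
        return {
            "test": self.subjects_in_fold(r["test"]),
            "validation": self.subjects_in_fold(r["validation"]),
            "train": sorted(
                s for f in r["train"] for s in self.subjects_in_fold(f)
            ),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"n_folds": self.n_folds, "fold_of_subject": self.fold_of_subject}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitAssignment":
        d = json.loads(Path(path).read_text())
        return cls(fold_of_subject=d["fold_of_subject"], n_folds=d["n_folds"])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_volume(path: str | Path) -> np.ndarray:
    """Load a NIfTI volume as a float array of axial slices, shape
    (n_slices, rows, cols).  The slice axis is the last array axis of the
    stored volume (the writer's convention); the affine is not interpreted
    beyond that."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    return np.moveaxis(data, -1, 0)


def save_volume(volume: np.ndarray, path: str | Path) -> None:
    """Write a (n_slices, rows, cols) stack as NIfTI with identity affine."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    img = nib.Nifti1Image(np.moveaxis(volume, 0, -1), affine=np.eye(4))
    nib.save(img, str(path))


def save_png_slices(volume: np.ndarray, directory: str | Path, prefix: str = "slice") -> list[Path]:
    """Export slices as 16-bit grayscale PNGs (slice index in the filename)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hi = float(volume.max()) or 1.0
    paths = []
    for i, sl in enumerate(volume):
        arr = np.round(np.clip(sl, 0, None) / hi * 65535).astype(np.uint16)
        p = directory / f"{prefix}_{i:04d}.png"
        iio.imwrite(p, arr)
        paths.append(p)
    return paths


def load_png_directory(
    directory: str | Path, subject_id: str, modality: str, label: int
) -> list[SliceRecord]:
    """Read every PNG in a directory (sorted by name) as one subject's
    slices."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(directory)
    records = []
    for i, p in enumerate(sorted(directory.glob("*.png"))):
        img = np.asarray(iio.imread(p), dtype=float)
        records.append(
            SliceRecord(subject_id=subject_id, slice_idx=i, modality=modality, label=label, image=img)
        )
    if not records:
        raise FileNotFoundError(f"no PNG slices found in {directory}")
    return records


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

LABELS_BINARY = {"non-MS": 0, "MS": 1}
LABELS_SEVERITY = {"mild": 0, "moderate": 1, "severe": 2}


def subjects_to_slices(subjects: Iterable[SubjectRecord], task: str = "binary") -> list[SliceRecord]:
    """Flatten phantom subjects into per-slice records with integer labels."""
    out = []
    for rec in subjects:
        if task == "binary":
            label = LABELS_BINARY[rec.label_binary]
        elif task == "severity":
            if rec.label_severity is None:
                raise ValueError(f"subject {rec.subject_id} has no severity label")
            label = LABELS_SEVERITY[rec.label_severity]
        else:
            raise ValueError(f"unknown task: {task!r}")
        for i, sl in enumerate(rec.volume):
            out.append(
                SliceRecord(
                    subject_id=rec.subject_id,
                    slice_idx=i,
                    modality=rec.modality,
                    label=label,
                    image=sl,
                )
            )
    return out


def write_manifest(
    subjects: Iterable[SubjectRecord], directory: str | Path, save_volumes: bool = True
) -> Path:
    """Write per-subject NIfTI volumes plus a CSV manifest; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in subjects:
        rel = f"{rec.subject_id}_{rec.modality}.nii.gz"
        if save_volumes:
            save_volume(rec.volume, directory / rel)
            save_volume(rec.lesion_mask.astype(np.uint8), directory / f"{rec.subject_id}_{rec.modality}_mask.nii.gz")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "modality": rec.modality,
                "label_binary": rec.label_binary,
                "label_severity": rec.label_severity or "",
                "path": rel,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, keep_default_na=False)


# ---------------------------------------------------------------------------
# subject-wise grouped stratified split
# ---------------------------------------------------------------------------

def subject_stratified_split(
    records: Sequence[SliceRecord] | pd.DataFrame,
    n_folds: int = 5,
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole subjects to ``n_folds`` folds, balancing per-class
    subject counts.

    Greedy seeded scheme: subjects of each class are shuffled by ``seed``
    and dealt one at a time to the fold currently holding the fewest
    subjects of that class (ties broken by lowest fold index).  Per-fold
    class counts therefore differ from perfect balance by at most one, and
    no subject ever lands in two folds.
    """
    if isinstance(records, pd.DataFrame):
        pairs = records[["subject_id", "label"]].drop_duplicates()
        subject_class = dict(zip(pairs["subject_id"], pairs["label"]))
    else:
        subject_class = {}
        for r in records:
            prev = subject_class.setdefault(r.subject_id, r.label)
            if prev != r.label:
                raise ValueError(f"subject {r.subject_id} has inconsistent labels")
    by_class: dict[int, list[str]] = {}
    for sid, lab in subject_class.items():
        by_class.setdefault(lab, []).append(sid)
    for lab, sids in by_class.items():
        if len(sids) < n_folds:
            raise ValueError(
                f"class {lab} has {len(sids)} subjects, fewer than {n_folds} folds"
            )
    rng = np.random.default_rng(seed)
    fold_of_subject: dict[str, int] = {}
    for lab in sorted(by_class):
        sids = sorted(by_class[lab])
        rng.shuffle(sids)
        load = [0] * n_folds
        for sid in sids:
            f = int(np.argmin(load))  # lowest index among least-loaded
            fold_of_subject[sid] = f
            load[f] += 1
    return SplitAssignment(fold_of_subject=fold_of_subject, n_folds=n_folds)
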