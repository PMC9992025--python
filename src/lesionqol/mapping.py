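"""Lesion segmentation, volumetry and atlas-overlap mapping.

Four lesion types are tracked per subject: resection cavity, contrast-
enhancing T1 lesion (t1ce), T2/FLAIR hyperintensity (flair) and the
amino-acid-PET positive volume (fet).  PET positivity is defined by
tumor-to-brain-ratio thresholding (uptake / healthy-background mean > 1.6 by
default).  The central product is the overlap table: for every subject,
lesion type and atlas region, the partial overlapping volume in mL and as a
fraction of the region volume.

All volumes must share one grid (shape + affine); this module refuses to
resample.  Nearest-neighbour label resampling is an upstream concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import AtlasParcellation

__all__ = [
    "LESION_TYPES",
    "LesionSet",
    "TbrParameters",
    "GridMismatchError",
    "segment_fet",
    "lesion_volume_ml",
    "overlap_table",
    "classify_laterality",
]

LESION_TYPES = ("cavity", "t1ce", "flair", "fet")


class GridMismatchError(ValueError):
    """Volumes do not share a common grid; resample upstream (nearest-neighbour
    for labels) before calling this module."""


@dataclass
class TbrParameters:
    """Tumor-to-brain-ratio thresholding parameters.

    ``background_mask`` selects the healthy-brain voxels whose arithmetic-mean
    uptake defines the denominator of the TBR.
    """

    threshold: float = 1.6
    background_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.threshold <= 1:
            raise ValueError(f"TBR threshold must exceed 1, got {self.threshold}")


@dataclass
class LesionSet:
    """Binary masks of the four lesion types for one subject."""

    subject: str
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, m in self.masks.items():
            if t not in LESION_TYPES:
                raise ValueError(f"unknown lesion type {t!r}")
            m = np.asarray(m)
            vals = np.unique(m)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"mask {t!r} of subject {self.subject!r} is not binary")
            self.masks[t] = m.astype(np.uint8)

    def union(self) -> np.ndarray:
        out = None
        for m in self.masks.values():
            out = m.astype(bool) if out is None else (out | m.astype(bool))
        if out is None:
            raise ValueError(f"subject {self.subject!r} has no masks")
        return out

    def save(self, directory: str | Path, affine: np.ndarray) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for t, m in self.masks.items():
            nib.save(nib.Nifti1Image(m.astype(np.uint8), affine),
                     str(directory / f"{self.subject}_{t}.nii.gz"))

    @classmethod
    def load(cls, directory: str | Path, subject: str) -> tuple["LesionSet", np.ndarray]:
        directory = Path(directory)
        masks, affine = {}, None
        for t in LESION_TYPES:
            p = directory / f"{subject}_{t}.nii.gz"
            if p.exists():
                img = nib.load(str(p))
                masks[t] = np.asarray(img.dataobj).astype(np.uint8)
                affine = img.affine
        if not masks:
            raise FileNotFoundError(f"no lesion masks for subject {subject!r} in {directory}")
        return cls(subject, masks), affine


def _check_same_grid(shape, affine, other_shape, other_affine, what: str) -> None:
    if tuple(shape) != tuple(other_shape) or not np.allclose(affine, other_affine, atol=1e-4):
        raise GridMismatchError(
            f"{what}: grid mismatch (shape {tuple(other_shape)} vs {tuple(shape)}, "
            "or affines differ); resample upstream to the atlas grid"
        )


def segment_fet(pet_volume: np.ndarray, params: TbrParameters) -> np.ndarray:
    """Threshold a PET volume at TBR > ``params.threshold``.

    The background mean is the arithmetic mean of uptake inside
    ``params.background_mask``; a voxel is positive iff
    ``uptake / background_mean > threshold``.
    """
    pet = np.asarray(pet_volume, dtype=float)
    if np.any(pet < 0):
        raise ValueError("PET volume must be nonnegative")
    bg = params.background_mask
    if bg is None or not np.any(bg):
        raise ValueError("TBR segmentation requires a nonempty background mask")
    bg_mean = float(pet[np.asarray(bg, dtype=bool)].mean())
    if bg_mean <= 0:
        raise ValueError("background mean uptake must be positive")
    return (pet / bg_mean > params.threshold).astype(np.uint8)


def lesion_volume_ml(mask: np.ndarray, voxel_size_mm) -> float:
    """Mask volume in mL: voxel count x voxel volume (mm^3) / 1000."""
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("lesion_volume_ml expects a binary mask")
    vox_mm3 = float(np.prod(np.asarray(voxel_size_mm, dtype=float)))
    return float(mask.sum()) * vox_mm3 / 1000.0


def _region_overlap_counts(mask: np.ndarray, labels: np.ndarray, max_label: int) -> np.ndarray:
    return np.bincount(labels[mask.astype(bool)].ravel(), minlength=max_label + 1)


def overlap_table(
    lesions: list[LesionSet],
    nodes: AtlasParcellation,
    tracts: AtlasParcellation,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partial overlap of every lesion with every node and tract.

    Returns
    -------
    overlaps
        Tidy frame with one row per (subject, lesion_type, atlas, region):
        ``overlap_ml`` is the intersected volume, ``overlap_fraction`` that
        volume divided by the region volume.  Zero rows are retained, so the
        table is a dense tensor.
    totals
        One row per (subject, lesion_type) with the total lesion volume and,
        per atlas, the lesion volume falling on background voxels
        (``off_nodes_ml`` / ``off_tracts_ml``), so that atlas overlap plus
        off-atlas volume always reconstructs the total.
    """
    _check_same_grid(nodes.labels.shape, nodes.affine, tracts.labels.shape, tracts.affine,
                     "node vs tract atlas")
    vox_ml = nodes.voxel_volume_mm3 / 1000.0
    atlases = {"nodes": nodes, "tracts": tracts}
    region_vol = {k: a.region_volumes_ml() for k, a in atlases.items()}
    max_label = {k: int(a.regions.index.max()) for k, a in atlases.items()}

    rows, total_rows = [], []
    for ls in lesions:
        for t, m in ls.masks.items():
            _check_same_grid(nodes.labels.shape, nodes.affine, m.shape, nodes.affine,
                             f"lesion {ls.subject}/{t}")
            total_ml = float(m.sum()) * vox_ml
            on_atlas = {}
            for key, a in atlases.items():
                counts = _region_overlap_counts(m, a.labels, max_label[key])
                on = 0.0
                for label in a.regions.index:
                    o_ml = counts[label] * vox_ml
                    rv = region_vol[key].loc[label]
                    rows.append(
                        {
                            "subject": ls.subject,
                            "lesion_type": t,
                            "atlas": key,
                            "region": int(label),
                            "region_name": a.regions.loc[label, "name"],
                            "hemisphere": a.regions.loc[label, "hemisphere"],
                            "class_": a.regions.loc[label, "class_"],
                            "overlap_ml": o_ml,
                            "overlap_fraction": (o_ml / rv) if rv > 0 else 0.0,
                        }
                    )
                    on += o_ml
                on_atlas[key] = on
            total_rows.append(
                {
                    "subject": ls.subject,
                    "lesion_type": t,
                    "total_ml": total_ml,
                    "off_nodes_ml": total_ml - on_atlas["nodes"],
                    "off_tracts_ml": total_ml - on_atlas["tracts"],
                }
            )
    overlaps = pd.DataFrame(rows)
    totals = pd.DataFrame(total_rows)
    return overlaps, totals


def classify_laterality(lesions: LesionSet, affine: np.ndarray) -> str:
    """Tumor side from the centre of mass of the union lesion mask.

    The side is the sign of the centre of mass along the first world axis;
    an exactly-zero centre falls to the side holding more lesion voxels
    (a deterministic tie-break for mirrored bilateral lesions).
    """
    union = lesions.union()
    if not union.any():
        raise ValueError(f"subject {lesions.subject!r}: empty union lesion, cannot classify")
    idx = np.nonzero(union)
    x_world = affine[0, 0] * idx[0] + affine[0, 3]
    com = float(x_world.mean())
    if com < 0:
        return "left"
    if com > 0:
        return "right"
    n_left = int((x_world < 0).sum())
    n_right = int((x_world > 0).sum())
    return "left" if n_left >= n_right else "right"
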