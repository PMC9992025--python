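"""Atlas parcellations on a common voxel grid.

An :class:`AtlasParcellation` couples an integer label volume with a region
table (label id, name, hemisphere, class).  Two parcellations are used
throughout the package: a cortical node atlas whose regions belong to
resting-state networks (100 nodes, 50 per hemisphere, 7 networks by default,
mirroring the Schaefer 100-parcel / 7-network layout) and a white-matter tract
atlas (24 tracts per hemisphere plus midline structures, mirroring the JHU
stereotaxic tract atlas).  The toy builder places regions deterministically on
a lattice so that every downstream computation has exact, enumerable ground
truth.

Hemisphere convention: the sign of the first *world* coordinate encodes
hemisphere (negative = left), so the affine of a toy grid centres the first
axis on zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AtlasParcellation",
    "PlacementError",
    "build_toy_atlas",
    "centered_affine",
    "NETWORK_NAMES",
    "TRACT_NAMES",
    "MIDLINE_TRACT_NAMES",
]

NETWORK_NAMES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)

#: Canonical tract families for the default 24-per-hemisphere layout.
TRACT_NAMES = (
    "anterior_limb_internal_capsule",
    "posterior_limb_internal_capsule",
    "retrolenticular_internal_capsule",
    "anterior_corona_radiata",
    "superior_corona_radiata",
    "posterior_corona_radiata",
    "fornix_stria_terminalis",
    "corticospinal_tract",
    "medial_lemniscus",
    "inferior_cerebellar_peduncle",
    "superior_cerebellar_peduncle",
    "cerebral_peduncle",
    "posterior_thalamic_radiation",
    "sagittal_stratum",
    "external_capsule",
    "cingulum_cingulate",
    "cingulum_hippocampal",
    "superior_longitudinal_fasciculus",
    "superior_fronto_occipital_fasciculus",
    "inferior_longitudinal_fasciculus",
    "uncinate_fasciculus",
    "tapetum",
    "optic_radiation",
    "corona_radiata_accessory",
)

MIDLINE_TRACT_NAMES = (
    "corpus_callosum_genu",
    "corpus_callosum_body",
    "corpus_callosum_splenium",
    "middle_cerebellar_peduncle",
    "pontine_crossing_tract",
)


class PlacementError(ValueError):
    """Raised when a toy grid is too small to place all atlas regions."""


def centered_affine(grid_shape, voxel_size_mm) -> np.ndarray:
    """Diagonal affine placing world x=0 on the midplane of the first axis.

    The second and third axes keep their origin at voxel 0; only the
    left/right axis needs a meaningful zero.
    """
    vx = np.asarray(voxel_size_mm, dtype=float)
    if vx.shape != (3,) or np.any(vx <= 0):
        raise ValueError("voxel_size_mm must be three positive values")
    aff = np.diag(np.append(vx, 1.0))
    aff[0, 3] = -vx[0] * (grid_shape[0] - 1) / 2.0
    return aff


@dataclass
class AtlasParcellation:
    """Integer label volume plus a region lookup table.

    Parameters
    ----------
    labels
        3D integer array; 0 is background, every nonzero value appears in
        ``regions``.
    affine
        4x4 voxel-to-world matrix. The sign of the first world coordinate
        encodes hemisphere for toy atlases.
    regions
        DataFrame indexed by label id with columns ``name``, ``hemisphere``
        (left/right/midline) and ``class_`` (network id for nodes, tract
        family for tracts).
    """

    labels: np.ndarray
    affine: np.ndarray
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        present = np.unique(self.labels)
        present = present[present != 0]
        missing = set(present.tolist()) - set(self.regions.index.tolist())
        if missing:
            raise ValueError(f"labels missing from region table: {sorted(missing)}")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def region_volumes_ml(self) -> pd.Series:
        """Volume of every region in the table, in mL (zero if absent)."""
        counts = np.bincount(self.labels.ravel(), minlength=int(self.regions.index.max()) + 1)
        vols = counts[self.regions.index.to_numpy()] * self.voxel_volume_mm3 / 1000.0
        return pd.Series(vols, index=self.regions.index, name="volume_ml")

    def x_world(self) -> np.ndarray:
        """World coordinate of the first axis for every voxel plane."""
        i = np.arange(self.labels.shape[0])
        return self.affine[0, 0] * i + self.affine[0, 3]

    # ------------------------------------------------------------------ I/O
    def save(self, labels_path: str | Path, regions_path: str | Path) -> None:
        img = nib.Nifti1Image(self.labels.astype(np.uint16), self.affine)
        nib.save(img, str(labels_path))
        self.regions.rename_axis("label").reset_index().to_csv(
            regions_path, sep="\t", index=False
        )

    @classmethod
    def load(cls, labels_path: str | Path, regions_path: str | Path) -> "AtlasParcellation":
        img = nib.load(str(labels_path))
        regions = pd.read_csv(regions_path, sep="\t").set_index("label")
        return cls(np.asarray(img.dataobj).astype(np.int32), img.affine, regions)


def _split_counts(total: int, groups: int) -> list[int]:
    """Partition ``total`` into ``groups`` near-equal positive counts."""
    if groups > total:
        raise ValueError(f"cannot split {total} regions into {groups} nonempty groups")
    base, extra = divmod(total, groups)
    return [base + (1 if g < extra else 0) for g in range(groups)]

def _lattice_slots(lo, hi, span, step):
    """Start indices of non-overlapping boxes of ``span`` voxels in [lo, hi)."""
    return list(range(lo, hi - span + 1, step))


def _place_boxes(shape, x_range, n, box, names, label_start):
    """Place ``n`` boxes on a lattice inside ``x_range`` of the first axis.

    Slots are consumed from the hemisphere centre outward, so a compact
    atlas sits in the interior of the grid (where simulated lesions live)
    rather than hugging a corner.  Raises :class:`PlacementError` naming the
    first region that does not fit.
    """
    gap = 1
    xs = _lattice_slots(x_range[0], x_range[1], box[0], box[0] + gap)
    ys = _lattice_slots(1, shape[1] - 1, box[1], box[1] + gap)
    zs = _lattice_slots(1, shape[2] - 1, box[2], box[2] + gap)
    cx = (x_range[0] + x_range[1]) / 2.0
    cy, cz = shape[1] / 2.0, shape[2] / 2.0

    def _dist(slot):
        x, y, z = slot
        return ((x + box[0] / 2 - cx) ** 2 + (y + box[1] / 2 - cy) ** 2
                + (z + box[2] / 2 - cz) ** 2)

    slots = sorted(((x, y, z) for z in zs for y in ys for x in xs), key=_dist)
    if len(slots) < n:
        raise PlacementError(
            f"grid too small: could not place region {names[len(slots)]!r} "
            f"({len(slots)} lattice slots available for {n} regions)"
        )
    out = []
    for k in range(n):
        x, y, z = slots[k]
        out.append((slice(x, x + box[0]), slice(y, y + box[1]), slice(z, z + box[2])))
    return out


def _mirror_slices(sl, nx):
    """Mirror a first-axis slice across the midplane of an nx-wide grid."""
    a, b = sl[0].start, sl[0].stop
    return (slice(nx - b, nx - a), sl[1], sl[2])


def build_toy_atlas(config) -> tuple[AtlasParcellation, AtlasParcellation]:
    """Build mirrored node and tract parcellations for a simulation config.

    Nodes are cubes on a lattice in each hemisphere, assigned to networks in
    near-equal contiguous blocks (both hemispheres contain every network).
    Tracts are elongated boxes on a separate lattice (the two atlases live in
    separate volumes, as grey-matter nodes and white-matter tracts do), plus
    midline structures straddling the midplane.
    """
    shape = tuple(int(s) for s in config.grid_shape)
    affine = centered_affine(shape, config.voxel_size_mm)
    nx = shape[0]
    half = nx // 2  # voxels strictly left of the midplane for even nx

    n_nodes = config.n_nodes_per_hemisphere
    n_networks = config.n_networks
    net_sizes = _split_counts(n_nodes, n_networks)

    node_box = (4, 4, 4)
    left_x = (1, half)
    node_slices = _place_boxes(
        shape, left_x, n_nodes, node_box,
        [f"LH_node_{i + 1}" for i in range(n_nodes)], 1,
    )

    node_labels = np.zeros(shape, dtype=np.uint16)
    rows = []
    net_of = []
    for net, size in zip(NETWORK_NAMES[:n_networks] if n_networks <= len(NETWORK_NAMES)
                         else [f"network_{i+1}" for i in range(n_networks)], net_sizes):
        net_of.extend([net] * size)
    for hemi_idx, hemi in enumerate(("left", "right")):
        for i in range(n_nodes):
            label = hemi_idx * n_nodes + i + 1
            sl = node_slices[i] if hemi == "left" else _mirror_slices(node_slices[i], nx)
            if np.any(node_labels[sl]):
                raise PlacementError(f"label collision placing node {label}")
            node_labels[sl] = label
            prefix = "LH" if hemi == "left" else "RH"
            rows.append(
                {"label": label, "name": f"{prefix}_{net_of[i]}_{i + 1}",
                 "hemisphere": hemi, "class_": net_of[i]}
            )
    nodes = AtlasParcellation(node_labels, affine, pd.DataFrame(rows).set_index("label"))

    # ------------------------------------------------------------- tracts
    n_tracts = config.n_tracts_per_hemisphere
    n_mid = config.n_midline_tracts
    tract_names = list(TRACT_NAMES[:n_tracts]) if n_tracts <= len(TRACT_NAMES) else [
        f"tract_{i + 1}" for i in range(n_tracts)
    ]
    mid_names = list(MIDLINE_TRACT_NAMES[:n_mid]) if n_mid <= len(MIDLINE_TRACT_NAMES) else [
        f"midline_tract_{i + 1}" for i in range(n_mid)
    ]
    tract_box = (3, 8, 3)
    tract_slices = _place_boxes(shape, left_x, n_tracts, tract_box, tract_names, 1)

    tract_labels = np.zeros(shape, dtype=np.uint16)
    rows = []
    for hemi_idx, hemi in enumerate(("left", "right")):
        for i in range(n_tracts):
            label = hemi_idx * n_tracts + i + 1
            sl = tract_slices[i] if hemi == "left" else _mirror_slices(tract_slices[i], nx)
            if np.any(tract_labels[sl]):
                raise PlacementError(f"label collision placing tract {label}")
            tract_labels[sl] = label
            prefix = "LH" if hemi == "left" else "RH"
            rows.append(
                {"label": label, "name": f"{prefix}_{tract_names[i]}",
                 "hemisphere": hemi, "class_": tract_names[i]}
            )
    if n_mid:
        mid_box = (4, 6, 3)
        x0 = half - mid_box[0] // 2
        ys = _lattice_slots(1, shape[1] - 1, mid_box[1], mid_box[1] + 1)
        zs = _lattice_slots(1, shape[2] - 1, mid_box[2], mid_box[2] + 1)
        # midline structures get their own y/z lattice, scanned from the
        # grid centre outward; slots colliding with hemispheric tracts that
        # reach the midplane are skipped
        cy, cz = shape[1] / 2.0, shape[2] / 2.0
        slots = sorted(
            ((y, z) for z in zs for y in ys),
            key=lambda s: (s[0] + mid_box[1] / 2 - cy) ** 2 + (s[1] + mid_box[2] / 2 - cz) ** 2,
        )
        placed = 0
        label = 2 * n_tracts
        for (y, z) in slots:
            if placed >= n_mid:
                break
            sl = (slice(x0, x0 + mid_box[0]), slice(y, y + mid_box[1]), slice(z, z + mid_box[2]))
            if np.any(tract_labels[sl]):
                continue
            label += 1
            tract_labels[sl] = label
            rows.append(
                {"label": label, "name": mid_names[placed],
                 "hemisphere": "midline", "class_": mid_names[placed]}
            )
            placed += 1
        if placed < n_mid:
            raise PlacementError(
                f"grid too small: could not place midline tract {mid_names[placed]!r}"
            )
    tracts = AtlasParcellation(tract_labels, affine, pd.DataFrame(rows).set_index("label"))
    return nodes, tracts
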