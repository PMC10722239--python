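"""Labeled atlas volumes: point lookup, border distances, toy construction.

An :class:`AtlasVolume` is a 3-D integer label grid in PIR orientation
with a label map to ``(area_acronym, layer_name)`` pairs.  Real CCF/ARA
annotation volumes (NIfTI + sidecar JSON label map) are drop-in
compatible with the toy volumes built here for testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

#: Canonical somatosensory area order (also the dominant-target tie-break order).
CANONICAL_AREAS = ("SSp-bfd", "SSp-n", "SSp-m", "SSp-ul", "SSp-ll", "SSs")

#: Cortical layers from the pia downward.
LAYERS = ("L1", "L2/3", "L4", "L5", "L6a", "L6b")

BACKGROUND = ("background", None)


class UnknownAreaError(KeyError):
    """Area acronym not present in the atlas label map."""


@dataclass
class AtlasVolume:
    """A labeled 3-D volume in PIR orientation.

    ``labels`` is indexed ``[ap, si, lr]``; ``label_map`` sends each
    nonzero label to ``(area_acronym, layer_name-or-None)``.
    """

    labels: np.ndarray
    voxel_size_um: float = 10.0
    label_map: dict[int, tuple[str, str | None]] = field(default_factory=dict)
    _edt_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.labels.size:
            present = set(np.unique(self.labels.reshape(-1))) - {0}
            missing = present - set(self.label_map)
            if missing:
                raise ValueError(f"labels {sorted(missing)} missing from label_map")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def extents_um(self) -> tuple[float, float, float]:
        return tuple(s * self.voxel_size_um for s in self.labels.shape)

    @property
    def area_groups(self) -> dict[str, set[int]]:
        groups: dict[str, set[int]] = {}
        for lab, (area, _layer) in self.label_map.items():
            groups.setdefault(area, set()).add(lab)
        return groups

    # -- lookup -------------------------------------------------------------

    def voxel_of(self, points_um) -> np.ndarray:
        """μm point(s) -> 0-based voxel index (floor, half-open ownership)."""
        return np.floor(np.atleast_2d(points_um) / self.voxel_size_um).astype(int)

    def label_at(self, p_um) -> tuple[str, str | None]:
        """Area/layer at a μm point; out-of-bounds or label 0 -> background."""
        v = self.voxel_of(p_um)[0]
        if np.any(v < 0) or np.any(v >= self.labels.shape):
            return BACKGROUND
        lab = int(self.labels[tuple(v)])
        return self.label_map.get(lab, BACKGROUND)

    def labels_at(self, points_um) -> list[tuple[str, str | None]]:
        """Vectorized :meth:`label_at` over an (n, 3) μm array."""
        v = self.voxel_of(points_um)
        out = []
        shape = np.asarray(self.labels.shape)
        inside = np.all((v >= 0) & (v < shape), axis=1)
        for ok, vox in zip(inside, v):
            if not ok:
                out.append(BACKGROUND)
            else:
                out.append(self.label_map.get(int(self.labels[tuple(vox)]), BACKGROUND))
        return out

    # -- border distances ---------------------------------------------------

    def _area_edt(self, area: str) -> np.ndarray:
        """Distance transform (μm) to the nearest voxel of ``area``, cached."""
        if area not in self.area_groups:
            raise UnknownAreaError(area)
        if area not in self._edt_cache:
            labs = self.area_groups[area]
            mask = ~np.isin(self.labels, sorted(labs))
            self._edt_cache[area] = ndimage.distance_transform_edt(
                mask, sampling=self.voxel_size_um)
        return self._edt_cache[area]

    def border_distance(self, p_um, target_area: str) -> float:
        """Euclidean μm distance from a point to the nearest voxel carrying
        any label of ``target_area`` (0 inside the area).

        Points outside the grid are clamped to the nearest edge voxel,
        which under-estimates by at most the out-of-grid excursion.
        """
        edt = self._area_edt(target_area)
        v = self.voxel_of(p_um)[0]
        v = np.clip(v, 0, np.asarray(self.labels.shape) - 1)
        return float(edt[tuple(v)])


# ---------------------------------------------------------------------------
# toy construction

def build_toy_atlas(
    shape_um: tuple[float, float, float] = (2000.0, 2000.0, 2000.0),
    voxel_size_um: float = 10.0,
    areas: tuple[str, ...] = CANONICAL_AREAS,
    layer_thickness_um: tuple[float, ...] = (100, 200, 150, 200, 200, 50),
    slab_top_um: float = 0.0,
    area_lr_edges_um: tuple[float, ...] | None = None,
    nucleus_center_um: tuple[float, float, float] | None = None,
    nucleus_radii_um: tuple[float, float, float] = (400.0, 300.0, 350.0),
) -> AtlasVolume:
    """Build a toy labeled volume: a layered cortical slab plus a nucleus.

    The slab starts at depth ``slab_top_um`` along the superior-inferior
    axis and is partitioned into ``areas`` along the left-right axis and
    into ``LAYERS`` (with the given thicknesses) along depth.  Area
    boundaries default to equal widths; ``area_lr_edges_um`` supplies
    the interior boundary positions (``len(areas) - 1`` values) for an
    unequal partition, with the first and last areas extending to the
    volume edges.  A subcortical nucleus ellipsoid sits below the slab
    (at its own label).  Raises if the nucleus would overlap the slab.
    """
    if len(layer_thickness_um) != len(LAYERS):
        raise ValueError(f"need {len(LAYERS)} layer thicknesses")
    dims = tuple(int(round(s / voxel_size_um)) for s in shape_um)
    if any(d <= 0 for d in dims):
        raise ValueError("dimensions must be positive")
    labels = np.zeros(dims, dtype=np.int32)
    label_map: dict[int, tuple[str, str | None]] = {}

    slab_depth_um = float(sum(layer_thickness_um))
    top_v = int(round(slab_top_um / voxel_size_um))
    if area_lr_edges_um is None:
        area_width_v = dims[2] // len(areas)
        if area_width_v < 1:
            raise ValueError("grid too small for the requested area count")
        edges_v = [ai * area_width_v for ai in range(1, len(areas))]
    else:
        if len(area_lr_edges_um) != len(areas) - 1:
            raise ValueError(f"need {len(areas) - 1} interior area boundaries")
        edges_v = [int(round(e / voxel_size_um)) for e in area_lr_edges_um]
        if sorted(edges_v) != edges_v or edges_v and (
                edges_v[0] < 1 or edges_v[-1] > dims[2] - 1):
            raise ValueError("area boundaries must be increasing and interior")
    bounds_v = [0, *edges_v, dims[2]]

    next_label = 1
    depth_v = top_v
    for layer, thick in zip(LAYERS, layer_thickness_um):
        n_v = int(round(thick / voxel_size_um))
        for ai, area in enumerate(areas):
            labels[:, depth_v:depth_v + n_v, bounds_v[ai]:bounds_v[ai + 1]] = next_label
            label_map[next_label] = (area, layer)
            next_label += 1
        depth_v += n_v

    if nucleus_center_um is None:
        nucleus_center_um = (
            shape_um[0] / 2,
            slab_top_um + slab_depth_um + nucleus_radii_um[1] + 200.0,
            shape_um[2] / 2,
        )
    center_v = np.asarray(nucleus_center_um) / voxel_size_um
    radii_v = np.asarray(nucleus_radii_um) / voxel_size_um
    gx, gy, gz = np.ogrid[:dims[0], :dims[1], :dims[2]]
    dist2 = (((gx + 0.5 - center_v[0]) / radii_v[0]) ** 2
             + ((gy + 0.5 - center_v[1]) / radii_v[1]) ** 2
             + ((gz + 0.5 - center_v[2]) / radii_v[2]) ** 2)
    nucleus_mask = dist2 <= 1.0
    if not np.any(nucleus_mask):
        raise ValueError("nucleus ellipsoid contains no voxels")
    if np.any(labels[nucleus_mask] != 0):
        raise ValueError("nucleus overlaps the cortical slab")
    nucleus_label = next_label
    labels[nucleus_mask] = nucleus_label
    label_map[nucleus_label] = ("VPM", None)

    return AtlasVolume(labels=labels, voxel_size_um=voxel_size_um,
                       label_map=label_map)


# ---------------------------------------------------------------------------
# NIfTI I/O (integer labels + sidecar JSON label map)

def write_atlas(a: AtlasVolume, nifti_path, label_map_path=None) -> None:
    import nibabel as nib

    affine = np.diag([a.voxel_size_um, a.voxel_size_um, a.voxel_size_um, 1.0])
    img = nib.Nifti1Image(a.labels.astype(np.int32), affine)
    nib.save(img, str(nifti_path))
    lm_path = label_map_path or str(nifti_path) + ".labels.json"
    doc = {str(k): list(v) for k, v in a.label_map.items()}
    with open(lm_path, "w") as fh:
        json.dump({"voxel_size_um": a.voxel_size_um, "label_map": doc}, fh)


def read_atlas(nifti_path, label_map_path=None) -> AtlasVolume:
    import nibabel as nib

    img = nib.load(str(nifti_path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    lm_path = label_map_path or str(nifti_path) + ".labels.json"
    with open(lm_path) as fh:
        doc = json.load(fh)
    label_map = {int(k): (v[0], v[1]) for k, v in doc["label_map"].items()}
    return AtlasVolume(labels=labels,
                       voxel_size_um=float(doc.get("voxel_size_um", 10.0)),
                       label_map=label_map)
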