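"""Morphology I/O and coordinate normalization.

A reconstructed neuron is stored as a pair of arrays: a *point* array of
3-D coordinates and a *line* array of per-point records carrying the
structure label (soma / axon / dendrite), the point's own index and the
index of its parent (-1 for the root).  All analysis downstream assumes
coordinates in micrometers in the PIR orientation of the Allen Common
Coordinate Framework: first axis anterior->posterior, second
superior->inferior, third left->right, origin at the
anterior-superior-left corner.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

SOMA, AXON, DENDRITE = "soma", "axon", "dendrite"

#: SWC structure-code mapping; codes outside this table map to dendrite.
_SWC_CODE_TO_LABEL = {1: SOMA, 2: AXON, 3: DENDRITE, 4: DENDRITE}
_LABEL_TO_SWC_CODE = {SOMA: 1, AXON: 2, DENDRITE: 3}

#: CCF v3.0 template extents at full resolution, micrometers (AP, SI, LR).
CCF_EXTENTS_UM = (13_200.0, 8_000.0, 11_400.0)


class MorphologyFormatError(ValueError):
    """Malformed file contents (unparseable line, missing key)."""


class MorphologyStructureError(ValueError):
    """Parseable file with an invalid tree (multiple roots, dangling parent)."""


@dataclass(frozen=True)
class SpaceSpec:
    """Coordinate space of a morphology source.

    Parameters
    ----------
    orientation
        Three-letter axis code naming the anatomical direction of each
        positive axis, e.g. ``"PIR"`` (posterior, inferior, right — the
        CCF convention) or ``"LIP"`` (left, inferior, posterior — the
        MouseLight convention).  Corner origin in all cases.
    unit_um
        Micrometers per coordinate unit (1.0 for μm data, 10.0 for
        10-μm-voxel data, 25.0 for 25-μm data).
    extents_um
        Template extents along (AP, SI, LR) in micrometers; used for the
        axis reflection when converting between mirrored orientations.
    """

    orientation: str = "PIR"
    unit_um: float = 1.0
    extents_um: tuple[float, float, float] = CCF_EXTENTS_UM

    def __post_init__(self) -> None:
        if self.unit_um <= 0:
            raise ValueError("unit_um must be positive")
        if len(self.orientation) != 3:
            raise ValueError(f"orientation must be a 3-letter code, got {self.orientation!r}")
        if any(e <= 0 for e in self.extents_um):
            raise ValueError("extents must be positive")


PIR = SpaceSpec("PIR", 1.0)
LIP = SpaceSpec("LIP", 1.0)


@dataclass
class NeuronMorphology:
    """A neuron as paired point/line arrays.

    ``points`` is an (n, 3) float array; ``structure``, ``point_index``
    and ``parent_index`` are length-n arrays forming the line records.
    ``parent_index`` is -1 for the root and otherwise refers to an
    earlier ``point_index``.
    """

    neuron_id: str
    points: np.ndarray
    structure: np.ndarray          # dtype object/str: soma|axon|dendrite
    parent_index: np.ndarray       # int, -1 for root
    source_db: str = "other"
    radius: np.ndarray | None = None
    space: SpaceSpec = field(default_factory=lambda: SpaceSpec())

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.structure = np.asarray(self.structure, dtype=object)
        self.parent_index = np.asarray(self.parent_index, dtype=int)
        n = len(self.points)
        if self.points.shape != (n, 3):
            raise MorphologyStructureError("points must be an (n, 3) array")
        if len(self.structure) != n or len(self.parent_index) != n:
            raise MorphologyStructureError("point and line arrays disagree in length")
        if not np.all(np.isfinite(self.points)):
            raise MorphologyStructureError("coordinates must be finite")
        roots = np.flatnonzero(self.parent_index == -1)
        if len(roots) != 1:
            raise MorphologyStructureError(
                f"expected exactly one root record, found {len(roots)}")
        bad = (self.parent_index >= np.arange(n)) & (self.parent_index != -1)
        if np.any(self.parent_index >= n) or np.any(bad):
            raise MorphologyStructureError(
                "parent_index must refer to an earlier-defined point")
        if SOMA not in self.structure:
            raise MorphologyStructureError("at least one soma-labeled point required")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def soma_index(self) -> int:
        return int(np.flatnonzero(self.structure == SOMA)[0])

    @property
    def soma_point(self) -> np.ndarray:
        return self.points[self.soma_index]

    def children_of(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.parent_index == i)

    def translated(self, offset) -> "NeuronMorphology":
        return replace(self, points=self.points + np.asarray(offset, float))

    def transformed(self, rotation: np.ndarray) -> "NeuronMorphology":
        return replace(self, points=self.points @ np.asarray(rotation, float).T)


# ---------------------------------------------------------------------------
# SWC

def read_swc(path, space: SpaceSpec = PIR, neuron_id: str | None = None,
             source_db: str = "other") -> NeuronMorphology:
    """Read a standard 7-column SWC file.

    Columns: sample id, structure code, x, y, z, radius, parent id.
    Structure codes 1 -> soma, 2 -> axon, 3/4 -> dendrite; any other code
    is mapped to dendrite with a warning.  Coordinates are left in the
    source space described by ``space``; conversion to canonical PIR μm
    is a separate step (:func:`to_ccf_pir`).
    """
    path = Path(path)
    ids, codes, xyz, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 7:
                raise MorphologyFormatError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(cols)}")
            try:
                ids.append(int(cols[0]))
                codes.append(int(cols[1]))
                xyz.append([float(c) for c in cols[2:5]])
                radii.append(float(cols[5]))
                parents.append(int(cols[6]))
            except ValueError as exc:
                raise MorphologyFormatError(f"{path.name}:{lineno}: {exc}") from exc
    if not ids:
        raise MorphologyFormatError(f"{path.name}: no records")

    id_to_row = {sid: row for row, sid in enumerate(ids)}
    if len(id_to_row) != len(ids):
        raise MorphologyStructureError(f"{path.name}: duplicate sample ids")
    parent_rows = np.empty(len(ids), dtype=int)
    for row, pid in enumerate(parents):
        if pid == -1:
            parent_rows[row] = -1
        elif pid in id_to_row:
            parent_rows[row] = id_to_row[pid]
        else:
            raise MorphologyStructureError(
                f"{path.name}: sample {ids[row]} references missing parent {pid}")

    unknown = sorted({c for c in codes if c not in _SWC_CODE_TO_LABEL})
    if unknown:
        warnings.warn(
            f"{path.name}: SWC structure codes {unknown} mapped to dendrite",
            stacklevel=2)
    labels = [_SWC_CODE_TO_LABEL.get(c, DENDRITE) for c in codes]
    return NeuronMorphology(
        neuron_id=neuron_id or path.stem,
        points=np.asarray(xyz, float),
        structure=np.asarray(labels, dtype=object),
        parent_index=parent_rows,
        radius=np.asarray(radii, float),
        space=space,
        source_db=source_db,
    )


def write_swc(m: NeuronMorphology, path) -> None:
    """Write a morphology as 7-column SWC (1-based contiguous sample ids)."""
    radii = m.radius if m.radius is not None else np.ones(m.n_points)
    with open(path, "w") as fh:
        fh.write(f"# id type x y z radius parent — {m.neuron_id}\n")
        for i in range(m.n_points):
            code = _LABEL_TO_SWC_CODE[m.structure[i]]
            p = m.points[i]
            parent = m.parent_index[i] + 1 if m.parent_index[i] >= 0 else -1
            fh.write(f"{i + 1} {code} {p[0]:.6g} {p[1]:.6g} {p[2]:.6g} "
                     f"{radii[i]:.6g} {parent}\n")


# ---------------------------------------------------------------------------
# portal-style JSON dialect

def read_json_morphology(path) -> NeuronMorphology:
    """Read the portal-style point/line JSON dialect.

    The dialect is an object with keys ``"id"``, ``"space"``
    (``{"orientation", "unit_um", "extents_um"}``), ``"points"`` (array of
    ``[x, y, z]``) and ``"lines"`` (array of
    ``[structure_code, point_index, parent_index]`` in SWC structure
    codes).  Space metadata is taken from the file header.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("points", "lines"):
        if key not in doc:
            raise MorphologyFormatError(f"{path.name}: missing {key!r} key")
    points = np.asarray(doc["points"], dtype=float)
    lines = doc["lines"]
    if points.ndim != 2 or points.shape[1] != 3:
        raise MorphologyFormatError(f"{path.name}: points must be an array of [x,y,z]")
    if len(lines) != len(points):
        raise MorphologyStructureError(
            f"{path.name}: {len(lines)} line records for {len(points)} points")

    n = len(points)
    order = np.empty(n, dtype=int)
    codes = np.empty(n, dtype=int)
    parents_of = np.empty(n, dtype=int)
    seen = set()
    for row, rec in enumerate(lines):
        code, pi, par = int(rec[0]), int(rec[1]), int(rec[2])
        if not (0 <= pi < n) or (par != -1 and not (0 <= par < n)):
            raise MorphologyStructureError(
                f"{path.name}: line record {row} references point index out of range")
        if pi in seen:
            raise MorphologyStructureError(f"{path.name}: duplicate point index {pi}")
        seen.add(pi)
        order[row] = pi
        codes[row] = code
        parents_of[row] = par

    # re-order records into point-array order
    perm = np.argsort(order)
    codes, parents_of, order = codes[perm], parents_of[perm], order[perm]
    labels = [_SWC_CODE_TO_LABEL.get(int(c), DENDRITE) for c in codes]

    sp = doc.get("space", {})
    space = SpaceSpec(
        orientation=sp.get("orientation", "PIR"),
        unit_um=float(sp.get("unit_um", 1.0)),
        extents_um=tuple(sp.get("extents_um", CCF_EXTENTS_UM)),
    )
    return NeuronMorphology(
        neuron_id=str(doc.get("id", path.stem)),
        points=points,
        structure=np.asarray(labels, dtype=object),
        parent_index=parents_of,
        space=space,
        source_db=str(doc.get("source_db", "other")),
    )


def write_json_morphology(m: NeuronMorphology, path) -> None:
    doc = {
        "id": m.neuron_id,
        "source_db": m.source_db,
        "space": {
            "orientation": m.space.orientation,
            "unit_um": m.space.unit_um,
            "extents_um": list(m.space.extents_um),
        },
        "points": np.round(m.points, 6).tolist(),
        "lines": [[_LABEL_TO_SWC_CODE[m.structure[i]], i, int(m.parent_index[i])]
                  for i in range(m.n_points)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# orientation normalization

def to_ccf_pir(m: NeuronMorphology, space: SpaceSpec | None = None) -> NeuronMorphology:
    """Normalize coordinates to micrometers in CCF PIR orientation.

    PIR sources are unit-rescaled only.  LIP sources (MouseLight) have
    their first and third coordinates swapped and the resulting third
    (left-right) coordinate reflected as ``extent_LR - value``.  The
    operation is idempotent on already-normalized input.
    """
    space = space or m.space
    pts = m.points * space.unit_um
    orient = space.orientation.upper()
    if orient == "PIR":
        pass
    elif orient == "LIP":
        pts = pts[:, [2, 1, 0]]
        extent_lr = space.extents_um[2]
        pts[:, 2] = extent_lr - pts[:, 2]
    else:
        raise ValueError(f"unknown orientation code {space.orientation!r}; "
                         "supported: PIR, LIP")
    return replace(m, points=pts, space=SpaceSpec("PIR", 1.0, space.extents_um))


def to_voxels(points_um: np.ndarray, voxel_size_um: float = 10.0) -> np.ndarray:
    """Micrometer PIR points -> 0-based voxel indices (floor convention)."""
    return np.floor(np.asarray(points_um, float) / voxel_size_um).astype(int)
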