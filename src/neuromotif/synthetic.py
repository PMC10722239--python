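"""Synthetic topographically organized populations with known ground truth.

The generator emulates the statistical structure of a first-order
thalamic relay projecting to somatosensory cortex:

* somata sampled uniformly inside a nucleus ellipsoid;
* a fixed affine soma-to-terminal map ``anchor = s·R*·soma + t`` whose
  rotation ``R*`` (Euler angles, degrees) is the recoverable topography
  ground truth;
* a *depth* parameter per neuron — its terminal anchor's normalized
  position along the topographic (left-right) axis of a layered
  cortical slab — which determines the primary target area, the number
  of terminals and the arbor width (all increasing monotonically with
  depth);
* a motif-order distribution (monofocal / bifurcating / trifurcating /
  quadrifurcating) with secondary targets drawn from areas adjacent in
  the topographic order, so the two extreme areas never co-occur;
* axonal trees grown as a trunk plus recursive bifurcations ending in
  terminal clusters, with interior sample points so the topological
  minor is a genuine reduction;
* optional isotropic Gaussian jitter of the terminal points.

Noiseless populations are exactly self-consistent. Every terminal of a
cluster keeps its anchor's left-right coordinate, so no terminal leaks
across an area boundary and the extracted motif equals the ground-truth
motif.  Each primary cluster carries a tight terminal knot at its
anchor that outnumbers all secondary terminals combined, plus
symmetric ± ring pairs, which pins the neuron's terminal *medoid* to
the anchor; the soma-to-medoid topography fit therefore recovers
``R*`` essentially exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .atlas import AtlasVolume, build_toy_atlas, write_atlas
from .morphology import AXON, DENDRITE, SOMA, NeuronMorphology, SpaceSpec, write_swc

#: area order along the topographic axis; the barrel field and the mouth
#: area sit at the two poles and never share a motif.
TOPOGRAPHIC_AREAS = ("SSp-bfd", "SSp-n", "SSs", "SSp-ul", "SSp-ll", "SSp-m")


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions of the synthetic population.

    ``motif_order_probs`` are the probabilities of a neuron targeting
    1, 2, 3 or 4 areas (defaults follow the broadcasting fractions
    observed in thalamocortical relay populations: 26% monofocal, 53%
    bifurcating, 17% trifurcating, 1.5% quadrifurcating, renormalized);
    ``rotation_deg`` are the extrinsic-xyz Euler angles of the
    generator's soma-to-terminal rotation; ``noise_um`` is the
    isotropic terminal jitter (σ, μm).
    """

    areas: tuple[str, ...] = TOPOGRAPHIC_AREAS
    motif_order_probs: tuple[float, ...] = (0.26, 0.53, 0.17, 0.015)
    rotation_deg: tuple[float, float, float] = (-60.0, 0.0, -120.0)
    scale: float = 1.4
    nucleus_radii_um: tuple[float, float, float] = (350.0, 320.0, 340.0)
    nucleus_distance_um: float = 2700.0
    noise_um: float = 20.0
    voxel_size_um: float = 20.0
    layer_thickness_um: tuple[float, ...] = (150, 300, 225, 300, 300, 75)
    base_width_um: float = 40.0
    width_range_um: float = 180.0
    min_ring_pairs: int = 6                 # primary ring terminals: 2 * pairs
    ring_pair_range: int = 5
    secondary_counts: tuple[int, ...] = (9, 7, 5)
    trunk_step_um: float = 150.0
    si_flatten: float = 0.35                # SI compression of terminal rings
    knot_eps_um: float = 1.5                # radius of the anchor terminal knot

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.motif_order_probs):
            raise ValueError("motif_order_probs must be nonnegative")
        if sum(self.motif_order_probs) <= 0:
            raise ValueError("motif_order_probs must not all be zero")
        if self.noise_um < 0 or self.scale <= 0:
            raise ValueError("noise_um >= 0 and scale > 0 required")


@dataclass
class SyntheticGroundTruth:
    """Manifest of the generator's choices; sufficient to predict the
    dominant target per neuron (noiseless), the motif-order distribution
    and the topography rotation without running the pipeline."""

    seed: int
    rotation_deg: tuple[float, float, float]
    motif_order_probs: tuple[float, ...]
    noise_um: float
    linear_map: list                 # 3x3 linear part, soma -> primary anchor
    translation_um: list             # 3-vector
    neurons: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticGroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        doc["rotation_deg"] = tuple(doc["rotation_deg"])
        doc["motif_order_probs"] = tuple(doc["motif_order_probs"])
        return cls(**doc)

    @property
    def depths(self) -> np.ndarray:
        return np.asarray([rec["depth"] for rec in self.neurons])

    @property
    def motifs(self) -> list[tuple[str, ...]]:
        return [tuple(rec["target_areas"]) for rec in self.neurons]


# ---------------------------------------------------------------------------
# geometry

class _Geometry:
    """Derived frame of the generator: the affine soma-to-anchor map, the
    slab and nucleus placement, and the topographic area boundaries."""

    def __init__(self, p: GeneratorParams):
        self.params = p
        self.R = Rotation.from_euler("xyz", p.rotation_deg, degrees=True).as_matrix()
        self.A = p.scale * self.R                       # linear part of the map
        radii = np.asarray(p.nucleus_radii_um, float)

        # support half-extents of the anchor ellipsoid along each PIR axis
        self.half = np.array([np.linalg.norm(radii * (self.A.T @ e))
                              for e in np.eye(3)])
        slab_depth = float(sum(p.layer_thickness_um))
        self.slab_depth = slab_depth
        ctx_si = slab_depth / 2.0
        if self.half[1] > ctx_si - 180.0:
            raise ValueError("generation error: anchors would not fit inside "
                             "the slab; reduce scale or nucleus radii")

        # direction from cortex to nucleus chosen so the trunk length is
        # (to first order) a linear function of the anchor's topographic
        # coordinate; blended toward straight-down when too horizontal.
        m = self.A.T @ np.array([0.0, 0.0, 1.0])        # LR row of A, soma frame
        AmI = self.A - np.eye(3)
        v = np.linalg.solve(AmI.T, m)
        v = v / np.linalg.norm(v)
        if v[1] > 0:
            v = -v
        min_down = 0.45
        if v[1] > -min_down:
            horiz = np.array([v[0], 0.0, v[2]])
            nh = np.linalg.norm(horiz)
            scale_h = np.sqrt(1.0 - min_down ** 2) / max(nh, 1e-12)
            v = np.array([v[0] * scale_h, -min_down, v[2] * scale_h])
        self.v_hat = v

        # design frame: cortex anchor center at AP/LR = 0, SI = mid-slab
        c_ctx = np.array([0.0, ctx_si, 0.0])
        c_nuc = c_ctx - p.nucleus_distance_um * self.v_hat
        # atlas box: contain anchors + arbors and the nucleus, with margin
        margin = 250.0
        w_max = p.base_width_um + p.width_range_um
        lo = np.minimum(c_ctx - self.half - w_max, c_nuc - radii) - margin
        hi = np.maximum(c_ctx + self.half + w_max, c_nuc + radii) + margin
        shift = np.where(lo < 0, -lo, 0.0)
        shift[1] = 0.0                                   # slab top stays at SI 0
        self.c_ctx = c_ctx + shift
        self.c_nuc = c_nuc + shift
        self.shape_um = tuple(float(h + s) for h, s in zip(hi, shift))
        self.translation = self.c_ctx - self.A @ self.c_nuc

        if self.c_nuc[1] - radii[1] < slab_depth + 100.0:
            raise ValueError("generation error: nucleus overlaps the slab; "
                             "increase nucleus_distance_um")

        # equal-width topographic partition of the anchor LR support
        n_areas = len(p.areas)
        self.lr_edges = [self.c_ctx[2] + self.half[2] * (2.0 * k / n_areas - 1.0)
                         for k in range(1, n_areas)]

    def anchor_of(self, soma: np.ndarray) -> np.ndarray:
        return self.A @ soma + self.translation

    def depth_of(self, anchor: np.ndarray) -> float:
        u = (anchor[2] - self.c_ctx[2]) / self.half[2]
        return float(np.clip((u + 1.0) / 2.0, 0.0, 1.0))

    def area_cell_center_lr(self, idx: int) -> float:
        n = len(self.params.areas)
        u = 2.0 * (idx + 0.5) / n - 1.0
        return self.c_ctx[2] + self.half[2] * u

    def build_atlas(self) -> AtlasVolume:
        p = self.params
        return build_toy_atlas(
            shape_um=self.shape_um,
            voxel_size_um=p.voxel_size_um,
            areas=p.areas,
            layer_thickness_um=p.layer_thickness_um,
            area_lr_edges_um=tuple(self.lr_edges),
            nucleus_center_um=tuple(self.c_nuc),
            nucleus_radii_um=p.nucleus_radii_um,
        )


# ---------------------------------------------------------------------------
# tree assembly

class _TreeBuilder:
    """Incrementally assembles the point/line arrays of one neuron."""

    def __init__(self, soma: np.ndarray):
        self.points = [np.asarray(soma, float)]
        self.structure = [SOMA]
        self.parents = [-1]

    def add(self, point, label: str, parent: int) -> int:
        self.points.append(np.asarray(point, float))
        self.structure.append(label)
        self.parents.append(parent)
        return len(self.points) - 1

    def add_chain(self, parent: int, target, step_um: float, label: str = AXON) -> int:
        """Interior points every ``step_um`` from the parent point to
        ``target``; returns the index of the target point."""
        start = self.points[parent]
        target = np.asarray(target, float)
        dist = np.linalg.norm(target - start)
        n_seg = max(1, int(np.ceil(dist / step_um)))
        idx = parent
        for k in range(1, n_seg + 1):
            idx = self.add(start + (target - start) * (k / n_seg), label, idx)
        return idx

    def finish(self, neuron_id: str) -> NeuronMorphology:
        return NeuronMorphology(
            neuron_id=neuron_id,
            points=np.asarray(self.points),
            structure=np.asarray(self.structure, dtype=object),
            parent_index=np.asarray(self.parents, int),
            source_db="synthetic",
            space=SpaceSpec("PIR", 1.0),
        )


def _knot_offsets(k: int, eps_um: float, si_flatten: float) -> np.ndarray:
    """A tight symmetric knot of k terminals around the anchor (the
    anchor itself plus ± pairs within ``eps_um``), LR component zero."""
    offsets = [np.zeros(3)]
    for j in range(1, (k - 1) // 2 + 1):
        theta = np.pi * j / max(1, (k - 1) // 2) * 0.9
        off = np.array([eps_um * np.cos(theta),
                        eps_um * np.sin(theta) * si_flatten, 0.0])
        offsets.extend([off, -off])
    return np.asarray(offsets[:k])


def _ring_offsets(n_pairs: int, width_um: float, si_flatten: float) -> np.ndarray:
    """Symmetric ± ring pairs in the AP-SI plane (LR component exactly
    zero, so a cluster never leaks across an area boundary without
    noise)."""
    offsets = []
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for j in range(1, n_pairs + 1):
        rho = width_um * (0.4 + 0.6 * j / n_pairs)
        theta = golden * j
        off = np.array([rho * np.cos(theta),
                        rho * np.sin(theta) * si_flatten, 0.0])
        offsets.extend([off, -off])
    return np.asarray(offsets).reshape(-1, 3)


def _grow_cluster(tb: _TreeBuilder, attach: int, hub: np.ndarray,
                  terminals: np.ndarray, step_um: float) -> None:
    """Trunk to the hub, then recursive binary splits down to terminals."""
    hub_idx = tb.add_chain(attach, hub, step_um)

    def split(node_idx: int, node_pt: np.ndarray, terms: np.ndarray) -> None:
        if len(terms) == 1:
            tb.add_chain(node_idx, terms[0], max(20.0, step_um / 4.0))
            return
        order = np.argsort(terms[:, 0] + 1e-6 * terms[:, 1], kind="stable")
        halves = (terms[order[:len(terms) // 2]], terms[order[len(terms) // 2:]])
        for half in halves:
            child_pt = node_pt + 0.55 * (half.mean(axis=0) - node_pt)
            if np.linalg.norm(child_pt - node_pt) < 1.0:
                child_pt = node_pt + np.array([1.5, 0.0, 0.0])
            child_idx = tb.add(child_pt, AXON, node_idx)
            split(child_idx, child_pt, half)

    split(hub_idx, np.asarray(tb.points[hub_idx]), terminals)


# ---------------------------------------------------------------------------
# population generation

def generate_population(n: int, params: GeneratorParams | None = None,
                        seed: int = 0, out_dir=None
                        ) -> tuple[list[NeuronMorphology], AtlasVolume,
                                   SyntheticGroundTruth]:
    """Generate ``n`` neurons, their toy atlas and the ground-truth manifest.

    Fully reproducible: the same ``(n, params, seed)`` produce identical
    morphologies, atlas and manifest.  With ``out_dir`` set, SWC files,
    the NIfTI atlas (+ JSON label map) and ``ground_truth.json`` are
    written there.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = params or GeneratorParams()
    geo = _Geometry(p)
    atlas = geo.build_atlas()
    rng = np.random.default_rng(seed)

    probs = np.asarray(p.motif_order_probs, float)
    probs = probs / probs.sum()
    radii = np.asarray(p.nucleus_radii_um, float)
    n_areas = len(p.areas)

    truth = SyntheticGroundTruth(
        seed=seed,
        rotation_deg=tuple(p.rotation_deg),
        motif_order_probs=tuple(np.round(probs, 6)),
        noise_um=p.noise_um,
        linear_map=np.round(geo.A, 9).tolist(),
        translation_um=np.round(geo.translation, 6).tolist(),
    )
    neurons: list[NeuronMorphology] = []

    # terminal anchors keep a guard band off the topographic area
    # boundaries (discrete module-center targeting, like barreloid axons
    # aiming at barrel centers): soma samples whose anchor would fall
    # inside the band are rejected and redrawn
    guard_um = max(3.0 * p.noise_um, 2.0 * p.voxel_size_um)

    for i in range(n):
        # soma uniform in the nucleus ellipsoid, conditioned on the guard
        for _attempt in range(500):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            soma = geo.c_nuc + radii * direction * rng.uniform() ** (1.0 / 3.0)
            anchor = geo.anchor_of(soma)
            if all(abs(anchor[2] - e) >= guard_um for e in geo.lr_edges):
                break
        else:
            raise ValueError("generation error: could not place an anchor "
                             "outside the boundary guard band")
        depth = geo.depth_of(anchor)
        primary_area = atlas.label_at(anchor)[0]
        primary_idx = p.areas.index(primary_area) if primary_area in p.areas \
            else int(np.clip(np.floor(depth * n_areas), 0, n_areas - 1))

        order = 1 + int(rng.choice(len(probs), p=probs))
        # secondary areas adjacent along the topographic axis, random side
        sign = 1 if rng.uniform() < 0.5 else -1
        candidates: list[int] = []
        for k in (1, 1, 2, 2, 3, 3):
            cand = primary_idx + sign * k
            sign = -sign
            if 0 <= cand < n_areas and cand not in candidates:
                candidates.append(cand)
        secondary_idx = candidates[:order - 1]
        sec_counts = list(p.secondary_counts[:len(secondary_idx)])

        width = p.base_width_um + p.width_range_um * depth
        n_pairs = p.min_ring_pairs + int(round(p.ring_pair_range * depth))
        # the anchor knot outnumbers all secondary terminals combined so
        # the neuron's terminal medoid is pinned to the primary anchor
        knot = max(3, sum(sec_counts) + 2)
        n_primary = knot + 2 * n_pairs

        tb = _TreeBuilder(soma)
        d0 = tb.add(soma + np.array([30.0, 20.0, 0.0]), DENDRITE, 0)
        tb.add(soma + np.array([55.0, 45.0, 10.0]), DENDRITE, d0)

        # main stem toward the primary hub, with a low bifurcation point
        # from which the collaterals to secondary areas depart
        hub_p = anchor + np.array([0.0, 90.0, 0.0])
        stem_break = soma + 0.75 * (hub_p - soma)
        break_idx = tb.add_chain(0, stem_break, p.trunk_step_um)

        term_sets = []
        for rank, (area_idx, n_t) in enumerate(
                zip([primary_idx, *secondary_idx], [n_primary, *sec_counts])):
            if rank == 0:
                cluster_anchor = anchor
                offs = np.vstack([
                    _knot_offsets(knot, p.knot_eps_um, p.si_flatten),
                    _ring_offsets(n_pairs, width, p.si_flatten),
                ])
                hub = hub_p
            else:
                cluster_anchor = anchor.copy()
                cluster_anchor[2] = geo.area_cell_center_lr(area_idx)
                offs = np.vstack([
                    np.zeros((1, 3)),
                    _ring_offsets((n_t - 1) // 2, 0.5 * width, p.si_flatten),
                ])
                hub = cluster_anchor + np.array([0.0, 90.0, 0.0])
            terms = cluster_anchor + offs
            if p.noise_um > 0:
                terms = terms + rng.normal(0.0, p.noise_um, size=terms.shape)
            _grow_cluster(tb, break_idx, hub, terms, p.trunk_step_um)
            term_sets.append((p.areas[area_idx] if 0 <= area_idx < n_areas
                              else "other", len(terms)))

        nid = f"syn-{seed}-{i:04d}"
        neurons.append(tb.finish(nid))
        truth.neurons.append({
            "neuron_id": nid,
            "soma_um": np.round(soma, 6).tolist(),
            "depth": round(float(depth), 9),
            "target_areas": [a for a, _c in term_sets],
            "terminal_counts": [c for _a, c in term_sets],
            "primary_anchor_um": np.round(anchor, 6).tolist(),
            "width_um": round(float(width), 6),
            "n_ring_pairs": int(n_pairs),
        })

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for m in neurons:
            write_swc(m, out / f"{m.neuron_id}.swc")
        write_atlas(atlas, out / "atlas.nii.gz")
        truth.to_json(out / "ground_truth.json")

    return neurons, atlas, truth


def monotone_morphology_params(**overrides) -> GeneratorParams:
    """Study conditions for gradient-recovery experiments: a purely
    monofocal population, so that trunk length, arbor width and terminal
    count — the features the pairwise registration error sees — form a
    monotone program of the depth parameter alone, without the
    depth-independent variability that random multi-area motifs add."""
    return GeneratorParams(motif_order_probs=(1.0, 0.0, 0.0, 0.0), **overrides)


# ---------------------------------------------------------------------------
# registration fixtures

def make_fixture_pair(kind: str, params: GeneratorParams | None = None,
                      seed: int = 0, angle_deg: float = 25.0,
                      axis: str = "si", sigma_um: float = 5.0
                      ) -> tuple[NeuronMorphology, NeuronMorphology]:
    """A pair of morphologies related by a named transform.

    ``kind``: ``identical`` (copy), ``rotated`` (second neuron rotated by
    ``angle_deg`` about the soma around the given PIR axis) or ``noisy``
    (every point displaced by isotropic Gaussian noise ``sigma_um``).
    """
    p = params or GeneratorParams()
    # a single monofocal neuron is the simplest registration subject
    base = generate_population(
        1, replace(p, noise_um=0.0, motif_order_probs=(1.0, 0.0, 0.0, 0.0)),
        seed=seed)[0][0]
    if kind == "identical":
        import copy
        return base, copy.deepcopy(base)
    if kind == "rotated":
        axis_name = {"ap": "x", "si": "y", "lr": "z"}[axis]
        R = Rotation.from_euler(axis_name, angle_deg, degrees=True).as_matrix()
        pts = (base.points - base.soma_point) @ R.T + base.soma_point
        return base, replace(base, points=pts,
                             neuron_id=base.neuron_id + "-rot")
    if kind == "noisy":
        rng = np.random.default_rng(seed + 1)
        pts = base.points + rng.normal(0.0, sigma_um, size=base.points.shape)
        return base, replace(base, points=pts,
                             neuron_id=base.neuron_id + "-noisy")
    raise ValueError(f"unknown fixture kind {kind!r}")
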