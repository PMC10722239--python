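"""End-to-end orchestration: ingest -> minor -> profiles -> motifs ->
dissimilarity -> embedding -> topography -> occupancy maps and plots.

The pipeline is configured by a single mapping (typically loaded from a
YAML file) and writes every stage's outputs plus a run log to one
output directory.  Re-running with the same inputs, configuration and
seeds reproduces all numeric outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import synthetic
from .atlas import CANONICAL_AREAS, AtlasVolume, read_atlas
from .cpd import CPDConfig, dissimilarity_matrix
from .embedding import (cluster_types, embed_tsne, fit_soma_to_gradient,
                        gradient_index, motifs_along_gradient, select_root)
from .morphology import NeuronMorphology, SpaceSpec, read_json_morphology, \
    read_swc, to_ccf_pir
from .projections import (classify_focality, layer_distribution, motif_census,
                          motif_significance, profiles_table, projection_profile)
from .topography import fit_topography, terminal_medoid
from .tree import extract_topological_minor, morphometric_table

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Invalid or incomplete pipeline configuration."""


DEFAULT_CONFIG = {
    "areas": list(CANONICAL_AREAS),
    "motif_min_terminals": 5,
    "focality_min_terminals": 4,
    "focality_min_border_um": 200.0,
    "cpd": {"max_iter": 60, "tol": 1e-3, "w": 0.0, "max_points": 400, "seed": 0},
    "tsne": {"perplexity": 30.0, "seed": 0},
    "gradient_knn": 10,
    "n_morph_types": 3,
    "euler_convention": "xyz",
    "topography_unit_um": 10.0,
    "occupancy_voxel_um": 10.0,
}


# ---------------------------------------------------------------------------
# occupancy maps

@dataclass
class OccupancyMap:
    """Sparse per-type soma (source) and terminal (target) voxel sets.

    The dense equivalent is a pair of binary 4-D arrays (three atlas
    axes plus a type axis); at 10 μm those are ~10⁹ voxels per type, so
    voxels are stored sparsely and densified only on demand.
    """

    voxel_size_um: float
    grid_dims: tuple[int, int, int]
    source_voxels: dict[int, np.ndarray] = field(default_factory=dict)
    target_voxels: dict[int, np.ndarray] = field(default_factory=dict)
    type_palette: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    n_dropped: int = 0

    def to_dense(self, which: str = "target") -> np.ndarray:
        """Binary 4-D array (x, y, z, type); keep the grid coarse."""
        table = self.target_voxels if which == "target" else self.source_voxels
        types = sorted(table)
        out = np.zeros((*self.grid_dims, len(types)), dtype=bool)
        for ti, t in enumerate(types):
            v = table[t]
            if len(v):
                out[v[:, 0], v[:, 1], v[:, 2], ti] = True
        return out


_PALETTE = [(0.89, 0.10, 0.11), (0.22, 0.49, 0.72), (0.30, 0.69, 0.29),
            (1.00, 0.50, 0.00), (0.60, 0.31, 0.64), (0.65, 0.34, 0.16)]


def build_occupancy(neurons: list[NeuronMorphology], minors,
                    type_labels: dict[str, int],
                    voxel_size_um: float = 10.0,
                    grid_dims: tuple[int, int, int] = (1320, 800, 1140)
                    ) -> OccupancyMap:
    """Sparse occupancy of soma (source) and terminal (target) voxels per
    neuronal type; out-of-grid points are dropped and counted."""
    missing = [m.neuron_id for m in neurons if m.neuron_id not in type_labels]
    if missing:
        raise ConfigurationError(f"untyped neurons: {missing[:5]}")
    src: dict[int, list] = {}
    tgt: dict[int, list] = {}
    dropped = 0
    dims = np.asarray(grid_dims)
    for m, t in zip(neurons, minors):
        ty = type_labels[m.neuron_id]
        sv = np.floor(m.soma_point / voxel_size_um).astype(int)
        if np.all((sv >= 0) & (sv < dims)):
            src.setdefault(ty, []).append(sv)
        else:
            dropped += 1
        tv = np.floor(t.terminal_points / voxel_size_um).astype(int)
        ok = np.all((tv >= 0) & (tv < dims), axis=1)
        dropped += int((~ok).sum())
        tgt.setdefault(ty, []).extend(tv[ok])
    if dropped:
        log.warning("occupancy: dropped %d out-of-grid points", dropped)

    def _dedup(rows):
        return np.unique(np.asarray(rows, int).reshape(-1, 3), axis=0)

    types = sorted(set(src) | set(tgt))
    return OccupancyMap(
        voxel_size_um=voxel_size_um,
        grid_dims=tuple(int(d) for d in grid_dims),
        source_voxels={t: _dedup(src.get(t, np.empty((0, 3)))) for t in types},
        target_voxels={t: _dedup(tgt.get(t, np.empty((0, 3)))) for t in types},
        type_palette={t: _PALETTE[i % len(_PALETTE)] for i, t in enumerate(types)},
        n_dropped=dropped,
    )


#: plane name -> projection axis in PIR (coronal: along AP, sagittal: along
#: LR, horizontal: along SI)
_PLANES = {"coronal": 0, "sagittal": 2, "horizontal": 1}


def max_projection_arrays(omap: OccupancyMap, which: str = "source"
                          ) -> dict[str, np.ndarray]:
    """Per-plane RGB maximum-projection images of the type-colored voxels."""
    table = omap.source_voxels if which == "source" else omap.target_voxels
    out = {}
    for plane, axis in _PLANES.items():
        keep = [k for k in range(3) if k != axis]
        h, w = omap.grid_dims[keep[0]], omap.grid_dims[keep[1]]
        img = np.zeros((h, w, 3))
        for t, vox in table.items():
            if len(vox) == 0:
                continue
            color = omap.type_palette.get(t, (1.0, 1.0, 1.0))
            img[vox[:, keep[0]], vox[:, keep[1]], :] = color
        out[plane] = img
    return out


def max_projection_plots(omap: OccupancyMap, out_dir,
                         background: np.ndarray | None = None,
                         which: str = "source") -> list[Path]:
    """Write the coronal/sagittal/horizontal maximum-projection images."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    arrays = max_projection_arrays(omap, which)
    for plane, img in arrays.items():
        fig, ax = plt.subplots(figsize=(5, 5))
        if background is not None:
            axis = _PLANES[plane]
            ax.imshow(background.max(axis=axis), cmap="gray", alpha=0.6)
        ax.imshow(np.clip(img, 0, 1))
        ax.set_title(f"{plane} maximum projection ({which})")
        ax.axis("off")
        p = out_dir / f"max_projection_{which}_{plane}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# ingest helpers

def morphology_paths(directory) -> list[Path]:
    """SWC/JSON morphology files under a directory, skipping sidecar
    files (atlas label maps, ground-truth manifests)."""
    skip = {"ground_truth.json"}
    return sorted(
        p for p in Path(directory).iterdir()
        if p.suffix.lower() in (".swc", ".json")
        and p.name not in skip and not p.name.endswith(".labels.json"))


def load_morphologies(paths, space: SpaceSpec | None = None
                      ) -> list[NeuronMorphology]:
    """Read SWC / JSON morphologies and normalize them to PIR μm."""
    out = []
    for p in map(Path, paths):
        if p.suffix.lower() == ".swc":
            m = read_swc(p, space=space or SpaceSpec("PIR", 1.0))
        elif p.suffix.lower() == ".json":
            m = read_json_morphology(p)
        else:
            raise ConfigurationError(f"unknown morphology format: {p}")
        out.append(to_ccf_pir(m))
    return out


def _merge_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


# ---------------------------------------------------------------------------
# the pipeline

def run_pipeline(config: dict, out_dir) -> dict:
    """Execute all stages and write their outputs under ``out_dir``.

    ``config`` extends :data:`DEFAULT_CONFIG`; it must reference input
    morphologies and an atlas, either as files (``morphology_dir``,
    ``atlas``) or via ``synthetic: {n, seed, ...}`` which generates a
    population in memory.  Returns a summary dict (also written as
    ``summary.json``).
    """
    cfg = _merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)
    timings: dict[str, float] = {}
    summary: dict = {"config": cfg}

    def stage(name):
        log.info("stage: %s", name)
        timings[name] = time.time()
        return time.time()

    # -- ingest ------------------------------------------------------------
    stage("ingest")
    if "synthetic" in cfg:
        syn_cfg = dict(cfg["synthetic"])
        n = int(syn_cfg.pop("n", 60))
        seed = int(syn_cfg.pop("seed", 0))
        params = synthetic.GeneratorParams(**syn_cfg)
        neurons, atlas, truth = synthetic.generate_population(n, params, seed=seed)
        truth.to_json(out / "ground_truth.json")
        cfg["areas"] = list(params.areas)
    else:
        if "morphology_dir" not in cfg or "atlas" not in cfg:
            raise ConfigurationError(
                "config needs either 'synthetic' or 'morphology_dir' + 'atlas'")
        atlas_path = Path(cfg["atlas"])
        if not atlas_path.exists():
            raise ConfigurationError(f"atlas not found: {atlas_path}")
        mdir = Path(cfg["morphology_dir"])
        paths = morphology_paths(mdir)
        if not paths:
            raise ConfigurationError(f"no morphologies under {mdir}")
        space = SpaceSpec(**cfg["space"]) if "space" in cfg else None
        neurons = load_morphologies(paths, space)
        atlas = read_atlas(atlas_path)
    areas = tuple(cfg["areas"])
    summary["n_neurons"] = len(neurons)

    # -- topological minors ------------------------------------------------
    stage("minor")
    minors, quarantined = [], []
    kept_neurons = []
    for m in neurons:
        try:
            minors.append(extract_topological_minor(m))
            kept_neurons.append(m)
        except Exception as exc:                         # noqa: BLE001
            quarantined.append({"neuron_id": m.neuron_id, "error": str(exc)})
            log.warning("quarantined %s: %s", m.neuron_id, exc)
    neurons = kept_neurons
    summary["n_quarantined"] = len(quarantined)
    morpho = morphometric_table(minors)
    morpho.to_csv(out / "morphometrics.tsv", sep="\t")

    # -- projection profiles and motifs -------------------------------------
    stage("profile")
    profiles = []
    for t in minors:
        prof = projection_profile(t, atlas, areas)
        prof.focality = classify_focality(
            t, atlas, prof.motif,
            min_terminals=int(cfg["focality_min_terminals"]),
            min_border_um=float(cfg["focality_min_border_um"]))
        profiles.append(prof)
    profiles_table(profiles, areas).to_csv(out / "profiles.tsv", sep="\t")

    stage("motifs")
    census = motif_census(profiles)
    census.to_csv(out / "motif_census.tsv", sep="\t")
    if len(census) and len(profiles):
        signif = motif_significance(census, profiles)
        signif.to_csv(out / "motif_significance.tsv", sep="\t")
    layer_len, preferred = layer_distribution(profiles, areas)
    layer_len.to_csv(out / "layer_lengths.tsv", sep="\t")
    preferred.to_csv(out / "preferred_layers.tsv", sep="\t", index=False)

    # -- CPD dissimilarity ---------------------------------------------------
    stage("cpd")
    cpd_cfg = CPDConfig(**{k: v for k, v in cfg["cpd"].items()})
    D = dissimilarity_matrix(minors, cpd_cfg)
    D.to_frame().to_csv(out / "dissimilarity.tsv", sep="\t")
    np.save(out / "dissimilarity.npy", D.values)

    # -- embedding, gradient, morphotypes -----------------------------------
    stage("embed")
    perplexity = min(float(cfg["tsne"]["perplexity"]), (len(minors) - 1) / 2)
    emb = embed_tsne(D, perplexity=perplexity, seed=int(cfg["tsne"]["seed"]))
    soma_si = np.array([m.soma_point[1] for m in neurons])
    root_id = select_root(emb.coords, D.neuron_ids,
                          [p.dominant_target for p in profiles], soma_si,
                          root_area=areas[0])
    gi, knn_k = gradient_index(emb.coords, D.neuron_ids.index(root_id),
                               k=int(cfg["gradient_knn"]))
    emb.root_id, emb.gradient_index, emb.knn_k = root_id, gi, knn_k
    emb.morph_type = cluster_types(emb.coords, gi, k=int(cfg["n_morph_types"]))
    emb_df = emb.to_frame()
    emb_df["dominant_target"] = [p.dominant_target for p in profiles]
    emb_df.to_csv(out / "embedding.csv")
    motifs_along_gradient([p.motif for p in profiles], gi) \
        .to_csv(out / "motifs_along_gradient.tsv", sep="\t")
    grad_corr = {
        name: dict(zip(("spearman_r", "p_value"),
                       _safe_corr(gi, morpho[name].to_numpy())))
        for name in ("n_branch_points", "mean_branch_width",
                     "mean_radial_distance")
    }
    summary["gradient_correlations"] = grad_corr
    coef, soma_mse = fit_soma_to_gradient(
        np.column_stack([soma_si, [m.soma_point[2] for m in neurons]]), gi)
    summary["soma_gradient_fit_mse"] = soma_mse

    # -- topography ----------------------------------------------------------
    stage("topography")
    medoids = np.array([terminal_medoid(t.terminal_points) for t in minors])
    somata = np.array([m.soma_point for m in neurons])
    fit = fit_topography(somata, medoids,
                         unit_um=float(cfg["topography_unit_um"]),
                         convention=cfg["euler_convention"])
    topo = {
        "linear": fit.linear.tolist(),
        "translation": fit.translation.tolist(),
        "rotation": fit.rotation.tolist(),
        "euler_deg": fit.euler_deg.tolist(),
        "convention": fit.convention,
        "mse": fit.mse,
        "unit_um": fit.unit_um,
    }
    with open(out / "topography.json", "w") as f:
        json.dump(topo, f, indent=1)
    summary["topography_euler_deg"] = topo["euler_deg"]
    summary["topography_mse"] = fit.mse

    # -- occupancy + plots ---------------------------------------------------
    stage("occupancy")
    vox = float(cfg["occupancy_voxel_um"])
    grid = tuple(int(np.ceil(e / vox)) for e in atlas.extents_um)
    types = {m.neuron_id: int(t) for m, t in zip(neurons, emb.morph_type)}
    omap = build_occupancy(neurons, minors, types, voxel_size_um=vox,
                           grid_dims=grid)
    with open(out / "occupancy.json", "w") as f:
        json.dump({
            "voxel_size_um": vox, "grid_dims": omap.grid_dims,
            "n_dropped": omap.n_dropped,
            "source_voxels": {str(t): v.tolist() for t, v in
                              omap.source_voxels.items()},
            "target_voxels": {str(t): v.tolist() for t, v in
                              omap.target_voxels.items()},
        }, f)
    stage("plot")
    max_projection_plots(omap, out, which="source")
    max_projection_plots(omap, out, which="target")

    marks = list(timings.items()) + [("end", time.time())]
    summary["timings_s"] = {name: round(marks[i + 1][1] - start, 3)
                            for i, (name, start) in enumerate(marks[:-1])}
    if quarantined:
        summary["quarantined"] = quarantined
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=1, default=str)
    logging.getLogger().removeHandler(fh)
    return summary


def _safe_corr(gi, values):
    from .embedding import correlate_gradient
    try:
        return correlate_gradient(gi, values)
    except ValueError:
        return float("nan"), float("nan")
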