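"""Projection profiles, dominant targets, motifs and their statistics.

The projection of a neuron to a cortical area is measured as the total
path length of the axonal terminal branches that terminate inside that
area.  A *motif* is the list of areas receiving at least a threshold
number of terminal branches, ordered by descending terminal count; the
motif order class (monofocal, bifurcating, ...) counts the areas in the
motif.  Multifocal neurons are further split into *center* and *border*
groups by how far their secondary-area terminals lie from the dominant
area.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .atlas import CANONICAL_AREAS, AtlasVolume
from .tree import TopologicalMinor

OTHER = "other"

ORDER_CLASSES = ("subthreshold", "monofocal", "bifurcating", "trifurcating",
                 "quadrifurcating", "higher")

#: default motif threshold: areas need >= 5 terminal branches
MOTIF_MIN_TERMINALS = 5
#: default focality rule: >= 4 secondary terminals > 200 μm from the border
FOCALITY_MIN_TERMINALS = 4
FOCALITY_MIN_BORDER_UM = 200.0


@dataclass
class ProjectionProfile:
    """Per-area and per-layer terminal-branch statistics for one neuron."""

    neuron_id: str
    area_length_um: dict[str, float] = field(default_factory=dict)
    area_layer_length_um: dict[tuple[str, str | None], float] = field(default_factory=dict)
    area_terminal_count: dict[str, int] = field(default_factory=dict)
    dominant_target: str | None = None
    dominant_tie: bool = False
    motif: tuple[str, ...] = ()
    order_class: str = "subthreshold"
    focality: str = "not_applicable"

    @property
    def total_length_um(self) -> float:
        return float(sum(self.area_length_um.values()))


def projection_profile(t: TopologicalMinor, a: AtlasVolume,
                       areas: tuple[str, ...] = CANONICAL_AREAS) -> ProjectionProfile:
    """Accrue each terminal branch's full path length to the area (and
    layer) containing its terminal point; branches terminating outside the
    configured areas tally under ``"other"``.
    """
    if not areas:
        raise ValueError("areas must be nonempty")
    prof = ProjectionProfile(neuron_id=t.neuron_id)
    labels = a.labels_at(t.terminal_points)
    lengths = t.path_lengths
    area_set = set(areas)
    for (area, layer), length in zip(labels, lengths):
        if area not in area_set:
            area, layer = OTHER, None
        prof.area_length_um[area] = prof.area_length_um.get(area, 0.0) + float(length)
        key = (area, layer)
        prof.area_layer_length_um[key] = prof.area_layer_length_um.get(key, 0.0) + float(length)
        prof.area_terminal_count[area] = prof.area_terminal_count.get(area, 0) + 1
    prof.dominant_target, prof.dominant_tie = dominant_target(
        prof, areas=areas, return_tie=True)
    prof.motif = tuple(extract_motif(prof, areas=areas))
    prof.order_class = classify_order(prof.motif)
    return prof


def dominant_target(p: ProjectionProfile, areas: tuple[str, ...] = CANONICAL_AREAS,
                    return_tie: bool = False):
    """Area receiving the greatest terminal-branch length.

    Ties are broken by the canonical area order and flagged.  Returns
    None when no configured area receives any length.
    """
    lengths = {a: p.area_length_um.get(a, 0.0) for a in areas}
    best = max(lengths.values(), default=0.0)
    if best <= 0.0:
        return (None, False) if return_tie else None
    winners = [a for a in areas if lengths[a] == best]
    return (winners[0], len(winners) > 1) if return_tie else winners[0]


def extract_motif(p: ProjectionProfile, min_terminal_branches: int = MOTIF_MIN_TERMINALS,
                  areas: tuple[str, ...] = CANONICAL_AREAS) -> list[str]:
    """Areas with >= ``min_terminal_branches`` terminal branches, ordered by
    descending terminal count (canonical area order breaks count ties)."""
    if min_terminal_branches < 1:
        raise ValueError("threshold must be >= 1")
    hits = [(a, p.area_terminal_count.get(a, 0)) for a in areas
            if p.area_terminal_count.get(a, 0) >= min_terminal_branches]
    hits.sort(key=lambda kv: -kv[1])  # stable: canonical order on ties
    return [a for a, _ in hits]


def classify_order(motif) -> str:
    """Motif size -> order class (0..4 areas, then 'higher')."""
    return ORDER_CLASSES[min(len(motif), 5)]


def classify_focality(t: TopologicalMinor, a: AtlasVolume, motif,
                      min_terminals: int = FOCALITY_MIN_TERMINALS,
                      min_border_um: float = FOCALITY_MIN_BORDER_UM) -> str:
    """Center/border classification of a multifocal neuron.

    *center*: at least ``min_terminals`` terminal points inside the
    secondary (second-ranked) motif area lie more than ``min_border_um``
    from the nearest voxel of the dominant area; otherwise *border*.
    Motifs with fewer than two areas are *not_applicable*.
    """
    motif = list(motif)
    if len(motif) < 2:
        return "not_applicable"
    dominant, secondary = motif[0], motif[1]
    terms = t.terminal_points
    labels = a.labels_at(terms)
    n_center = 0
    for (area, _layer), p in zip(labels, terms):
        if area == secondary and a.border_distance(p, dominant) > min_border_um:
            n_center += 1
    return "center" if n_center >= min_terminals else "border"


# ---------------------------------------------------------------------------
# population-level tables

def motif_census(profiles: list[ProjectionProfile]) -> pd.DataFrame:
    """Counts and fractions per unique motif (order-sensitive key).

    Returns a DataFrame indexed by the motif string (areas joined with
    " - "), sorted by descending neuron count, with columns ``motif``
    (tuple), ``n_neurons``, ``fraction``, ``order_class`` and
    ``dominant_target``.
    """
    if not profiles:
        return pd.DataFrame(columns=["motif", "n_neurons", "fraction",
                                     "order_class", "dominant_target"])
    counts = Counter(p.motif for p in profiles)
    total = len(profiles)
    rows = []
    for motif, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        rows.append({
            "motif": motif,
            "n_neurons": n,
            "fraction": n / total,
            "order_class": classify_order(motif),
            "dominant_target": motif[0] if motif else None,
        })
    df = pd.DataFrame(rows)
    df.index = [" - ".join(m) if m else "(subthreshold)" for m in df["motif"]]
    return df


def order_class_fractions(profiles: list[ProjectionProfile]) -> dict[str, float]:
    """Fraction of neurons per motif order class."""
    n = len(profiles)
    counts = Counter(p.order_class for p in profiles)
    return {cls: counts.get(cls, 0) / n for cls in ORDER_CLASSES} if n else {}


def motif_significance(census: pd.DataFrame, profiles: list[ProjectionProfile],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Exact binomial test of multi-area motifs against area-independence.

    For each motif with >= 2 areas, the null joint probability is the
    product of the marginal per-area targeting probabilities (the
    fraction of neurons whose motif contains the area); the observed
    motif count is tested two-sided against Binomial(n, Π p_area) and
    Bonferroni-corrected over the number of motifs tested.
    """
    n = len(profiles)
    if n < 1:
        raise ValueError("need at least one profile")
    area_hits: Counter = Counter()
    for p in profiles:
        for a in set(p.motif):
            area_hits[a] += 1
    multi = census[census["motif"].map(len) >= 2]
    m = len(multi)
    rows = []
    for key, row in multi.iterrows():
        p_null = float(np.prod([area_hits[a] / n for a in row["motif"]]))
        p_null = min(max(p_null, 0.0), 1.0)
        pval = binomtest(int(row["n_neurons"]), n, p_null,
                         alternative="two-sided").pvalue
        p_corr = min(1.0, pval * m)
        rows.append({"motif": row["motif"], "n_neurons": row["n_neurons"],
                     "p_null": p_null, "p_value": pval,
                     "p_bonferroni": p_corr, "significant": p_corr < alpha})
    return pd.DataFrame(rows, index=multi.index)


def layer_distribution(profiles: list[ProjectionProfile],
                       areas: tuple[str, ...] = CANONICAL_AREAS):
    """Per-area layer histograms and per-neuron preferred layers.

    Returns ``(layer_length, preferred)``: ``layer_length`` sums terminal
    length (μm) per (area, layer) over neurons; ``preferred`` has one row
    per neuron with the argmax layer of its first and second
    most-targeted areas.
    """
    sums: dict[tuple[str, str], float] = {}
    pref_rows = []
    for p in profiles:
        for (area, layer), length in p.area_layer_length_um.items():
            if area in areas and layer is not None:
                sums[(area, layer)] = sums.get((area, layer), 0.0) + length
        ranked = sorted((a for a in areas if p.area_length_um.get(a, 0) > 0),
                        key=lambda a: -p.area_length_um[a])
        rec = {"neuron_id": p.neuron_id, "primary_area": None, "primary_layer": None,
               "secondary_area": None, "secondary_layer": None}
        for rank, name in zip(range(2), ("primary", "secondary")):
            if rank < len(ranked):
                area = ranked[rank]
                by_layer = {lay: ln for (ar, lay), ln in p.area_layer_length_um.items()
                            if ar == area and lay is not None}
                if by_layer:
                    rec[f"{name}_area"] = area
                    rec[f"{name}_layer"] = max(by_layer, key=by_layer.get)
        pref_rows.append(rec)
    layer_length = pd.Series(sums, name="length_um").rename_axis(["area", "layer"])
    return layer_length, pd.DataFrame(pref_rows)


# ---------------------------------------------------------------------------
# barrel-level census (same machinery, barrel labels in the atlas)

def barrel_census(profiles_barrel: list[ProjectionProfile],
                  profiles_area: list[ProjectionProfile],
                  barrel_prefix: str = "barrel:",
                  min_terminals: int = 4) -> dict[str, int]:
    """Partition neurons by barrel targeting given a barrel-labeled atlas.

    ``profiles_barrel`` are profiles computed against barrel labels
    (acronyms starting with ``barrel_prefix``) alongside the area labels;
    a barrel/area counts as targeted with >= ``min_terminals`` terminal
    branches.  Neurons split into monofocal (one cortical area) vs
    multifocal, crossed with single- vs multi-barrel; the four groups
    partition the barrel-targeting neurons.
    """
    out = {"monofocal_single_barrel": 0, "monofocal_multi_barrel": 0,
           "multifocal_single_barrel": 0, "multifocal_multi_barrel": 0}
    for pb, pa in zip(profiles_barrel, profiles_area):
        barrels = [a for a, c in pb.area_terminal_count.items()
                   if a.startswith(barrel_prefix) and c >= min_terminals]
        if not barrels:
            continue
        multi_b = len(barrels) > 1
        multi_f = len(pa.motif) > 1
        key = (("multifocal" if multi_f else "monofocal") + "_" +
               ("multi" if multi_b else "single") + "_barrel")
        out[key] += 1
    return out


def profiles_table(profiles: list[ProjectionProfile],
                   areas: tuple[str, ...] = CANONICAL_AREAS) -> pd.DataFrame:
    """One row per neuron: per-area lengths, dominant target, motif, class."""
    rows = []
    for p in profiles:
        row = {"neuron_id": p.neuron_id}
        for a in areas:
            row[f"len_{a}"] = p.area_length_um.get(a, 0.0)
        row["len_other"] = p.area_length_um.get(OTHER, 0.0)
        row["dominant_target"] = p.dominant_target
        row["motif"] = " - ".join(p.motif)
        row["order_class"] = p.order_class
        row["focality"] = p.focality
        rows.append(row)
    return pd.DataFrame(rows).set_index("neuron_id")
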