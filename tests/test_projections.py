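import numpy as np
import pytest
from scipy.stats import binomtest

from neuromotif.atlas import AtlasVolume
from neuromotif.projections import (ProjectionProfile, classify_focality,
                                    classify_order, dominant_target,
                                    extract_motif, layer_distribution,
                                    motif_census, motif_significance,
                                    order_class_fractions, projection_profile)
from neuromotif.tree import TopologicalMinor


def star_minor(soma, terminal_points, neuron_id="star"):
    """Minor with one straight terminal branch per terminal point."""
    soma = np.asarray(soma, float)
    branches = [np.vstack([soma, np.asarray(t, float)])
                for t in terminal_points]
    return TopologicalMinor(neuron_id=neuron_id, soma_point=soma,
                            branch_nodes=np.empty((0, 3)),
                            terminal_branches=branches,
                            n_points_full=1 + len(branches))


@pytest.fixture
def two_area_atlas():
    """SSp-bfd (L4) at LR < 1,000 μm, SSs (L4) beyond, 10 μm voxels."""
    labels = np.zeros((50, 50, 300), dtype=np.int32)
    labels[:, :, :100] = 1
    labels[:, :, 100:200] = 2
    return AtlasVolume(labels, 10.0,
                       {1: ("SSp-bfd", "L4"), 2: ("SSs", "L4")})


def test_profile_hand_sum(two_area_atlas):
    soma = [250, 250, 500]
    t = star_minor(soma, [[250, 250, 380], [250, 250, 620]])
    prof = projection_profile(t, two_area_atlas, ("SSp-bfd", "SSs"))
    assert prof.area_length_um == {"SSp-bfd": 240.0}
    assert prof.area_layer_length_um == {("SSp-bfd", "L4"): 240.0}
    assert prof.area_terminal_count == {"SSp-bfd": 2}
    assert prof.dominant_target == "SSp-bfd"


def test_profile_outside_goes_to_other(two_area_atlas):
    t = star_minor([250, 250, 500], [[250, 250, 2500]])
    prof = projection_profile(t, two_area_atlas, ("SSp-bfd", "SSs"))
    assert "other" in prof.area_length_um
    assert prof.dominant_target is None


def test_profile_length_conservation(noiseless_minors, noiseless_population):
    _, atlas, _, params = noiseless_population
    for t in noiseless_minors[:10]:
        prof = projection_profile(t, atlas, params.areas)
        np.testing.assert_allclose(prof.total_length_um,
                                   t.path_lengths.sum(), rtol=1e-9)


def test_dominant_target_rules():
    p = ProjectionProfile("x", area_length_um={"SSp-m": 300.0, "SSs": 100.0})
    assert dominant_target(p) == "SSp-m"
    tie = ProjectionProfile("y", area_length_um={"SSp-m": 100.0, "SSs": 100.0})
    # canonical order puts SSp-m before SSs; the tie is flagged
    area, flagged = dominant_target(tie, return_tie=True)
    assert area == "SSp-m" and flagged
    assert dominant_target(ProjectionProfile("z")) is None


def test_dominant_matches_bruteforce():
    rng = np.random.default_rng(3)
    areas = ("SSp-bfd", "SSp-n", "SSp-m", "SSs")
    for _ in range(50):
        lengths = {a: float(rng.integers(0, 50)) for a in areas}
        p = ProjectionProfile("r", area_length_um=dict(lengths))
        expected = max(areas, key=lambda a: (lengths[a], ))
        got = dominant_target(p, areas)
        if got is not None:
            assert lengths[got] == max(lengths.values())


def test_motif_threshold_boundary():
    counts = {"A": 20, "B": 7, "C": 4}
    p = ProjectionProfile("m", area_terminal_count=dict(counts))
    assert extract_motif(p, 5, areas=("A", "B", "C")) == ["A", "B"]
    p5 = ProjectionProfile("m", area_terminal_count={"A": 5})
    assert extract_motif(p5, 5, areas=("A",)) == ["A"]
    p4 = ProjectionProfile("m", area_terminal_count={"A": 4})
    assert extract_motif(p4, 5, areas=("A",)) == []


def test_motif_monotone_in_threshold():
    rng = np.random.default_rng(4)
    areas = tuple("ABCDEF")
    for _ in range(30):
        counts = {a: int(rng.integers(0, 12)) for a in areas}
        p = ProjectionProfile("m", area_terminal_count=counts)
        prev = None
        for thr in (1, 3, 5, 8):
            motif = set(extract_motif(p, thr, areas=areas))
            if prev is not None:
                assert motif <= prev
            prev = motif


def test_order_classes():
    assert classify_order([]) == "subthreshold"
    assert classify_order(["A"]) == "monofocal"
    assert classify_order(["A", "B"]) == "bifurcating"
    assert classify_order(["A", "B", "C"]) == "trifurcating"
    assert classify_order(["A", "B", "C", "D"]) == "quadrifurcating"
    assert classify_order(list("ABCDE")) == "higher"


def test_focality_rule(two_area_atlas):
    # dominant SSp-bfd ends at LR 1,000 μm; secondary SSs terminals at
    # border distances ~{250, 260, 300, 270} μm
    soma = [250, 250, 0]
    primary = [[250, 250, z] for z in (300, 350, 400, 450, 500)]
    secondary = [[250, 250, 1000 + d] for d in (250, 260, 300, 270)]
    t = star_minor(soma, primary + secondary)
    motif = ("SSp-bfd", "SSs")
    assert classify_focality(t, two_area_atlas, motif) == "center"
    t3 = star_minor(soma, primary + secondary[:3])
    assert classify_focality(t3, two_area_atlas, motif) == "border"
    assert classify_focality(t, two_area_atlas, ("SSp-bfd",)) == "not_applicable"


def test_focality_matches_bruteforce(noiseless_minors, noiseless_population):
    _, atlas, _, params = noiseless_population
    for t in noiseless_minors:
        prof = projection_profile(t, atlas, params.areas)
        if len(prof.motif) < 2:
            continue
        got = classify_focality(t, atlas, prof.motif)
        dom, sec = prof.motif[0], prof.motif[1]
        n_center = 0
        for p in t.terminal_points:
            if atlas.label_at(p)[0] == sec and \
                    atlas.border_distance(p, dom) > 200.0:
                n_center += 1
        assert got == ("center" if n_center >= 4 else "border")


def _stub(neuron_id, motif):
    p = ProjectionProfile(neuron_id, motif=tuple(motif))
    p.order_class = classify_order(motif)
    return p


def test_census_hand_count():
    profiles = [_stub(f"n{i}", m) for i, m in
                enumerate([("A",), ("A",), ("A", "B"), ("B",), ("A", "B")])]
    census = motif_census(profiles)
    assert census.loc["A", "n_neurons"] == 2
    assert census.loc["A - B", "n_neurons"] == 2
    assert census.loc["B", "n_neurons"] == 1
    fr = order_class_fractions(profiles)
    assert fr["monofocal"] == pytest.approx(0.6)
    assert fr["bifurcating"] == pytest.approx(0.4)
    assert census["n_neurons"].sum() == len(profiles)
    assert motif_census([]).empty


def test_significance_expected_vs_enriched():
    # 25 joint A-B out of 100 with marginals 0.5/0.5: exactly the null
    profiles = ([_stub(f"a{i}", ("A", "B")) for i in range(25)]
                + [_stub(f"b{i}", ("A",)) for i in range(25)]
                + [_stub(f"c{i}", ("B",)) for i in range(25)]
                + [_stub(f"d{i}", ()) for i in range(25)])
    census = motif_census(profiles)
    res = motif_significance(census, profiles)
    row = res.loc["A - B"]
    assert row["p_null"] == pytest.approx(0.25)
    assert row["p_value"] > 0.9 and not row["significant"]
    # single motif tested: Bonferroni with m=1 equals the raw p
    assert row["p_bonferroni"] == pytest.approx(
        binomtest(25, 100, 0.25).pvalue)

    enriched = ([_stub(f"a{i}", ("A", "B")) for i in range(50)]
                + [_stub(f"d{i}", ()) for i in range(50)])
    res2 = motif_significance(motif_census(enriched), enriched)
    assert res2.loc["A - B", "p_value"] < 1e-3
    assert res2.loc["A - B", "significant"]


def test_layer_distribution_hand_fixture():
    p1 = ProjectionProfile("n1", area_length_um={"SSp-bfd": 300.0},
                           area_layer_length_um={("SSp-bfd", "L4"): 240.0,
                                                 ("SSp-bfd", "L2/3"): 60.0})
    p2 = ProjectionProfile(
        "n2", area_length_um={"SSp-bfd": 80.0, "SSs": 120.0},
        area_layer_length_um={("SSp-bfd", "L5"): 80.0, ("SSs", "L4"): 120.0})
    sums, pref = layer_distribution([p1, p2], ("SSp-bfd", "SSs"))
    assert sums[("SSp-bfd", "L4")] == 240.0
    assert sums[("SSp-bfd", "L2/3")] == 60.0
    assert sums[("SSs", "L4")] == 120.0
    r1 = pref[pref.neuron_id == "n1"].iloc[0]
    assert r1.primary_area == "SSp-bfd" and r1.primary_layer == "L4"
    r2 = pref[pref.neuron_id == "n2"].iloc[0]
    assert r2.primary_area == "SSs" and r2.secondary_area == "SSp-bfd"
    assert r2.secondary_layer == "L5"
    # conservation: per-(area,layer) sums equal the sum over neurons
    np.testing.assert_allclose(
        sums.sum(), 240.0 + 60.0 + 80.0 + 120.0)
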