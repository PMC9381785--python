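"""Broad/narrow phase, pruning calculus and connectome assembly."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pma
from pma.connectivity import (broad_phase, build_connectome,
                              default_class_pair_table, load_class_pair_table,
                              narrow_phase, prune, target_count)
from pma.errors import ConfigError, FormatError
from pma.geometry import (Ellipsoid, OrientationFrame, PointCloud, aabb,
                          aabb_overlap, convex_hull, ellipsoid_surface_points,
                          hull_contains)
from pma.morphology import SampledMorphology
from pma.placement import CellRecord


def _toy_morph(cid, soma, axon_center, axon_semiaxes, dend_radius=10.0,
               label="deep-PC", rng=None):
    """Hand-built morphology: one ellipsoidal axon, a small dendritic ball."""
    rng = rng or np.random.default_rng(cid)
    soma = np.asarray(soma, dtype=float)
    frame = OrientationFrame.identity()
    axon = Ellipsoid(axon_center, frame, axon_semiaxes)
    surface = ellipsoid_surface_points(axon, 60)
    hull = convex_hull(surface)
    pts = soma + rng.uniform(-dend_radius, dend_radius, size=(30, 3))
    cloud = PointCloud(pts, role="basal-dendrite")
    return SampledMorphology(cid, label, soma, frame, [(0, "axon", axon)],
                             [hull], [axon], [aabb(surface)], [cloud], pts, [{}])


class TestBroadPhase:
    def test_distant_cells_and_self_excluded(self):
        a = _toy_morph(0, [0, 0, 0], [0, 0, 0], (10, 10, 10))
        b = _toy_morph(1, [1000, 0, 0], [1000, 0, 0], (10, 10, 10))
        assert len(broad_phase([a, b], [a, b])) == 0 or \
            (broad_phase([a, b], [a, b])[:, 0] != broad_phase([a, b], [a, b])[:, 1]).all()
        assert len(broad_phase([a], [a])) == 0

    def test_matches_allpairs_scan(self, small_circuit):
        morphs = list(small_circuit["morphs"].values())[:200]
        got = set(map(tuple, broad_phase(morphs, morphs)))
        brute = {(p.cell_id, q.cell_id)
                 for p in morphs for q in morphs
                 if p.cell_id != q.cell_id
                 and aabb_overlap(p.axon_aabb, q.dendrite_aabb)}
        assert got == brute


class TestNarrowPhase:
    def test_cloud_at_hull_centroid_is_hit(self):
        pre = _toy_morph(0, [0, 0, 0], [100, 0, 0], (150, 60, 60))
        post = _toy_morph(1, [100, 0, 0], [500, 500, 500], (10, 10, 10))
        assert narrow_phase(pre, post)

    def test_disjoint_aabbs_are_miss(self):
        pre = _toy_morph(0, [0, 0, 0], [0, 0, 0], (50, 50, 50))
        post = _toy_morph(1, [500, 0, 0], [500, 0, 0], (10, 10, 10))
        assert not narrow_phase(pre, post)

    def test_matches_pointwise_oracle(self, small_circuit):
        morphs = list(small_circuit["morphs"].values())
        rng = np.random.default_rng(0)
        pairs = rng.choice(len(morphs), size=(100, 2), replace=True)
        for i, j in pairs:
            pre, post = morphs[i], morphs[j]
            oracle = any(
                any(hull_contains(h, p) for h in pre.axon_hulls)
                for p in post.dendrite_points)
            assert narrow_phase(pre, post) == oracle


class TestPruningCalculus:
    def test_worked_example(self):
        assert target_count(216_435, 5_074, 0.000933) == 1_024_612

    def test_edge_cases(self):
        assert target_count(10, 10, 0.0) == 0
        assert target_count(1, 1, 1.0) == 1
        with pytest.raises(ConfigError):
            target_count(1, 1, 1.5)

    def test_prune_keeps_all_when_target_exceeds(self, caplog):
        pairs = np.array([[0, 1], [0, 2], [1, 2]])
        with caplog.at_level(logging.WARNING):
            kept = prune(pairs, 10, seed=0)
        np.testing.assert_array_equal(kept, pairs)
        assert any("exceeds" in r.message for r in caplog.records)
        assert len(prune(pairs, 0, seed=0)) == 0

    def test_prune_deterministic_per_seed(self):
        pairs = np.arange(40).reshape(20, 2)
        a = prune(pairs, 7, seed=5)
        b = prune(pairs, 7, seed=5)
        np.testing.assert_array_equal(a, b)
        assert len(a) == 7

    def test_prune_uniformity_chi2(self):
        pairs = np.column_stack([np.arange(10), np.arange(10) + 100])
        rng = np.random.default_rng(12)
        counts = np.zeros(10)
        reps = 2000
        for _ in range(reps):
            kept = prune(pairs, 5, seed=rng)
            counts[kept[:, 0]] += 1
        chi2, p = stats.chisquare(counts)
        assert p > 0.01
        assert np.abs(counts / reps - 0.5).max() < 0.05


class TestClassPairTable:
    def test_default_table_contains_published_entry(self):
        tab = default_class_pair_table()
        row = tab[(tab.pre_class == "superficial-PC") & (tab.post_class == "IVY")]
        assert float(row["p"].iloc[0]) == pytest.approx(0.000933)

    def test_validation(self, tmp_path):
        bad = tmp_path / "t.csv"
        bad.write_text("pre_class,post_class,p\ndeep-PC,NOPE,0.5\n")
        with pytest.raises(FormatError):
            load_class_pair_table(bad)
        bad.write_text("pre_class,post_class,p\ndeep-PC,IVY,1.5\n")
        with pytest.raises(FormatError):
            load_class_pair_table(bad)


class TestBuildConnectome:
    def test_toy_chain_yields_exactly_reachable_edges(self):
        cells = [CellRecord(i, "deep-PC", "SO", [300.0 * i, 0, 0])
                 for i in range(3)]
        morphs = {i: _toy_morph(i, [300.0 * i, 0, 0],
                                [300.0 * i + 175.0, 0, 0], (180, 60, 60))
                  for i in range(3)}
        table = pd.DataFrame({"pre_class": ["deep-PC"], "post_class": ["deep-PC"],
                              "p": [1.0]})
        edges = build_connectome(cells, morphs, table, seed=0)
        assert set(zip(edges.pre_id, edges.post_id)) == {(0, 1), (1, 2)}

    def test_zero_probability_gives_empty(self, small_circuit):
        table = pd.DataFrame({"pre_class": ["deep-PC"], "post_class": ["deep-PC"],
                              "p": [0.0]})
        edges = build_connectome(small_circuit["cells"], small_circuit["morphs"],
                                 table, seed=0)
        assert len(edges) == 0

    def test_deterministic_per_seed(self, small_circuit):
        table = default_class_pair_table()
        a = build_connectome(small_circuit["cells"], small_circuit["morphs"],
                             table, seed=9)
        b = build_connectome(small_circuit["cells"], small_circuit["morphs"],
                             table, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_no_self_edges_or_duplicates(self, small_circuit):
        edges = small_circuit["edges"]
        assert (edges.pre_id != edges.post_id).all()
        assert not edges.duplicated(["pre_id", "post_id", "pre_class",
                                     "post_class"]).any()

    def test_per_pair_count_is_min_of_target_and_candidates(self, small_circuit):
        cells, morphs = small_circuit["cells"], small_circuit["morphs"]
        by = {}
        for c in cells:
            by.setdefault(c.class_label, []).append(c)
        table = default_class_pair_table()
        edges = small_circuit["edges"]
        sizes = edges.groupby(["pre_class", "post_class"]).size()
        for _, row in table.sample(6, random_state=0).iterrows():
            a, b, p = row.pre_class, row.post_class, float(row.p)
            cand = 0
            for pre in by[a]:
                for post in by[b]:
                    if pre.id != post.id and narrow_phase(morphs[pre.id],
                                                          morphs[post.id]):
                        cand += 1
            target = target_count(len(by[a]), len(by[b]), p)
            assert sizes.get((a, b), 0) == min(target, cand)

    def test_axon_growth_never_loses_candidates(self):
        rng = np.random.default_rng(3)
        somata = rng.uniform(0, 400, size=(20, 3))
        cells = [CellRecord(i, "deep-PC", "SO", s) for i, s in enumerate(somata)]
        dend_rngs = [np.random.default_rng(100 + i) for i in range(20)]

        def build(scale):
            return {i: _toy_morph(i, somata[i], somata[i] + [50, 0, 0],
                                  (scale * 80, scale * 50, scale * 50),
                                  rng=np.random.default_rng(100 + i))
                    for i in range(20)}

        table = pd.DataFrame({"pre_class": ["deep-PC"], "post_class": ["deep-PC"],
                              "p": [1.0]})
        small = build_connectome(cells, build(1.0), table, seed=0)
        large = build_connectome(cells, build(1.6), table, seed=0)
        small_set = set(zip(small.pre_id, small.post_id))
        large_set = set(zip(large.pre_id, large.post_id))
        assert small_set <= large_set

    def test_missing_morphology_raises(self, small_circuit):
        cells = small_circuit["cells"][:10]
        morphs = {c.id: small_circuit["morphs"][c.id] for c in cells[:5]}
        with pytest.raises(ConfigError):
            build_connectome(cells, morphs, default_class_pair_table(), seed=0)
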