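"""Vertex clustering, family classification, ROI subdivision, RG assembly."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from hyperflow.clustering import (
    FAMILIES,
    SUPER_REGIONS,
    aggregate_rg_series,
    build_region_groups,
    classify_family,
    cluster_vertices,
    subdivide_roi,
)
from hyperflow.synth import FAMILY_ARCHETYPES, simulate_vertex_features

from oracles import complete_linkage_labels


class TestClusterVertices:
    def test_k_equals_n_gives_singletons(self, rng):
        feats = rng.standard_normal((6, 3))
        lab = cluster_vertices(feats, 6)
        assert sorted(lab.labels) == list(range(1, 7))

    def test_separated_clouds_recovered_exactly(self, rng):
        centers = rng.standard_normal((7, 3)) * 20.0
        feats = np.vstack([c + 0.05 * rng.standard_normal((30, 3)) for c in centers])
        true = np.repeat(np.arange(7), 30)
        lab = cluster_vertices(feats, 7)
        assert adjusted_rand_score(true, lab.labels) == 1.0

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_small_set_matches_bruteforce_linkage(self, k):
        pts = np.array(
            [
                [0.0, 0.0, 0.0],
                [0.4, 0.1, 0.0],
                [5.0, 5.0, 5.0],
                [5.3, 5.2, 4.9],
                [-3.0, 2.0, 1.0],
            ]
        )
        lab = cluster_vertices(pts, k)
        oracle = complete_linkage_labels(pts, k)
        assert adjusted_rand_score(oracle, lab.labels) == 1.0

    def test_input_order_invariance(self, rng):
        feats, _, _ = simulate_vertex_features(n_rois=6, seed=5)
        lab1 = cluster_vertices(feats, 3)
        perm = rng.permutation(len(feats))
        lab2 = cluster_vertices(feats[perm], 3)
        restored = np.empty_like(lab2.labels)
        restored[perm] = lab2.labels
        assert adjusted_rand_score(lab1.labels, restored) == 1.0

    def test_invalid_k(self, rng):
        feats = rng.standard_normal((5, 3))
        for k in (0, 6):
            with pytest.raises(ValueError):
                cluster_vertices(feats, k)


class TestClassifyFamily:
    @pytest.mark.parametrize(
        "pattern,family",
        [
            ((0.1, 0.9, 0.2), "flow"),  # higher in team only
            ((0.5, 0.4, -0.9), "team"),  # lower in flow only
            ((0.9, 0.1, 0.1), "teamflow"),  # higher in team flow
        ],
    )
    def test_reference_patterns(self, pattern, family):
        assert classify_family(np.array(pattern)) == family

    def test_archetypes_self_classify(self):
        for name, arch in FAMILY_ARCHETYPES.items():
            assert classify_family(arch) == name

    def test_exact_tie_unresolved(self):
        with pytest.raises(ValueError, match="unresolved"):
            classify_family(np.array([0.5, 0.5, 0.5]))
        assert classify_family(np.array([0.5, 0.5, 0.5]), strict=False) is None

    def test_family_recovery_under_noise(self):
        """Vertices drawn from the archetypes + noise recover their family
        on >= 95% of vertices."""
        feats, labels, _ = simulate_vertex_features(
            n_rois=30, vertices_per_roi=10, noise_sd=0.1, seed=0
        )
        lab = cluster_vertices(feats, 3)
        fam_names = list(FAMILY_ARCHETYPES)
        planted = np.array([fam_names[l] for l in labels], dtype=object)
        assert np.mean(planted == lab.family_of_vertex()) >= 0.95


class TestSubdivideRoi:
    def test_pure_roi_stays_whole(self):
        fams = np.array(["teamflow"] * 40, dtype=object)
        parts = subdivide_roi(fams, "roi1")
        assert len(parts) == 1 and len(parts[0][2]) == 40

    def test_50_30_20_splits_three_ways(self):
        fams = np.array(
            ["flow"] * 50 + ["team"] * 30 + ["teamflow"] * 20, dtype=object
        )
        parts = subdivide_roi(fams, "r", threshold=0.20)
        sizes = {p[1]: len(p[2]) for p in parts}
        assert sizes == {"flow": 50, "team": 30, "teamflow": 20}

    def test_partition_property(self, rng):
        fams = np.array(
            [FAMILIES[i] for i in rng.integers(0, 3, 67)], dtype=object
        )
        parts = subdivide_roi(fams, "r")
        all_idx = np.concatenate([p[2] for p in parts])
        assert sorted(all_idx) == list(range(67))
        assert len(set(all_idx)) == 67

    def test_unlabeled_vertices_rejected(self):
        with pytest.raises(ValueError, match="unlabeled"):
            subdivide_roi(np.array(["flow", None], dtype=object), "r")


def _toy_anatomy(n_rois: int) -> dict:
    return {
        f"roi{i}": ("L" if i % 2 == 0 else "R", SUPER_REGIONS[i % 6])
        for i in range(n_rois)
    }


class TestBuildRegionGroups:
    def test_toy_grouping_matches_hand_rule(self):
        anatomy = _toy_anatomy(6)
        flags = {f"roi{i}": i == 2 for i in range(6)}
        subdivisions = {
            f"roi{i}": [(f"roi{i}", "teamflow", np.arange(5))] for i in range(6)
        }
        subdivisions["roi0"] = [
            ("roi0.flow", "flow", np.arange(3)),
            ("roi0.teamflow", "teamflow", np.arange(3, 5)),
        ]
        groups = build_region_groups(flags, subdivisions, anatomy)
        # roi2 (L, IFC) is significant -> L-RG7, not L-RG3
        assert "roi2" in groups.by_name("L-RG7").members
        assert groups.by_name("L-RG3").members == []
        # roi0 subdivisions land in L-RG1 (PFC)
        assert set(groups.by_name("L-RG1").members) == {"roi0.flow", "roi0.teamflow"}
        # roi1 (R, ACC) -> R-RG2
        assert groups.by_name("R-RG2").members == ["roi1"]

    def test_always_14_disjoint_groups(self):
        anatomy = _toy_anatomy(12)
        flags = {r: False for r in anatomy}
        subs = {r: [(r, "team", np.arange(4))] for r in anatomy}
        groups = build_region_groups(flags, subs, anatomy)
        assert len(groups.groups) == 14
        member_map = groups.member_map()  # raises on overlap
        assert len(member_map) == 12

    def test_all_significant_warns(self):
        anatomy = _toy_anatomy(4)
        flags = {r: True for r in anatomy}
        subs = {r: [(r, "teamflow", np.arange(2))] for r in anatomy}
        with pytest.warns(UserWarning, match="RG1-RG6"):
            groups = build_region_groups(flags, subs, anatomy)
        assert len(groups.by_name("L-RG7").members) == 2

    def test_missing_roi_in_anatomy_rejected(self):
        with pytest.raises(KeyError, match="anatomical map"):
            build_region_groups({"roiX": False}, {}, {})


class TestAggregate:
    def _groups(self, members_per_group):
        anatomy = _toy_anatomy(12)
        flags = {r: False for r in anatomy}
        subs = {r: [(r, "team", np.arange(1))] for r in anatomy}
        return build_region_groups(flags, subs, anatomy)

    def test_single_member_identity_and_mean_oracle(self, rng):
        groups = self._groups(1)
        series = {f"roi{i}": rng.standard_normal(40) for i in range(12)}
        out, names = aggregate_rg_series(series, groups)
        assert out.shape == (14, 40)
        for gi, g in enumerate(groups.groups):
            if not g.members:
                assert np.all(np.isnan(out[gi]))
            else:
                expected = np.mean([series[m] for m in g.members], axis=0)
                assert np.allclose(out[gi], expected)

    def test_two_identical_members_average_to_same(self, rng):
        groups = self._groups(1)
        base = rng.standard_normal(20)
        series = {f"roi{i}": base.copy() for i in range(12)}
        out, _ = aggregate_rg_series(series, groups)
        for gi, g in enumerate(groups.groups):
            if g.members:
                assert np.allclose(out[gi], base)

    def test_missing_member_rejected(self, rng):
        groups = self._groups(1)
        series = {f"roi{i}": rng.standard_normal(10) for i in range(11)}
        with pytest.raises(KeyError, match="missing member"):
            aggregate_rg_series(series, groups)
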