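import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import voxelmap as vx
from voxelmap.centerline import CenterlineTree, Segment
from voxelmap.errors import InputError, ParameterError
from voxelmap.quantify import DEFAULT_SCHEME, Plaque, report_long
from voxelmap.segmentation import LumenMask
from voxelmap.voxel_map import VoxelMapLabels, WallModel


class TestClassifyLevel:
    def test_all_integers_match_linear_scan_oracle(self):
        edges = [(0, 50), (50, 100), (100, 200), (200, 300), (300, 400), (400, np.inf)]

        def oracle(h):
            for lev, (lo, hi) in enumerate(edges, start=1):
                if lo <= h < hi:
                    return lev
            raise AssertionError

        hus = np.arange(0, 601)
        got = vx.classify_level(hus)
        assert got.tolist() == [oracle(h) for h in hus]

    @pytest.mark.parametrize(
        "hu,level", [(0, 1), (49, 1), (50, 2), (99, 2), (100, 3), (199, 3), (200, 4), (299, 4), (300, 5), (399, 5), (400, 6), (1000, 6)]
    )
    def test_bin_edges(self, hu, level):
        assert vx.classify_level(hu) == level

    def test_negative_input_rejected(self):
        with pytest.raises(InputError, match="clamp"):
            vx.classify_level(-1)


class TestPercents:
    def test_two_level_volumes_round_half_up(self):
        # 0.9834 : 1.9703 mm^3 split -> 33.29% / 66.71%
        assert vx.level_percents({1: 0.9834, 2: 1.9703}) == {1: 33.29, 2: 66.71}

    def test_single_level_is_exactly_100(self):
        p = Plaque(id=1, voxels=np.zeros((5, 3), int), levels=np.full(5, 2), layers=np.full(5, 3))
        vx.quantify_plaque(p, (0.4, 0.4, 0.75))
        assert p.level_percents == {2: 100.0}
        assert p.total_volume_mm3 == pytest.approx(5 * 0.4 * 0.4 * 0.75)

    def test_random_counts_match_count_and_multiply_oracle(self):
        rng = np.random.default_rng(4)
        spacing = (0.4, 0.4, 0.75)
        voxvol = 0.4 * 0.4 * 0.75
        for _ in range(10):
            counts = {lev: int(c) for lev, c in zip((1, 2, 3), rng.integers(1, 200, 3))}
            levels = np.concatenate([np.full(c, lev) for lev, c in counts.items()])
            n = len(levels)
            p = Plaque(id=1, voxels=np.zeros((n, 3), int), levels=levels, layers=np.ones(n, int))
            vx.quantify_plaque(p, spacing)
            assert p.level_counts == counts
            total = n * voxvol
            for lev, c in counts.items():
                assert p.level_volumes_mm3[lev] == pytest.approx(c * voxvol)
                assert p.level_percents[lev] == pytest.approx(100 * c / n, abs=0.005)
            assert p.total_volume_mm3 == pytest.approx(total)

    @given(st.dictionaries(st.integers(1, 6), st.floats(0.01, 1e4), min_size=1, max_size=6))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_percent_sum_is_100_within_rounding(self, volumes):
        pct = vx.level_percents(volumes)
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.01 * len(pct))

    def test_empty_plaque_rejected(self):
        p = Plaque(id=1, voxels=np.zeros((0, 3), int), levels=np.zeros(0, int), layers=np.zeros(0, int))
        with pytest.raises(InputError):
            vx.quantify_plaque(p, (1, 1, 1))


def _synthetic_wall(shape=(20, 20, 20)):
    """A fabricated layer map at baseline attenuation everywhere."""
    labels = np.zeros(shape, dtype=np.int8)
    labels[2:18, 2:18, 4:8] = 1
    labels[2:18, 2:18, 8:12] = 2
    labels[2:18, 2:18, 12:16] = 3
    values = np.zeros(shape, dtype=np.int32)
    values[labels == 1] = 150  # level 3 = baseline for layer +1
    values[labels == 2] = 75   # level 2 = baseline for layer +2
    values[labels == 3] = 25   # level 1 = baseline for layer +3
    vmap = VoxelMapLabels((1, 1, 1), (0, 0, 0), labels)
    wall = WallModel((1, 1, 1), (0, 0, 0), values, np.zeros(shape, bool), vmap)
    return wall, vmap


class TestDetect:
    def test_baseline_perfect_wall_has_no_plaques(self):
        wall, vmap = _synthetic_wall()
        assert vx.detect_plaques(wall, vmap) == []

    def test_27_voxel_blob_in_layer2_is_one_level3_plaque(self):
        wall, vmap = _synthetic_wall()
        wall.values[8:11, 8:11, 8:11] = 120  # 3x3x3 inside layer +2
        plaques = vx.detect_plaques(wall, vmap)
        assert len(plaques) == 1
        p = plaques[0]
        assert p.n_voxels == 27
        assert (p.levels == 3).all()
        assert (p.layers == 2).all()

    def test_separated_blobs_split_but_diagonal_contact_merges(self):
        wall, vmap = _synthetic_wall()
        wall.values[4:6, 4:6, 8:10] = 120
        wall.values[9:11, 9:11, 8:10] = 120  # > 1 voxel away in every direction
        assert len(vx.detect_plaques(wall, vmap)) == 2
        wall2, vmap2 = _synthetic_wall()
        wall2.values[4:6, 4:6, 8:10] = 120
        wall2.values[6:8, 6:8, 10:12] = 120  # touches the first diagonally at (5,5,9)/(6,6,10)
        assert len(vx.detect_plaques(wall2, vmap2)) == 1

    def test_min_voxels_suppresses_specks(self):
        wall, vmap = _synthetic_wall()
        wall.values[9, 9, 9] = 120
        assert vx.detect_plaques(wall, vmap) == []
        assert len(vx.detect_plaques(wall, vmap, min_voxels=1)) == 1

    def test_fat_flagged_voxels_are_not_candidates(self):
        wall, vmap = _synthetic_wall()
        wall.values[8:11, 8:11, 8:11] = 120
        wall.fat_flag[8:11, 8:11, 8:11] = True
        assert vx.detect_plaques(wall, vmap) == []

    def test_calcified_levels_never_form_ncp_components(self):
        wall, vmap = _synthetic_wall()
        wall.values[8:11, 8:11, 8:11] = 450  # level 6: calcified, reported separately
        assert vx.detect_plaques(wall, vmap) == []
        per_plaque, _ = vx.report([], wall=wall)
        assert per_plaque.attrs["cp_voxel_counts"][6] == 27

    def test_baseline_missing_a_layer_raises(self):
        wall, vmap = _synthetic_wall()
        with pytest.raises(ParameterError, match="layer"):
            vx.detect_plaques(wall, vmap, baseline={1: 3, 2: 2})

    def test_phantom_plaque_recovered_exactly(self, segmented_phantom):
        _, truth, _, vmap, wall = segmented_phantom
        plaques = vx.detect_plaques(wall, vmap)
        assert len(plaques) == len(truth.plaques) == 1
        got = {tuple(v) for v in plaques[0].voxels}
        want = {tuple(v) for v in truth.plaques[0].voxels}
        assert got == want


def _two_segment_tree():
    stem = Segment(0, None, points=np.array([[0.0, 0, z] for z in range(5)]),
                   indices=np.array([[0, 0, z] for z in range(5)]), label="pRCA")
    arm = Segment(1, 0, points=np.array([[10.0, 0, z] for z in range(4, 9)]),
                  indices=np.array([[10, 0, z] for z in range(4, 9)]), label="RMA")
    return CenterlineTree(segments={0: stem, 1: arm}, root=0)


class TestLocate:
    def test_single_segment_tree_always_wins(self):
        tree = CenterlineTree(segments={0: Segment(0, None, np.zeros((3, 3)), np.zeros((3, 3), int), label="RMA")}, root=0)
        mask = LumenMask((1, 1, 1), (0, 0, 0), np.ones((4, 4, 4), bool))
        p = Plaque(id=1, voxels=np.array([[3, 3, 3]]), levels=np.array([2]), layers=np.array([2]))
        assert vx.locate_plaque(p, tree, mask) == "RMA"

    def test_majority_vote(self):
        tree = _two_segment_tree()
        mask = LumenMask((1, 1, 1), (0, 0, 0), np.ones((12, 4, 10), bool))
        vox = np.array([[0, 1, 2]] * 14 + [[10, 1, 6]] * 13)
        p = Plaque(id=1, voxels=vox, levels=np.full(27, 2), layers=np.full(27, 2))
        assert vx.locate_plaque(p, tree, mask) == "pRCA"
        assert p.vote_counts == {"pRCA": 14, "RMA": 13}

    def test_exact_tie_goes_to_segment_closer_to_root(self):
        tree = _two_segment_tree()
        mask = LumenMask((1, 1, 1), (0, 0, 0), np.ones((12, 4, 10), bool))
        vox = np.array([[0, 1, 2]] * 5 + [[10, 1, 6]] * 5)
        p = Plaque(id=1, voxels=vox, levels=np.full(10, 2), layers=np.full(10, 2))
        assert vx.locate_plaque(p, tree, mask) == "pRCA"  # depth 0 beats depth 1

    def test_unlabeled_tree_rejected(self):
        tree = _two_segment_tree()
        for s in tree.segments.values():
            s.label = "unlabeled"
        mask = LumenMask((1, 1, 1), (0, 0, 0), np.ones((2, 2, 2), bool))
        p = Plaque(id=1, voxels=np.array([[0, 0, 0]]), levels=np.array([1]), layers=np.array([1]))
        with pytest.raises(InputError, match="label"):
            vx.locate_plaque(p, tree, mask)

    def test_phantom_plaque_localizes_to_generating_branch(self, segmented_phantom):
        _, truth, mask, vmap, wall = segmented_phantom
        tree = vx.build_tree(vx.skeletonize(mask), mask.spacing, mask.origin)
        tree = vx.apply_labels(tree, vx.label_map_from_truth(tree, truth))
        plaques = vx.detect_plaques(wall, vmap)
        assert vx.locate_plaque(plaques[0], tree, mask) == truth.plaques[0].branch == "RMA"


class TestExportObj:
    def test_single_voxel_mesh_is_watertight_and_local(self, tmp_path):
        import trimesh

        p = Plaque(id=1, voxels=np.array([[0, 0, 0]]), levels=np.array([1]), layers=np.array([1]))
        vx.export_obj(p, (1, 1, 1), (0, 0, 0), tmp_path / "v.obj")
        mesh = trimesh.load(tmp_path / "v.obj")
        assert mesh.is_watertight
        # all vertices inside the voxel's circumscribing ball around its centre
        assert np.linalg.norm(mesh.vertices - 0.0, axis=1).max() <= np.sqrt(3) / 2 + 1e-9

    def test_cube_mesh_volume_near_27(self, tmp_path):
        import trimesh

        cube = np.zeros((5, 5, 5), bool)
        cube[1:4, 1:4, 1:4] = True
        vx.export_obj(cube, (1, 1, 1), (0, 0, 0), tmp_path / "c.obj")
        mesh = trimesh.load(tmp_path / "c.obj")
        assert mesh.is_watertight
        assert abs(mesh.volume - 27.0) <= 0.3 * 27.0

    def test_phantom_plaque_obj_parses_back(self, tmp_path, segmented_phantom):
        _, _, _, vmap, wall = segmented_phantom
        p = vx.detect_plaques(wall, vmap)[0]
        path = tmp_path / "p.obj"
        vx.export_obj(p, wall.spacing, wall.origin, path)
        verts, faces = [], []
        for line in path.read_text().splitlines():
            if line.startswith("v "):
                verts.append([float(t) for t in line.split()[1:4]])
            elif line.startswith("f "):
                faces.append([int(t.split("/")[0]) for t in line.split()[1:]])
        assert len(verts) >= 8
        assert all(1 <= i <= len(verts) for f in faces for i in f)

    def test_empty_input_rejected(self, tmp_path):
        with pytest.raises(InputError):
            vx.export_obj(np.zeros((3, 3, 3), bool), (1, 1, 1), (0, 0, 0), tmp_path / "e.obj")


class TestReport:
    def test_zero_plaques_yields_header_only_tables(self):
        per_plaque, per_segment = vx.report([])
        assert len(per_plaque) == 0 and len(per_segment) == 0
        assert "total_mm3" in per_plaque.columns

    def test_single_plaque_row_matches_record(self):
        p = Plaque(id=1, voxels=np.zeros((8, 3), int), levels=np.full(8, 3), layers=np.full(8, 2))
        vx.quantify_plaque(p, (0.5, 0.5, 0.5))
        p.label = "RMA"
        per_plaque, per_segment = vx.report([p])
        row = per_plaque.iloc[0]
        assert row.label == "RMA"
        assert row.total_mm3 == pytest.approx(p.total_volume_mm3)
        assert row.level3_pct == 100.0
        long = report_long(per_plaque)
        assert len(long) == 1 and long.iloc[0].level == 3

    def test_segment_aggregate_adds_plaques_on_same_branch(self):
        ps = []
        for i, n in enumerate((10, 20), start=1):
            p = Plaque(id=i, voxels=np.zeros((n, 3), int), levels=np.full(n, 2), layers=np.full(n, 3))
            vx.quantify_plaque(p, (1, 1, 1))
            p.label = "RMA"
            ps.append(p)
        _, per_segment = vx.report(ps)
        assert len(per_segment) == 1
        assert per_segment.iloc[0].total_mm3 == pytest.approx(30.0)
        # volume conservation: totals are exactly voxel count x voxel volume
        assert sum(p.total_volume_mm3 for p in ps) == 30.0
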