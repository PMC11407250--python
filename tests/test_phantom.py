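import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetaldot.phantom import (Channel, GeometryError, PhantomSpec, TetMesh,
                              TissueLabel, _top_surface_faces, build_phantom,
                              build_probe_layout, group_channels,
                              min_surface_to_label_distance, select_channels,
                              structured_box_mesh, tet_volumes)

from ._oracles import point_triangle_distance


class TestPhantomSpec:
    def test_zero_fat_thickness_rejected(self, mini_phantom_spec):
        spec = dataclasses.replace(mini_phantom_spec, fat_thickness=0.0)
        with pytest.raises(ValueError, match="fat_thickness"):
            spec.validate()

    def test_nonpositive_edge_length_rejected(self, mini_phantom_spec):
        spec = dataclasses.replace(mini_phantom_spec, target_edge_length=-1.0)
        with pytest.raises(ValueError, match="target_edge_length"):
            spec.validate()

    def test_shells_exceeding_head_radius_rejected(self, mini_phantom_spec):
        spec = dataclasses.replace(mini_phantom_spec, scalp_thickness=25.0)
        with pytest.raises(GeometryError):
            spec.validate()

    def test_inconsistent_brain_depth_rejected(self, mini_phantom_spec):
        spec = dataclasses.replace(mini_phantom_spec, brain_depth=99.0)
        with pytest.raises(ValueError, match="brain_depth"):
            spec.validate()

    def test_consistent_brain_depth_accepted(self, mini_phantom_spec):
        depth = mini_phantom_spec.derived_brain_depth
        dataclasses.replace(mini_phantom_spec, brain_depth=depth).validate()


class TestBuildPhantom:
    def test_brain_depth_recovered(self):
        spec = PhantomSpec(fat_thickness=10, muscle_thickness=10, fluid_gap=4,
                           fetal_head_radius=45.0, target_edge_length=5.0)
        assert spec.derived_brain_depth == 30.0
        mesh = build_phantom(spec, seed=0)
        d = min_surface_to_label_distance(mesh, TissueLabel.FETAL_BRAIN)
        assert d == pytest.approx(30.0, abs=spec.target_edge_length)

    def test_op_like_fluid_gap_increases_depth(self):
        spec = PhantomSpec(fat_thickness=10, muscle_thickness=10,
                           fluid_gap=19.0, fetal_head_radius=45.0,
                           target_edge_length=5.0)
        assert spec.derived_brain_depth == 45.0
        mesh = build_phantom(spec, seed=0)
        d = min_surface_to_label_distance(mesh, TissueLabel.FETAL_BRAIN)
        assert d == pytest.approx(45.0, abs=spec.target_edge_length)

    def test_deterministic_for_fixed_spec_and_seed(self, mini_phantom_spec):
        a = build_phantom(mini_phantom_spec, seed=7)
        b = build_phantom(mini_phantom_spec, seed=7)
        assert a.nodes.tobytes() == b.nodes.tobytes()
        assert a.elements.tobytes() == b.elements.tobytes()
        assert a.element_labels.tobytes() == b.element_labels.tobytes()

    def test_all_volumes_positive(self, mini_phantom):
        assert (mini_phantom.element_volumes > 0).all()

    def test_every_node_in_an_element(self, mini_phantom):
        used = np.unique(mini_phantom.elements.ravel())
        assert len(used) == mini_phantom.num_nodes

    def test_all_seven_labels_present(self, mini_phantom):
        present = set(np.unique(mini_phantom.element_labels))
        assert present == {int(lab) for lab in TissueLabel}

    def test_node_volumes_sum_to_total(self, mini_phantom):
        assert mini_phantom.node_volumes.sum() == pytest.approx(
            mini_phantom.element_volumes.sum()
        )

    def test_curved_phantom_builds(self, mini_phantom_spec):
        spec = dataclasses.replace(mini_phantom_spec,
                                   abdomen_curvature_radius=200.0)
        mesh = build_phantom(spec, seed=0)
        assert (mesh.element_volumes > 0).all()
        # surface sags laterally: edge-of-slab surface nodes sit deeper
        top = mesh.nodes[np.unique(_top_surface_faces(mesh).ravel())]
        assert top[np.abs(top[:, 1]).argmax(), 2] > top[:, 2].min() + 1.0


class TestSurfaceFaces:
    def test_boundary_faces_match_brute_force(self):
        nodes, elems = structured_box_mesh((10.0, 10.0, 10.0), 5.0)
        mesh = TetMesh(nodes, elems, np.zeros(len(elems), dtype=np.int64))
        from collections import Counter

        count = Counter()
        for tet in elems:
            for f in ([tet[0], tet[1], tet[2]], [tet[0], tet[1], tet[3]],
                      [tet[0], tet[2], tet[3]], [tet[1], tet[2], tet[3]]):
                count[tuple(sorted(f))] += 1
        expected = {f for f, c in count.items() if c == 1}
        got = {tuple(sorted(f)) for f in mesh.surface_faces}
        assert got == expected

    def test_invalid_element_index_rejected(self):
        nodes = np.zeros((3, 3))
        with pytest.raises(ValueError, match="out of range"):
            TetMesh(nodes, np.array([[0, 1, 2, 5]]), np.zeros(1))


class TestProbeLayout:
    def test_6x6_grid_gives_18_18_and_324_pairs(self, mini_phantom):
        layout = build_probe_layout(mini_phantom, (6, 6), (60.0, 42.0))
        assert layout.num_sources == 18
        assert layout.num_detectors == 18
        assert layout.num_sources * layout.num_detectors == 324

    def test_2x2_grid(self, mini_phantom):
        layout = build_probe_layout(mini_phantom, (2, 2), (20.0, 20.0))
        assert layout.num_sources == 2
        assert layout.num_detectors == 2

    def test_positions_on_surface(self, mini_phantom):
        layout = build_probe_layout(mini_phantom, (6, 6), (60.0, 42.0))
        tris = mini_phantom.nodes[mini_phantom.surface_faces]
        for p in np.vstack([layout.source_positions,
                            layout.detector_positions]):
            d = min(point_triangle_distance(p, t) for t in tris)
            assert d < 0.5

    def test_grid_larger_than_surface_rejected(self, mini_phantom):
        from fetaldot.phantom import ProjectionError

        with pytest.raises(ProjectionError):
            build_probe_layout(mini_phantom, (6, 6), (500.0, 500.0))


class TestSelectChannels:
    def test_matches_brute_force_on_flat_grid(self, mini_phantom):
        layout = build_probe_layout(mini_phantom, (6, 6), (60.0, 42.0))
        chans = select_channels(layout, 20.0, 120.0)
        count = 0
        for s in layout.source_positions:
            for d in layout.detector_positions:
                if 20.0 <= np.linalg.norm(s - d) <= 120.0:
                    count += 1
        assert len(chans) == count

    def test_no_filter_keeps_all_pairs(self, mini_phantom):
        layout = build_probe_layout(mini_phantom, (6, 6), (60.0, 42.0))
        assert len(select_channels(layout, 0.0, np.inf)) == 324

    def test_boundary_distance_excluded(self):
        from fetaldot.phantom import ProbeLayout

        layout = ProbeLayout(
            source_positions=np.array([[0.0, 0.0, 0.0]]),
            detector_positions=np.array([[19.9, 0.0, 0.0]]),
            grid_shape=(1, 2), grid_extent=(19.9, 0.0),
        )
        assert select_channels(layout, 20.0, 120.0) == []

    def test_dmin_ge_dmax_rejected(self, mini_phantom):
        layout = build_probe_layout(mini_phantom, (2, 2), (20.0, 20.0))
        with pytest.raises(ValueError, match="dmin"):
            select_channels(layout, 50.0, 50.0)


class TestGroupChannels:
    def _mk(self, distances):
        return [Channel(i, i, float(d)) for i, d in enumerate(distances)]

    def test_half_open_convention(self):
        groups = group_channels(self._mk([40.0]))
        assert [g.nm for g in groups] == [0, 1, 0, 0, 0]
        assert groups[1].label == "40-60"

    def test_last_bin_closed(self):
        groups = group_channels(self._mk([120.0]))
        assert groups[-1].nm == 1
        assert groups[-1].label == "100-120"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside bins"):
            group_channels(self._mk([130.0]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=20.0, max_value=120.0,
                              allow_nan=False), min_size=1, max_size=40))
    def test_partition_property(self, distances):
        groups = group_channels(self._mk(distances))
        assert sum(g.nm for g in groups) == len(distances)
        for g in groups:
            for ch in g.channels:
                if g.upper == 120.0:
                    assert g.lower <= ch.distance <= g.upper
                else:
                    assert g.lower <= ch.distance < g.upper
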