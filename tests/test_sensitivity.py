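import numpy as np
import pytest

from fetaldot.forward import SurfaceSampler, assemble, build_patch, make_source
from fetaldot.optics import assign_properties
from fetaldot.phantom import (Channel, ChannelGroup, TissueLabel,
                              build_probe_layout, group_channels,
                              select_channels)
from fetaldot.sensitivity import (brain_sensitivity_scores,
                                  channel_orientation_map, jacobian,
                                  rank_top_channels,
                                  total_normalized_jacobian)

from ._oracles import finite_difference_jacobian_entry


@pytest.fixture(scope="module")
def slab_jacobian(small_slab):
    """Three-channel Jacobian on the homogeneous slab."""
    mesh, props = small_slab
    system = assemble(mesh, props)
    sampler = SurfaceSampler(mesh)
    sources = [make_source(mesh, props, np.array([x, 0.0, 0.0]))
               for x in (-25.0, -5.0)]
    patches = [build_patch(sampler, np.array([x, 0.0, 0.0]))
               for x in (5.0, 25.0)]
    channels = [Channel(0, 0, 30.0), Channel(0, 1, 50.0), Channel(1, 1, 30.0)]
    J = jacobian(system, sources, patches, channels)
    return mesh, props, system, sources, patches, channels, J


class TestJacobian:
    def test_matches_finite_difference(self, fd_box):
        mesh, props = fd_box
        assert mesh.num_nodes <= 2000
        system = assemble(mesh, props)
        sampler = SurfaceSampler(mesh)
        src = make_source(mesh, props, np.array([-15.0, 0.0, 0.0]))
        patch = build_patch(sampler, np.array([15.0, 0.0, 0.0]))
        J = jacobian(system, [src], [patch], [Channel(0, 0, 30.0)])
        row = J.values[0]
        peak = np.abs(row).max()
        rng = np.random.default_rng(42)
        nodes = rng.choice(np.flatnonzero(np.abs(row) > 1e-6 * peak),
                           size=10, replace=False)
        for node in nodes:
            fd = finite_difference_jacobian_entry(mesh, props, src, patch,
                                                  int(node))
            assert row[node] == pytest.approx(fd, rel=5e-3)

    def test_all_entries_nonpositive(self, slab_jacobian):
        *_, J = slab_jacobian
        assert (J.values <= 0).all()

    def test_fluences_positive(self, slab_jacobian):
        *_, J = slab_jacobian
        assert (J.fluences > 0).all()

    def test_short_channel_has_no_deep_mass(self, slab_jacobian):
        mesh, *_, channels, J = slab_jacobian
        row = np.abs(J.values[0])  # 30 mm channel
        deep = mesh.nodes[:, 2] > 25.0
        assert row[deep].sum() < 0.02 * row.sum()

    def test_unknown_optode_rejected(self, slab_jacobian):
        _, _, system, sources, patches, _, _ = slab_jacobian
        with pytest.raises(IndexError, match="unknown optode"):
            jacobian(system, sources, patches, [Channel(5, 0, 30.0)])


class TestTotalNormalizedJacobian:
    def _group(self, channels):
        return ChannelGroup("20-40", 20.0, 40.0, channels)

    def test_peak_magnitude_exactly_one(self, slab_jacobian):
        *_, channels, J = slab_jacobian
        m = total_normalized_jacobian(J, self._group(channels))
        assert np.abs(m.values).max() == 1.0

    def test_single_channel_group_is_scaled_row(self, slab_jacobian):
        *_, channels, J = slab_jacobian
        m = total_normalized_jacobian(J, self._group([channels[1]]))
        expected = J.values[1] / np.abs(J.values[1]).max()
        assert np.allclose(m.values, expected)

    def test_duplicated_channels_leave_map_unchanged(self, slab_jacobian):
        *_, channels, J = slab_jacobian
        once = total_normalized_jacobian(J, self._group(channels))
        twice = total_normalized_jacobian(J, self._group(channels * 2))
        assert np.allclose(once.values, twice.values)

    def test_empty_group_rejected(self, slab_jacobian):
        *_, J = slab_jacobian
        with pytest.raises(ValueError, match="empty"):
            total_normalized_jacobian(J, self._group([]))


class TestBrainScores:
    def test_two_way_summation_agreement(self, slab_jacobian):
        *_, J = slab_jacobian
        nodes = np.array([3, 17, 200, 401])
        scores = brain_sensitivity_scores(J, nodes)
        for i in range(J.num_channels):
            manual = sum(abs(J.values[i, j]) for j in nodes)
            assert scores[i] == pytest.approx(manual, rel=1e-14)

    def test_empty_brain_rejected(self, slab_jacobian):
        *_, J = slab_jacobian
        with pytest.raises(ValueError, match="empty"):
            brain_sensitivity_scores(J, np.array([], dtype=int))

    def test_phantom_without_brain_label_raises(self, small_slab,
                                                slab_jacobian):
        mesh, _ = small_slab  # all elements labeled maternal fat
        *_, J = slab_jacobian
        nodes = mesh.nodes_with_label(TissueLabel.FETAL_BRAIN)
        assert nodes.size == 0
        with pytest.raises(ValueError, match="empty"):
            brain_sensitivity_scores(J, nodes)


class TestRanking:
    def _group(self, channels):
        return ChannelGroup("g", 20.0, 60.0, channels)

    def test_matches_brute_force_sort(self, slab_jacobian):
        *_, channels, J = slab_jacobian
        scores = brain_sensitivity_scores(J, np.arange(50))
        ranking = rank_top_channels(scores, J, self._group(channels), k=3)
        brute = sorted(range(len(channels)),
                       key=lambda i: (-scores[i], channels[i].distance, i))
        assert [e.channel for e in ranking.entries] == [
            J.channels[i] for i in brute[:3]
        ]
        assert [e.score for e in ranking.entries] == sorted(
            (float(s) for s in scores), reverse=True
        )[:3]

    def test_k_larger_than_group_clamps(self, slab_jacobian):
        *_, channels, J = slab_jacobian
        scores = brain_sensitivity_scores(J, np.arange(50))
        ranking = rank_top_channels(scores, J, self._group(channels), k=99)
        assert len(ranking) == len(channels)

    def test_tie_breaks_deterministic(self, slab_jacobian):
        *_, channels, J = slab_jacobian
        scores = np.ones(len(channels))  # forced tie
        r1 = rank_top_channels(scores, J, self._group(channels))
        r2 = rank_top_channels(scores, J, self._group(channels))
        assert [e.channel for e in r1.entries] == [e.channel
                                                   for e in r2.entries]
        dists = [e.channel.distance for e in r1.entries]
        assert dists == sorted(dists)

    def test_invalid_k_rejected(self, slab_jacobian):
        *_, channels, J = slab_jacobian
        with pytest.raises(ValueError, match="k must be"):
            rank_top_channels(np.ones(3), J, self._group(channels), k=0)


@pytest.fixture(scope="module")
def phantom_ranking(mini_phantom):
    import warnings

    props = assign_properties(mini_phantom, 730.0)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*low-scattering.*")
        system = assemble(mini_phantom, props)
    layout = build_probe_layout(mini_phantom, (2, 3), (40.0, 20.0))
    channels = select_channels(layout, 10.0, 60.0)
    groups = group_channels(channels, edges=(10.0, 35.0, 60.0))
    channels = [ch for g in groups for ch in g.channels]
    sampler = SurfaceSampler(mini_phantom)
    sources = [make_source(mini_phantom, props, p)
               for p in layout.source_positions]
    patches = [build_patch(sampler, p)
               for p in layout.detector_positions]
    J = jacobian(system, sources, patches, channels)
    brain = mini_phantom.nodes_with_label(TissueLabel.FETAL_BRAIN)
    scores = brain_sensitivity_scores(J, brain)
    group = next(g for g in groups if g.nm)
    ranking = rank_top_channels(scores, J, group, k=4)
    return mini_phantom, layout, J, brain, ranking


class TestOrientationMap:
    def test_record_count_matches_ranking(self, phantom_ranking):
        mesh, layout, J, brain, ranking = phantom_ranking
        records = channel_orientation_map(ranking, layout, J, brain, mesh)
        assert len(records) == len(ranking)

    def test_peak_node_is_brain_labeled(self, phantom_ranking):
        mesh, layout, J, brain, ranking = phantom_ranking
        records = channel_orientation_map(ranking, layout, J, brain, mesh)
        for rec in records:
            assert rec.peak_brain_node in set(brain.tolist())

    def test_midpoints_lie_over_head(self, phantom_ranking):
        mesh, layout, J, brain, ranking = phantom_ranking
        records = channel_orientation_map(ranking, layout, J, brain, mesh)
        best = records[0]
        assert np.linalg.norm(best.midpoint[:2]) < 25.0
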