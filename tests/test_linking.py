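"""k-NN link graph, gap bridging, component merging and export."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import tifffile

from serialseg import (
    LinkParams,
    PhantomSpec,
    SegmentRecord,
    assign_labels,
    bridge_gaps,
    build_link_graph,
    export_reconstruction,
    generate_phantom,
    merge_components,
)
from serialseg.pipeline import run_chain


def rec(z, centroid, area=50, coords=None):
    y, x = int(centroid[0]), int(centroid[1])
    return SegmentRecord(
        label=0,
        z_index=z,
        area_px=area,
        centroid=centroid,
        major_axis_px=8.0,
        bbox=(y, x, y + 3, x + 3),
        mean_intensity=0.2,
        coords=coords,
    )


def table_from(points, voxel=(30.0, 30.0, 30.0)):
    """points: list of (z, y, x)."""
    return assign_labels([rec(z, (y, x)) for z, y, x in points], {"voxel": voxel})


def brute_force_graph(table, params: LinkParams):
    """Independent oracle: exhaustive all-pairs candidate search."""
    x_nm, y_nm, _ = table.voxel
    g = nx.Graph()
    segs = [s for s in table.segments if not s.pruned_flag]
    for s in segs:
        g.add_node(s.label)
        cands = []
        for o in segs:
            dz = o.z_index - s.z_index
            if not 1 <= dz <= params.max_gap_sections:
                continue
            d = np.hypot((o.centroid[0] - s.centroid[0]) * y_nm, (o.centroid[1] - s.centroid[1]) * x_nm)
            if d <= params.radius_nm:
                cands.append((float(d), o.label, dz))
        cands.sort(key=lambda t: (t[0], t[1]))
        for d, lbl, dz in cands[: params.k]:
            if d <= params.link_cap_nm:
                g.add_edge(s.label, lbl, distance_nm=d, z_gap=dz)
    return g


class TestBuildGraph:
    def test_two_aligned_disks_one_edge(self):
        t = table_from([(0, 50.0, 50.0), (1, 50.0, 50.3)])
        g = build_link_graph(t, LinkParams())
        assert list(g.edges()) == [(1, 2)]

    def test_knn_pools_candidates_across_offsets(self):
        # query at z=0; candidates at in-plane 5 px and 7 px on z+1, 6 px on z+2
        t = table_from([(0, 100.0, 100.0), (1, 100.0, 105.0), (1, 100.0, 107.0), (2, 100.0, 106.0)])
        g = build_link_graph(t, LinkParams(k=2, radius_nm=10_000))
        assert set(g.edges(1)) == {(1, 2), (1, 4)}  # the 5 px and 6 px candidates

    def test_candidate_beyond_radius_never_linked(self):
        t = table_from([(0, 10.0, 10.0), (1, 10.0, 90.0)])  # 80 px * 30 nm = 2400 nm
        g = build_link_graph(t, LinkParams(k=2, radius_nm=2000.0))
        assert g.number_of_edges() == 0

    def test_tie_breaks_toward_smaller_label(self):
        t = table_from([(0, 50.0, 50.0), (1, 50.0, 55.0), (1, 50.0, 45.0)])
        g = build_link_graph(t, LinkParams(k=1, radius_nm=10_000))
        assert set(g.edges(1)) == {(1, 2)}

    def test_per_query_degree_bounded_by_k(self):
        rng = np.random.default_rng(0)
        pts = [(int(z), float(y), float(x)) for z, y, x in zip(rng.integers(0, 5, 60), rng.uniform(0, 100, 60), rng.uniform(0, 100, 60))]
        params = LinkParams(k=2, radius_nm=5000)
        t = table_from(pts)
        # count upward edges initiated per node
        g = build_link_graph(t, params)
        for n in g.nodes():
            z = t.get(n).z_index
            up = [m for m in g.neighbors(n) if t.get(m).z_index > z]
            down = [m for m in g.neighbors(n) if t.get(m).z_index < z]
            # upward links: own k plus possibly dedup-merged reverse picks
            assert len(up) <= 2 * params.k and len(down) <= 60

    def test_pruned_segments_are_excluded(self):
        segs = [rec(0, (50.0, 50.0)), rec(1, (50.0, 50.0))]
        t = assign_labels(segs)
        t.get(2).pruned_flag = True
        g = build_link_graph(t, LinkParams())
        assert g.number_of_edges() == 0 and 2 not in g.nodes()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 120))
        pts = [
            (int(z), float(y), float(x))
            for z, y, x in zip(
                rng.integers(0, 12, n), rng.uniform(0, 300, n), rng.uniform(0, 300, n)
            )
        ]
        t = table_from(pts)
        params = LinkParams(k=2, radius_nm=1500.0, max_gap_sections=3)
        got = build_link_graph(t, params)
        want = brute_force_graph(t, params)
        assert set(map(frozenset, got.edges())) == set(map(frozenset, want.edges()))


class TestBridgeGaps:
    def test_dropout_section_is_bridged(self):
        spec = PhantomSpec(n_sections=12, section_shape=(256, 256), n_processes=2, dropout_sections=(6,), seed=8)
        sections, _ = generate_phantom(spec)
        _, recon, _ = run_chain(sections, equalize=False)
        assert len(recon.components) == 2

    def test_gap_beyond_limit_not_bridged(self):
        t = table_from([(0, 50.0, 50.0), (4, 50.0, 50.0)])
        params = LinkParams(max_gap_sections=3)
        g = bridge_gaps(build_link_graph(t, params, max_gap=1), t, params)
        assert g.number_of_edges() == 0

    def test_adds_only_gap_edges_and_nothing_without_gaps(self):
        t = table_from([(0, 50.0, 50.0), (1, 50.0, 50.0), (2, 50.0, 50.0)])
        params = LinkParams(k=1)
        g1 = build_link_graph(t, params, max_gap=1)
        g2 = bridge_gaps(g1, t, params)
        assert set(g2.edges()) == set(g1.edges())

    def test_reconnects_across_removed_section(self):
        t = table_from([(0, 50.0, 50.0), (2, 50.0, 50.0)])  # section 1 missing
        params = LinkParams()
        g1 = build_link_graph(t, params, max_gap=1)
        assert g1.number_of_edges() == 0
        g2 = bridge_gaps(g1, t, params)
        assert list(g2.edges(data="z_gap")) == [(1, 2, 2)]


class TestMerge:
    def test_chain_and_disjoint_chains(self):
        chain1 = [(z, 50.0, 50.0) for z in range(10)]
        chain2 = [(z, 400.0, 400.0) for z in range(10)]
        t = table_from(chain1 + chain2)
        recon = merge_components(build_link_graph(t, LinkParams()), t)
        assert len(recon.components) == 2
        sizes = sorted(len(v) for v in recon.components.values())
        assert sizes == [10, 10]

    def test_overlapping_same_section_components_merge(self):
        block = np.array(list(itertools.product(range(10, 20), range(10, 20))))
        shifted = block + np.array([0, 1])  # 90% overlap
        a = rec(0, (14.5, 14.5), area=100, coords=block)
        b = rec(0, (14.5, 15.5), area=100, coords=shifted)
        t = assign_labels([a, b])
        recon = merge_components(nx.Graph(), t)
        assert len(recon.components) == 1

    def test_disjoint_same_section_components_stay_separate(self):
        a = rec(0, (10.0, 10.0), coords=np.array([[10, 10]]))
        b = rec(0, (40.0, 40.0), coords=np.array([[40, 40]]))
        t = assign_labels([a, b])
        recon = merge_components(nx.Graph(), t)
        assert len(recon.components) == 2

    def test_partition_covers_all_non_pruned_segments(self, small_chain):
        *_, table, recon, _ = small_chain
        members = [lbl for m in recon.components.values() for lbl in m]
        non_pruned = [s.label for s in table.segments if not s.pruned_flag]
        assert sorted(members) == sorted(non_pruned)

    def test_numbering_by_descending_area(self):
        big = [(z, 50.0, 50.0) for z in range(3)]
        small = [(z, 200.0, 200.0) for z in range(2)]
        segs = [rec(z, (y, x), area=500) for z, y, x in big] + [
            rec(z, (y, x), area=10) for z, y, x in small
        ]
        t = assign_labels(segs)
        recon = merge_components(build_link_graph(t, LinkParams()), t)
        assert recon.summary.iloc[0]["total_area_px"] == 1500
        assert list(recon.summary["component"]) == [1, 2]


class TestExport:
    def test_round_trip_label_stack_and_summary(self, tmp_path, small_chain):
        *_, table, recon, _ = small_chain
        export_reconstruction(recon, tmp_path)
        stack = tifffile.imread(tmp_path / "components.tif")
        assert set(np.unique(stack)) - {0} == set(recon.components)
        summary = pd.read_csv(tmp_path / "summary.csv")
        non_pruned = sum(1 for s in table.segments if not s.pruned_flag)
        assert summary["n_segments"].sum() == non_pruned
        chains = pd.read_csv(tmp_path / "centroid_chains.csv")
        assert set(chains.columns) == {"component", "z_nm", "y_nm", "x_nm"}

    def test_empty_reconstruction_exports_valid_files(self, tmp_path):
        t = assign_labels([])
        recon = merge_components(nx.Graph(), t)
        export_reconstruction(recon, tmp_path)
        assert (tmp_path / "summary.csv").exists()
        assert tifffile.imread(tmp_path / "components.tif").sum() == 0
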