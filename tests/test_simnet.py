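"""Pair scoring rules, max-rule compression, networks, GML and the sweep."""

import io
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from _oracles import components as uf_components
from colnet.region_extract import ExtractionParams, Orientation, Subsequence, add_reversed
from colnet.seq_io import Condition
from colnet.simnet import (
    SimilarityMatrix,
    SweepGrid,
    build_network,
    compress_chain_level,
    compress_collagen_level,
    compress_matrix,
    connected_components,
    count_pairings,
    default_network_thresholds,
    grid_statistics,
    pairwise_similarities,
    pareto_front,
    read_gml,
    run_sweep,
    write_gml,
)
from colnet.synthetic import SynthParams, generate_dataset


def _sub(parent, residues, orientation=Orientation.FORWARD, start=0):
    return Subsequence(
        parent_id=parent, start=start, end=start + len(residues), residues=residues,
        mean_confidence=90.0, orientation=orientation,
        condition=Condition.WHOLE_SEQUENCE, length_param=len(residues),
        conf_threshold=70.0,
    )


def _records(*specs):
    return add_reversed([_sub(p, r, start=s) for p, r, s in specs])


class TestPairwiseSimilarities:
    def test_pair_enumeration_skips_reversed_vs_reversed(self, eisenberg_matrix):
        subs = _records(("A", "GPAFI", 0), ("B", "WLRDE", 0))
        table = pairwise_similarities(subs, eisenberg_matrix)
        # {f1,f2},{f1,r1},{f1,r2},{f2,r1},{f2,r2}; r1-vs-r2 skipped
        assert len(table) == 5
        pairs = set(zip(table["id_a"], table["id_b"]))
        rev = [s.header for s in subs if s.orientation is Orientation.REVERSED]
        assert (rev[0], rev[1]) not in pairs and (rev[1], rev[0]) not in pairs

    def test_skipped_pair_equals_forward_pair(self, eisenberg_matrix):
        f1, r1, f2, r2 = _records(("A", "GPAFI", 0), ("B", "WLRDE", 0))
        from colnet.hydro_align import similarity

        assert similarity(r1.residues, r2.residues, eisenberg_matrix) == pytest.approx(
            similarity(f1.residues, f2.residues, eisenberg_matrix)
        )

    def test_single_forward_record_scores_own_reversal(self, eisenberg_matrix):
        table = pairwise_similarities(_records(("A", "GPAFI", 0)), eisenberg_matrix)
        assert len(table) == 1
        assert set(table[["parent_a", "parent_b"]].iloc[0]) == {"A"}

    def test_empty_set(self, eisenberg_matrix):
        assert len(pairwise_similarities([], eisenberg_matrix)) == 0


def _table(rows):
    return pd.DataFrame(
        rows, columns=["id_a", "id_b", "parent_a", "parent_b", "similarity"]
    )


class TestCompression:
    def test_single_pair(self):
        table = _table([("a1", "b1", "A", "B", 17.3)])
        sm = compress_chain_level(table)
        assert sm.entry("A", "B") == 17.3
        assert sm.entry("A", "A") == 20.0  # self-similarity convention

    def test_max_rule(self):
        table = _table(
            [("a1", "b1", "A", "B", 15.0), ("a2", "b1", "A", "B", 18.0)]
        )
        assert compress_chain_level(table).entry("A", "B") == 18.0

    def test_matches_bruteforce_max(self, rng):
        chains = list("ABCDE")
        rows = []
        rec = 0
        for ca, cb in itertools.combinations_with_replacement(chains, 2):
            for _ in range(rng.integers(1, 4)):
                rows.append((f"r{rec}", f"r{rec + 1}", ca, cb, float(rng.uniform(12, 20))))
                rec += 2
        table = _table(rows)
        sm = compress_chain_level(table)
        for ca, cb in itertools.combinations(chains, 2):
            mask = (
                ((table["parent_a"] == ca) & (table["parent_b"] == cb))
                | ((table["parent_a"] == cb) & (table["parent_b"] == ca))
            )
            assert sm.entry(ca, cb) == table.loc[mask, "similarity"].max()

    def test_collagen_level_single_chain_groups_equal_chain_level(self):
        table = _table([("a1", "b1", "A", "B", 16.0)])
        chain_sm = compress_chain_level(table)
        coll_sm = compress_collagen_level(table, {"A": "COLA", "B": "COLB"})
        assert coll_sm.entry("COLA", "COLB") == chain_sm.entry("A", "B")

    def test_collagen_group_max_over_member_chains(self):
        table = _table(
            [
                ("a1", "d1", "A1", "D", 14.0),
                ("a2", "d1", "A2", "D", 17.0),
                ("a3", "d1", "A3", "D", 13.0),
            ]
        )
        coll = compress_collagen_level(
            table, {"A1": "COL9", "A2": "COL9", "A3": "COL9", "D": "COLD"}
        )
        assert coll.entry("COL9", "COLD") == 17.0

    def test_compression_idempotence_and_group_max(self, eisenberg_matrix):
        subs = _records(("A", "GPAFI", 0), ("B", "WLRDE", 0), ("C", "MNQHC", 0))
        table = pairwise_similarities(subs, eisenberg_matrix)
        chain_sm = compress_chain_level(table)
        identity = compress_matrix(chain_sm, lambda c: c, "chain")
        assert identity.labels == chain_sm.labels
        assert np.allclose(identity.values, chain_sm.values)

        grouping = {"A": "G1", "B": "G1", "C": "G2"}
        via_matrix = compress_matrix(chain_sm, grouping, "collagen")
        via_table = compress_collagen_level(table, grouping)
        assert via_matrix.labels == via_table.labels
        off = ~np.eye(len(via_matrix.labels), dtype=bool)
        assert np.allclose(via_matrix.values[off], via_table.values[off])


class TestCountPairings:
    def test_all_below_range(self):
        sm = SimilarityMatrix("chain", ["A", "B"], np.array([[20.0, 11.0], [11.0, 20.0]]))
        counts = count_pairings(sm)
        assert (counts["n_pairs"] == 0).all()
        assert len(counts) == 32

    def test_direct_count(self):
        values = np.full((3, 3), 20.0)
        values[0, 1] = values[1, 0] = 17.5
        values[0, 2] = values[2, 0] = 13.0
        values[1, 2] = values[2, 1] = 20.0
        sm = SimilarityMatrix("chain", list("ABC"), values)
        counts = count_pairings(sm, [17.5])
        assert counts["n_pairs"].tolist() == [2]

    def test_counts_non_increasing(self, rng):
        n = 6
        values = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = rng.uniform(10, 20, len(iu[0]))
        values[iu] = vals
        values = values + values.T + np.eye(n) * 20
        counts = count_pairings(SimilarityMatrix("chain", [str(i) for i in range(n)], values))
        diffs = np.diff(counts["n_pairs"].to_numpy())
        assert (diffs <= 0).all()
        assert counts["n_pairs"].iloc[0] <= n * (n - 1) // 2


def _toy_matrix():
    labels = ["A", "B", "C", "D"]
    values = np.array(
        [
            [20.0, 18.0, 13.0, 13.0],
            [18.0, 20.0, 13.0, 13.0],
            [13.0, 13.0, 20.0, 19.0],
            [13.0, 13.0, 19.0, 20.0],
        ]
    )
    return SimilarityMatrix("chain", labels, values, params={"length": 30})


class TestNetworks:
    def test_threshold_above_everything_isolates_all(self):
        net = build_network(_toy_matrix(), 20.01)
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 4

    def test_edge_sets_nested_across_thresholds(self):
        sm = _toy_matrix()
        edges = {
            tau: set(map(frozenset, build_network(sm, tau).edges())) for tau in (17.5, 18.0)
        }
        assert edges[18.0] <= edges[17.5]

    def test_planted_cliques_recovered_at_design_threshold(self):
        net = build_network(_toy_matrix(), 17.5)
        parts, n_sub = connected_components(net)
        assert sorted(map(sorted, parts)) == [["A", "B"], ["C", "D"]]
        assert n_sub == 2

    def test_no_self_edges_and_weights_at_least_threshold(self):
        net = build_network(_toy_matrix(), 13.0)
        assert all(a != b for a, b in net.edges())
        assert all(d["weight"] >= 13.0 for _, _, d in net.edges(data=True))

    def test_family_colors_attached(self, default_dataset):
        _, _, family_map = default_dataset
        labels = list(family_map["chain_id"][:4])
        sm = SimilarityMatrix("chain", labels, np.eye(4) * 20.0)
        net = build_network(sm, 17.5, family_map)
        row = family_map.iloc[0]
        attrs = net.nodes[row["chain_id"]]
        assert attrs["family"] == row["family"]
        assert attrs["graphics"]["fill"] == row["color"]

    def test_missing_family_defaults_to_other(self, caplog):
        sm = SimilarityMatrix("chain", ["ZZ"], np.array([[20.0]]))
        fam = pd.DataFrame(columns=["chain_id", "collagen_id", "family", "color"])
        with caplog.at_level("WARNING"):
            net = build_network(sm, 17.5, fam)
        assert net.nodes["ZZ"]["family"] == "other"
        assert net.nodes["ZZ"]["color"] == "#FF0000"


class TestConnectedComponents:
    def test_isolated_nodes_not_subnetworks(self):
        net = nx.Graph()
        net.add_nodes_from(range(5))
        parts, n_sub = connected_components(net)
        assert len(parts) == 5 and n_sub == 0

    def test_one_edge_among_many_nodes(self):
        net = nx.Graph()
        net.add_nodes_from(range(44))
        net.add_edge(0, 1)
        parts, n_sub = connected_components(net)
        assert n_sub == 1
        assert sum(1 for p in parts if len(p) == 1) == 42

    def test_matches_union_find_oracle(self, rng):
        nodes = list(range(30))
        edges = [
            (int(a), int(b))
            for a, b in rng.integers(0, 30, size=(40, 2))
            if a != b
        ]
        net = nx.Graph()
        net.add_nodes_from(nodes)
        net.add_edges_from(edges)
        parts, _ = connected_components(net)
        expected = uf_components(nodes, edges)
        assert sorted(map(sorted, parts)) == sorted(map(sorted, expected))


class TestGml:
    def test_format_contract(self):
        net = build_network(
            SimilarityMatrix("chain", ["A", "B"], np.array([[20.0, 18.0], [18.0, 20.0]])),
            17.5,
        )
        buf = io.StringIO()
        write_gml(net, buf)
        text = buf.getvalue()
        assert "graph [" in text
        assert text.count("node [") == 2
        assert text.count("edge [") == 1

    def test_round_trip(self, tmp_path, default_dataset):
        _, _, family_map = default_dataset
        labels = sorted(family_map["chain_id"][:10])
        values = np.eye(10) * 20.0
        values[0, 1] = values[1, 0] = 18.5
        values[2, 3] = values[3, 2] = 17.75
        net = build_network(SimilarityMatrix("chain", labels, values), 17.5, family_map)
        path = tmp_path / "net.gml"
        write_gml(net, path)
        back = read_gml(path)
        assert set(back.nodes) == set(net.nodes)
        assert set(map(frozenset, back.edges())) == set(map(frozenset, net.edges()))
        for node in net.nodes:
            assert back.nodes[node] == net.nodes[node]
        for a, b in net.edges:
            assert back[a][b]["weight"] == net[a][b]["weight"]
        assert back.graph["threshold"] == net.graph["threshold"]

    def test_empty_network_valid(self):
        net = nx.Graph(level="chain", threshold=17.5)
        buf = io.StringIO()
        write_gml(net, buf)
        back = read_gml(io.StringIO(buf.getvalue()))
        assert back.number_of_nodes() == 0

    def test_malformed_gml_raises(self):
        with pytest.raises(nx.NetworkXError):
            read_gml(io.StringIO("graph [ node [ id ] ]"))


class TestSweep:
    def test_full_grid_cardinality(self):
        grid = SweepGrid()
        assert len(grid.conditions) == 3
        assert len(grid.lengths) == 50
        assert len(grid.conf_thresholds) == 20
        assert len(grid.net_thresholds) == 32
        assert len(grid.levels) == 2
        assert grid.n_networks == 192_000

    def test_inclusive_threshold_grid_has_endpoint(self):
        taus = default_network_thresholds(inclusive=True)
        assert len(taus) == 33 and taus[-1] == 20.0

    def test_reduced_grid_manifest_product(self, tmp_path, default_dataset):
        sequences, _, family_map = default_dataset
        grid = SweepGrid(
            conditions=(Condition.WITHOUT_SIGNAL,),
            lengths=(30, 40),
            conf_thresholds=(70.0, 95.0),
            net_thresholds=(16.0, 17.5, 19.0),
            levels=("chain",),
        )
        manifest = run_sweep(sequences, family_map, grid, tmp_path, dry_run=True)
        assert len(manifest) == 1 * 2 * 2 * 3 * 1

    def test_dry_run_manifest_deterministic(self, tmp_path, default_dataset):
        sequences, _, family_map = default_dataset
        grid = SweepGrid(
            conditions=(Condition.WHOLE_SEQUENCE,),
            lengths=(30,),
            conf_thresholds=(70.0,),
            net_thresholds=(17.5,),
        )
        run_sweep(sequences, family_map, grid, tmp_path / "a", dry_run=True)
        run_sweep(sequences, family_map, grid, tmp_path / "b", dry_run=True)
        assert (tmp_path / "a/manifest.tsv").read_bytes() == (
            tmp_path / "b/manifest.tsv"
        ).read_bytes()

    def test_real_sweep_writes_networks(self, tmp_path, default_dataset, eisenberg_matrix):
        sequences, _, family_map = default_dataset
        subset = sequences[:6]  # two collagens' worth of chains
        grid = SweepGrid(
            conditions=(Condition.WITHOUT_SIGNAL,),
            lengths=(30,),
            conf_thresholds=(70.0,),
            net_thresholds=(16.0, 17.5),
            levels=("chain", "collagen"),
        )
        manifest = run_sweep(
            subset, family_map, grid, tmp_path, matrix=eisenberg_matrix
        )
        assert len(manifest) == 4
        for rel in manifest["path"]:
            net = read_gml(tmp_path / rel)
            assert net.number_of_nodes() > 0


class TestGridStatistics:
    def test_counts_and_sd(self, default_dataset, eisenberg_matrix):
        sequences, _, _ = default_dataset
        subset = sequences[:4]
        grid = SweepGrid(
            conditions=(Condition.WITHOUT_SIGNAL,),
            lengths=(30, 5000),
            conf_thresholds=(70.0,),
        )
        stats = grid_statistics(subset, grid, eisenberg_matrix)
        row30 = stats[stats["length"] == 30].iloc[0]
        assert row30["n_subsequences"] == 8  # one motif window per chain, + reversed
        assert row30["similarity_sd"] > 0
        row_big = stats[stats["length"] == 5000].iloc[0]
        assert row_big["n_subsequences"] == 0
        assert np.isnan(row_big["similarity_sd"])

    def test_sd_matches_direct_formula(self, default_dataset, eisenberg_matrix):
        import statistics

        sequences, _, _ = default_dataset
        subset = sequences[:3]
        grid = SweepGrid(
            conditions=(Condition.WITHOUT_SIGNAL,),
            lengths=(30,),
            conf_thresholds=(70.0,),
        )
        stats = grid_statistics(subset, grid, eisenberg_matrix)
        from colnet.region_extract import extract_regions
        from colnet.seq_io import apply_condition

        subs = [
            s
            for seq in subset
            for s in extract_regions(
                apply_condition(seq, Condition.WITHOUT_SIGNAL),
                ExtractionParams(30, 70.0),
            )
        ]
        table = pairwise_similarities(add_reversed(subs), eisenberg_matrix)
        expected = statistics.pstdev(table["similarity"])
        assert stats["similarity_sd"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_pareto_front_non_dominated(self):
        stats = pd.DataFrame(
            {
                "condition": ["w"] * 3,
                "length": [10, 20, 30],
                "conf_threshold": [70.0] * 3,
                "n_subsequences": [10, 5, 10],
                "similarity_sd": [1.0, 2.0, 2.0],
            }
        )
        marked = pareto_front(stats)
        assert marked["pareto"].tolist() == [False, False, True]
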