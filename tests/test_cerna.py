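"""Triplet rules, network assembly, tripartiteness, and export round-trips."""

import math

import numpy as np
import pytest

from cernaforge.cerna import (
    Triplet,
    TripletParams,
    assemble_network,
    correlate,
    export_network,
    find_triplets,
    import_network,
    summarize_network,
)
from cernaforge.diffexpr import (
    DESets,
    desets_from_truth,
    screen_de,
    test_differential as welch_test,
)
from cernaforge.targetnet import ConsensusInteractions, InteractionTable, combine_sources


def _consensus(edges):
    edges = sorted(edges)
    return ConsensusInteractions(edges=edges,
                                 provenance={e: ("A", "B") for e in edges})


def _desets(up=None, down=None):
    up = up or {}
    down = down or {}
    return DESets(up={c: sorted(v) for c, v in up.items()},
                  down={c: sorted(v) for c, v in down.items()})


class TestCorrelate:
    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        assert correlate(x, -2 * x + 1) == pytest.approx(-1.0)

    def test_identity_both_methods(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        assert correlate(x, x, "pearson") == pytest.approx(1.0)
        assert correlate(x, x, "spearman") == pytest.approx(1.0)

    def test_spearman_hand_ranked(self):
        assert correlate([1, 2, 3, 4], [2, 1, 4, 3], "spearman") == pytest.approx(0.6)

    def test_zero_variance_is_nan(self):
        assert math.isnan(correlate([1, 1, 1], [1, 2, 3]))

    @pytest.mark.parametrize("x,y,err", [
        ([1, 2], [1, 2], "at least 3"),
        ([1, 2, 3], [1, 2], "equal length"),
        ([1, 2, np.inf], [1, 2, 3], "non-finite"),
    ])
    def test_invalid_inputs(self, x, y, err):
        with pytest.raises(ValueError, match=err):
            correlate(x, y)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="method"):
            correlate([1, 2, 3], [3, 2, 1], "kendall")


class TestFindTriplets:
    DS = staticmethod(lambda: _desets(
        up={"lncRNA": ["L1"], "mRNA": ["G1"]},
        down={"miRNA": ["M1"]},
    ))

    def test_direction_coherent_triplet_found(self):
        cons = _consensus([("lnc_mir", "L1", "M1"), ("mir_mrna", "M1", "G1")])
        out = find_triplets(self.DS(), cons)
        assert [(t.lnc_id, t.mir_id, t.mrna_id) for t in out] == [("L1", "M1", "G1")]
        assert out[0].evidence == (("A", "B"), ("A", "B"))

    def test_same_direction_pair_excluded(self):
        ds = _desets(up={"lncRNA": ["L1"], "miRNA": ["M1"], "mRNA": ["G1"]})
        cons = _consensus([("lnc_mir", "L1", "M1"), ("mir_mrna", "M1", "G1")])
        assert find_triplets(ds, cons) == []

    def test_missing_consensus_edge_blocks_triplet(self):
        cons = _consensus([("mir_mrna", "M1", "G1")])  # lnc edge absent
        assert find_triplets(self.DS(), cons) == []

    def test_non_de_mirna_blocks_triplet(self):
        ds = _desets(up={"lncRNA": ["L1"], "mRNA": ["G1"]})  # M1 not DE
        cons = _consensus([("lnc_mir", "L1", "M1"), ("mir_mrna", "M1", "G1")])
        assert find_triplets(ds, cons) == []

    def test_row_order_invariance(self):
        edges = [("lnc_mir", "L1", "M1"), ("mir_mrna", "M1", "G1")]
        a = find_triplets(self.DS(), _consensus(edges))
        b = find_triplets(self.DS(), _consensus(list(reversed(edges))))
        assert a == b

    def test_correlation_mode_needs_enough_samples(self, bundle):
        cons = _consensus([("lnc_mir", "L1", "M1")])
        params = TripletParams(mode="correlation", min_samples=10)
        with pytest.raises(ValueError, match="direction"):
            find_triplets(self.DS(), cons, expr=bundle, params=params)

    def test_correlation_mode_on_anticorrelated_fixture(self, noisefree_world):
        # 3+3 samples with min_samples lowered: planted DE features are
        # strongly anticorrelated with their miRNA because the fold change
        # dominates the dispersion
        cfg, b, truth = noisefree_world
        tables = [InteractionTable.from_frame(df, source=s)
                  for s, df in truth.source_tables.items()]
        cons = combine_sources(tables)
        desets = screen_de(welch_test(b))
        params = TripletParams(mode="correlation", min_samples=6, r_max=-0.7)
        got = {(t.lnc_id, t.mir_id, t.mrna_id)
               for t in find_triplets(desets, cons, expr=b, params=params)}
        assert got <= set(truth.planted_triplets)
        for t in find_triplets(desets, cons, expr=b, params=params):
            assert t.r_lnc_mir < -0.7 and t.r_mir_mrna < -0.7

    def test_noise_free_recovery_is_exact(self, noisefree_world):
        # DE sets from the generator's truth labels, so the only question is
        # whether the triplet rule reconstructs what was planted
        cfg, b, truth = noisefree_world
        tables = [InteractionTable.from_frame(df, source=s)
                  for s, df in truth.source_tables.items()]
        cons = combine_sources(tables)
        desets = desets_from_truth(b)
        got = {(t.lnc_id, t.mir_id, t.mrna_id) for t in find_triplets(desets, cons)}
        assert got == set(truth.planted_triplets)


def _trip(l, m, g):
    return Triplet(lnc_id=l, mir_id=m, mrna_id=g)


class TestAssembleAndSummarize:
    def test_two_triplets_sharing_mirna(self):
        net = assemble_network([_trip("L1", "M1", "G1"), _trip("L2", "M1", "G2")])
        assert len(net.nodes) == 5
        assert len(net.edges) == 4
        summary = summarize_network(net)
        assert summary["by_role"] == {"lncRNA": 2, "miRNA": 1, "mRNA": 2}
        assert summary["degree"]["M1"] == 4

    def test_empty_triplets_empty_network(self):
        net = assemble_network([])
        assert net.nodes == {} and net.edges == []
        summary = summarize_network(net)
        assert summary["n_nodes"] == summary["n_edges"] == 0
        assert summary["by_role"] == {"lncRNA": 0, "miRNA": 0, "mRNA": 0}

    def test_single_triplet_star(self):
        summary = summarize_network(assemble_network([_trip("L1", "M1", "G1")]))
        assert summary["degree"] == {"G1": 1, "L1": 1, "M1": 2}

    def test_role_collision_rejected(self):
        with pytest.raises(ValueError, match="X1"):
            assemble_network([_trip("X1", "M1", "G1"), _trip("L2", "X1", "G2")])

    def test_directions_attached_from_desets(self):
        ds = _desets(up={"lncRNA": ["L1"], "mRNA": ["G1"]}, down={"miRNA": ["M1"]})
        net = assemble_network([_trip("L1", "M1", "G1")], desets=ds)
        assert net.nodes["L1"] == ("lncRNA", "up")
        assert net.nodes["M1"] == ("miRNA", "down")

    def test_tripartiteness_on_synthetic_world(self, noisefree_world):
        cfg, b, truth = noisefree_world
        net = assemble_network([_trip(*t) for t in truth.planted_triplets])
        for s, t, kind in net.edges:
            if kind == "lnc_mir":
                assert net.nodes[s][0] == "lncRNA" and net.nodes[t][0] == "miRNA"
            else:
                assert net.nodes[s][0] == "miRNA" and net.nodes[t][0] == "mRNA"
        for fid in net.nodes:
            assert any(fid in (t.lnc_id, t.mir_id, t.mrna_id) for t in net.triplets)


class TestExport:
    def test_sif_has_one_row_per_edge(self, tmp_path):
        net = assemble_network([_trip("L1", "M1", "G1")])
        p = export_network(net, tmp_path / "n.sif", "sif")
        rows = p.read_text().splitlines()
        assert rows == ["L1\tlnc_mir\tM1", "M1\tmir_mrna\tG1"]

    def test_graphml_round_trip(self, tmp_path):
        ds = _desets(up={"lncRNA": ["L1", "L2"], "mRNA": ["G1"]},
                     down={"miRNA": ["M1"], "mRNA": ["G2"]})
        net = assemble_network([_trip("L1", "M1", "G1"), _trip("L2", "M1", "G2")],
                               desets=ds)
        p = export_network(net, tmp_path / "n.graphml", "graphml")
        back = import_network(p, "graphml")
        assert back.nodes == net.nodes
        assert back.edges == net.edges

    def test_tab_in_node_id_rejected(self, tmp_path):
        net = assemble_network([_trip("L\t1", "M1", "G1")])
        with pytest.raises(ValueError, match="sanitize"):
            export_network(net, tmp_path / "n.sif", "sif")

    def test_unknown_format_rejected(self, tmp_path):
        net = assemble_network([])
        with pytest.raises(ValueError, match="format"):
            export_network(net, tmp_path / "n.xyz", "xyz")
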